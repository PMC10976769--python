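"""Family distribution statistics across species and clades.

The miR166 family is one of the deepest-conserved plant miRNA families,
present from mosses to eudicots.  A recurring observation is that in
older lineages (bryophytes, ferns, gymnosperms) each precursor yields a
single retained mature strand, while many angiosperms retain more
mature strands than they have precursor loci — both arms of some
hairpins are processed and kept.  This module summarises per-species
precursor/mature counts to make that comparison explicit.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .io import ParseError, read_tsv, write_tsv
from .records import DIVISIONS, CensusRecord

_REQUIRED = (
    "species_name",
    "abbreviation",
    "division",
    "clade_family",
    "monocot_dicot",
    "n_precursor",
    "n_mature",
)


def packaged_census_path() -> Path:
    """Path of the bundled cross-species miR166 census table."""
    return Path(resources.files("mirfam.data") / "mir166_census.tsv")


def packaged_alfalfa_path() -> Path:
    """Path of the bundled alfalfa-only census row (separate fixture,
    excluded from cross-species summaries by default)."""
    return Path(resources.files("mirfam.data") / "alfalfa_census.tsv")


def load_census(path: str | Path | None = None) -> list[CensusRecord]:
    """Load a census TSV into records; defaults to the packaged table.

    Rejects negative counts, unknown divisions and duplicate species
    abbreviations.
    """
    if path is None:
        path = packaged_census_path()
    df = read_tsv(path, required=_REQUIRED)
    records: list[CensusRecord] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.division not in DIVISIONS:
            raise ParseError(f"unknown division {row.division!r} for {row.abbreviation}")
        if row.abbreviation in seen:
            raise ParseError(f"duplicate abbreviation {row.abbreviation!r}")
        seen.add(row.abbreviation)
        records.append(
            CensusRecord(
                species_name=row.species_name,
                abbreviation=row.abbreviation,
                division=row.division,
                clade_family=row.clade_family,
                monocot_dicot=row.monocot_dicot,
                n_precursor=int(row.n_precursor),
                n_mature=int(row.n_mature),
            )
        )
    return records


@dataclass
class CladeSummary:
    """Counts of mature-vs-precursor relationships within one division.

    ``n_mature_gt_pre`` + ``n_mature_eq_pre`` + ``n_mature_lt_pre``
    always equals ``n_species``.  ``max_species``/``min_species`` list
    every species tied at the extreme mature count, sorted
    lexicographically by abbreviation.
    """

    division: str
    n_species: int
    n_mature_gt_pre: int
    n_mature_eq_pre: int
    n_mature_lt_pre: int
    max_species: list[str]
    min_species: list[str]
    total_precursor: int
    total_mature: int


def clade_summary(records: list[CensusRecord], division: str) -> CladeSummary:
    """Summarise one division of the census.

    Raises ``ValueError`` for an unknown division or a division with no
    records.
    """
    if division not in DIVISIONS:
        raise ValueError(f"unknown division {division!r}; expected one of {DIVISIONS}")
    rows = [r for r in records if r.division == division]
    if not rows:
        raise ValueError(f"no census records for division {division!r}")
    gt = sum(1 for r in rows if r.n_mature > r.n_precursor)
    eq = sum(1 for r in rows if r.n_mature == r.n_precursor)
    lt = sum(1 for r in rows if r.n_mature < r.n_precursor)
    hi = max(r.n_mature for r in rows)
    lo = min(r.n_mature for r in rows)
    return CladeSummary(
        division=division,
        n_species=len(rows),
        n_mature_gt_pre=gt,
        n_mature_eq_pre=eq,
        n_mature_lt_pre=lt,
        max_species=sorted(r.abbreviation for r in rows if r.n_mature == hi),
        min_species=sorted(r.abbreviation for r in rows if r.n_mature == lo),
        total_precursor=sum(r.n_precursor for r in rows),
        total_mature=sum(r.n_mature for r in rows),
    )


def summary_table(records: list[CensusRecord]) -> pd.DataFrame:
    """One summary row per division present in the census."""
    rows = []
    for div in DIVISIONS:
        if not any(r.division == div for r in records):
            continue
        s = clade_summary(records, div)
        rows.append(
            {
                "division": s.division,
                "n_species": s.n_species,
                "n_mature_gt_pre": s.n_mature_gt_pre,
                "n_mature_eq_pre": s.n_mature_eq_pre,
                "n_mature_lt_pre": s.n_mature_lt_pre,
                "max_species": ",".join(s.max_species),
                "min_species": ",".join(s.min_species),
                "total_precursor": s.total_precursor,
                "total_mature": s.total_mature,
            }
        )
    return pd.DataFrame(rows)


def write_summary(records: list[CensusRecord], path: str | Path) -> None:
    write_tsv(summary_table(records), path)
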