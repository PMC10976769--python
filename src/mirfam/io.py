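"""Readers and writers for the on-disk formats used by the pipeline.

FASTA goes through Biopython, Newick through dendropy, tabular data
through pandas TSV (tab-separated, one header row).  All of them
round-trip: ``read(write(x)) == x``.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import Arm, MirSeqRecord, SeqKind

logger = logging.getLogger("mirfam")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(
    path: str | Path,
    kind: SeqKind = SeqKind.MATURE,
    species_code: str = "",
) -> list[MirSeqRecord]:
    """Read a FASTA file into :class:`MirSeqRecord` objects.

    DNA input (T) is normalized to U; entry order is preserved.  An
    empty file yields an empty list with a warning.  Malformed entries
    raise :class:`ParseError` naming the offending record.
    """
    path = Path(path)
    records: list[MirSeqRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if not rec.id:
            raise ParseError(f"{path}: entry {i} has an empty header")
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate id {rec.id!r} (entry {i})")
        seen.add(rec.id)
        try:
            records.append(
                MirSeqRecord(
                    id=rec.id,
                    sequence=str(rec.seq),
                    kind=kind,
                    species_code=species_code or _species_from_id(rec.id),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: entry {i} ({rec.id}): {exc}") from exc
    if not records:
        logger.warning("FASTA file %s contained no sequences", path)
    return records


def _species_from_id(seq_id: str) -> str:
    """Extract a miRBase-style species prefix ('mtr-miR166a' -> 'mtr')."""
    head = seq_id.split("-", 1)[0].lower()
    return head if 2 <= len(head) <= 4 and head.isalpha() else ""


def write_fasta(records: Iterable[MirSeqRecord], path: str | Path) -> None:
    """Write records as FASTA (RNA alphabet, 60-column wrap)."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write a tree as Newick with branch lengths and integer bootstrap
    support stored as internal node labels.

    Raises ``ValueError`` for duplicate or missing leaf names or a tree
    with fewer than two leaves.
    """
    leaves = [lf.taxon.label if lf.taxon else None for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")
    if None in leaves or len(set(leaves)) != len(leaves):
        raise ValueError("leaf names must be present and unique")
    Path(path).write_text(newick_string(tree) + "\n")


def newick_string(tree: dendropy.Tree) -> str:
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()
    return s


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree; internal node labels are kept as-is (they
    carry bootstrap supports for trees written by this package)."""
    return dendropy.Tree.get(
        path=str(path),
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_tsv(path: str | Path, required: Sequence[str] = ()) -> pd.DataFrame:
    """Read a tab-separated table with a header row; '#'-prefixed lines
    before the header are treated as comments."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, header_note: str | None = None) -> None:
    """Write a TSV table; optional '#' comment line documents the
    coordinate convention (1-based inclusive) for position columns."""
    buf = _io.StringIO()
    if header_note:
        buf.write(f"# {header_note}\n")
    df.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())
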