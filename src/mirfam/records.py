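"""Core domain records shared across the pipeline stages.

All sequences are held internally as RNA (``ACGU``); DNA input is
normalized on read.  Coordinates in every record and on-disk table are
1-based inclusive, matching the convention of degradome cleavage-site
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


class SeqKind(str, Enum):
    PRECURSOR = "precursor"
    MATURE = "mature"


class Arm(str, Enum):
    FIVE_PRIME = "5p"
    THREE_PRIME = "3p"
    UNKNOWN = "unknown"


def normalize_rna(seq: str) -> str:
    """Uppercase a nucleotide string and convert T to U.

    Raises ``ValueError`` on ambiguity codes or other non-ACGU(T)
    characters — ambiguous bases are rejected rather than guessed.
    """
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-ACGU characters in sequence: {sorted(bad)}")
    if not s:
        raise ValueError("empty sequence")
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA string (A<->U, G<->C)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MirSeqRecord:
    """One precursor or mature miRNA sequence.

    ``species_code`` is the 3-4 letter miRBase-style abbreviation
    (e.g. ``mtr`` for Medicago truncatula); ``arm`` records which
    precursor arm a mature strand derives from when known.
    """

    id: str
    sequence: str
    species_code: str = ""
    kind: SeqKind = SeqKind.MATURE
    arm: Arm = Arm.UNKNOWN

    def __post_init__(self) -> None:
        self.sequence = normalize_rna(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RunConfig:
    """Pipeline configuration.

    A fixed ``seed`` makes every stochastic stage byte-reproducible.
    ``duplex_score_threshold`` is the maximum penalty (points) for a
    reported miRNA/target duplex; ``alpha`` the significance level for
    the expression letter display.
    """

    seed: int = 0
    bootstrap_replicates: int = 1000
    energy_param_set: str = "turner-like"
    duplex_score_threshold: float = 5.0
    alpha: float = 0.05
    distance_model: str = "p-distance"  # or "jukes-cantor"
    allow_lonely_pairs: bool = False

    def __post_init__(self) -> None:
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class CensusRecord:
    """Per-species precursor/mature counts with taxonomic labels."""

    species_name: str
    abbreviation: str
    division: str  # bryophyta | fern | gymnosperm | angiosperm
    clade_family: str
    monocot_dicot: str  # monocot | dicot | base | na
    n_precursor: int
    n_mature: int

    def __post_init__(self) -> None:
        if self.n_precursor < 0 or self.n_mature < 0:
            raise ValueError(
                f"negative count for {self.abbreviation}: "
                f"{self.n_precursor}/{self.n_mature}"
            )


DIVISIONS = ("bryophyta", "fern", "gymnosperm", "angiosperm")
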