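"""Multiple-sequence-alignment container shared by the conservation and
phylogenetics stages."""

from __future__ import annotations

from dataclasses import dataclass

ALN_ALPHABET = frozenset("ACGU-")
GAP = "-"


@dataclass
class MsAlignment:
    """A multiple alignment of RNA sequences.

    ``rows`` holds ``(id, gapped_sequence)`` pairs; every gapped
    sequence has the same length and is drawn from ``{A,C,G,U,-}``.
    """

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        for rid, s in self.rows:
            bad = set(s) - ALN_ALPHABET
            if bad:
                raise ValueError(f"row {rid!r} has invalid symbols {sorted(bad)}")
        ids = [rid for rid, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids in alignment")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def column(self, j: int) -> str:
        """Column ``j`` (0-based) as a string, one symbol per row."""
        return "".join(s[j] for _, s in self.rows)

    def ungapped(self, rid: str) -> str:
        for r, s in self.rows:
            if r == rid:
                return s.replace(GAP, "")
        raise KeyError(rid)
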