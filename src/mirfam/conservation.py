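"""Sequence conservation analysis: pairwise identity, progressive
multiple alignment, consensus positions, and per-column information
content.

Mature miR166 strands are among the most conserved sequences in plant
genomes; the family signature includes an invariant G at position 9, C
at 11 and U at 12 and 16 of the 3p mature strand.  This module
quantifies that conservation: a global-alignment percent identity for
sequence pairs, a guide-tree progressive aligner for small families,
and a sequence-logo-style information-content profile
(IC = 2 - Shannon entropy, bits per column).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import GAP, MsAlignment
from .io import write_tsv
from .records import MirSeqRecord, normalize_rna

BASES = "ACGU"

MATCH = 1.0
MISMATCH = 0.0
GAP_PENALTY = -1.0


# ---------------------------------------------------------------------------
# Pairwise identity
# ---------------------------------------------------------------------------

def _nw_align(a: str, b: str) -> tuple[str, str]:
    """Global Needleman-Wunsch alignment (match +1, mismatch 0, linear
    gap -1).  Ties prefer diagonal, then gap in ``b``, so the result is
    deterministic."""
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = GAP_PENALTY * np.arange(n + 1)
    score[0, :] = GAP_PENALTY * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1, j - 1] + (MATCH if a[i - 1] == b[j - 1] else MISMATCH)
            score[i, j] = max(diag, score[i - 1, j] + GAP_PENALTY,
                              score[i, j - 1] + GAP_PENALTY)
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            diag = score[i - 1, j - 1] + (MATCH if a[i - 1] == b[j - 1] else MISMATCH)
            if np.isclose(score[i, j], diag):
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i, j = i - 1, j - 1
                continue
        if i > 0 and np.isclose(score[i, j], score[i - 1, j] + GAP_PENALTY):
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity of two sequences under a global alignment.

    identity = matches / aligned columns x 100; gap columns count in
    the denominator.  Symmetric, and 100 for identical sequences.
    """
    a = normalize_rna(a)
    b = normalize_rna(b)
    ga, gb = _nw_align(a, b)
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != GAP)
    return 100.0 * matches / len(ga)


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------

def _profile_align(pa: list[str], pb: list[str]) -> tuple[list[str], list[str]]:
    """Align two profiles (lists of equal-length gapped rows) with
    sum-of-pairs scoring over the same match/mismatch/gap scheme."""
    n, m = len(pa[0]), len(pb[0])
    cols_a = ["".join(r[i] for r in pa) for i in range(n)]
    cols_b = ["".join(r[j] for r in pb) for j in range(m)]

    def col_score(ca: str, cb: str) -> float:
        s = 0.0
        for x in ca:
            for y in cb:
                if x == GAP or y == GAP:
                    continue
                s += MATCH if x == y else MISMATCH
        return s / (len(ca) * len(cb))

    score = np.zeros((n + 1, m + 1))
    score[:, 0] = GAP_PENALTY * np.arange(n + 1)
    score[0, :] = GAP_PENALTY * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            score[i, j] = max(
                score[i - 1, j - 1] + col_score(cols_a[i - 1], cols_b[j - 1]),
                score[i - 1, j] + GAP_PENALTY,
                score[i, j - 1] + GAP_PENALTY,
            )
    out_a: list[list[str]] = [[] for _ in pa]
    out_b: list[list[str]] = [[] for _ in pb]
    i, j = n, m
    gap_a = GAP * len(pa)
    gap_b = GAP * len(pb)
    while i > 0 or j > 0:
        if i > 0 and j > 0 and np.isclose(
            score[i, j], score[i - 1, j - 1] + col_score(cols_a[i - 1], cols_b[j - 1])
        ):
            ca, cb = cols_a[i - 1], cols_b[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and np.isclose(score[i, j], score[i - 1, j] + GAP_PENALTY):
            ca, cb = cols_a[i - 1], gap_b
            i -= 1
        else:
            ca, cb = gap_a, cols_b[j - 1]
            j -= 1
        for r, x in zip(out_a, ca):
            r.append(x)
        for r, y in zip(out_b, cb):
            r.append(y)
    rows_a = ["".join(reversed(r)) for r in out_a]
    rows_b = ["".join(reversed(r)) for r in out_b]
    return rows_a, rows_b


def progressive_align(records: list[MirSeqRecord]) -> MsAlignment:
    """Progressive multiple alignment guided by a Neighbor-Joining tree
    of pairwise-identity distances (d = 100 - %identity).

    Every input residue is preserved; the alignment has at least as
    many columns as the longest input.
    """
    if len(records) < 2:
        raise ValueError("progressive_align needs at least 2 records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    if len(records) == 2:
        ga, gb = _nw_align(records[0].sequence, records[1].sequence)
        return MsAlignment(rows=[(ids[0], ga), (ids[1], gb)])

    from .phylo import DistanceMatrix, neighbor_joining  # local import: avoid cycle

    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 100.0 - pairwise_identity(
                records[i].sequence, records[j].sequence
            )
    guide = neighbor_joining(DistanceMatrix(taxa=ids, d=d))

    by_id = {r.id: r.sequence for r in records}

    def merge(node) -> tuple[list[str], list[str]]:
        """Postorder merge; returns (row ids, gapped rows)."""
        if not node.children:
            return [node.label], [by_id[node.label]]
        sub = [merge(c) for c in node.children]
        acc_ids, acc_rows = sub[0]
        for nxt_ids, nxt_rows in sub[1:]:
            acc_rows, nxt_rows = _profile_align(acc_rows, nxt_rows)
            acc_ids = acc_ids + nxt_ids
            acc_rows = acc_rows + nxt_rows
        return acc_ids, acc_rows

    merged_ids, merged_rows = merge(guide.root)
    order = {rid: k for k, rid in enumerate(ids)}
    rows = sorted(zip(merged_ids, merged_rows), key=lambda t: order[t[0]])
    return MsAlignment(rows=list(rows))


# ---------------------------------------------------------------------------
# Consensus and information content
# ---------------------------------------------------------------------------

@dataclass
class ConsensusProfile:
    """Per-column base frequencies, information content and consensus.

    ``frequencies`` is (n_columns, 4) over A,C,G,U computed over
    non-gap rows; ``information`` is 2 - H (bits, in [0, 2]);
    ``all_gap`` flags columns with no residues (IC recorded as 0).
    """

    frequencies: np.ndarray
    information: np.ndarray
    consensus: list[str]
    dominance: np.ndarray
    all_gap: np.ndarray


def column_information(
    aln: MsAlignment, small_sample_correction: bool = False
) -> ConsensusProfile:
    """Sequence-logo information content per alignment column.

    Gaps are excluded from the frequency denominators.  The optional
    small-sample correction subtracts e(n) = 3 / (2 ln2 n) from each
    column's IC (clipped at 0), with n the number of non-gap rows.
    """
    n_cols = aln.n_columns
    freqs = np.zeros((n_cols, 4))
    ic = np.zeros(n_cols)
    cons: list[str] = []
    dom = np.zeros(n_cols)
    all_gap = np.zeros(n_cols, dtype=bool)
    for j in range(n_cols):
        col = aln.column(j)
        counts = np.array([col.count(b) for b in BASES], dtype=float)
        total = counts.sum()
        if total == 0:
            all_gap[j] = True
            cons.append(GAP)
            continue
        p = counts / total
        freqs[j] = p
        nz = p[p > 0]
        entropy = -np.sum(nz * np.log2(nz))
        val = 2.0 - entropy
        if small_sample_correction:
            val -= 3.0 / (2.0 * np.log(2) * total)
        ic[j] = max(val, 0.0)
        k = int(np.argmax(p))
        cons.append(BASES[k])
        dom[j] = p[k]
    return ConsensusProfile(
        frequencies=freqs, information=ic, consensus=cons,
        dominance=dom, all_gap=all_gap,
    )


def consensus_positions(
    aln: MsAlignment, dominance_threshold: float = 0.9
) -> list[tuple[int, str]]:
    """1-based alignment columns whose dominant base reaches the given
    frequency threshold, with the base.  Threshold must be in (0.5, 1]
    so the dominant base is unique."""
    if not 0.5 < dominance_threshold <= 1.0:
        raise ValueError("dominance_threshold must lie in (0.5, 1]")
    prof = column_information(aln)
    out: list[tuple[int, str]] = []
    for j in range(aln.n_columns):
        if prof.all_gap[j]:
            continue
        if prof.dominance[j] >= dominance_threshold:
            out.append((j + 1, prof.consensus[j]))
    return out


def profile_table(aln: MsAlignment) -> pd.DataFrame:
    """Per-column profile as a DataFrame (column, A/C/G/U freq, IC,
    consensus) ready for TSV export."""
    prof = column_information(aln)
    return pd.DataFrame(
        {
            "column": np.arange(1, aln.n_columns + 1),
            "A": prof.frequencies[:, 0],
            "C": prof.frequencies[:, 1],
            "G": prof.frequencies[:, 2],
            "U": prof.frequencies[:, 3],
            "information_bits": prof.information,
            "consensus": prof.consensus,
        }
    )


def write_profile(aln: MsAlignment, path: str | Path) -> None:
    write_tsv(profile_table(aln), path, header_note="columns are 1-based")
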