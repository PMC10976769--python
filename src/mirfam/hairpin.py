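"""Minimum-free-energy secondary-structure prediction for miRNA
precursors, stem-loop validation, and mature-arm localization.

The folder is a Zuker-style dynamic program over the nearest-neighbor
model in :mod:`mirfam.energy`: hairpin, bulge/internal and multibranch
loops, with G:U wobble pairs allowed everywhere, a 3-nt minimum
hairpin loop, and (by default) no lonely pairs — every helix must hold
at least two stacked pairs, as in mfold-style folders.  The global
minimum is exact within those constraints, deterministic, and
certified against exhaustive structure enumeration in the test suite.

A plant pre-miRNA should fold into a single long hairpin; the mature
strand sits on the 5' or the 3' arm of that hairpin, which is what
:func:`locate_arm` reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import energy as en
from .io import write_tsv
from .records import Arm, MirSeqRecord, normalize_rna

INF = math.inf
_EPS = 1e-7


@dataclass
class FoldResult:
    """MFE structure of one sequence.

    ``pairs`` are 1-based (i, j) with i < j; ``dot_bracket`` is the
    equivalent Vienna string; ``delta_G`` is the free energy in
    kcal/mol (0 for the open chain); ``loop_span`` is the 1-based
    inclusive span of the terminal loop when the structure is a single
    hairpin, else ``None``.
    """

    id: str
    sequence: str
    pairs: list[tuple[int, int]]
    delta_G: float
    dot_bracket: str = field(init=False)
    n_hairpins: int = field(init=False)
    loop_span: tuple[int, int] | None = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        db = ["."] * n
        for i, j in self.pairs:
            db[i - 1] = "("
            db[j - 1] = ")"
        self.dot_bracket = "".join(db)
        closing = hairpin_closing_pairs(self.pairs)
        self.n_hairpins = len(closing)
        if len(closing) == 1:
            i, j = closing[0]
            self.loop_span = (i + 1, j - 1)
        else:
            self.loop_span = None


def hairpin_closing_pairs(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Pairs that close a terminal (hairpin) loop: no pair nested
    strictly inside them."""
    return sorted(
        (i, j)
        for i, j in pairs
        if not any(i < p and q < j for p, q in pairs)
    )


def pairs_from_dot_bracket(db: str) -> list[tuple[int, int]]:
    """Parse a Vienna dot-bracket string into 1-based pairs."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for k, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(k)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {k}")
            pairs.append((stack.pop(), k))
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket symbol {ch!r} at position {k}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return sorted(pairs)


# ---------------------------------------------------------------------------
# The dynamic program
# ---------------------------------------------------------------------------

def fold_mfe(
    seq: str,
    seq_id: str = "",
    params: str = "turner-like",
    allow_lonely_pairs: bool = False,
) -> FoldResult:
    """Global MFE structure of an RNA sequence (length >= 10).

    Recursions (0-based indices; ``hmin`` = 2 unless lonely pairs are
    allowed):

    * ``V(i,j)``: best energy with (i,j) the *outermost* pair of a
      helix of ``h >= hmin`` contiguous stacked pairs, both helix-end
      penalties included, followed by the loop ``L`` the helix closes.
    * ``L(k,l)``: loop closed by helix-inner pair (k,l) — hairpin,
      bulge/internal loop (size capped at 30 nt) to the next helix, or
      a multibranch loop.
    * ``WM/WM2``: multiloop segment energies with >= 1 / >= 2 branches.
    * ``W(k)``: external loop over the first ``k`` nt.
    """
    if params not in en.PARAM_SETS:
        raise ValueError(f"unknown energy parameter set {params!r}")
    seq = normalize_rna(seq)
    n = len(seq)
    if n < 10:
        raise ValueError("sequence must be at least 10 nt")
    hmin = 1 if allow_lonely_pairs else 2

    pairable = [
        [
            j - i > en.MIN_HAIRPIN and en.can_pair(seq[i], seq[j])
            for j in range(n)
        ]
        for i in range(n)
    ]
    pair_str = [[seq[i] + seq[j] for j in range(n)] for i in range(n)]

    V = [[INF] * n for _ in range(n)]
    L = [[INF] * n for _ in range(n)]
    WM = [[INF] * n for _ in range(n)]
    WM2 = [[INF] * n for _ in range(n)]

    def compute_L(i: int, j: int) -> float:
        best = en.hairpin_energy(j - i - 1)
        # bulge / internal loop to the next helix
        for p in range(i + 1, j - 1):
            n1 = p - i - 1
            if n1 > en.MAX_INTERIOR:
                break
            row = V[p]
            qmin = max(p + en.MIN_HAIRPIN + 1, j - 1 - (en.MAX_INTERIOR - n1))
            for q in range(qmin, j):
                if n1 == 0 and q == j - 1:
                    continue  # that is a stack, handled by the helix run
                v = row[q]
                if v < INF:
                    e = en.internal_energy(n1, j - q - 1, pair_str[i][j],
                                           pair_str[p][q]) + v
                    if e < best:
                        best = e
        # multibranch loop
        if WM2[i + 1][j - 1] < INF:
            e = en.ML_CLOSING + WM2[i + 1][j - 1]
            if e < best:
                best = e
        return best

    def compute_V(i: int, j: int) -> float:
        best = INF
        cum = 0.0
        term_out = en.terminal_penalty(pair_str[i][j])
        h = 1
        while True:
            ii, jj = i + h - 1, j - h + 1
            if jj - ii <= en.MIN_HAIRPIN or not pairable[ii][jj]:
                break
            if h >= hmin and L[ii][jj] < INF:
                e = cum + term_out + en.terminal_penalty(pair_str[ii][jj]) + L[ii][jj]
                if e < best:
                    best = e
            # extend the helix by one more stacked pair
            ni, nj = ii + 1, jj - 1
            if nj - ni <= en.MIN_HAIRPIN or not pairable[ni][nj]:
                break
            cum += en.stack_energy(pair_str[ii][jj], pair_str[ni][nj])
            h += 1
        return best

    for span in range(en.MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            if pairable[i][j]:
                L[i][j] = compute_L(i, j)
                V[i][j] = compute_V(i, j)
            # WM
            best = WM[i + 1][j] + en.ML_UNPAIRED if i + 1 <= j else INF
            alt = WM[i][j - 1] + en.ML_UNPAIRED if i <= j - 1 else INF
            if alt < best:
                best = alt
            if V[i][j] < INF:
                alt = V[i][j] + en.ML_BRANCH
                if alt < best:
                    best = alt
            best2 = INF
            for k in range(i, j):
                if WM[i][k] < INF and WM[k + 1][j] < INF:
                    s = WM[i][k] + WM[k + 1][j]
                    if s < best2:
                        best2 = s
            WM2[i][j] = best2
            if best2 < best:
                best = best2
            WM[i][j] = best

    W = [0.0] * (n + 1)
    for k in range(1, n + 1):
        best = W[k - 1]
        for i in range(0, k - en.MIN_HAIRPIN - 1):
            if V[i][k - 1] < INF:
                e = W[i] + V[i][k - 1]
                if e < best:
                    best = e
        W[k] = best

    pairs = _traceback(seq, n, hmin, pairable, pair_str, V, L, WM, WM2, W)
    return FoldResult(
        id=seq_id, sequence=seq, pairs=sorted(pairs), delta_G=round(W[n], 10)
    )


def _traceback(seq, n, hmin, pairable, pair_str, V, L, WM, WM2, W) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []

    def close(x: float, y: float) -> bool:
        return abs(x - y) < _EPS

    def trace_V(i: int, j: int) -> None:
        cum = 0.0
        term_out = en.terminal_penalty(pair_str[i][j])
        h = 1
        while True:
            ii, jj = i + h - 1, j - h + 1
            if jj - ii <= en.MIN_HAIRPIN or not pairable[ii][jj]:
                raise AssertionError("traceback failed in V")
            if (
                h >= hmin
                and L[ii][jj] < INF
                and close(V[i][j],
                          cum + term_out + en.terminal_penalty(pair_str[ii][jj]) + L[ii][jj])
            ):
                pairs.extend((i + t + 1, j - t + 1) for t in range(h))
                trace_L(ii, jj)
                return
            ni, nj = ii + 1, jj - 1
            if nj - ni <= en.MIN_HAIRPIN or not pairable[ni][nj]:
                raise AssertionError("traceback failed in V (helix end)")
            cum += en.stack_energy(pair_str[ii][jj], pair_str[ni][nj])
            h += 1

    def trace_L(i: int, j: int) -> None:
        if close(L[i][j], en.hairpin_energy(j - i - 1)):
            return
        for p in range(i + 1, j - 1):
            n1 = p - i - 1
            if n1 > en.MAX_INTERIOR:
                break
            qmin = max(p + en.MIN_HAIRPIN + 1, j - 1 - (en.MAX_INTERIOR - n1))
            for q in range(qmin, j):
                if n1 == 0 and q == j - 1:
                    continue
                if V[p][q] < INF and close(
                    L[i][j],
                    en.internal_energy(n1, j - q - 1, pair_str[i][j], pair_str[p][q])
                    + V[p][q],
                ):
                    trace_V(p, q)
                    return
        if WM2[i + 1][j - 1] < INF and close(L[i][j], en.ML_CLOSING + WM2[i + 1][j - 1]):
            trace_WM2(i + 1, j - 1)
            return
        raise AssertionError("traceback failed in L")

    def trace_WM2(i: int, j: int) -> None:
        for k in range(i, j):
            if WM[i][k] < INF and WM[k + 1][j] < INF and close(
                WM2[i][j], WM[i][k] + WM[k + 1][j]
            ):
                trace_WM(i, k)
                trace_WM(k + 1, j)
                return
        raise AssertionError("traceback failed in WM2")

    def trace_WM(i: int, j: int) -> None:
        if i + 1 <= j and WM[i + 1][j] < INF and close(WM[i][j], WM[i + 1][j] + en.ML_UNPAIRED):
            trace_WM(i + 1, j)
            return
        if i <= j - 1 and WM[i][j - 1] < INF and close(WM[i][j], WM[i][j - 1] + en.ML_UNPAIRED):
            trace_WM(i, j - 1)
            return
        if V[i][j] < INF and close(WM[i][j], V[i][j] + en.ML_BRANCH):
            trace_V(i, j)
            return
        trace_WM2(i, j)

    k = n
    while k > 0:
        if close(W[k], W[k - 1]):
            k -= 1
            continue
        done = False
        for i in range(0, k - en.MIN_HAIRPIN - 1):
            if V[i][k - 1] < INF and close(W[k], W[i] + V[i][k - 1]):
                trace_V(i, k - 1)
                k = i
                done = True
                break
        if not done:
            raise AssertionError("traceback failed in W")
    return pairs


# ---------------------------------------------------------------------------
# Stem-loop validation and arm calls
# ---------------------------------------------------------------------------

@dataclass
class StemLoopMetrics:
    n_hairpins: int
    longest_stem: int
    loop_size: int  # terminal loop of the single hairpin, 0 otherwise


def is_stem_loop(fold: FoldResult) -> tuple[bool, StemLoopMetrics]:
    """True iff the MFE structure is a single hairpin (exactly one
    terminal loop), the miRNA-typical precursor shape."""
    longest = _longest_stem(fold.pairs)
    loop_size = 0
    if fold.loop_span is not None:
        loop_size = fold.loop_span[1] - fold.loop_span[0] + 1
    return fold.n_hairpins == 1, StemLoopMetrics(
        n_hairpins=fold.n_hairpins, longest_stem=longest, loop_size=loop_size
    )


def _longest_stem(pairs: list[tuple[int, int]]) -> int:
    pset = set(pairs)
    best = 0
    for i, j in pset:
        if (i - 1, j + 1) in pset:
            continue  # not a helix start
        h = 1
        while (i + h, j - h) in pset:
            h += 1
        best = max(best, h)
    return best


@dataclass
class ArmCall:
    """Location of a mature strand on its folded precursor."""

    mature_id: str
    precursor_id: str
    arm: Arm
    mature_span: tuple[int, int]  # 1-based inclusive on the precursor


def locate_arm(fold: FoldResult, mature: MirSeqRecord) -> ArmCall:
    """Assign a mature strand to the 5p or 3p arm of a folded hairpin.

    The mature sequence must occur exactly once in the precursor; the
    arm is 5p if the whole mature span lies before the terminal loop,
    3p if it lies after.  A mature overlapping the loop is an explicit
    error (no guessing), as is a precursor that is not a single
    stem-loop.
    """
    hits = _find_all(fold.sequence, mature.sequence)
    if len(hits) == 0:
        raise ValueError(
            f"mature {mature.id!r} not found in precursor {fold.id!r}"
        )
    if len(hits) > 1:
        raise ValueError(
            f"mature {mature.id!r} occurs {len(hits)} times in precursor {fold.id!r}"
        )
    if fold.loop_span is None:
        raise ValueError(
            f"precursor {fold.id!r} does not fold into a single stem-loop "
            f"({fold.n_hairpins} terminal loops)"
        )
    start = hits[0] + 1
    end = start + len(mature.sequence) - 1
    loop_start, loop_end = fold.loop_span
    if end < loop_start:
        arm = Arm.FIVE_PRIME
    elif start > loop_end:
        arm = Arm.THREE_PRIME
    else:
        raise ValueError(
            f"mature {mature.id!r} spans the terminal loop "
            f"({start}-{end} vs loop {loop_start}-{loop_end})"
        )
    return ArmCall(
        mature_id=mature.id, precursor_id=fold.id, arm=arm, mature_span=(start, end)
    )


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    k = haystack.find(needle)
    while k != -1:
        out.append(k)
        k = haystack.find(needle, k + 1)
    return out


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_dot_bracket(results: list[FoldResult], path: str | Path) -> None:
    """Vienna-style output: header, sequence, structure with energy."""
    lines = []
    for r in results:
        lines.append(f">{r.id}")
        lines.append(r.sequence)
        lines.append(f"{r.dot_bracket} ({r.delta_G:.2f})")
    Path(path).write_text("\n".join(lines) + "\n")


def energy_table(results: list[FoldResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        ok, m = is_stem_loop(r)
        rows.append(
            {
                "id": r.id,
                "length": len(r.sequence),
                "delta_G_kcal_mol": r.delta_G,
                "is_stem_loop": ok,
                "n_hairpins": m.n_hairpins,
                "longest_stem": m.longest_stem,
                "loop_size": m.loop_size,
            }
        )
    return pd.DataFrame(rows)


def write_energies(results: list[FoldResult], path: str | Path) -> None:
    write_tsv(energy_table(results), path)
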