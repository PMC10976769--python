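"""Nearest-neighbor free-energy model for RNA secondary structure.

A Turner-style parameter set at 37 degC in kcal/mol: Watson-Crick
stack energies from the Xia et al. (1998) measurements, wobble (G:U)
stacks from the Mathews et al. (1999) compilation, loop initiation
tables with Jacobson-Stockmayer size extrapolation, an affine
multiloop penalty, and a terminal AU/GU helix-end penalty.  Terminal
mismatch/dangle contributions and special small-loop tables are
deliberately omitted so the model stays simple and exactly
enumerable; see the methods note for the consequences.

Energies are defined for a *loop decomposition*: hairpin loops,
stacked pairs, bulge/internal loops, multiloops and the external loop.
Both the folding DP and :func:`energy_of_structure` (which scores an
arbitrary given structure) are built on the same primitives here, so a
dynamic program and an exhaustive enumeration are directly comparable.
"""

from __future__ import annotations

import math

RT = 0.616  # kcal/mol at 310.15 K
LOOP_EXTRAPOLATION = 1.75  # Jacobson-Stockmayer prefactor
MIN_HAIRPIN = 3  # minimum unpaired nt in a hairpin loop
MAX_INTERIOR = 30  # size cap for bulge/internal loops in the DP search

CANONICAL_PAIRS = frozenset(["AU", "UA", "GC", "CG", "GU", "UG"])
WEAK_PAIRS = frozenset(["GU", "UG", "AU", "UA"])
TERMINAL_AU_PENALTY = 0.5  # per helix end closed by AU/UA/GU/UG

# Multiloop affine parameters (offset, per-branch, per-unpaired-nt).
ML_CLOSING = 3.4
ML_BRANCH = 0.4
ML_UNPAIRED = 0.0

# Stack free energies, keyed ((a, b), (c, d)) for the motif
#   5'-a c-3'
#   3'-b d-5'
# with a:b the outer pair and c:d the inner pair.  Only one rotation of
# each motif is listed; _symmetrize fills in the other.
_STACKS_RAW: dict[tuple[str, str], float] = {
    # Watson-Crick / Watson-Crick (Xia et al. 1998)
    ("AU", "AU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("CG", "UA"): -2.08,
    ("CG", "AU"): -2.11,
    ("GC", "UA"): -2.24,
    ("GC", "AU"): -2.35,
    ("CG", "GC"): -2.36,
    ("GC", "GC"): -3.26,
    ("GC", "CG"): -3.42,
    ("CG", "CG"): -3.26,
    # wobble-containing stacks (Mathews et al. 1999, rounded)
    ("AU", "GU"): -0.55,
    ("AU", "UG"): -1.36,
    ("CG", "GU"): -1.41,
    ("CG", "UG"): -2.11,
    ("GC", "GU"): -1.53,
    ("GC", "UG"): -2.51,
    ("UA", "GU"): -1.27,
    ("UA", "UG"): -1.00,
    ("GU", "GU"): -0.50,
    ("GU", "UG"): +1.29,
    ("UG", "GU"): +0.30,
    ("UG", "UG"): -0.50,
}


def _rotate(key: tuple[str, str]) -> tuple[str, str]:
    (outer, inner) = key
    return (inner[1] + inner[0], outer[1] + outer[0])


def _symmetrize(raw: dict[tuple[str, str], float]) -> dict[tuple[str, str], float]:
    table = dict(raw)
    for key, val in raw.items():
        rot = _rotate(key)
        if rot not in table:
            table[rot] = val
        elif not math.isclose(table[rot], val, abs_tol=1e-9):
            raise AssertionError(f"inconsistent stack rotation {key} vs {rot}")
    return table


STACKS = _symmetrize(_STACKS_RAW)

# Loop initiation tables (kcal/mol), indexed by loop size in nt.
HAIRPIN_INIT = {3: 5.7, 4: 5.6, 5: 5.6, 6: 5.4, 7: 5.9, 8: 5.6, 9: 6.4}
BULGE_INIT = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
INTERNAL_INIT = {2: 1.5, 3: 1.6, 4: 1.7, 5: 1.8, 6: 2.0}
NINIO_ASYMMETRY = 0.5  # per nt of |n1 - n2|, capped
NINIO_MAX = 3.0

PARAM_SETS = ("turner-like",)


def can_pair(a: str, b: str) -> bool:
    return a + b in CANONICAL_PAIRS


def is_weak_pair(a: str, b: str) -> bool:
    """AU/UA/GU/UG pairs that attract the terminal helix-end penalty."""
    return a + b in WEAK_PAIRS


def _extrapolate(table: dict[int, float], size: int) -> float:
    if size in table:
        return table[size]
    ref = max(table)
    return table[ref] + LOOP_EXTRAPOLATION * RT * math.log(size / ref)


def hairpin_energy(size: int) -> float:
    """Hairpin loop of ``size`` unpaired nt (size >= 3)."""
    if size < MIN_HAIRPIN:
        raise ValueError(f"hairpin loop must have >= {MIN_HAIRPIN} nt, got {size}")
    return _extrapolate(HAIRPIN_INIT, size)


def stack_energy(outer: str, inner: str) -> float:
    """Stack of two adjacent pairs; ``outer``/``inner`` are two-letter
    pair strings, e.g. ('GC', 'AU') for 5'-GA-3'/3'-CU-5'."""
    return STACKS[(outer, inner)]


def internal_energy(n1: int, n2: int, outer: str, inner: str) -> float:
    """Bulge (one side empty) or internal loop with ``n1``/``n2``
    unpaired nt on the two strands.  A single-nt bulge keeps the
    coaxial stack of its flanking pairs, per the standard convention.

    Helix-end AU/GU penalties are *not* charged here; they are applied
    uniformly at every non-stacking pair by the helix-end rule (see
    :func:`energy_of_structure`).
    """
    if n1 == 0 and n2 == 0:
        raise ValueError("size-0 loop is a stack, not an internal loop")
    size = n1 + n2
    if n1 == 0 or n2 == 0:  # bulge
        e = _extrapolate(BULGE_INIT, size)
        if size == 1:
            e += stack_energy(outer, inner)
        return e
    e = _extrapolate(INTERNAL_INIT, size)
    e += min(NINIO_ASYMMETRY * abs(n1 - n2), NINIO_MAX)
    return e


def _terminal(pair: str) -> float:
    return TERMINAL_AU_PENALTY if pair in WEAK_PAIRS else 0.0


def terminal_penalty(pair: str) -> float:
    """Helix-end penalty for AU/UA/GU/UG closing pairs."""
    return _terminal(pair)


def multiloop_energy(n_branches: int, n_unpaired: int) -> float:
    """Affine multiloop cost: closing + per-branch + per-unpaired-nt.
    ``n_branches`` counts the internal branches (not the closing pair).
    """
    return ML_CLOSING + ML_BRANCH * n_branches + ML_UNPAIRED * n_unpaired


# ---------------------------------------------------------------------------
# Scoring a given structure (loop-decomposition evaluator)
# ---------------------------------------------------------------------------

def energy_of_structure(seq: str, pairs: list[tuple[int, int]]) -> float:
    """Free energy of a given structure (pairs are 1-based (i, j),
    i < j) under this model.

    The structure is decomposed into loops: each pair closes either a
    stack, a hairpin, a bulge/internal loop, or a multiloop; helix-end
    terminal penalties are charged on every pair that does not stack
    outward and every pair that does not stack inward.  This evaluator
    is a straight transcription of the model definition and is
    independent of the folding dynamic program, so enumerating all
    structures with it provides an oracle for the DP.
    """
    n = len(seq)
    pset = {(i - 1, j - 1) for i, j in pairs}
    for i, j in pset:
        if not 0 <= i < j < n:
            raise ValueError(f"pair out of range: {(i + 1, j + 1)}")
        if not can_pair(seq[i], seq[j]):
            raise ValueError(f"non-canonical pair {seq[i]}{seq[j]} at {(i + 1, j + 1)}")
        if j - i - 1 < MIN_HAIRPIN and (i + 1, j - 1) not in pset and not _has_inner(pset, i, j):
            # direct hairpin smaller than the minimum loop
            raise ValueError(f"hairpin loop below {MIN_HAIRPIN} nt at {(i + 1, j + 1)}")
    _check_non_crossing(pset)

    partners = {}
    for i, j in pset:
        partners[i] = j
        partners[j] = i

    total = 0.0
    for i, j in pset:
        children = _direct_children(pset, i, j)
        pij = seq[i] + seq[j]
        if not children:
            size = j - i - 1
            total += hairpin_energy(size)
        elif len(children) == 1:
            (p, q) = children[0]
            if p == i + 1 and q == j - 1:
                total += stack_energy(pij, seq[p] + seq[q])
            else:
                total += internal_energy(p - i - 1, j - q - 1, pij, seq[p] + seq[q])
        else:
            unpaired = (j - i - 1) - sum(q - p + 1 for p, q in children)
            total += multiloop_energy(len(children), unpaired)
        # helix-end penalties: outward and inward non-stacking ends
        if (i - 1, j + 1) not in pset:
            total += _terminal(pij)
        if (i + 1, j - 1) not in pset:
            total += _terminal(pij)
    return total


def _has_inner(pset: set[tuple[int, int]], i: int, j: int) -> bool:
    return any(i < p and q < j for p, q in pset)


def _direct_children(
    pset: set[tuple[int, int]], i: int, j: int
) -> list[tuple[int, int]]:
    inner = sorted((p, q) for p, q in pset if i < p and q < j)
    children = []
    last_end = i
    for p, q in inner:
        if p > last_end:
            children.append((p, q))
            last_end = q
    return children


def _check_non_crossing(pset: set[tuple[int, int]]) -> None:
    ps = sorted(pset)
    ends: set[int] = set()
    for i, j in ps:
        if i in ends or j in ends:
            raise ValueError("a base participates in two pairs")
        ends.update((i, j))
    for a, (i, j) in enumerate(ps):
        for p, q in ps[a + 1:]:
            if i < p <= j < q:
                raise ValueError(f"crossing pairs (pseudoknot): {(i, j)} x {(p, q)}")


def structure_is_lonely_pair_free(pairs: list[tuple[int, int]]) -> bool:
    """True iff every pair stacks on a neighbour, i.e. all helices have
    length >= 2 (pairs are 1-based)."""
    pset = {(i, j) for i, j in pairs}
    return all(
        (i - 1, j + 1) in pset or (i + 1, j - 1) in pset for i, j in pset
    )
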