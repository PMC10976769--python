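"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration,
closed forms, direct recounts — and shares nothing with the package's
algorithmic code paths beyond the energy parameter tables (which are
the model under test, not the search)."""

from __future__ import annotations

import itertools
import random
from functools import lru_cache

import numpy as np

from mirfam import energy as en


# ---------------------------------------------------------------------------
# RNA folding: exhaustive structure enumeration
# ---------------------------------------------------------------------------

def enumerate_structures(seq: str) -> list[frozenset]:
    """All non-crossing canonical pair sets with the 3-nt minimum
    hairpin loop, by interval recursion (0-based pairs)."""

    @lru_cache(maxsize=None)
    def structs(i: int, j: int):
        if j - i < en.MIN_HAIRPIN + 1:
            return (frozenset(),)
        out = list(structs(i + 1, j))
        for k in range(i + en.MIN_HAIRPIN + 1, j + 1):
            if en.can_pair(seq[i], seq[k]):
                for inner in structs(i + 1, k - 1):
                    for rest in structs(k + 1, j):
                        out.append(frozenset({(i, k)}) | inner | rest)
        return tuple(out)

    return list(structs(0, len(seq) - 1))


def brute_force_mfe(seq: str, allow_lonely_pairs: bool = False) -> float:
    """Minimum energy over every enumerated structure, scored with the
    loop-decomposition evaluator."""
    best = 0.0
    for st in enumerate_structures(seq):
        if not st:
            continue
        pairs = sorted((i + 1, j + 1) for i, j in st)
        if not allow_lonely_pairs and not en.structure_is_lonely_pair_free(pairs):
            continue
        best = min(best, en.energy_of_structure(seq, pairs))
    return best


# ---------------------------------------------------------------------------
# Global alignment: exhaustive alignment enumeration
# ---------------------------------------------------------------------------

def best_alignment_score(a: str, b: str, match=1.0, mismatch=0.0, gap=-1.0) -> float:
    """Maximum global alignment score by plain recursion (no tables)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        opts = []
        if i < len(a) and j < len(b):
            opts.append(rec(i + 1, j + 1) + (match if a[i] == b[j] else mismatch))
        if i < len(a):
            opts.append(rec(i + 1, j) + gap)
        if j < len(b):
            opts.append(rec(i, j + 1) + gap)
        return max(opts)

    return rec(0, 0)


# ---------------------------------------------------------------------------
# Random additive trees for NJ exactness
# ---------------------------------------------------------------------------

def random_additive_distances(
    n: int, rng: random.Random
) -> tuple[list[str], np.ndarray]:
    """Leaf labels and the additive distance matrix of a random binary
    tree with strictly positive branch lengths.

    The tree is built by repeatedly attaching a new leaf to a random
    existing edge; distances are accumulated over explicit edge paths,
    independent of any package tree code.
    """
    labels = [f"T{k}" for k in range(n)]
    # adjacency: node -> list of (node, length); leaves are labels,
    # internal nodes are ints
    next_internal = [0]

    def new_internal():
        next_internal[0] += 1
        return -next_internal[0]

    adj: dict = {labels[0]: [], labels[1]: []}
    edges: list[tuple] = []

    def add_edge(u, v, w):
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
        edges.append((u, v))

    def remove_edge(u, v):
        adj[u] = [(x, w) for x, w in adj[u] if x != v]
        adj[v] = [(x, w) for x, w in adj[v] if x != u]
        edges.remove((u, v) if (u, v) in edges else (v, u))

    def weight(u, v):
        return next(w for x, w in adj[u] if x == v)

    add_edge(labels[0], labels[1], rng.uniform(0.2, 2.0))
    for leaf in labels[2:]:
        u, v = rng.choice(edges)
        w = weight(u, v)
        cut = rng.uniform(0.25, 0.75) * w
        mid = new_internal()
        remove_edge(u, v)
        add_edge(u, mid, cut)
        add_edge(mid, v, w - cut)
        add_edge(mid, leaf, rng.uniform(0.2, 2.0))

    def dist(src, dst):
        seen = {src}
        stack = [(src, 0.0)]
        while stack:
            node, acc = stack.pop()
            if node == dst:
                return acc
            for nxt, w in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, acc + w))
        raise AssertionError("disconnected tree")

    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dist(labels[i], labels[j])
    return labels, d


# ---------------------------------------------------------------------------
# Census recount
# ---------------------------------------------------------------------------

def recount_division(records, division):
    """Direct loop recount of the gt/eq/lt partition for one division."""
    gt = eq = lt = 0
    for r in records:
        if r.division != division:
            continue
        if r.n_mature > r.n_precursor:
            gt += 1
        elif r.n_mature == r.n_precursor:
            eq += 1
        else:
            lt += 1
    return gt, eq, lt
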