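"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (quadratic DP, exhaustive window
enumeration, path-length tree metrics) and shares no code with the
implementation under test.
"""

from __future__ import annotations

import itertools
import random

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def brute_iupac_hits(pattern: str, seq: str, strands: str = "both"):
    """All (start, end, strand) windows matching the pattern (data-N never matches)."""
    L = len(pattern)
    hits = []
    for i in range(len(seq) - L + 1):
        w = seq[i : i + L]
        if "N" in w:
            continue
        if strands in ("both", "fwd") and all(b in IUPAC[p] for p, b in zip(pattern, w)):
            hits.append((i, i + L, "+"))
        if strands in ("both", "rev") and all(
            b in IUPAC[p] for p, b in zip(pattern, rc(w))
        ):
            hits.append((i, i + L, "-"))
    return sorted(hits, key=lambda h: (h[0], h[2]))


def brute_targetable_fraction(pattern: str) -> float:
    """Exhaustive enumeration of all 4^L windows."""
    L = len(pattern)
    n = sum(
        all(b in IUPAC[p] for p, b in zip(pattern, w))
        for w in map("".join, itertools.product("ACGT", repeat=L))
    )
    return n / 4**L


def global_affine_score(
    x: str,
    y: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    free_end_gaps: bool = True,
) -> float:
    """Gotoh affine-gap global alignment score (length-k gap costs open+k*ext).

    Plain-Python quadratic DP, independent of any alignment library.
    With free end gaps, leading/trailing gaps in either sequence are free.
    """
    n, m = len(x), len(y)
    NEG = float("-inf")
    open_cost = gap_open + gap_extend
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in y (x consumed)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in x (y consumed)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = 0.0 if free_end_gaps else -(gap_open + i * gap_extend)
    for j in range(1, m + 1):
        Iy[0][j] = 0.0 if free_end_gaps else -(gap_open + j * gap_extend)
    for i in range(1, n + 1):
        xi = x[i - 1]
        for j in range(1, m + 1):
            s = match if xi == y[j - 1] else mismatch
            best_prev = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = best_prev + s
            # adjacent deletion+insertion allowed (each pays its own open)
            Ix[i][j] = max(
                M[i - 1][j] - open_cost,
                Iy[i - 1][j] - open_cost,
                Ix[i - 1][j] - gap_extend,
            )
            Iy[i][j] = max(
                M[i][j - 1] - open_cost,
                Ix[i][j - 1] - open_cost,
                Iy[i][j - 1] - gap_extend,
            )
    if not free_end_gaps:
        return max(M[n][m], Ix[n][m], Iy[n][m])
    best = NEG
    for i in range(n + 1):
        best = max(best, M[i][m], Ix[i][m], Iy[i][m])
    for j in range(m + 1):
        best = max(best, M[n][j], Ix[n][j], Iy[n][j])
    return best


def local_best_alignment(
    query: str,
    target: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = 5.0,
    gap_extend: float = 2.0,
) -> tuple[float, int, int]:
    """Smith-Waterman best score and target interval (start, end)."""
    n, m = len(target), len(query)
    open_cost = gap_open + gap_extend
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[float("-inf")] * (m + 1) for _ in range(n + 1)]
    Iy = [[float("-inf")] * (m + 1) for _ in range(n + 1)]
    best, best_i = 0.0, 0
    for i in range(1, n + 1):
        ti = target[i - 1]
        for j in range(1, m + 1):
            s = match if ti == query[j - 1] else mismatch
            Ix[i][j] = max(H[i - 1][j] - open_cost, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(H[i][j - 1] - open_cost, Iy[i][j - 1] - gap_extend)
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, Ix[i][j], Iy[i][j])
            if H[i][j] > best:
                best, best_i = H[i][j], i
    # walk back along the best row to estimate the start (score-only oracle:
    # callers assert score and end coordinate containment, not exact start)
    return best, best_i, best_i


def random_additive_tree(rng: random.Random, n_taxa: int):
    """A random unrooted binary tree with positive branch lengths.

    Returns (labels, distance matrix as list of lists, set of non-trivial
    splits frozenset-of-frozensets) with distances computed by path
    lengths through the tree — additive by construction.
    """
    labels = [f"T{i}" for i in range(n_taxa)]
    # adjacency: node -> list of (node, length); leaves are 0..n-1
    next_id = n_taxa
    edges: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n_taxa)}

    def link(a, b, w):
        edges.setdefault(a, []).append((b, w))
        edges.setdefault(b, []).append((a, w))

    def bl():
        return rng.uniform(0.1, 2.0)

    # start from a 3-star, then attach each remaining leaf to a random edge
    center = next_id
    next_id += 1
    for leaf in (0, 1, 2):
        link(center, leaf, bl())
    edge_list = [(center, leaf) for leaf in (0, 1, 2)]
    for leaf in range(3, n_taxa):
        a, b = edge_list[rng.randrange(len(edge_list))]
        w = next(wt for nb, wt in edges[a] if nb == b)
        mid = next_id
        next_id += 1
        edges[a] = [(nb, wt) for nb, wt in edges[a] if nb != b]
        edges[b] = [(nb, wt) for nb, wt in edges[b] if nb != a]
        w1 = w * rng.uniform(0.2, 0.8)
        link(a, mid, w1)
        link(mid, b, w - w1)
        link(mid, leaf, bl())
        edge_list.remove((a, b))
        edge_list += [(a, mid), (mid, b), (mid, leaf)]

    def dist_from(src):
        d = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in edges[u]:
                if v not in d:
                    d[v] = d[u] + w
                    stack.append(v)
        return d

    D = [[0.0] * n_taxa for _ in range(n_taxa)]
    for i in range(n_taxa):
        di = dist_from(i)
        for j in range(i + 1, n_taxa):
            D[i][j] = D[j][i] = di[j]  # exact float symmetry

    all_leaves = frozenset(labels)
    splits = set()
    for a, b in edge_list:
        # leaves on the a-side of edge (a, b)
        side = set()
        stack = [a]
        seen = {a, b}
        while stack:
            u = stack.pop()
            if u < n_taxa:
                side.add(labels[u])
            for v, _ in edges[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        fs = frozenset(side)
        if 1 < len(fs) < n_taxa - 1:
            splits.add(min(fs, all_leaves - fs, key=sorted))
    return labels, D, splits
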