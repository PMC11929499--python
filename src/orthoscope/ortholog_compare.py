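"""Ortholog sequence comparison: identity, distances, neighbor joining.

Pairwise global protein alignment (BLOSUM62, affine gaps) yields a percent
identity matrix; identities convert to evolutionary distances under a
p-distance or Jukes-Cantor-type model; a Saitou-Nei neighbor-joining tree
is built from the distance matrix and serialized as Newick.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seqcore import ProteinSequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IdentityMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # symmetric, diagonal 100

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not np.allclose(v, v.T):
            raise ValueError("identity matrix must be symmetric")
        if (v < 0).any() or (v > 100).any():
            raise ValueError("identities must lie in [0, 100]")


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # symmetric, non-negative, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")


@dataclass
class Clade:
    """A tree node; leaves carry names, edges carry lengths to the parent."""

    name: str | None = None
    branch_length: float | None = None
    children: list["Clade"] = field(default_factory=list)

    def leaves(self) -> list["Clade"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass(frozen=True)
class PhyloTree:
    root: Clade

    @property
    def leaf_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.root.leaves())

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions (one side each) induced by internal edges."""
        all_leaves = frozenset(self.leaf_names)
        out: set[frozenset[str]] = set()

        def walk(node: Clade) -> frozenset[str]:
            if not node.children:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                out.add(min(below, all_leaves - below, key=sorted))
            return below

        for c in self.root.children:
            walk(c)
        return out


_aligner_cache: dict[tuple, Align.PairwiseAligner] = {}


def _protein_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    key = (gap_open, gap_extend)
    if key not in _aligner_cache:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -(gap_open + gap_extend)
        aligner.extend_gap_score = -gap_extend
        _aligner_cache[key] = aligner
    return _aligner_cache[key]


def pairwise_identity(
    a: ProteinSequence,
    b: ProteinSequence,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    denominator: str = "all_columns",
) -> float:
    """Percent identity of the optimal global alignment, nearest integer.

    ``denominator='all_columns'`` divides identical pairs by all alignment
    columns including gap columns; ``'aligned_only'`` divides by aligned
    residue pairs.  Symmetric by construction (the pair is canonically
    ordered before aligning).
    """
    if denominator not in ("all_columns", "aligned_only"):
        raise ValueError(f"unknown denominator {denominator!r}")
    x, y = sorted((a.residues, b.residues))
    aligner = _protein_aligner(gap_open, gap_extend)
    aln = aligner.align(x, y)[0]  # BLOSUM62 covers X
    t_blocks, q_blocks = aln.aligned
    ident = aligned_pairs = 0
    last_t = last_q = None
    gap_cols = (t_blocks[0][0] if len(t_blocks) else 0) + (
        q_blocks[0][0] if len(q_blocks) else 0
    )
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if last_t is not None:
            gap_cols += (ts - last_t) + (qs - last_q)
        ident += sum(p == q for p, q in zip(x[ts:te], y[qs:qe]))
        aligned_pairs += te - ts
        last_t, last_q = te, qe
    if last_t is not None:
        gap_cols += (len(x) - last_t) + (len(y) - last_q)
    denom = aligned_pairs + (gap_cols if denominator == "all_columns" else 0)
    if denom == 0:
        raise ValueError("empty alignment")
    return round(100.0 * ident / denom)


def identity_matrix(seqs: Sequence[ProteinSequence], **params) -> IdentityMatrix:
    n = len(seqs)
    m = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pairwise_identity(seqs[i], seqs[j], **params)
    return IdentityMatrix(tuple(s.id for s in seqs), m)


def identity_to_distance(
    idm: IdentityMatrix,
    model: str = "jukes_cantor",
    alphabet_size: int = 20,
    saturation_cap: float = 5.0,
) -> DistanceMatrix:
    """Convert identities to distances.

    p-distance: d = p = 1 - identity/100.  Jukes-Cantor with alphabet size
    a (20 for proteins, 4 for nucleotides):
    d = -((a-1)/a) * ln(1 - a*p/(a-1)); saturated entries
    (p >= (a-1)/a) are capped at *saturation_cap* with a warning.
    """
    p = 1.0 - idm.values / 100.0
    if model == "p-distance":
        d = p.copy()
    elif model == "jukes_cantor":
        a = alphabet_size
        pmax = (a - 1) / a
        sat = p >= pmax
        if sat.any():
            logger.warning(
                "%d saturated pairs (p >= %.3f) capped at %.1f",
                int(sat.sum() // 2), pmax, saturation_cap,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(sat, saturation_cap, -pmax * np.log(1.0 - p / pmax))
    else:
        raise ValueError(f"unknown model {model!r}")
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    return DistanceMatrix(idm.labels, (d + d.T) / 2.0)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Canonical Saitou-Nei neighbor joining with the Q-criterion.

    Ties in Q break on the lowest (i, j) label-index pair; negative
    branch lengths are clamped to zero with a warning.  For two labels a
    single edge split evenly is returned; for one, a single leaf.
    """
    labels = list(dm.labels)
    n = len(labels)
    if n == 0:
        raise ValueError("empty distance matrix")
    if n == 1:
        return PhyloTree(Clade(name=labels[0], branch_length=0.0))
    if n == 2:
        d = float(dm.values[0, 1])
        return PhyloTree(
            Clade(children=[
                Clade(labels[0], d / 2.0), Clade(labels[1], d / 2.0),
            ])
        )

    D = dm.values.astype(float).copy()
    nodes: list[Clade] = [Clade(name=l) for l in labels]
    active = list(range(n))
    size = n

    def clamp(x: float) -> float:
        if x < 0:
            logger.warning("negative NJ branch length %.4g clamped to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest flat index = lowest (i, j) pair among ties
        i_loc, j_loc = divmod(int(np.argmin(q)), m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = idx[i_loc], idx[j_loc]
        dij = D[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        new = Clade(children=[nodes[i], nodes[j]])
        nodes[i].branch_length = clamp(li)
        nodes[j].branch_length = clamp(lj)
        # distances to the new node
        dnew = 0.5 * (D[i, idx] + D[j, idx] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[size, idx] = dnew
        D[idx, size] = dnew
        D[size, size] = 0.0
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [size]
        size += 1

    # final unrooted trifurcation via the three-point formulas
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for k, lk in zip((a, b, c), (la, lb, lc)):
        nodes[k].branch_length = clamp(lk)
    return PhyloTree(Clade(children=[nodes[a], nodes[b], nodes[c]]))


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def write_newick(tree: PhyloTree) -> str:
    def fmt(node: Clade) -> str:
        if node.children:
            inner = ",".join(fmt(c) for c in node.children)
            s = f"({inner})"
        else:
            s = node.name or ""
        if node.branch_length is not None:
            s += f":{node.branch_length:.10g}"
        return s

    return fmt(tree.root) + ";"


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string (delegates to dendropy) into a PhyloTree."""
    import dendropy

    if not text.rstrip().endswith(";"):
        raise ValueError(f"malformed Newick at position {len(text.rstrip())}: missing ';'")
    try:
        dt = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises its own hierarchy
        raise ValueError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Clade:
        name = dnode.taxon.label if dnode.taxon else (dnode.label or None)
        length = dnode.edge.length
        return Clade(
            name=name,
            branch_length=float(length) if length is not None else None,
            children=[convert(c) for c in dnode.child_nodes()],
        )

    root = convert(dt.seed_node)
    return PhyloTree(root)


def write_matrix_tsv(labels: Sequence[str], values: np.ndarray, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(values, index=list(labels), columns=list(labels)).to_csv(
        path, sep="\t", float_format="%.6g"
    )
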