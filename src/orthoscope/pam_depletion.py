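"""PAM inference from randomized-library depletion sequencing.

A Cas9 incubated with a plasmid library carrying a randomized PAM destroys
the members whose PAM it recognizes, so functional PAMs appear as k-mers
*depleted* in the post-cleavage library relative to an uncleaved control.
This module turns control/cleaved k-mer count tables into fold-depletion
ratios, thresholds them (10-fold by default), summarizes the depleted set
as a position frequency matrix, collapses that to an IUPAC consensus, and
computes logo heights and the targetable fraction of sequence space.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .seqcore import BASES_TO_IUPAC, IUPAC_CODES, IupacPattern

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}


class NoCallError(ValueError):
    """Raised when a consensus cannot be called (e.g. nothing depleted)."""


@dataclass(frozen=True)
class PamLibrary:
    """k-mer counts from one sequencing library (control or cleaved)."""

    k: int
    counts: Mapping[str, int]
    label: str = "control"

    def __post_init__(self) -> None:
        for w, c in self.counts.items():
            if len(w) != self.k or set(w) - set(BASES):
                raise ValueError(f"bad {self.k}-mer key {w!r}")
            if c < 0:
                raise ValueError(f"negative count for {w!r}")
        if self.total <= 0:
            raise ValueError(f"library {self.label!r} has zero total count")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class DepletionTable:
    """Fold-depletion per k-mer: >1 means reduced by cleavage."""

    k: int
    ratio: Mapping[str, float]
    pseudocount: float


@dataclass(frozen=True)
class Pfm:
    """Position frequency matrix: L positions x 4 base frequencies (ACGT)."""

    freqs: np.ndarray  # shape (L, 4)

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", f)
        if f.ndim != 2 or f.shape[1] != 4:
            raise ValueError("Pfm must be L x 4")
        if (f < 0).any():
            raise ValueError("negative frequency")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("Pfm rows must sum to 1")

    def __len__(self) -> int:
        return self.freqs.shape[0]


@dataclass(frozen=True)
class PamConsensus:
    """IUPAC PAM call with its supporting matrix and targetable fraction."""

    iupac: IupacPattern
    support_size: int
    pfm: Pfm
    targetable_fraction: float


def depletion_ratios(
    control: PamLibrary, cleaved: PamLibrary, pseudocount: float = 0.5
) -> DepletionTable:
    """Library-size-normalized fold depletion for every observed k-mer.

    ratio(w) = [(c_ctrl + p) / (N_ctrl + p·4^k)] / [(c_clv + p) / (N_clv + p·4^k)]

    The pseudocount keeps ratios finite when a k-mer is fully cleaved away;
    at p=0 the ratio is invariant under uniform depth rescaling.
    """
    if control.k != cleaved.k:
        raise ValueError(f"k mismatch: control {control.k} vs cleaved {cleaved.k}")
    k = control.k
    p = float(pseudocount)
    denom_ctrl = control.total + p * 4**k
    denom_clv = cleaved.total + p * 4**k
    kmers = set(control.counts) | set(cleaved.counts)
    ratio: dict[str, float] = {}
    for w in kmers:
        f_ctrl = (control.counts.get(w, 0) + p) / denom_ctrl
        f_clv = (cleaved.counts.get(w, 0) + p) / denom_clv
        if f_clv == 0:
            ratio[w] = math.inf
        else:
            ratio[w] = f_ctrl / f_clv
    return DepletionTable(k=k, ratio=ratio, pseudocount=p)


def depleted_set(table: DepletionTable, threshold: float = 10.0) -> set[str]:
    """k-mers depleted at least *threshold*-fold after cleavage."""
    if threshold <= 1:
        raise ValueError(f"threshold must exceed 1, got {threshold}")
    return {w for w, r in table.ratio.items() if r >= threshold}


def pfm_from_set(kmers: Iterable[str], weights: Mapping[str, float] | None = None) -> Pfm:
    """Column base frequencies over a k-mer set.

    Uniform weighting by default (robust to PCR jackpots); pass per-k-mer
    *weights* (e.g. read depths) for depth weighting.
    """
    kmers = sorted(set(kmers))
    if not kmers:
        raise NoCallError("empty k-mer set: no PAM call possible")
    L = len(kmers[0])
    counts = np.zeros((L, 4))
    for w in kmers:
        wt = 1.0 if weights is None else float(weights[w])
        for pos, base in enumerate(w):
            counts[pos, _BASE_IDX[base]] += wt
    return Pfm(counts / counts.sum(axis=1, keepdims=True))


def iupac_consensus(
    pfm: Pfm,
    include_threshold: float = 0.10,
    support_size: int = 0,
) -> PamConsensus:
    """Collapse a Pfm to an IUPAC string.

    Per position, the letter covers every base with frequency >=
    *include_threshold*; all four passing gives N.  Trailing 3'-most N
    positions are trimmed from the reported string (they carry no
    constraint) but the full Pfm is retained; leading Ns are kept because
    PAM position 1 abuts the protospacer.
    """
    if include_threshold > 0.25:
        raise ValueError("include_threshold must be <= 0.25 so every position calls")
    letters = []
    for row in pfm.freqs:
        bases = frozenset(b for b, f in zip(BASES, row) if f >= include_threshold)
        letters.append(BASES_TO_IUPAC[bases])
    s = "".join(letters).rstrip("N")
    if not s:
        s = "N"  # fully unconstrained PAM
    frac = targetable_fraction(IupacPattern("".join(letters)))
    return PamConsensus(
        iupac=IupacPattern(s),
        support_size=support_size,
        pfm=pfm,
        targetable_fraction=frac,
    )


def logo_matrix(pfm: Pfm) -> pd.DataFrame:
    """Information content and letter heights per position.

    IC(pos) = 2 + sum_b f·log2 f (with 0·log0 := 0), heights = f·IC.
    Columns: A,C,G,T heights plus 'IC'; one row per PAM position (1-based
    index).
    """
    f = pfm.freqs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(np.where(f > 0, f, 1.0)), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    ic = np.clip(ic, 0.0, 2.0)
    heights = f * ic[:, None]
    df = pd.DataFrame(heights, columns=list(BASES), index=range(1, len(pfm) + 1))
    df["IC"] = ic
    return df


def targetable_fraction(iupac: IupacPattern | str) -> float:
    """Probability a uniformly random window matches the degenerate PAM.

    Product over positions of |allowed bases| / 4; equals the exhaustive
    match count over all 4^L windows divided by 4^L.
    """
    if isinstance(iupac, str):
        iupac = IupacPattern(iupac)
    frac = 1.0
    for letter in iupac.letters:
        frac *= len(IUPAC_CODES[letter]) / 4.0
    return frac


def all_kmers(k: int) -> list[str]:
    """All 4^k DNA k-mers in lexicographic order."""
    return ["".join(t) for t in itertools.product(BASES, repeat=k)]


# ---------------------------------------------------------------------------
# TSV I/O and the end-to-end convenience call
# ---------------------------------------------------------------------------

def read_counts_tsv(path: str | Path, label: str = "control") -> PamLibrary:
    """Read a two-column (kmer, count) TSV into a PamLibrary."""
    df = pd.read_csv(path, sep="\t", dtype={"kmer": str, "count": int})
    if not {"kmer", "count"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'kmer' and 'count'")
    k = len(df["kmer"].iloc[0])
    return PamLibrary(k=k, counts=dict(zip(df["kmer"], df["count"])), label=label)


def write_counts_tsv(lib: PamLibrary, path: str | Path) -> None:
    pd.DataFrame(
        {"kmer": list(lib.counts), "count": list(lib.counts.values())}
    ).sort_values("kmer").to_csv(path, sep="\t", index=False)


def infer_pam(
    control: PamLibrary,
    cleaved: PamLibrary,
    threshold: float = 10.0,
    pseudocount: float = 0.5,
    include_threshold: float = 0.10,
) -> PamConsensus:
    """Counts -> depletion -> threshold -> Pfm -> IUPAC consensus."""
    table = depletion_ratios(control, cleaved, pseudocount)
    dep = depleted_set(table, threshold)
    pfm = pfm_from_set(dep)  # raises NoCallError when empty
    return iupac_consensus(pfm, include_threshold, support_size=len(dep))


def plot_logo(pfm: Pfm, path: str | Path) -> None:
    """Render a simple stacked-letter sequence logo to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = logo_matrix(pfm)
    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    fig, ax = plt.subplots(figsize=(0.8 * len(pfm) + 1, 2.5))
    for pos in df.index:
        y = 0.0
        row = df.loc[pos, list(BASES)].sort_values()
        for base, h in row.items():
            if h <= 0:
                continue
            ax.text(
                pos, y + h / 2, base, ha="center", va="center",
                fontsize=8 + 16 * h / 2, color=colors[base], fontweight="bold",
            )
            y += h
    ax.set_xlim(0.4, len(pfm) + 0.6)
    ax.set_ylim(0, 2.05)
    ax.set_xticks(list(df.index))
    ax.set_ylabel("bits")
    ax.set_xlabel("PAM position")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
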