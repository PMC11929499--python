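"""Amplicon deep-sequencing edit quantification.

Aligns amplicon reads to their reference with an affine-gap global
aligner (free end gaps), calls indels within a window around the
predicted Cas9 cut site (blunt cut 3 nt 5' of the PAM), and tabulates
per-protospacer-position base-conversion rates among indel-free reads —
the readout of a base-editing experiment.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .seqcore import FastqRecord, NucSequence, revcomp

logger = logging.getLogger(__name__)

_BASES = "ACGT"


class NoCallError(ValueError):
    pass


@dataclass(frozen=True)
class AmpliconRef:
    """An amplicon reference with protospacer/PAM annotation.

    ``cut_site`` is an inter-base coordinate in forward reference
    coordinates: the blunt Cas9 cut 3 nt 5' of the PAM on the protospacer
    strand (between protospacer positions 17 and 18 of a 20-nt
    protospacer), recomputed for other spacer lengths.
    """

    sequence: NucSequence
    proto_start: int
    proto_end: int
    pam_len: int
    strand: str = "+"
    cut_site: int = field(init=False)

    def __post_init__(self) -> None:
        L = len(self.sequence)
        if not 0 <= self.proto_start < self.proto_end <= L:
            raise ValueError("protospacer interval out of bounds")
        if self.strand == "+":
            if self.proto_end + self.pam_len > L:
                raise ValueError("PAM extends past reference end")
            cut = self.proto_end - 3
        elif self.strand == "-":
            if self.proto_start - self.pam_len < 0:
                raise ValueError("PAM extends past reference start")
            cut = self.proto_start + 3
        else:
            raise ValueError("strand must be '+' or '-'")
        object.__setattr__(self, "cut_site", cut)

    @property
    def pam_interval(self) -> tuple[int, int]:
        if self.strand == "+":
            return (self.proto_end, self.proto_end + self.pam_len)
        return (self.proto_start - self.pam_len, self.proto_start)

    @property
    def spacer_len(self) -> int:
        return self.proto_end - self.proto_start

    def proto_position_to_ref(self, p: int) -> int:
        """Forward reference coordinate of 1-based protospacer position."""
        if not 1 <= p <= self.spacer_len:
            raise ValueError(f"protospacer position {p} outside 1..{self.spacer_len}")
        if self.strand == "+":
            return self.proto_start + p - 1
        return self.proto_end - p


@dataclass(frozen=True)
class AlignOp:
    """One alignment operation in reference coordinates.

    kind 'M' consumes both sequences (matches and mismatches), 'D' consumes
    reference only, 'I' consumes read only (ref_start == ref_end).
    """

    kind: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int


@dataclass(frozen=True)
class ReadAlignment:
    ops: tuple[AlignOp, ...]
    score: float
    read_len: int

    @property
    def has_indel(self) -> bool:
        return any(op.kind in "ID" for op in self.ops)

    def read_index_for_ref(self, ref_pos: int) -> int | None:
        """Read index aligned to *ref_pos*, or None if gapped/unaligned."""
        for op in self.ops:
            if op.kind == "M" and op.ref_start <= ref_pos < op.ref_end:
                return op.read_start + (ref_pos - op.ref_start)
        return None


def _make_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float,
                  free_end_gaps: bool) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -(gap_open + gap_extend)  # length-k gap: open + k*extend
    aligner.extend_gap_score = -gap_extend
    if free_end_gaps:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    return aligner


def align_read(
    read: NucSequence,
    ref: AmpliconRef,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    free_end_gaps: bool = True,
) -> ReadAlignment:
    """Optimal affine-gap global alignment of a read to the amplicon."""
    if len(read) < 30:
        raise ValueError(f"read {read.id!r} shorter than 30 nt")
    r = read.residues
    t = ref.sequence.residues
    # Fast path: a length-preserving near-copy aligns gapless whenever the
    # mismatch cost is below one gap pair; avoids the DP for the bulk of
    # typical amplicon data.
    if len(r) == len(t):
        mm = sum(a != b for a, b in zip(r, t))
        if mm * (match - mismatch) < 2 * (gap_open + gap_extend):
            score = (len(r) - mm) * match + mm * mismatch
            return ReadAlignment(
                ops=(AlignOp("M", 0, len(t), 0, len(r)),),
                score=float(score), read_len=len(r),
            )
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend, free_end_gaps)
    aln = aligner.align(t, r)[0]
    t_blocks, q_blocks = aln.aligned
    ops: list[AlignOp] = []
    last_t = last_q = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if last_t is not None:
            if ts > last_t:
                ops.append(AlignOp("D", last_t, ts, last_q, last_q))
            if qs > last_q:
                ops.append(AlignOp("I", ts, ts, last_q, qs))
        ops.append(AlignOp("M", ts, te, qs, qe))
        last_t, last_q = te, qe
    return ReadAlignment(ops=tuple(ops), score=float(aln.score), read_len=len(r))


def classify_indel(
    aln: ReadAlignment, ref: AmpliconRef, window: int = 8
) -> bool:
    """True iff any insertion/deletion op overlaps cut_site +/- window.

    An op spanning reference interval [a, b] (a == b for insertions)
    overlaps the window iff a <= cut + window and b >= cut - window; at
    window 0 this reduces to the op interval containing the cut inter-base
    coordinate (a deletion abutting the cut counts).
    """
    cut = ref.cut_site
    for op in aln.ops:
        if op.kind in "ID" and op.ref_start <= cut + window and op.ref_end >= cut - window:
            return True
    return False


def conversion_rates(
    alignments: Sequence[ReadAlignment],
    reads: Sequence[NucSequence],
    ref: AmpliconRef,
    weights: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-protospacer-position substitution fractions among indel-free reads.

    Rows: 1-based protospacer positions (5'->3' on the protospacer
    strand).  Columns: reference base, fraction of reads showing each base
    A/C/G/T (bases read off the protospacer strand; reverse-strand
    protospacers are complemented), and the count n of reads informative
    at that position.  The conversion rate at a position is the fraction
    under the non-reference product base (e.g. 'G' at a reference-A
    position for an adenine base editor).
    """
    if weights is None:
        weights = [1] * len(alignments)
    t = ref.sequence.residues
    S = ref.spacer_len
    counts = np.zeros((S, 4), dtype=float)
    totals = np.zeros(S, dtype=float)
    any_free = False
    for aln, read, w in zip(alignments, reads, weights):
        if aln.has_indel:
            continue
        any_free = True
        r = read.residues
        for p in range(1, S + 1):
            ref_pos = ref.proto_position_to_ref(p)
            ri = aln.read_index_for_ref(ref_pos)
            if ri is None:
                continue
            base = r[ri]
            if ref.strand == "-":
                base = revcomp(base)
            if base in _BASES:
                counts[p - 1, _BASES.index(base)] += w
                totals[p - 1] += w
    if not any_free:
        raise NoCallError("no indel-free reads: conversion rates undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        fracs = np.where(totals[:, None] > 0, counts / totals[:, None], 0.0)
    ref_bases = [
        t[ref.proto_position_to_ref(p)] if ref.strand == "+"
        else revcomp(t[ref.proto_position_to_ref(p)])
        for p in range(1, S + 1)
    ]
    df = pd.DataFrame(fracs, columns=list(_BASES), index=range(1, S + 1))
    df.insert(0, "ref_base", ref_bases)
    df["n"] = totals
    df.index.name = "protospacer_position"
    return df


@dataclass(frozen=True)
class EditSummary:
    n_reads: int
    n_discarded: int
    n_indel: int
    indel_fraction: float
    conversions: pd.DataFrame | None


def quantify(
    reads: Sequence[NucSequence] | Sequence[FastqRecord],
    ref: AmpliconRef,
    indel_window: int = 8,
    min_score_frac: float = 0.6,
    **align_params,
) -> EditSummary:
    """Full amplicon pipeline: align -> filter -> indel call -> conversions.

    Reads under *min_score_frac* of the maximum attainable score are
    discarded (contaminants must not deflate rates);
    indel_fraction = n_indel / (n_reads - n_discarded).  Identical reads
    are collapsed before alignment, so the summary is invariant under read
    duplication and order permutation.
    """
    seqs = [r.seq if isinstance(r, FastqRecord) else r for r in reads]
    if not seqs:
        raise ValueError("no reads supplied")
    match = align_params.get("match", 5.0)
    groups = Counter(s.residues for s in seqs)
    uniq = [NucSequence(f"u{i}", res) for i, res in enumerate(sorted(groups))]
    weights = [groups[u.residues] for u in uniq]

    alignments: list[ReadAlignment] = []
    kept_aln, kept_reads, kept_w = [], [], []
    n_discarded = n_indel = 0
    for u, w in zip(uniq, weights):
        aln = align_read(u, ref, **align_params)
        if aln.score < min_score_frac * match * len(u):
            n_discarded += w
            continue
        alignments.append(aln)
        if classify_indel(aln, ref, indel_window):
            n_indel += w
        else:
            kept_aln.append(aln)
            kept_reads.append(u)
            kept_w.append(w)
    n_reads = sum(weights)
    n_used = n_reads - n_discarded
    if n_used == 0:
        raise NoCallError(
            f"all {n_reads} reads discarded below score fraction {min_score_frac}"
        )
    conversions = None
    if kept_aln:
        conversions = conversion_rates(kept_aln, kept_reads, ref, kept_w)
    return EditSummary(
        n_reads=n_reads,
        n_discarded=n_discarded,
        n_indel=n_indel,
        indel_fraction=n_indel / n_used,
        conversions=conversions,
    )
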