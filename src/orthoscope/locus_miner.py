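"""CRISPR locus mining: repeat-spacer arrays, tracrRNA anti-repeat, sgRNA.

Detects repeat-spacer arrays with a seed-and-extend k-mer recurrence
scanner (CRT-style), calls a column-majority consensus repeat, finds the
tracrRNA anti-repeat as the best local alignment of the repeat's reverse
complement near the array, assembles a crRNA:tracrRNA single-guide
scaffold joined by the canonical "CGAA" tetraloop, and predicts a PAM from
the flanks of spacer->protospacer matches in user-supplied target
sequences.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from . import pam_depletion
from .seqcore import NucSequence, revcomp

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Degenerate or inconsistent detection parameters."""


@dataclass(frozen=True)
class CrisprArray:
    """A repeat-spacer array on one contig (0-based half-open intervals)."""

    contig: str
    repeat_intervals: tuple[tuple[int, int], ...]
    repeats: tuple[NucSequence, ...]
    spacers: tuple[NucSequence, ...]
    consensus_repeat: NucSequence

    def __post_init__(self) -> None:
        iv = self.repeat_intervals
        if len(iv) < 2:
            raise ValueError("array needs at least 2 repeat copies")
        for (a, b), (c, d) in zip(iv, iv[1:]):
            if not (a < b <= c < d):
                raise ValueError("repeat intervals must be ascending, non-overlapping")
        if len(self.spacers) != len(iv) - 1:
            raise ValueError("|spacers| must equal |repeats| - 1")

    @property
    def start(self) -> int:
        return self.repeat_intervals[0][0]

    @property
    def end(self) -> int:
        return self.repeat_intervals[-1][1]


@dataclass(frozen=True)
class AntiRepeatHit:
    """A candidate anti-repeat: local alignment of the repeat complement."""

    start: int
    end: int
    strand: str  # '+': anti-repeat on forward strand; '-': on reverse strand
    identity: float  # percent of alignment columns identical
    aligned_length: int
    score: float


@dataclass(frozen=True)
class SgRnaScaffold:
    """Single-guide scaffold: spacer + crRNA segment + CGAA + tracr segment."""

    spacer: NucSequence
    crrna_segment: NucSequence
    tracr_segment: NucSequence
    tetraloop: str = "CGAA"
    full_sequence: NucSequence = field(init=False)

    def __post_init__(self) -> None:
        if self.tetraloop != "CGAA":
            raise ValueError("tetraloop is fixed to CGAA")
        full = (
            self.spacer.residues
            + self.crrna_segment.residues
            + self.tetraloop
            + self.tracr_segment.residues
        )
        object.__setattr__(
            self, "full_sequence", NucSequence(f"sgRNA_{self.spacer.id}", full)
        )


# ---------------------------------------------------------------------------
# Array detection
# ---------------------------------------------------------------------------

_COL_MATCH = 1
_COL_MISMATCH = -3
_XDROP = 12


def _column_score(bases: list[str]) -> int:
    c = Counter(bases).most_common(1)[0][1]
    return c * _COL_MATCH + (len(bases) - c) * _COL_MISMATCH


def _extend_copies(
    s: str, positions: list[int], seed_k: int, max_repeat_len: int
) -> tuple[int, int]:
    """X-drop extension of seed occurrences into full repeat copies.

    Returns (left, right): columns gained left of the seed start and right
    of the seed end, maximizing the cumulative column-majority score while
    allowing bounded dips (single-copy substitutions score 0 for 4 copies
    and are absorbed; divergent flanking columns are strongly negative).
    """
    n = len(s)

    def extend(direction: int) -> int:
        best, best_d, cum = 0.0, 0, 0.0
        d = 0
        while True:
            d += 1
            if direction < 0:
                cols = [p - d for p in positions]
            else:
                cols = [p + seed_k - 1 + d for p in positions]
            if cols[0] < 0 or cols[-1] >= n:
                break
            cum += _column_score([s[c] for c in cols])
            if cum > best:
                best, best_d = cum, d
            if best - cum > _XDROP:
                break
        return best_d

    left = extend(-1)
    right = extend(+1)
    over = (seed_k + left + right) - max_repeat_len
    if over > 0:  # trim symmetrically if the extension overshot the cap
        trim_r = min(right, over)
        right -= trim_r
        left -= over - trim_r
    return left, right


def _chain_positions(positions: list[int], lo: int, hi: int) -> list[list[int]]:
    """Split sorted seed positions into maximal runs with period in [lo, hi]."""
    runs: list[list[int]] = []
    cur = [positions[0]]
    for p in positions[1:]:
        if lo <= p - cur[-1] <= hi:
            cur.append(p)
        else:
            if len(cur) > 1:
                runs.append(cur)
            cur = [p]
    if len(cur) > 1:
        runs.append(cur)
    return runs


def consensus_of(copies: list[str]) -> str:
    """Column-majority consensus of equal-or-near-equal-length strings.

    Copies are compared at the modal length; longer copies are trimmed at
    the 3' end, shorter ones simply stop voting beyond their length.
    Column ties break alphabetically (logged).
    """
    if not copies:
        raise ValueError("no repeat copies")
    modal_len = Counter(len(c) for c in copies).most_common(1)[0][0]
    out = []
    for i in range(modal_len):
        col = Counter(c[i] for c in copies if i < len(c))
        top = col.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            tied = sorted(b for b, n in top if n == top[0][1])
            logger.info("consensus tie at column %d: %s -> %s", i, tied, tied[0])
            out.append(tied[0])
        else:
            out.append(top[0][0])
    return "".join(out)


def detect_arrays(
    genome: NucSequence,
    min_repeats: int = 3,
    repeat_len: tuple[int, int] = (21, 48),
    spacer_len: tuple[int, int] = (18, 48),
    seed_k: int = 8,
    max_repeat_mismatch_frac: float = 0.2,
) -> list[CrisprArray]:
    """Find repeat-spacer arrays by seed-and-extend k-mer recurrence.

    Every exact seed k-mer recurring with a period compatible with the
    repeat/spacer length bounds nominates a candidate array; occurrences
    are extended into full repeat copies, validated against the length
    bounds and the per-copy mismatch budget, and deduplicated.
    Deterministic for fixed input and parameters; arrays are reported
    5'->3' on the forward strand.
    """
    if min_repeats < 2:
        raise ConfigError(f"min_repeats must be >= 2, got {min_repeats}")
    for name, (lo, hi) in (("repeat_len", repeat_len), ("spacer_len", spacer_len)):
        if lo > hi or lo < 1:
            raise ConfigError(f"inverted or degenerate {name} bounds {lo, hi}")
    if not 0 <= max_repeat_mismatch_frac < 1:
        raise ConfigError("max_repeat_mismatch_frac must be in [0, 1)")
    s = genome.residues
    if len(s) < 2 * repeat_len[0] + spacer_len[0]:
        return []

    period_lo = repeat_len[0] + spacer_len[0]
    period_hi = repeat_len[1] + spacer_len[1]

    kmer_pos: dict[str, list[int]] = defaultdict(list)
    for i in range(len(s) - seed_k + 1):
        kmer_pos[s[i : i + seed_k]].append(i)

    candidates: list[CrisprArray] = []
    seen: set[tuple[tuple[int, int], ...]] = set()
    for kmer in sorted(k for k, pos in kmer_pos.items() if len(pos) >= min_repeats):
        for run in _chain_positions(kmer_pos[kmer], period_lo, period_hi):
            if len(run) < min_repeats:
                continue
            left, right = _extend_copies(s, run, seed_k, repeat_len[1])
            intervals = [(p - left, p + seed_k + right) for p in run]
            rep_len = seed_k + left + right
            if not repeat_len[0] <= rep_len <= repeat_len[1]:
                continue
            if any(b > c for (_, b), (c, _) in zip(intervals, intervals[1:])):
                continue  # extension made copies overlap: not array-like
            gaps = [(b, c) for (_, b), (c, _) in zip(intervals, intervals[1:])]
            if not all(spacer_len[0] <= c - b <= spacer_len[1] for b, c in gaps):
                continue
            copies = [s[a:b] for a, b in intervals]
            cons = consensus_of(copies)
            budget = max_repeat_mismatch_frac * rep_len
            if any(
                sum(x != y for x, y in zip(c, cons)) > budget for c in copies
            ):
                continue
            key = tuple(intervals)
            if key in seen:
                continue
            seen.add(key)
            candidates.append(
                CrisprArray(
                    contig=genome.id,
                    repeat_intervals=key,
                    repeats=tuple(
                        NucSequence(f"{genome.id}_repeat{i}", c)
                        for i, c in enumerate(copies, 1)
                    ),
                    spacers=tuple(
                        NucSequence(f"{genome.id}_spacer{i}", s[b:c])
                        for i, (b, c) in enumerate(gaps, 1)
                    ),
                    consensus_repeat=NucSequence(f"{genome.id}_repeat_consensus", cons),
                )
            )

    # Deduplicate overlapping nominations (seeds at different offsets of the
    # same repeat converge to the same boundaries; keep the best per locus).
    candidates.sort(
        key=lambda a: (-len(a.repeat_intervals), -(a.end - a.start), a.start)
    )
    chosen: list[CrisprArray] = []
    for cand in candidates:
        if all(cand.end <= c.start or cand.start >= c.end for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda a: a.start)
    return chosen


def consensus_repeat(array: CrisprArray) -> NucSequence:
    """Column-majority consensus over an array's repeat copies."""
    if not array.repeats:
        raise ValueError("empty array")
    return NucSequence(
        f"{array.contig}_repeat_consensus",
        consensus_of([r.residues for r in array.repeats]),
    )


# ---------------------------------------------------------------------------
# Anti-repeat search
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    alphabet = "ACGTN"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            if "N" in (x, y):
                mat[x, y] = -1000.0  # N acts as a hard mask
            else:
                mat[x, y] = 2.0 if x == y else -3.0
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -7.0  # gap of length k costs 5 + 2k
    aligner.extend_gap_score = -2.0
    return aligner


def _alignment_stats(aln) -> tuple[int, int, int, int]:
    """(target_start, target_end, identities, columns) of a local alignment."""
    t_blocks, q_blocks = aln.aligned
    ident = 0
    cols = 0
    last_t = last_q = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if last_t is not None:
            cols += (ts - last_t) + (qs - last_q)  # gap columns
        t_seg = aln.target[ts:te]
        q_seg = aln.query[qs:qe]
        ident += sum(a == b for a, b in zip(t_seg, q_seg))
        cols += te - ts
        last_t, last_q = te, qe
    return int(t_blocks[0][0]), int(t_blocks[-1][1]), ident, cols


def find_anti_repeat(
    genome: NucSequence,
    repeat: NucSequence,
    exclude: list[tuple[int, int]] = (),
    min_identity: float = 60.0,
    min_len_frac: float = 0.66,
    flank_window: int = 20000,
    max_hits: int = 5,
) -> list[AntiRepeatHit]:
    """Rank candidate anti-repeats outside the array.

    The anti-repeat is located as a local alignment of the repeat's
    reverse complement against the genome ('+' hits; the tracrRNA is then
    transcribed off the forward strand) and of the repeat itself ('-'
    hits, anti-repeat on the reverse strand).  The search is confined to
    *flank_window* nt around the excluded array intervals; hits below the
    identity/length thresholds are dropped; output is sorted by score
    descending.
    """
    if len(repeat) < 15:
        raise ValueError("repeat too short for anti-repeat search (< 15 nt)")
    s = list(genome.residues)
    for a, b in exclude:
        for i in range(max(a, 0), min(b, len(s))):
            s[i] = "N"
    if exclude and flank_window:
        lo = max(0, min(a for a, _ in exclude) - flank_window)
        hi = min(len(s), max(b for _, b in exclude) + flank_window)
        for i in range(0, lo):
            s[i] = "N"
        for i in range(hi, len(s)):
            s[i] = "N"
    target = "".join(s)

    aligner = _make_aligner()
    min_len = min_len_frac * len(repeat)
    hits: list[AntiRepeatHit] = []
    for query, strand in ((revcomp(repeat.residues), "+"), (repeat.residues, "-")):
        masked = target
        for _ in range(max_hits):
            alns = aligner.align(masked, query)
            if len(alns) == 0 or alns.score <= 0:
                break
            aln = alns[0]
            if len(aln.aligned[0]) == 0:
                break
            ts, te, ident, cols = _alignment_stats(aln)
            if cols == 0:
                break
            identity = 100.0 * ident / cols
            if cols >= min_len and identity >= min_identity:
                hits.append(
                    AntiRepeatHit(
                        start=ts, end=te, strand=strand,
                        identity=identity, aligned_length=cols,
                        score=float(alns.score),
                    )
                )
            elif identity < min_identity and cols < min_len:
                break  # nothing above threshold remains
            masked = masked[:ts] + "N" * (te - ts) + masked[te:]
    hits.sort(key=lambda h: (-h.score, h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# sgRNA scaffold assembly
# ---------------------------------------------------------------------------

def assemble_sgrna(
    repeat: NucSequence,
    tracr_candidate: NucSequence,
    anti_repeat_interval: tuple[int, int],
    spacer: NucSequence,
    repeat_3p_trim: int = 0,
    antirepeat_5p_trim: int = 0,
) -> SgRnaScaffold:
    """Join repeat and tracrRNA into a single-guide scaffold (DNA alphabet).

    full = spacer + repeat[: -repeat_3p_trim] + "CGAA" + tracr[anti_repeat
    start + antirepeat_5p_trim :].  The crRNA repeat 3' end and the
    anti-repeat 5' end form the duplex closed by the tetraloop; both trims
    are exposed because the duplex register is organism-specific.
    """
    a, b = anti_repeat_interval
    if not 0 <= a < b <= len(tracr_candidate):
        raise ConfigError("anti-repeat interval must lie within the tracr candidate")
    if repeat_3p_trim < 0 or repeat_3p_trim >= len(repeat):
        raise ConfigError(f"repeat_3p_trim {repeat_3p_trim} out of range")
    crrna = repeat.residues[: len(repeat) - repeat_3p_trim]
    tracr_tail = tracr_candidate.residues[a + antirepeat_5p_trim :]
    if antirepeat_5p_trim < 0 or not tracr_tail:
        raise ConfigError(f"antirepeat_5p_trim {antirepeat_5p_trim} out of range")
    return SgRnaScaffold(
        spacer=spacer,
        crrna_segment=NucSequence(f"{repeat.id}_crrna", crrna),
        tracr_segment=NucSequence(f"{tracr_candidate.id}_tracr", tracr_tail),
    )


# ---------------------------------------------------------------------------
# PAM prediction from spacer -> protospacer matches
# ---------------------------------------------------------------------------

def _hamming_occurrences(spacer: str, target: str, max_mismatch: int):
    L = len(spacer)
    for i in range(len(target) - L + 1):
        mm = 0
        for a, b in zip(spacer, target[i : i + L]):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            yield i


def predict_pam_from_spacers(
    spacers: list[NucSequence],
    targets: list[NucSequence],
    max_mismatch: int = 2,
    flank_len: int = 10,
    include_threshold: float = 0.10,
) -> tuple[list[str], "pam_depletion.PamConsensus | None"]:
    """Collect 3'-of-protospacer flanks and call an IUPAC PAM consensus.

    Each spacer is matched ungapped (<= *max_mismatch* mismatches) on both
    strands of every target; the *flank_len*-nt flank 3' of the
    protospacer on the protospacer strand is collected.  Occurrences too
    close to a target end for a full flank are skipped with a log line.
    Returns (flanks, consensus); consensus is None when no flank was
    collected (explicit no-call).
    """
    if not spacers:
        raise ValueError("need at least one spacer")
    if not targets:
        raise ValueError("targets collection is empty")
    flanks: list[str] = []
    for spacer in spacers:
        sp = spacer.residues
        for tgt in targets:
            t = tgt.residues
            L = len(sp)
            for i in _hamming_occurrences(sp, t, max_mismatch):
                if i + L + flank_len <= len(t):
                    flanks.append(t[i + L : i + L + flank_len])
                else:
                    logger.info(
                        "spacer %s hit at %s:%d lacks %d-nt 3' flank; skipped",
                        spacer.id, tgt.id, i, flank_len,
                    )
            for i in _hamming_occurrences(revcomp(sp), t, max_mismatch):
                if i - flank_len >= 0:
                    flanks.append(revcomp(t[i - flank_len : i]))
                else:
                    logger.info(
                        "spacer %s reverse hit at %s:%d lacks flank; skipped",
                        spacer.id, tgt.id, i,
                    )
    if not flanks:
        return [], None
    weights = Counter(flanks)
    pfm = pam_depletion.pfm_from_set(set(flanks), weights=weights)
    consensus = pam_depletion.iupac_consensus(
        pfm, include_threshold, support_size=len(flanks)
    )
    return flanks, consensus
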