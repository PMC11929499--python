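# Methods

This note documents the models and procedures implemented in orthoscope,
the parameter choices that matter, what the synthetic generators emulate,
and the known limitations. Coordinates are 0-based half-open internally
and 1-based inclusive in all user-facing reports.

## CRISPR array detection (`locus_miner.detect_arrays`)

A seed-and-extend k-mer recurrence scanner in the CRT family. Every
exact 8-mer that recurs with a period compatible with the length bounds
(repeat 21–48 nt, spacer 18–48 nt, so period 39–96) nominates a
candidate array. Occurrences are extended outward column-by-column under
an X-drop criterion: a column contributes (majority count)·(+1) +
(minority count)·(−3), extension keeps the offset maximizing the
cumulative score and stops after a 12-point drop. With four identical
copies a flanking random column scores ≥ 0 only when at least three
copies agree by chance, so boundaries are sharp; with one substitution
per copy the affected column scores 0 and is absorbed. Candidates are
validated (length bounds, per-copy mismatch fraction ≤ 0.2 against the
column-majority consensus, spacer-length bounds), deduplicated across
seeds, and reported 5'→3' on the forward strand — the detector does not
attempt to orient arrays by a leader sequence, and the choice of which
repeat end abuts the tracrRNA duplex is left to the scaffold-assembly
trims (below).

The consensus repeat is per-column majority over equal-length copies
(modal length; longer copies trimmed 3'); ties break alphabetically and
are logged. This replaces a multiple alignment, which is unnecessary
when copies are near-identical and equal-length by construction.

## Anti-repeat search (`locus_miner.find_anti_repeat`)

The tracrRNA anti-repeat is found as the best local alignment (match +2,
mismatch −3, gap of length k costs 5 + 2k) of the repeat's reverse
complement against the genome ('+' hits) and of the repeat itself ('−'
hits, anti-repeat on the reverse strand), with the array masked out and
the search confined to 20 kb around it. Iterated best-hit-then-mask
yields a ranked list; hits below 60% identity or 2/3 of the repeat
length are dropped. The alignment engine is Biopython's
`PairwiseAligner`; the scoring thresholds are this package's defaults
since no published values exist for this step.

## sgRNA scaffold (`locus_miner.assemble_sgrna`)

full = spacer + repeat[:−repeat_3p_trim] + `CGAA` + tracr[anti_repeat_start
+ antirepeat_5p_trim:]. The two trims set the register of the
crRNA:tracrRNA duplex closed by the tetraloop; they are exposed
parameters because the duplex register is organism-specific and no
general rule exists. Output is DNA alphabet; transcription is the
user's concern.

## PAM inference (`pam_depletion`)

Fold depletion uses library-size normalization with pseudocount 0.5 so
fully cleaved k-mers keep finite ratios; at pseudocount 0 ratios are
exactly invariant under uniform depth rescaling. The depleted set
(threshold 10) is summarized with *uniform* k-mer weighting in the
position frequency matrix — depth weighting is available but jackpot
PCR duplicates would otherwise dominate. IUPAC consensus letters cover
every base with frequency ≥ 0.10 (configurable; must be ≤ 0.25 so every
position calls); positions where all four bases pass become N; trailing
3' N positions are trimmed from the reported string (a 7-mer window thus
reports e.g. a 6-nt PAM) while leading Ns are kept because position 1
abuts the protospacer. Logo heights use the standard small-sample-free
information content IC = 2 + Σ f·log₂f.

Whether the control library is the naive plasmid pool or a no-sgRNA
cleavage control is an experimental choice; the module accepts any
control count table.

## Base-editing target space (`edit_targets`)

Protospacer positions are numbered 1..L from the 5' (PAM-distal) end;
the PAM sits immediately 3' of position L. Editing windows default to
4–8 (SpyCas9-class) and 3–11 (SauCas9-class, also used for the compact
orthologs). The reversion convention is the default: a pathogenic SNV is
ABE-addressable when the *alt* allele presents adenine on some strand and
A→G editing restores ref (genomic alt→ref ∈ {A→G, T→C}); CBE analogous.
The opposite orientation ("install") is a flag. Variants whose context
lacks a full spacer+PAM flank on either side are reported as a distinct
"undeterminable" category, never silently false.

## Amplicon quantification (`amplicon_quant`)

Alignment: global, affine gaps (match +5, mismatch −4, open 10, extend
0.5), free end gaps, via Biopython's `PairwiseAligner`; a
length-preserving near-copy (mismatch cost below one gap pair) takes a
gapless fast path. Identical reads are collapsed before alignment, which
also makes summaries exactly invariant under read duplication and
permutation. Reads scoring below 0.6 of the maximum attainable score are
discarded and counted (contaminants must not deflate rates). The cut
site is fixed 3 nt 5' of the PAM (blunt Cas9 cut); an indel read is one
with an insertion/deletion op overlapping cut ± 8 nt (window
configurable; no published window exists for this assay class, ±8
matches common amplicon-analysis practice). Conversion rates are
tabulated only among indel-free reads to avoid alignment-ambiguity
artifacts, as a full per-position substitution matrix so either an A→G
or an A→C reading of "conversion" is recoverable. Base qualities are
parsed but ignored by default.

## Ortholog comparison (`ortholog_compare`)

Percent identity = identical pairs / all alignment columns (including
gap columns) × 100, rounded to integer, from a global BLOSUM62 alignment
(open 10, extend 0.5); the aligned-pairs-only denominator is a flag. The
pair is canonically ordered before aligning so identity is exactly
symmetric. Distances: p-distance or Jukes-Cantor-type
d = −((a−1)/a)·ln(1 − a·p/(a−1)) with a = 20 for proteins (4 for
nucleotides); saturated pairs (p ≥ (a−1)/a) are capped at d = 5 with a
warning rather than infinity. Neighbor joining is the canonical
Saitou–Nei algorithm with the Q-criterion, lowest-index tie-breaking and
negative branch lengths clamped to zero; on additive matrices it
provably recovers the generating topology, which the test suite checks
on 100 random additive trees. Trees are built from pairwise distances
only — no multiple alignment or bootstrap resampling is performed, a
deliberate simplification — and serialized as Newick (round-trip safe to
1e−6).

## Synthetic generators (`synth`)

All generators draw from a single `numpy.random.default_rng(seed)`
stream and regenerate byte-identically; each writes a truth record, and
recovery tests read truth only from that record.

- **Genomes** (default 3 kb, four 36-nt repeats, 30-nt spacers): random
  background, planted array, planted reverse-complement anti-repeat
  (degradable to a target identity) 400 nt downstream. The two columns
  just outside each repeat boundary are redrawn so no base reaches
  majority across copies: a flanking column that agreed across all
  copies would itself be part of the repeat under any consistent
  definition, so this guarantees the planted coordinates are the unique
  well-defined answer.
- **PAM libraries**: control counts multinomial over all 4^7 7-mers at
  100× mean depth; cleaved counts are per-molecule binomial survival with
  cleavage probability 0.95 for PAM-matching 7-mers and 0.01 otherwise —
  an idealized, sequence-independent cleavage model.
- **Amplicon reads**: full-length amplicon copies; indels (geometric
  size 1–10, deletion/insertion equally likely) are placed uniformly
  within ±3 nt of the cut site so the ±8 nt classification window always
  captures them (a documented coupling); A→G conversions are applied per
  protospacer position to non-indel reads; uniform 0.1% substitution
  noise everywhere. No quality-dependent error model, no paired ends,
  no PCR bias.
- **Variant tables**: contexts are an ablated all-C backbone with a G>A
  variant at the center, so only forward-strand ABE guides can qualify
  and targetability is controlled entirely by planting or withholding
  PAM bases (NGG for the reference editor, NNAATA for the query editor)
  at offsets chosen so no category's motif can create a match for the
  other editor. Truth is therefore known by construction and never
  computed with the checker under test.
- **Ortholog panel**: random proteins with planted lengths (1,122 /
  1,130 / 1,140 / 1,053 / 1,368 aa) and a Sin/Spy-style pair planted at
  70% identity by substituting 30% of a shared template. These are
  synthetic stand-ins — real Cas9 sequences have domain structure,
  composition bias and indel divergence these do not — so tests against
  them validate the alignment/measurement machinery, not any biological
  claim.

What passing these benchmarks shows: the detectors, estimators and
bookkeeping recover planted parameters at realistic scale. What they do
not show: robustness to real sequencing error structure, repeat-rich
genomes, diverged repeat copies beyond the mismatch budget, or real
protein families.

## Problem sizes

The standard verification run uses 200 seeded genomes for locus-mining
recovery, 20 seeded libraries for PAM recovery, 20 seeds × 5,000 reads ×
three indel rates (0.05 / 0.2 / 0.5) for rate recovery, 50,000 reads for
the ~1% conversion profile, 500 random read/reference pairs against an
independent Gotoh DP oracle, 200 planted variants for target-space
bookkeeping, and 100 random additive trees (4–10 taxa) for NJ; the whole
suite completes in about a minute on one core.
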