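# orthoscope

A tested, reusable pipeline for the computational characterization of
CRISPR-Cas9 orthologs. Novel Cas9 proteins — for example the compact
orthologs from *Streptococcus uberis*, *S. gallolyticus*, *S.
parasanguinis* and *S. iniae* — are attractive genome-editing effectors
because of their size (single-AAV deliverable), orthogonal PAM
preferences, and low expected human pre-immunity. Characterizing one is a
chain of sequence-analysis steps, each implemented here as a library
module with a thin CLI on top:

| stage | module | what it computes |
| --- | --- | --- |
| CRISPR locus mining | `locus_miner` | repeat-spacer arrays (seed-and-extend k-mer recurrence), consensus repeat, tracrRNA anti-repeat (local alignment of the repeat complement), sgRNA scaffold (crRNA + `CGAA` tetraloop + tracr), PAM prediction from spacer→protospacer flanks |
| empirical PAM inference | `pam_depletion` | fold-depletion of 7-mer PAM candidates between control and cleaved randomized libraries, ≥10-fold depleted set, position frequency matrix, IUPAC consensus, logo, targetable fraction |
| base-editing target space | `edit_targets` | guide-site scanning, per-SNV targetability under an editor's PAM + editing window + chemistry, target-space gains of new editors over a reference set |
| amplicon edit quantification | `amplicon_quant` | affine-gap global alignment of reads, indel calling in a ±8 nt cut-site window, per-protospacer-position A→G conversion rates |
| ortholog comparison | `ortholog_compare` | pairwise global-alignment percent identity (BLOSUM62), Jukes-Cantor distances, Saitou-Nei neighbor-joining trees, Newick I/O |
| synthetic data | `synth` | seeded generators for every input above, with machine-readable planted truth |

## The core quantities

**Fold depletion.** In a depletion assay a Cas9:sgRNA ribonucleoprotein
cleaves a plasmid library carrying a randomized 7-bp PAM; functional PAMs
are destroyed, so for each 7-mer *w* with counts *c*(·) and library sizes
*N*(·),

    ratio(w) = [(c_ctrl(w)+p) / (N_ctrl+p·4^k)] / [(c_clv(w)+p) / (N_clv+p·4^k)]

(pseudocount *p* = 0.5). k-mers with ratio ≥ 10 form the depleted set,
whose column base frequencies collapse to an IUPAC consensus (letters
cover every base with frequency ≥ 0.10). The **targetable fraction** of a
degenerate PAM is ∏ᵢ |bases(letterᵢ)|/4 — e.g. NNARTA covers exactly
twice the sequence space of NNAATA.

**Base-editing targetability.** A G→A variant is addressable by an
adenine base editor when the pathogenic allele presents an adenine on
some strand at protospacer position *p* with w_lo ≤ p ≤ w_hi of a guide
whose PAM matches immediately 3′ of the protospacer (window 4–8 for
SpyCas9-class editors, 3–11 for SauCas9-class), so that A→G editing
restores the reference allele.

**Edit quantification.** Reads align to the amplicon under affine gap
penalties (match +5, mismatch −4, gap open 10, extend 0.5, free end
gaps); a read is an indel read iff an insertion/deletion op overlaps the
cut site (3 nt 5′ of the PAM) ± 8 nt; conversion rates are tabulated per
protospacer position among indel-free reads.

## Worked example

Simulate a depletion experiment for a cleaver whose true PAM is NNARTA,
then infer the PAM from the count tables alone:

```
$ orthoscope synth pam-library --seed 7 --out lib
pam-library (seed 7) -> lib/
$ orthoscope pam-infer --control lib/control.tsv --cleaved lib/cleaved.tsv --out pam.json
PAM NNARTA (targetable fraction 0.007812) -> pam.json
```

The inferred consensus is `NNARTA` with 125 seven-mers depleted ≥10-fold
behind it, and a targetable fraction of 0.0078 (= 1/128: positions A, R,
T, A constrain 1/4 · 1/2 · 1/4 · 1/4 of random sequence space).

Mining a (synthetic) genome for its CRISPR locus:

```
$ orthoscope synth genome --seed 7 --out g
$ orthoscope mine --genome g/genome.fasta --out loci.json
1 array(s) -> loci.json
```

`loci.json` reports the array (four 36-nt repeats at 1-based intervals
[2138, 2173] … [2336, 2371]), the consensus repeat
`TGGTGTTAACCTTACTATACTCCCGCTCCGGGGTTT`, the top anti-repeat hit
([2772, 2807], forward strand, 100% identity, score 72), and an
assembled sgRNA scaffold (spacer + repeat + `CGAA` + tracr tail).

The other stages work the same way — `orthoscope target-space`,
`orthoscope amplicon`, `orthoscope compare` — and every `orthoscope
synth` generator writes a `truth.json` recording exactly what was
planted.

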