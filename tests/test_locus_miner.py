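"""Locus mining: array detection, consensus, anti-repeat, sgRNA, PAM."""

import numpy as np
import pytest

from orthoscope import synth
from orthoscope.locus_miner import (
    ConfigError,
    CrisprArray,
    SgRnaScaffold,
    assemble_sgrna,
    consensus_of,
    consensus_repeat,
    detect_arrays,
    find_anti_repeat,
    predict_pam_from_spacers,
)
from orthoscope.seqcore import NucSequence, revcomp

from oracles import local_best_alignment


def _toy_array_genome(repeat, spacers, flank_left="T" * 60, flank_right="A" * 60):
    parts = [flank_left, repeat]
    for sp in spacers:
        parts += [sp, repeat]
    parts.append(flank_right)
    return NucSequence("toy", "".join(parts)), len(flank_left)


class TestDetectArrays:
    def test_planted_exact_array_recovered(self):
        rng = np.random.default_rng(5)
        repeat = "".join(rng.choice(list("ACGT"), 36))
        spacers = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(3)]
        genome, off = _toy_array_genome(repeat, spacers)
        arrays = detect_arrays(genome)
        assert len(arrays) == 1
        a = arrays[0]
        assert len(a.repeat_intervals) == 4
        assert a.repeat_intervals[0] == (off, off + 36)
        assert [s.residues for s in a.spacers] == spacers
        assert a.consensus_repeat.residues == repeat

    def test_random_sequence_has_no_arrays(self):
        rng = np.random.default_rng(17)
        genome = NucSequence("rand", "".join(rng.choice(list("ACGT"), 10_000)))
        assert detect_arrays(genome) == []

    def test_mutated_repeat_copies_recovered(self):
        rng = np.random.default_rng(3)
        repeat = "".join(rng.choice(list("ACGT"), 36))
        copies = []
        for i in range(4):
            c = list(repeat)
            j = int(rng.integers(0, 36))
            c[j] = {"A": "C", "C": "G", "G": "T", "T": "A"}[c[j]]
            copies.append("".join(c))
        spacers = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(3)]
        parts = ["T" * 60, copies[0]]
        for sp, c in zip(spacers, copies[1:]):
            parts += [sp, c]
        parts.append("A" * 60)
        genome = NucSequence("mut", "".join(parts))
        arrays = detect_arrays(genome)
        assert len(arrays) == 1
        assert len(arrays[0].repeat_intervals) == 4
        assert arrays[0].repeat_intervals[0][0] == 60

    def test_flank_concatenation_shifts_coordinates(self, planted_genome):
        genome, truth = planted_genome
        prefix = "TGCA" * 250
        shifted = NucSequence("shifted", prefix + genome.residues)
        a0 = detect_arrays(genome)[0]
        a1 = detect_arrays(shifted)[0]
        assert [
            (s + len(prefix), e + len(prefix)) for s, e in a0.repeat_intervals
        ] == list(a1.repeat_intervals)

    def test_degenerate_params_rejected(self, planted_genome):
        genome, _ = planted_genome
        with pytest.raises(ConfigError):
            detect_arrays(genome, min_repeats=1)
        with pytest.raises(ConfigError):
            detect_arrays(genome, repeat_len=(48, 21))


class TestConsensusRepeat:
    def test_unanimous(self):
        assert consensus_of(["ACGT", "ACGT", "ACGT"]) == "ACGT"

    def test_majority_column(self):
        assert consensus_of(["ACGT", "ACGT", "ACTT"]) == "ACGT"

    def test_tie_breaks_alphabetically(self):
        assert consensus_of(["ACGT", "ACTT"]) == "ACGT"  # G vs T tie -> G

    def test_array_consensus_matches_planted_repeat(self, planted_genome):
        genome, truth = planted_genome
        a = detect_arrays(genome)[0]
        assert consensus_repeat(a).residues == truth.params["repeat"]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            consensus_of([])


class TestAntiRepeat:
    def test_exact_planted_anti_repeat_is_top_hit(self, planted_genome):
        genome, truth = planted_genome
        a = detect_arrays(genome)[0]
        hits = find_anti_repeat(
            genome, a.consensus_repeat, exclude=list(a.repeat_intervals)
        )
        lo, hi = truth.params["anti_repeat_interval"]
        assert hits and (hits[0].start, hits[0].end) == (lo, hi)
        assert hits[0].identity == 100.0

    def test_degraded_anti_repeat_still_top_hit_and_matches_oracle(self):
        genome, truth = synth.make_genome_with_array(
            23, genome_len=2000, anti_repeat_identity=91.7, anti_repeat_offset=300
        )
        repeat = NucSequence("rep", truth.params["repeat"])
        exclude = [tuple(iv) for iv in truth.params["repeat_intervals"]]
        hits = find_anti_repeat(genome, repeat, exclude=exclude)
        lo, hi = truth.params["anti_repeat_interval"]
        top = hits[0]
        assert top.start < hi and top.end > lo  # overlaps planted interval
        # score agrees with an exhaustive local-alignment oracle on the
        # masked genome
        masked = list(genome.residues)
        for s, e in exclude:
            masked[s:e] = "N" * (e - s)
        oracle_score, _, o_end = local_best_alignment(
            revcomp(repeat.residues), "".join(masked)
        )
        assert top.score == pytest.approx(oracle_score)

    def test_everything_excluded_gives_no_hits(self):
        rng = np.random.default_rng(2)
        repeat = "".join(rng.choice(list("ACGT"), 36))
        genome = NucSequence("onlyarray", repeat + "ACGT" * 8 + repeat)
        hits = find_anti_repeat(
            genome, NucSequence("r", repeat), exclude=[(0, len(genome))]
        )
        assert hits == []

    def test_score_invariant_under_genome_revcomp(self, planted_genome):
        genome, truth = planted_genome
        a = detect_arrays(genome)[0]
        fwd = find_anti_repeat(genome, a.consensus_repeat,
                               exclude=list(a.repeat_intervals))
        L = len(genome)
        rc_exclude = [(L - e, L - s) for s, e in a.repeat_intervals]
        rev = find_anti_repeat(revcomp(genome), a.consensus_repeat,
                               exclude=rc_exclude)
        assert fwd and rev
        assert fwd[0].score == rev[0].score
        assert (rev[0].start, rev[0].end) == (L - fwd[0].end, L - fwd[0].start)
        assert rev[0].strand != fwd[0].strand

    def test_short_repeat_rejected(self, planted_genome):
        genome, _ = planted_genome
        with pytest.raises(ValueError):
            find_anti_repeat(genome, NucSequence("r", "ACGTACGTACGT"))


class TestAssembleSgrna:
    repeat = NucSequence("rep", "GTTTTAGAGCTA")
    tracr = NucSequence("tracr", "TAGCTCTAAAACTTGCTATGCTGTT")

    def test_concatenation_definition(self):
        spacer = NucSequence("sp", "N" * 20)
        sc = assemble_sgrna(self.repeat, self.tracr, (0, 12), spacer)
        assert sc.full_sequence.residues == (
            spacer.residues + self.repeat.residues + "CGAA" + self.tracr.residues
        )

    def test_repeat_3p_trim(self):
        sc = assemble_sgrna(
            self.repeat, self.tracr, (0, 12), NucSequence("sp", "A" * 20),
            repeat_3p_trim=2,
        )
        assert sc.crrna_segment.residues == self.repeat.residues[:-2]

    def test_round_trip_split_at_tetraloop(self):
        sc = assemble_sgrna(self.repeat, self.tracr, (0, 12),
                            NucSequence("sp", "A" * 20))
        body = sc.full_sequence.residues[20:]
        crrna, tracr = body.split("CGAA", 1)
        assert crrna == sc.crrna_segment.residues
        assert tracr == sc.tracr_segment.residues

    def test_bad_trims_rejected(self):
        with pytest.raises(ConfigError):
            assemble_sgrna(self.repeat, self.tracr, (0, 12),
                           NucSequence("sp", "A" * 20), repeat_3p_trim=12)
        with pytest.raises(ConfigError):
            assemble_sgrna(self.repeat, self.tracr, (5, 30),
                           NucSequence("sp", "A" * 20))


class TestPredictPamFromSpacers:
    def _plant(self, rng, spacer, flank, strand="+"):
        bg = "".join(rng.choice(list("C"), 120))
        ins = spacer + flank if strand == "+" else revcomp(spacer + flank)
        pos = int(rng.integers(10, 60))
        return NucSequence(f"t{pos}", bg[:pos] + ins + bg[pos:])

    def test_planted_ngg_flanks_give_ngg_consensus(self):
        # flanks share GG at positions 2-3; position 1 varies over all bases
        rng = np.random.default_rng(9)
        spacers = [
            NucSequence(f"sp{i}", "".join(rng.choice(list("AGT"), 20)))
            for i in range(8)
        ]
        targets = [
            self._plant(
                rng, sp.residues,
                "ACGT"[i % 4] + "GG" + "".join(rng.choice(list("ACGT"), 7)),
            )
            for i, sp in enumerate(spacers)
        ]
        flanks, consensus = predict_pam_from_spacers(spacers, targets)
        assert len(flanks) == 8
        assert consensus.iupac.letters.startswith("NGG")

    def test_absent_spacer_contributes_nothing(self):
        spacers = [NucSequence("sp", "ACGTACGTACGTACGTACGT")]
        targets = [NucSequence("t", "T" * 200)]
        flanks, consensus = predict_pam_from_spacers(spacers, targets)
        assert flanks == [] and consensus is None

    def test_reverse_strand_gives_same_flank(self):
        rng = np.random.default_rng(4)
        spacer = NucSequence("sp", "".join(rng.choice(list("AGT"), 20)))
        flank = "TGGATTCCAA"
        fwd_t = self._plant(np.random.default_rng(1), spacer.residues, flank, "+")
        rev_t = self._plant(np.random.default_rng(1), spacer.residues, flank, "-")
        f1, _ = predict_pam_from_spacers([spacer], [fwd_t])
        f2, _ = predict_pam_from_spacers([spacer], [rev_t])
        assert f1 == f2 == [flank]
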