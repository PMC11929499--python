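"""Guide scanning, variant targetability, target-space bookkeeping."""

import numpy as np
import pytest

from orthoscope import synth
from orthoscope.edit_targets import (
    ConfigError,
    Editor,
    VariantRecord,
    read_variants_tsv,
    read_vcf,
    scan_guides,
    summarize_target_space,
    variant_targetable,
    write_vcf,
)
from orthoscope.seqcore import IupacPattern, NucSequence, iupac_matches, revcomp

from oracles import brute_iupac_hits

ABE_NGG = Editor("SpyABE", IupacPattern("NGG"), (4, 8))


def brute_guides(seq: str, editor: Editor):
    """Independent guide enumeration from raw IUPAC window hits."""
    S, P = editor.spacer_len, len(editor.pam)
    out = []
    for start, end, strand in brute_iupac_hits(editor.pam.letters, seq):
        if strand == "+" and start >= S:
            out.append((start - S, start, "+"))
        if strand == "-" and end + S <= len(seq):
            out.append((end, end + S, "-"))
    return sorted(out)


class TestEditor:
    def test_window_must_fit_spacer(self):
        with pytest.raises(ConfigError):
            Editor("bad", IupacPattern("NGG"), (0, 8))
        with pytest.raises(ConfigError):
            Editor("bad", IupacPattern("NGG"), (4, 21))

    def test_substrate_product(self):
        assert ABE_NGG.substrate == "A" and ABE_NGG.product == "G"
        cbe = Editor("CBE", IupacPattern("NGG"), (4, 8), chemistry="CBE")
        assert cbe.substrate == "C" and cbe.product == "T"


class TestScanGuides:
    def test_two_planted_forward_ngg_sites(self):
        # two NGG occurrences >= 20 nt from the 5' end, forward strand only
        s = "T" * 20 + "AGG" + "T" * 17 + "CGG" + "T" * 17
        guides = scan_guides(NucSequence("toy", s), ABE_NGG)
        fwd = [g for g in guides if g.strand == "+"]
        assert len(fwd) == 2
        assert {g.pam_start for g in fwd} == {20, 40}

    def test_saturating_pam_yields_guide_per_window_per_strand(self):
        editor = Editor("any", IupacPattern("NNNNNNN"), (4, 8))
        s = "ACGTACGTACGTACGTACGTACGTACGTACG"  # len 31
        guides = scan_guides(NucSequence("t", s), editor)
        eligible = len(s) - editor.spacer_len - 7 + 1
        assert len(guides) == 2 * eligible

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_sequence(self, seed):
        rng = np.random.default_rng(seed)
        s = "".join(rng.choice(list("ACGT"), 500))
        editor = Editor("SubABE", IupacPattern("NNARTA"), (3, 11))
        got = sorted(
            (g.proto_start, g.proto_end, g.strand)
            for g in scan_guides(NucSequence("r", s), editor)
        )
        assert got == brute_guides(s, editor)

    def test_region_out_of_bounds(self):
        with pytest.raises(ValueError):
            scan_guides(NucSequence("t", "ACGT" * 20), ABE_NGG, region=(0, 1000))


def _toy_context(proto_pos_of_variant: int, pam: str = "AGG", length: int = 60):
    """All-T context with one A inside a planted forward NGG protospacer.

    The 10-nt protospacer occupies [20, 30), PAM at [30, 33); the variant
    sits at the requested 1-based protospacer position.
    """
    s = ["T"] * length
    s[30:33] = list(pam)
    v0 = 20 + proto_pos_of_variant - 1
    s[v0] = "G"  # ref allele G; alt A presents the ABE substrate
    return NucSequence("ctx", "".join(s)), v0


class TestVariantTargetable:
    def test_substrate_in_window_true(self):
        ctx, v0 = _toy_context(5)
        v = VariantRecord("ctx", v0 + 1, "G", "A")
        editor = Editor("e", IupacPattern("NGG"), (4, 8), spacer_len=10)
        decision, guides = variant_targetable(v, ctx, editor)
        assert decision is True and guides

    def test_no_pam_anywhere_false(self):
        s = ["T"] * 60
        s[30] = "G"
        ctx = NucSequence("ctx", "".join(s))
        v = VariantRecord("ctx", 31, "G", "A")
        decision, guides = variant_targetable(v, ctx, ABE_NGG)
        assert decision is False and guides == []

    def test_position_outside_window_false(self):
        ctx, v0 = _toy_context(9)  # window is 4..8
        v = VariantRecord("ctx", v0 + 1, "G", "A")
        editor = Editor("e", IupacPattern("NGG"), (4, 8), spacer_len=10)
        decision, _ = variant_targetable(v, ctx, editor)
        # brute check: A only at protospacer position 9 of any guide
        assert decision is False

    def test_wrong_substrate_false(self):
        ctx, v0 = _toy_context(5)
        v = VariantRecord("ctx", v0 + 1, "C", "A")  # alt->ref A->C, not A->G
        editor = Editor("e", IupacPattern("NGG"), (4, 8), spacer_len=10)
        assert variant_targetable(v, ctx, editor)[0] is False

    def test_insufficient_flank_is_undeterminable(self):
        ctx = NucSequence("ctx", "T" * 30)
        v = VariantRecord("ctx", 5, "G", "A")
        assert variant_targetable(v, ctx, ABE_NGG)[0] == "undeterminable"

    def test_strand_symmetry(self):
        variants, contexts, truth = synth.make_variant_table(3, n_variants=40)
        editor = synth.DEFAULT_QUERY_EDITOR
        for v in variants[:20]:
            ctx = contexts[v.contig]
            d1, _ = variant_targetable(v, ctx, editor)
            mirrored = VariantRecord(
                v.contig, len(ctx) - v.position + 1, revcomp(v.ref), revcomp(v.alt)
            )
            d2, _ = variant_targetable(mirrored, revcomp(ctx), editor)
            assert d1 == d2

    def test_monotone_in_window_and_pam(self):
        variants, contexts, _ = synth.make_variant_table(5, n_variants=60)
        tight = Editor("t", IupacPattern("NGG"), (5, 6))
        wide = Editor("w", IupacPattern("NGG"), (3, 11))
        relaxed = Editor("r", IupacPattern("NGN"), (5, 6))
        for v in variants:
            ctx = contexts[v.contig]
            base, _ = variant_targetable(v, ctx, tight)
            if base is True:
                assert variant_targetable(v, ctx, wide)[0] is True
                assert variant_targetable(v, ctx, relaxed)[0] is True


class TestSummarize:
    def test_constructed_three_variant_truth(self):
        variants, contexts, _ = synth.make_variant_table(
            2, n_variants=3,
            mix={"reference_only": 1 / 3, "query_only": 1 / 3, "none": 1 / 3},
        )
        summary = summarize_target_space(
            variants, contexts,
            [synth.DEFAULT_REF_EDITOR, synth.DEFAULT_QUERY_EDITOR],
            ["SpyABE"], ["SubABE"],
        )
        assert summary.reference_count == 1
        assert summary.union_count == 2
        assert summary.added_count == 1
        assert summary.total == 3

    def test_query_equal_reference_adds_nothing(self):
        variants, contexts, _ = synth.make_variant_table(4, n_variants=30)
        s = summarize_target_space(
            variants, contexts,
            [synth.DEFAULT_REF_EDITOR, synth.DEFAULT_QUERY_EDITOR],
            ["SpyABE"], ["SpyABE"],
        )
        assert s.added_count == 0

    def test_planted_truth_exact_and_invariants(self):
        variants, contexts, truth = synth.make_variant_table(6, n_variants=200)
        s = summarize_target_space(
            variants, contexts,
            [synth.DEFAULT_REF_EDITOR, synth.DEFAULT_QUERY_EDITOR],
            ["SpyABE"], ["SubABE"],
        )
        counts = truth.params["counts"]
        assert s.per_editor["SpyABE"] == counts["reference_only"] + counts["both"]
        assert s.per_editor["SubABE"] == counts["query_only"] + counts["both"]
        assert s.reference_count == counts["reference_only"] + counts["both"]
        assert s.added_count == counts["query_only"]
        assert s.union_count == s.total - counts["none"]
        assert s.added_count >= 0
        assert s.union_count >= max(s.per_editor.values())

    def test_unknown_editor_name(self):
        variants, contexts, _ = synth.make_variant_table(1, n_variants=4)
        with pytest.raises(ConfigError):
            summarize_target_space(
                variants, contexts, [synth.DEFAULT_REF_EDITOR], ["nope"], []
            )


class TestVariantIO:
    def test_vcf_round_trip_and_snv_filter(self, tmp_path):
        recs = [VariantRecord("c1", 10, "G", "A"), VariantRecord("c2", 5, "C", "T")]
        p = tmp_path / "v.vcf"
        write_vcf(recs, p)
        with open(p, "a") as fh:
            fh.write("c3\t7\t.\tGT\tG\t.\t.\t.\n")  # indel: skipped
        assert read_vcf(p) == recs

    def test_tsv_reader(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text("contig\tposition\tref\talt\nc1\t10\tG\tA\n")
        assert read_variants_tsv(p) == [VariantRecord("c1", 10, "G", "A")]
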