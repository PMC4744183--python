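"""Conversion engine, digest prediction and COBRA informativeness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from methylscreen.bisulfite import (
    ALL_METHYLATED,
    ALL_UNMETHYLATED,
    DEFAULT_ENZYME_PANEL,
    MethylationState,
    RestrictionEnzyme,
    classify_from_observed,
    cobra_predict,
    convert,
    cpg_positions,
    digest,
    reverse_complement,
)
from conftest import convert_oracle, digest_oracle, random_dna

dna = st.text(alphabet="ACGT", min_size=2, max_size=400)


class TestConvert:
    @pytest.mark.parametrize("seq,state,expected", [
        ("ACGT", ALL_UNMETHYLATED, "ATGT"),
        ("ACGT", ALL_METHYLATED, "ACGT"),
        ("ACCGT", ALL_METHYLATED, "ATCGT"),  # non-CpG C converts, CpG C protected
        ("ANCGN", ALL_METHYLATED, "ANCGN"),  # N passes through
    ])
    def test_worked_examples(self, seq, state, expected):
        assert convert(seq, state) == expected

    def test_non_cpg_flag_rejected(self):
        with pytest.raises(ValueError, match="non-CpG"):
            convert("ACGT", MethylationState.from_positions([3]))
        # permitted with the explicit toggle
        state = MethylationState.from_positions([0], allow_non_cpg=True)
        assert convert("CAAT", state) == "CAAT"

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(dna, st.randoms(use_true_random=False))
    def test_matches_per_base_oracle(self, seq, rand):
        cpgs = cpg_positions(seq)
        meth = {int(p) for p in cpgs if rand.random() < 0.5}
        state = MethylationState.from_positions(meth)
        for strand in ("OT", "OB"):
            assert convert(seq, state, strand) == convert_oracle(seq, meth, strand)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(dna)
    def test_idempotent_unmethylated(self, seq):
        once = convert(seq, ALL_UNMETHYLATED)
        assert convert(once, ALL_UNMETHYLATED) == once
        assert "C" not in once

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(dna, st.randoms(use_true_random=False))
    def test_strand_symmetry(self, seq, rand):
        """OB conversion equals the mirror of OT conversion of the mirror."""
        cpgs = cpg_positions(seq)
        meth = {int(p) for p in cpgs if rand.random() < 0.5}
        mirrored = {len(seq) - p - 2 for p in meth}
        ob = convert(seq, MethylationState.from_positions(meth), "OB")
        ot_mirror = convert(reverse_complement(seq),
                            MethylationState.from_positions(mirrored), "OT")
        assert ob == reverse_complement(ot_mirror)

    def test_stochastic_failure_rate(self, rng):
        seq = "AC" * 5000  # no CpGs: every C eligible for conversion
        out = convert(seq, ALL_UNMETHYLATED, failure_rate=0.2, rng=rng)
        kept = out.count("C")
        # 3 binomial SEs around 20% of 5000 cytosines
        assert abs(kept - 1000) < 3 * np.sqrt(5000 * 0.2 * 0.8)

    def test_failure_requires_rng(self):
        with pytest.raises(ValueError, match="rng"):
            convert("ACGT", ALL_UNMETHYLATED, failure_rate=0.1)


class TestDigest:
    def test_taqi_single_site(self):
        pat = digest("TTCGAA", RestrictionEnzyme("TaqI", "TCGA", 1))
        assert pat.cut_positions == (2,)
        assert pat.fragment_lengths == (2, 4)

    def test_site_free_sequence(self):
        pat = digest("AAAAAA", RestrictionEnzyme("TaqI", "TCGA", 1))
        assert pat.cut_positions == ()
        assert pat.fragment_lengths == (6,)

    def test_overlapping_sites_each_cut(self):
        # CGCGCG: BstUI (CGCG, offset 2) matches at 0 and 2 -> cuts 2 and 4
        pat = digest("CGCGCG", RestrictionEnzyme("BstUI", "CGCG", 2))
        assert pat.cut_positions == (2, 4)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=300),
           st.sampled_from(DEFAULT_ENZYME_PANEL + (
               RestrictionEnzyme("EcoRI", "GAATTC", 1),
               RestrictionEnzyme("Degenerate", "RCGY", 2),
           )))
    def test_matches_sliding_window_oracle(self, seq, enzyme):
        pat = digest(seq, enzyme)
        cuts, frags = digest_oracle(seq, enzyme.recognition, enzyme.cut_offset)
        assert pat.cut_positions == cuts
        assert pat.fragment_lengths == frags
        assert sum(pat.fragment_lengths) == len(seq)
        assert len(pat.fragment_lengths) == len(pat.cut_positions) + 1

    def test_appending_site_never_decreases_fragments(self, rng):
        enz = RestrictionEnzyme("TaqI", "TCGA", 1)
        for _ in range(20):
            t = random_dna(rng, int(rng.integers(10, 200)))
            before = len(digest(t, enz).fragment_lengths)
            after = len(digest(t + "ATCGAT", enz).fragment_lengths)
            assert after >= before

    def test_invalid_enzyme_rejected(self):
        with pytest.raises(ValueError):
            RestrictionEnzyme("bad", "ACGX", 1)
        with pytest.raises(ValueError):
            RestrictionEnzyme("bad", "ACGT", 7)


class TestCobra:
    def test_taqi_informative_on_destroyed_site(self):
        (res,) = cobra_predict("ATCGAT", [RestrictionEnzyme("TaqI", "TCGA", 1)])
        assert res.informative
        # methylated conversion keeps the TCGA site, unmethylated loses it
        assert res.pattern_methylated.cut_positions == (2,)
        assert res.pattern_unmethylated.cut_positions == ()

    def test_ecori_not_informative_on_c_free_region(self):
        (res,) = cobra_predict("GGAATTAGGATTA", [RestrictionEnzyme("EcoRI", "GAATTC", 1)])
        assert not res.informative
        assert res.pattern_methylated.fragment_lengths == res.pattern_unmethylated.fragment_lengths

    def test_bstui_informative(self):
        (res,) = cobra_predict("ACGCGT", [RestrictionEnzyme("BstUI", "CGCG", 2)])
        assert res.informative

    def test_conversion_created_site_detected(self):
        # unmethylated conversion of ACGAA -> ATGAA creates a TGAA site that
        # the methylation-protected template lacks (synthetic enzyme)
        (res,) = cobra_predict("ACGAA", [RestrictionEnzyme("FakeTGAA", "TGAA", 1)])
        assert res.informative
        assert res.pattern_unmethylated.cut_positions == (2,)
        assert res.pattern_methylated.cut_positions == ()

    def test_conversion_neutral_enzyme_never_informative(self, rng):
        """Sites whose IUPAC sets never distinguish C from T are immune to
        conversion, hence never informative."""
        neutral = [RestrictionEnzyme("n1", "AGGA", 1),
                   RestrictionEnzyme("n2", "GYRA", 2),  # Y contains both C and T
                   RestrictionEnzyme("n3", "GANG", 2)]
        for _ in range(25):
            seq = random_dna(rng, 300)
            for res in cobra_predict(seq, neutral):
                assert not res.informative

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            cobra_predict("ACGT", [])


class TestClassifyFromObserved:
    @pytest.fixture
    def report(self):
        (res,) = cobra_predict("ATCGATTCGAATTT", [RestrictionEnzyme("TaqI", "TCGA", 1)])
        return res

    def test_matches_methylated_prediction(self, report):
        obs = list(report.pattern_methylated.fragment_lengths)
        assert classify_from_observed(obs, report) == "methylated"

    def test_matches_unmethylated_prediction(self, report):
        obs = list(report.pattern_unmethylated.fragment_lengths)
        assert classify_from_observed(obs, report) == "unmethylated"

    def test_noninformative_is_ambiguous(self):
        (res,) = cobra_predict("GGAATTAGGATTA", [RestrictionEnzyme("EcoRI", "GAATTC", 1)])
        assert classify_from_observed([13], res) == "ambiguous"

    def test_gel_tolerance(self, report):
        obs = [f * 1.03 for f in report.pattern_methylated.fragment_lengths]
        assert classify_from_observed(obs, report, tolerance=0.05) == "methylated"
        assert classify_from_observed([999.0], report) == "ambiguous"

    def test_empty_observation_rejected(self, report):
        with pytest.raises(ValueError):
            classify_from_observed([], report)
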