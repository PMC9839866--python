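"""Hydropathy, compound score, charge, composition, conservation, motif and
deletion-scan features, each checked against an independent oracle."""

import math

import numpy as np
import pytest
from Bio.SeqUtils import ProtParamData
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from hypothesis import assume, given, settings, strategies as st

from sigpep.io_formats import SignalPeptide
from sigpep.feature_metrics import (
    classify_c_motif,
    classify_translocation_bias,
    compound_score,
    enumerate_single_deletions,
    kd_window_profile,
    n_region_charge,
    positional_information,
    region_composition,
    round_half_away,
)
from sigpep.region_model import RegionDecomposition, decompose_regions

AA = "ACDEFGHIKLMNPQRSTVWY"
LOG2_20 = math.log2(20)


def make_sp(seq, n_end=None, h_end=None):
    return SignalPeptide(gene_id="G", sp_seq=seq, n_end=n_end, h_end=h_end)


class TestHydropathyProfile:
    @pytest.mark.parametrize(
        "seq, expected",
        [("LLLLLLLLL", [3.8]), ("KKKKKKKKK", [-3.9]), ("LL", [3.8])],
    )
    def test_frozen_examples(self, seq, expected):
        prof = kd_window_profile(seq, window=9)
        assert prof.means == pytest.approx(expected)

    def test_window_count(self):
        prof = kd_window_profile("MKRLLLLLLLLLSVSA", window=9)
        assert len(prof.means) == 16 - 9 + 1

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            kd_window_profile("MKRB")

    @given(st.text(alphabet=AA, min_size=3, max_size=60),
           st.sampled_from([3, 5, 7, 9, 11, 13]))
    @settings(max_examples=300, derandomize=True)
    def test_matches_biopython_protscale(self, seq, window):
        """Window means agree with Biopython's ProtParam Kyte-Doolittle
        scale computation (independent implementation; odd windows no longer
        than the sequence, where ProtParam's unweighted profile is the plain
        window mean)."""
        assume(window <= len(seq))
        prof = kd_window_profile(seq, window=window)
        expected = ProteinAnalysis(seq).protein_scale(ProtParamData.kd, window)
        assert np.allclose(prof.means, expected)

    @given(st.text(alphabet=AA, min_size=1, max_size=60))
    @settings(max_examples=300, derandomize=True)
    def test_max_equals_bruteforce(self, seq):
        from sigpep.region_model import KYTE_DOOLITTLE as KD
        prof = kd_window_profile(seq, window=9)
        w = min(9, len(seq))
        brute = max(sum(KD[c] for c in seq[s:s + w]) / w
                    for s in range(len(seq) - w + 1))
        assert prof.max_mean == pytest.approx(brute)


class TestCompoundScore:
    def test_poly_leucine_h9(self):
        sp = make_sp("MKRLLLLLLLLLSVSA")
        d = decompose_regions(sp.sp_seq)
        cs = compound_score(sp, d)
        assert d.h_len == 9
        assert cs.score == pytest.approx(3.8 * 9)

    def test_linear_in_h_len(self):
        sp = make_sp("MKRLLLLLLLLLSVSA")
        for h in (1, 5, 12):
            d = RegionDecomposition(n_len=2, h_len=h, c_len=14 - h)
            cs = compound_score(sp, d)
            assert cs.score == pytest.approx(cs.max_window_mean * h)

    def test_negative_core_gives_negative_score(self):
        sp = make_sp("KKKKKKKKKKKKKKKK")
        d = RegionDecomposition(n_len=3, h_len=9, c_len=4)
        assert compound_score(sp, d).score == pytest.approx(-3.9 * 9)


class TestNRegionCharge:
    @pytest.mark.parametrize("n_region, charge",
                             [("MKR", 2), ("MDE", -2), ("MKH", 2), ("MSG", 0)])
    def test_counting_rule(self, n_region, charge):
        seq = n_region + "LLLLLLLLLSVSA"
        sp = make_sp(seq, n_end=3, h_end=12)
        d = RegionDecomposition(n_len=3, h_len=9, c_len=len(seq) - 12)
        assert n_region_charge(sp, d) == charge


class TestRegionComposition:
    def test_single_sp_n_region(self):
        sp = make_sp("MKLLLLLLLLLSVSA", n_end=2, h_end=11)
        d = RegionDecomposition(n_len=2, h_len=9, c_len=4)
        table = region_composition([sp], [d])
        assert table.at["N", "M"] == pytest.approx(0.5)
        assert table.at["N", "K"] == pytest.approx(0.5)

    def test_pooling_across_sps(self):
        sps = [make_sp("MKLLSVSA", n_end=2, h_end=4),
               make_sp("MKVVSVSA", n_end=2, h_end=4)]
        ds = [RegionDecomposition(2, 2, 4)] * 2
        table = region_composition(sps, ds)
        assert table.at["H", "L"] == pytest.approx(0.5)
        assert table.at["H", "V"] == pytest.approx(0.5)

    def test_rows_sum_to_one(self, small_cohort):
        sps, _ = small_cohort
        ds = [decompose_regions(sp.sp_seq) for sp in sps]
        table = region_composition(sps, ds)
        assert np.allclose(table.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            region_composition([], [])


class TestPositionalInformation:
    def test_fully_conserved_column(self):
        bits = positional_information(["AL", "AL", "AV"])
        assert bits[0] == pytest.approx(LOG2_20)

    def test_uniform_column_is_zero(self):
        seqs = [aa for aa in AA]
        assert positional_information(seqs)[0] == pytest.approx(0.0)

    def test_two_state_column(self):
        bits = positional_information(["A", "A", "L", "L"])
        assert bits[0] == pytest.approx(LOG2_20 - 1.0)

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            positional_information(["AL", "ALA"])

    @given(st.lists(st.text(alphabet=AA, min_size=8, max_size=8),
                    min_size=2, max_size=30))
    @settings(max_examples=200, derandomize=True)
    def test_bounds(self, seqs):
        bits = positional_information(seqs)
        assert all(-1e-9 <= b <= LOG2_20 + 1e-9 for b in bits)

    def test_monotone_under_added_diversity(self):
        base = ["A"] * 6
        more_diverse = ["A"] * 5 + ["L"]
        assert positional_information(more_diverse + ["A"])[0] < \
            positional_information(base + ["A"])[0]


class TestMotifClass:
    @pytest.mark.parametrize("tail, klass",
                             [("ALA", "AXA"), ("VSA", "VXA"), ("IAA", "OTHER"),
                              ("AAA", "AXA"), ("VAV", "OTHER")])
    def test_rule_instances(self, tail, klass):
        sp = make_sp("MKRLLLLLLLLLS" + tail)
        motif = classify_c_motif(sp)
        assert motif.klass == klass
        assert motif.triplet == tail

    def test_classes_partition_cohort(self, small_cohort):
        sps, _ = small_cohort
        classes = [classify_c_motif(sp).klass for sp in sps]
        assert set(classes) <= {"AXA", "VXA", "OTHER"}
        fractions = [classes.count(k) / len(classes)
                     for k in ("AXA", "VXA", "OTHER")]
        assert sum(fractions) == pytest.approx(1.0)


class TestDeletionScan:
    def test_one_variant_per_h_position(self):
        sp = make_sp("MKRLLLLLLLLLSVSA")
        d = decompose_regions(sp.sp_seq)
        variants = enumerate_single_deletions(sp, d)
        assert len(variants) == d.h_len

    def test_variant_scores_self_consistent(self):
        sp = make_sp("MKRLLLLLLLLLSVSA")
        d = decompose_regions(sp.sp_seq)
        for v in enumerate_single_deletions(sp, d):
            vd = decompose_regions(v.variant_seq)
            recomputed = compound_score(make_sp(v.variant_seq), vd)
            assert v.score.score == pytest.approx(recomputed.score)

    def test_exit_from_bad_band_flagged(self):
        # mixed hydrophobic core with score inside [23, 24]; deleting a
        # core residue moves the score out of the band
        seq = "MKRVLLLALALSSA"
        sp = make_sp(seq)
        d = decompose_regions(seq)
        original = compound_score(sp, d).score
        assert 23.0 <= original <= 24.0
        variants = enumerate_single_deletions(sp, d)
        exited = [v for v in variants
                  if not 23.0 <= v.score.score <= 24.0]
        assert exited
        for v in variants:
            assert v.exits_bad_band == (not 23.0 <= v.score.score <= 24.0)


class TestTranslocationBias:
    @pytest.mark.parametrize("score, expected",
                             [(1.70, "post_dependent"), (1.75, "post_dependent"),
                              (1.78, "intermediate"),
                              (1.81, "srp_biased"), (1.90, "srp_biased")])
    def test_thresholds(self, score, expected):
        assert classify_translocation_bias(score) == expected


@pytest.mark.parametrize("x, expected",
                         [(23.5, 24), (23.4, 23), (-0.5, -1), (0.5, 1), (2.0, 2)])
def test_round_half_away(x, expected):
    assert round_half_away(x) == expected
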