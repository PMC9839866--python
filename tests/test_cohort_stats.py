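"""Dedup, chromosome/length summaries, category titer means, rule report."""

import math

import numpy as np
import pandas as pd
import pytest
from sigpep.io_formats import SignalPeptide
from sigpep.cohort_stats import (
    RULE_COLUMNS,
    category_means,
    chromosome_distribution,
    dedupe,
    length_distributions,
    rule_report,
)
from sigpep.feature_metrics import feature_table
from sigpep.region_model import decomposition_for
from sigpep.synthetic_data import SynthParams, sample_cohort

SEQ = "MKRLLLLLLLLLSVSA"


def sp(gene_id, seq=SEQ, **kw):
    return SignalPeptide(gene_id=gene_id, sp_seq=seq, **kw)


class TestDedupe:
    def test_first_kept_order_preserved(self):
        cohort = [sp("A"), sp("B", SEQ.replace("K", "R")), sp("C")]
        unique, removed = dedupe(cohort)
        assert [s.gene_id for s in unique] == ["A", "B"]
        assert removed == 1

    def test_no_duplicates(self):
        cohort = [sp("A"), sp("B", SEQ.replace("K", "R"))]
        assert dedupe(cohort)[1] == 0

    def test_three_identical_rows(self):
        unique, removed = dedupe([sp("A"), sp("B"), sp("C")])
        assert len(unique) == 1 and removed == 2

    def test_idempotent(self, small_cohort):
        sps, _ = small_cohort
        once, n1 = dedupe(sps)
        twice, n2 = dedupe(once)
        assert twice == once and n2 == 0

    def test_generated_duplicates_removed_exactly(self, small_cohort, small_params):
        sps, _ = small_cohort
        unique, removed = dedupe(sps)
        assert removed == small_params.n_duplicates
        assert len(unique) == small_params.n_sps - small_params.n_duplicates


class TestChromosomeDistribution:
    def test_percentage(self):
        cohort = [sp("A", chromosome="I"), sp("B", SEQ.replace("K", "R"),
                                              chromosome="I")]
        df = chromosome_distribution(cohort, {"I": 20, "II": 10})
        assert df.set_index("chromosome").at["I", "pct"] == pytest.approx(10.0)
        assert df.set_index("chromosome").at["II", "pct"] == pytest.approx(0.0)

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError, match="unknown chromosome"):
            chromosome_distribution([sp("A", chromosome="XX")], {"I": 10})

    def test_zero_gene_chromosome_rejected(self):
        with pytest.raises(ValueError, match="no genes"):
            chromosome_distribution([sp("A", chromosome="I")], {"I": 0})


class TestLengthDistributions:
    def test_c5_fraction(self):
        from sigpep.region_model import RegionDecomposition
        cohort = [sp("A"), sp("B", SEQ.replace("K", "R")), sp("C", SEQ + "A")]
        ds = [RegionDecomposition(3, 8, 5), RegionDecomposition(3, 8, 5),
              RegionDecomposition(4, 9, 4)]
        out = length_distributions(cohort, ds)
        assert out["frac_c5"] == pytest.approx(2 / 3)

    def test_single_sp_mass(self):
        from sigpep.region_model import RegionDecomposition
        out = length_distributions([sp("A")], [RegionDecomposition(3, 9, 4)])
        assert out["n"]["count"].tolist() == [1]
        assert out["total"]["length"].tolist() == [16]


class TestCategoryMeans:
    def make_features(self, rows):
        return pd.DataFrame(rows)

    def test_mean_and_sample_sd(self):
        feats = self.make_features(
            [{"motif_class": "AXA", "titer": 2.0},
             {"motif_class": "AXA", "titer": 4.0},
             {"motif_class": "OTHER", "titer": 1.0}])
        out = category_means(feats, "motif_class").set_index("category")
        assert out.at["AXA", "mean_titer"] == pytest.approx(3.0)
        assert out.at["AXA", "sd_titer"] == pytest.approx(math.sqrt(2))

    def test_untitered_counted_separately(self):
        feats = self.make_features(
            [{"motif_class": "AXA", "titer": 2.0},
             {"motif_class": "AXA", "titer": None}])
        out = category_means(feats, "motif_class").set_index("category")
        assert out.at["AXA", "n_titered"] == 1
        assert out.at["AXA", "n_untitered"] == 1

    def test_counts_partition_cohort(self, small_cohort):
        sps, _ = small_cohort
        ds = [decomposition_for(s) for s in sps]
        feats = feature_table(sps, ds)
        for by in ("n_charge", "score_bin", "motif_class"):
            out = category_means(feats, by)
            assert out["count"].sum() == len(sps)

    def test_configured_shift_effect_recovered(self):
        """Titer means split by the true shifted flag recover the configured
        multiplier after adjusting for the other flag effects."""
        p = SynthParams(n_sps=4000, n_duplicates=0, seed=55)
        sps, truth = sample_cohort(p)
        t = truth.copy()
        t["titer"] = [s.titer for s in sps]
        other = t.true_titer_multiplier / np.where(t.true_shifted,
                                                   p.mult_shifted, 1.0)
        adj = t.titer / other
        shifted, unshifted = adj[t.true_shifted], adj[~t.true_shifted]
        ratio = shifted.mean() / unshifted.mean()
        se = ratio * math.sqrt(
            shifted.std() ** 2 / shifted.mean() ** 2 / len(shifted)
            + unshifted.std() ** 2 / unshifted.mean() ** 2 / len(unshifted))
        assert abs(ratio - p.mult_shifted) <= 2 * se


class TestRuleReport:
    def make_row(self, **kw):
        row = {"gene_id": "G", "n_len": 5, "h_len": 9, "c_len": 5,
               "n_charge": 1, "compound_score": 30.0, "motif_class": "AXA",
               "shifted": False, "titer": 1.0}
        row.update(kw)
        return row

    def test_all_rules_satisfied(self):
        df = rule_report(pd.DataFrame([self.make_row()]))
        assert df.loc[0, "rule_count"] == 7
        assert df.loc[0, RULE_COLUMNS].all()

    def test_score_in_bad_band_fails_flag(self):
        df = rule_report(pd.DataFrame([self.make_row(compound_score=23.5)]))
        assert not df.loc[0, "rule_score_outside_band"]
        assert df.loc[0, "rule_count"] == 6

    def test_rule_count_equals_flag_sum(self, small_cohort):
        sps, _ = small_cohort
        ds = [decomposition_for(s) for s in sps]
        feats = feature_table(sps, ds, shifted=[False] * len(sps))
        df = rule_report(feats)
        assert (df["rule_count"] == df[RULE_COLUMNS].sum(axis=1)).all()

    def test_ranking_deterministic(self, small_cohort):
        sps, _ = small_cohort
        ds = [decomposition_for(s) for s in sps]
        feats = feature_table(sps, ds)
        a = rule_report(feats)
        b = rule_report(feats)
        assert a.equals(b)
        counts = a["rule_count"].to_numpy()
        assert (counts[:-1] >= counts[1:]).all()
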