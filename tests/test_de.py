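"""Differential-expression statistics: per-gene fits, empirical-Bayes
moderation, BH adjustment and regulated-set consolidation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lactokin.config import AnalysisThresholds
from lactokin.de import (
    bh_adjust, consolidate_and_venn, fit_gene, moderate_variances,
    run_contrast, run_de, select_regulated,
)
from lactokin.microarray import replicate_column


class TestFitGene:
    def test_hand_arithmetic(self):
        lfc, var, df = fit_gene([1.2, 1.4])
        assert lfc == pytest.approx(1.3)
        assert var == pytest.approx(0.02)
        assert df == 1

    def test_identical_replicates_zero_variance(self):
        assert fit_gene([2.0, 2.0]) == (2.0, 0.0, 1)

    def test_single_value_untestable(self):
        assert fit_gene([1.0, np.nan]) is None


class TestModeration:
    def _sim(self, n=500, seed=0):
        rng = np.random.default_rng(seed)
        lfc = rng.normal(0, 1, n)
        s2 = stats.chi2.rvs(3, size=n, random_state=seed) / 3 * 0.1
        df = np.full(n, 3)
        reps = np.full(n, 4)
        return lfc, s2, df, reps

    def test_zero_prior_df_recovers_ordinary_t(self):
        lfc, s2, df, reps = self._sim()
        mod = moderate_variances(lfc, s2, df, reps, prior_df=0.0)
        ordinary = lfc / np.sqrt(s2 / reps)
        np.testing.assert_allclose(mod["moderated_t"], ordinary, atol=1e-12)

    def test_infinite_prior_df_pools_all_variances(self):
        lfc, s2, df, reps = self._sim()
        mod = moderate_variances(lfc, s2, df, reps, prior_df=np.inf)
        assert mod["posterior_variance"].nunique() == 1

    def test_null_p_values_uniform(self):
        """2,000 null genes, 2 replicates: estimated-prior moderated-t
        p-values are uniform (KS statistic < 0.05)."""
        rng = np.random.default_rng(42)
        vals = pd.DataFrame(
            rng.normal(0, 0.3, (2000, 2)),
            index=[f"g{i}" for i in range(2000)],
            columns=[replicate_column("NG14", 1, r) for r in (1, 2)])
        res = run_contrast(vals, "NG14", 1, AnalysisThresholds())
        ks = stats.kstest(res["p_value"], "uniform").statistic
        assert ks < 0.05

    def test_degenerate_variances_fall_back_to_pooling(self, caplog):
        lfc = np.zeros(50)
        s2 = np.full(50, 0.04)
        mod = moderate_variances(lfc, s2, np.full(50, 3), np.full(50, 4))
        assert np.isinf(mod["prior_df"].iloc[0])
        np.testing.assert_allclose(mod["posterior_variance"], 0.04, rtol=0.05)


class TestBH:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.04, 0.03]),
                                   [0.03, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_identity(self):
        assert bh_adjust([0.02])[0] == pytest.approx(0.02)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2,
                    max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_p(self, ps):
        order = np.argsort(ps)
        adj = bh_adjust(ps)[order]
        assert np.all(np.diff(adj) >= -1e-12)
        assert np.all(adj <= 1.0)


class TestSelection:
    def _frame(self, fdr, lfc):
        return pd.DataFrame({
            "gene_id": ["g"], "strain": ["NG14"], "time_h": [1],
            "lfc": [lfc], "fdr": [fdr]})

    @pytest.mark.parametrize("fdr,lfc,expect", [
        (0.04, 1.2, True),
        (0.04, 0.9, False),   # |lfc| <= 1
        (0.06, 1.2, False),   # above the FDR cut
        (0.04, -1.2, True),
    ])
    def test_dual_rule(self, fdr, lfc, expect, thresholds):
        reg = (fdr <= thresholds.fdr_cutoff) and abs(lfc) > thresholds.lfc_cutoff
        assert reg is expect

    def test_null_simulation_controls_fdr(self):
        """Pure-null data: fraction of genes at FDR <= 0.05 stays below
        0.05 plus 3 Monte-Carlo standard errors."""
        rng = np.random.default_rng(7)
        vals = pd.DataFrame(
            rng.normal(0, 0.3, (2000, 2)),
            index=[f"g{i}" for i in range(2000)],
            columns=[replicate_column("NG14", 1, r) for r in (1, 2)])
        res = run_contrast(vals, "NG14", 1, AnalysisThresholds())
        frac = (res["fdr"] <= 0.05).mean()
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 2000)


class TestVenn:
    def _de(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "strain", "time_h",
                                           "regulated"])

    def test_single_strain_specific(self):
        de = self._de([("g1", "NG14", 24, True), ("g1", "RUTC30", 24, False)])
        v = consolidate_and_venn(de)["venn"]
        assert v == {"specific_NG14": 1, "specific_RUTC30": 0,
                     "shared": 0, "total": 1}

    def test_shared_gene(self):
        de = self._de([("g1", "NG14", 1, True), ("g1", "RUTC30", 1, True)])
        v = consolidate_and_venn(de)["venn"]
        assert v["shared"] == 1 and v["total"] == 1

    def test_constructed_partition_recovered_exactly(self):
        """50 NG14-only, 10 RUTC30-only, 20 shared genes."""
        rows = []
        for i in range(50):
            rows.append((f"a{i}", "NG14", 1, True))
        for i in range(10):
            rows.append((f"b{i}", "RUTC30", 3, True))
        for i in range(20):
            rows.append((f"c{i}", "NG14", 6, True))
            rows.append((f"c{i}", "RUTC30", 24, True))
        v = consolidate_and_venn(self._de(rows))["venn"]
        assert (v["specific_NG14"], v["specific_RUTC30"], v["shared"]) \
            == (50, 10, 20)
        assert v["total"] == 80

    @given(st.lists(st.tuples(st.integers(0, 30), st.sampled_from(["NG14", "RUTC30"]),
                              st.sampled_from([1, 3, 6, 24]), st.booleans()),
                    min_size=1, max_size=60))
    @settings(max_examples=40, deadline=None)
    def test_partition_conservation(self, raw):
        de = self._de([(f"g{g}", s, t, r) for g, s, t, r in raw])
        out = consolidate_and_venn(de)
        if "venn" in out:
            v = out["venn"]
            assert v["specific_NG14"] + v["specific_RUTC30"] + v["shared"] \
                == v["total"]


def test_untestable_genes_excluded_per_contrast():
    vals = pd.DataFrame(
        {"NG14_1h_r1": [1.0, 2.0], "NG14_1h_r2": [np.nan, 2.2],
         "NG14_3h_r1": [1.0, 2.0], "NG14_3h_r2": [1.1, 2.2]},
        index=["g1", "g2"])
    de = run_de(vals, prior_df=0.0)
    at1 = de[(de["time_h"] == 1)]
    at3 = de[(de["time_h"] == 3)]
    assert list(at1["gene_id"]) == ["g2"]       # g1 untestable at 1 h only
    assert sorted(at3["gene_id"]) == ["g1", "g2"]


def test_up_down_counts_shape():
    de = pd.DataFrame({
        "gene_id": ["a", "b", "c"], "strain": ["NG14"] * 3,
        "time_h": [1, 1, 1], "regulated": [True, True, False],
        "direction": ["up", "down", "none"]})
    counts = select_regulated(de)
    row = counts[(counts["strain"] == "NG14") & (counts["time_h"] == 1)]
    assert int(row["up"].iloc[0]) == 1 and int(row["down"].iloc[0]) == 1
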