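"""Probe-to-transcript preprocessing: normalization, background
thresholding, detectability and summarization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lactokin.microarray import (
    NormalizationError, assemble_ratio_table, background_threshold,
    compute_ma, flag_detectable, global_lowess_normalize,
    preprocess_probe_table, summarize_transcripts,
)
from lactokin.synthetic import generate_probe_signals, generate_profiles


def _probe_frame(m, a, **kw):
    base = dict(status="found", in_cds=True, strand_match=True,
                dye_orientation="forward", gene_id="g", strain="NG14",
                time_h=1, replicate=1)
    base.update(kw)
    df = pd.DataFrame({"intensity_test": 2.0 ** (np.asarray(a) + np.asarray(m) / 2),
                       "intensity_ref": 2.0 ** (np.asarray(a) - np.asarray(m) / 2)})
    for k, v in base.items():
        df[k] = v
    return compute_ma(df)


class TestLowess:
    def test_zero_signal_stays_zero(self):
        rng = np.random.default_rng(0)
        df = _probe_frame(np.zeros(200), rng.normal(10, 1.5, 200))
        out = global_lowess_normalize(df)
        np.testing.assert_allclose(out["M"], 0.0, atol=1e-9)

    def test_removes_intensity_dependent_bias(self):
        """Injected M = 0.5 sin(A) over 5000 probes is flattened to
        mean |M| < 0.05."""
        rng = np.random.default_rng(1)
        a = rng.normal(10, 1.5, 5000)
        df = _probe_frame(0.5 * np.sin(a), a)
        out = global_lowess_normalize(df, span=0.3)
        assert np.abs(out["M"]).mean() < 0.05

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        a = rng.normal(10, 1.5, 300)
        df = _probe_frame(rng.normal(0, 1, 300), a)
        out1 = global_lowess_normalize(df)
        out2 = global_lowess_normalize(df)
        pd.testing.assert_frame_equal(out1, out2)

    def test_idempotent_on_exactly_centred_data(self):
        """Bias-free data with no scatter is a fixed point; noisy but
        centred data moves only at the smoother's noise floor (signed
        mean change near zero), never systematically."""
        a = np.random.default_rng(3).normal(10, 1.5, 2000)
        exact = global_lowess_normalize(_probe_frame(np.zeros(2000), a))
        again = global_lowess_normalize(exact)
        assert np.abs(again["M"] - exact["M"]).mean() < 1e-6
        noisy = _probe_frame(np.random.default_rng(4).normal(0, 0.2, 2000), a)
        once = global_lowess_normalize(noisy)
        twice = global_lowess_normalize(once)
        assert abs((twice["M"] - once["M"]).mean()) < 1e-3

    def test_too_few_probes(self):
        df = _probe_frame(np.zeros(10), np.full(10, 10.0))
        with pytest.raises(NormalizationError):
            global_lowess_normalize(df)


class TestBackgroundThreshold:
    def test_zero_variance(self):
        assert background_threshold([100, 100, 100], 2) == 100.0

    def test_two_point_hand_value(self):
        # mean 100, sample SD sqrt(200) = 14.1421...
        assert background_threshold([90, 110], 2) == pytest.approx(128.2843, abs=1e-4)

    def test_zero_multiplier_gives_mean(self):
        assert background_threshold([80, 100, 120], 0) == 100.0

    def test_insufficient_features(self):
        with pytest.raises(ValueError):
            background_threshold([100], 2)


class TestDetectable:
    @pytest.mark.parametrize("test,ref,thr,expect", [
        (200, 300, 150, True),
        (200, 120, 150, False),   # one channel below
        (120, 120, 150, False),
    ])
    def test_both_channels_rule(self, test, ref, thr, expect):
        df = pd.DataFrame({"status": ["found"], "intensity_test": [test],
                           "intensity_ref": [ref]})
        assert flag_detectable(df, thr)["detectable"].iloc[0] is np.bool_(expect)

    def test_not_found_never_detectable(self):
        df = pd.DataFrame({"status": ["not_found"],
                           "intensity_test": [1e6], "intensity_ref": [1e6]})
        assert not flag_detectable(df, 100)["detectable"].iloc[0]

    @given(st.floats(min_value=0, max_value=1e4),
           st.floats(min_value=0, max_value=1e4))
    @settings(max_examples=30, deadline=None)
    def test_raising_threshold_is_monotone(self, t1, t2):
        lo, hi = sorted((t1, t2))
        rng = np.random.default_rng(4)
        df = pd.DataFrame({
            "status": "found",
            "intensity_test": rng.uniform(0, 1e4, 100),
            "intensity_ref": rng.uniform(0, 1e4, 100),
        })
        n_lo = flag_detectable(df, lo)["detectable"].sum()
        n_hi = flag_detectable(df, hi)["detectable"].sum()
        assert n_hi <= n_lo


class TestSummarize:
    def _probes(self, ms, **overrides):
        df = _probe_frame(ms, np.full(len(ms), 10.0))
        df["detectable"] = True
        df["probe_id"] = [f"p{i}" for i in range(len(ms))]
        for col, vals in overrides.items():
            df[col] = vals
        return df

    def test_mean_of_usable(self):
        out = summarize_transcripts(self._probes([1.0, 2.0]))
        assert out["log2_ratio"].iloc[0] == pytest.approx(1.5)
        assert out["n_probes_used"].iloc[0] == 2

    def test_probe_outside_cds_excluded(self):
        out = summarize_transcripts(self._probes(
            [9.0, 1.0, 1.0], in_cds=[False, True, True]))
        assert out["log2_ratio"].iloc[0] == pytest.approx(1.0)

    def test_all_below_threshold_discarded(self):
        out = summarize_transcripts(self._probes(
            [1.0, 1.0], detectable=[False, False]))
        assert out.empty

    def test_swapped_orientation_sign_flip(self):
        out = summarize_transcripts(self._probes(
            [-2.0, -2.0], dye_orientation="swapped"))
        assert out["log2_ratio"].iloc[0] == pytest.approx(2.0)


class TestRatioTable:
    def _ratios(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "strain", "time_h",
                                           "replicate", "log2_ratio"])

    def test_complete_table(self):
        rows = [(g, s, t, r, 1.0) for g in ("a", "b")
                for s in ("NG14", "RUTC30") for t in (1, 3, 6, 24)
                for r in (1, 2)]
        wide = assemble_ratio_table(self._ratios(rows))
        assert wide.shape == (2, 16)
        assert wide.isna().sum().sum() == 0

    def test_one_discarded_entry_is_missing(self):
        rows = [(g, s, t, r, 1.0) for g in ("a", "b")
                for s in ("NG14",) for t in (1, 3) for r in (1, 2)]
        rows.remove(("b", "NG14", 3, 2, 1.0))
        wide = assemble_ratio_table(self._ratios(rows))
        assert wide.isna().sum().sum() == 1
        assert np.isnan(wide.loc["b", "NG14_3h_r2"])

    def test_duplicate_triple_rejected(self):
        rows = [("a", "NG14", 1, 1, 1.0), ("a", "NG14", 1, 1, 2.0)]
        with pytest.raises(ValueError, match="duplicate"):
            assemble_ratio_table(self._ratios(rows))

    def test_tsv_round_trip(self, tmp_path):
        rows = [("a", "NG14", 1, 1, 1.25), ("a", "NG14", 1, 2, -0.5)]
        wide = assemble_ratio_table(self._ratios(rows))
        p = tmp_path / "t.tsv"
        wide.to_csv(p, sep="\t", na_rep="NA")
        back = pd.read_csv(p, sep="\t", index_col=0, na_values="NA")
        pd.testing.assert_frame_equal(back, wide)


def test_dye_swap_symmetry_end_to_end(clean_config):
    """With zero noise and no dye bias, the forward and swapped
    replicates give identical transcript ratios (exactly without the
    lowess step; within the smoother's wiggle with it)."""
    mat, _ = generate_profiles(clean_config)
    probes = generate_probe_signals(mat, clean_config)
    exact = preprocess_probe_table(probes, normalize=False)
    for strain in ("NG14", "RUTC30"):
        for t in (1, 3, 6, 24):
            r1 = exact[f"{strain}_{t}h_r1"]
            r2 = exact[f"{strain}_{t}h_r2"]
            both = r1.notna() & r2.notna()
            assert both.mean() > 0.95   # detectability losses are rare
            np.testing.assert_allclose(r1[both], r2[both], atol=1e-9)
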