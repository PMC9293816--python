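"""Normalization chain: hand-computed factor oracles and invariance properties."""

import numpy as np
import pandas as pd
import pytest

from hclsig.normalization import (NormalizationConfig, NormalizationError,
                                  background_correct, housekeeping_normalize,
                                  normalize_pipeline, positive_control_scale)
from hclsig.synthetic_data import ExperimentDesign, simulate_experiment

from conftest import make_counts, make_panel

CFG = NormalizationConfig(housekeeping_genes=("HK1", "HK2"))


def lanes_equal(counts, lanes_values):
    return make_counts(lanes_values, panel=make_panel())


class TestPositiveControlScale:
    def test_identical_positives_leave_counts_unchanged(self):
        vals = {"L1": [10, 20, 30, 40, 50, 60, 70, 100, 200, 5, 5],
                "L2": [11, 21, 31, 41, 51, 61, 71, 100, 200, 6, 4]}
        cm = make_counts(vals)
        out, factors = positive_control_scale(cm, CFG)
        np.testing.assert_allclose(factors.table["positive_factor"], [1.0, 1.0])
        np.testing.assert_allclose(out.values.to_numpy(), cm.values.to_numpy())

    def test_doubled_lane_gets_hand_computed_factors(self):
        # lane2 positives exactly 2x lane1: g2 = 2 g1, mean = 1.5 g1
        vals = {"L1": [10, 20, 30, 40, 50, 60, 70, 100, 400, 5, 5],
                "L2": [10, 20, 30, 40, 50, 60, 70, 200, 800, 5, 5]}
        out, factors = positive_control_scale(make_counts(vals), CFG)
        np.testing.assert_allclose(factors.table["positive_factor"], [1.5, 0.75])
        # non-positive probes of lane1 multiplied by 1.5
        np.testing.assert_allclose(out.values.loc["E1", "L1"], 15.0)
        # positives themselves untouched
        assert out.values.loc["P1", "L2"] == 200

    @pytest.mark.parametrize("c", [2, 5])
    def test_invariant_to_global_lane_rescaling(self, c):
        """Rescaling one whole lane by c cancels out of the lane's scaled
        profile up to the common reference level: cross-lane count ratios are
        exactly unchanged, and the lane's own counts shift only by the single
        reference factor (mean over lanes of the positive geomeans)."""
        rng = np.random.default_rng(42)
        vals = {f"L{i}": rng.integers(1, 1000, 11).tolist() for i in range(5)}
        base, _ = positive_control_scale(make_counts(vals), CFG)
        vals["L2"] = [v * c for v in vals["L2"]]
        scaled, _ = positive_control_scale(make_counts(vals), CFG)
        non_pos = [p for p in base.values.index if not p.startswith("P")]
        np.testing.assert_allclose(
            scaled.values.loc[non_pos, "L2"] / scaled.values.loc[non_pos, "L0"],
            base.values.loc[non_pos, "L2"] / base.values.loc[non_pos, "L0"],
            rtol=1e-12)
        ratio = scaled.values.loc[non_pos, "L2"] / base.values.loc[non_pos, "L2"]
        np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-12)

    def test_factor_conservation(self):
        """Mean of F_i weighted by g_i equals mean g."""
        rng = np.random.default_rng(7)
        vals = {f"L{i}": rng.integers(1, 1000, 11).tolist() for i in range(6)}
        cm = make_counts(vals)
        _, factors = positive_control_scale(cm, CFG)
        from scipy.stats import gmean
        g = gmean(cm.values.loc[["P1", "P2"]], axis=0)
        f = factors.table["positive_factor"].to_numpy()
        assert np.isclose(np.mean(f * g), np.mean(g))

    def test_zero_positive_count_errors_under_exclude_zeros(self):
        vals = {"L1": [1] * 7 + [0, 100, 5, 5], "L2": [1] * 7 + [50, 100, 5, 5]}
        cfg = NormalizationConfig(housekeeping_genes=("HK1",),
                                  geomean_zero_policy="exclude_zeros")
        with pytest.raises(NormalizationError, match="zero positive"):
            positive_control_scale(make_counts(vals), cfg)


class TestBackgroundCorrect:
    def test_zero_variance_negatives(self):
        # negatives all 5 -> SD 0, b = 5; endogenous 25 -> 20
        vals = {"L1": [25, 30, 40, 50, 60, 70, 80, 100, 200, 5, 5],
                "L2": [25, 30, 40, 50, 60, 70, 80, 100, 200, 5, 5]}
        out, factors = background_correct(make_counts(vals), CFG)
        np.testing.assert_allclose(factors.table["background"], [5.0, 5.0])
        assert out.values.loc["E1", "L1"] == 20.0
        assert out.state == "background_corrected"

    def test_mean_plus_two_sample_sd(self):
        # negatives {4, 6}: mean 5, sample SD sqrt(2), b = 5 + 2*sqrt(2)
        vals = {"L1": [7, 30, 40, 50, 60, 70, 80, 100, 200, 4, 6],
                "L2": [9, 30, 40, 50, 60, 70, 80, 100, 200, 4, 6]}
        out, factors = background_correct(make_counts(vals), CFG)
        np.testing.assert_allclose(factors.table["background"],
                                   [7.82842712, 7.82842712], rtol=1e-8)
        assert out.values.loc["E1", "L1"] == 0.0  # 7 floored
        np.testing.assert_allclose(out.values.loc["E1", "L2"],
                                   9 - 7.82842712474619)
        # negatives and positives untouched
        assert out.values.loc["N1", "L1"] == 4

    def test_output_bounded_by_input_and_zero(self):
        rng = np.random.default_rng(3)
        vals = {f"L{i}": rng.integers(0, 300, 11).tolist() for i in range(4)}
        cm = make_counts(vals)
        out, _ = background_correct(cm, CFG)
        assert (out.values.to_numpy() >= 0).all()
        assert (out.values.to_numpy() <= cm.values.to_numpy() + 1e-12).all()

    def test_single_negative_probe_errors(self):
        panel = make_panel(n_neg=1)
        vals = {"L1": [1] * 10, "L2": [2] * 10}
        with pytest.raises(NormalizationError, match=">= 2 negative"):
            background_correct(make_counts(vals, panel=panel), CFG)


class TestHousekeepingNormalize:
    def test_identity_when_profiles_identical(self):
        vals = {"L1": [10, 20, 30, 40, 50, 100, 400, 100, 200, 5, 5],
                "L2": [11, 22, 33, 44, 55, 100, 400, 100, 200, 5, 5]}
        cm = make_counts(vals, state="background_corrected")
        out, factors = housekeeping_normalize(cm, CFG)
        np.testing.assert_allclose(factors.table["housekeeping_factor"], [1, 1])
        np.testing.assert_allclose(out.values.to_numpy(), cm.values.to_numpy())
        assert out.state == "normalized"

    def test_hand_computed_factors(self):
        # geometric means h = (100, 400) -> mean 250 -> K = (2.5, 0.625)
        vals = {"L1": [10, 20, 30, 40, 50, 50, 200, 100, 200, 5, 5],
                "L2": [10, 20, 30, 40, 50, 200, 800, 100, 200, 5, 5]}
        cm = make_counts(vals, state="background_corrected")
        out, factors = housekeeping_normalize(cm, CFG)
        np.testing.assert_allclose(factors.table["housekeeping_factor"],
                                   [2.5, 0.625])
        np.testing.assert_allclose(out.values.loc["E1"], [25.0, 6.25])
        # housekeeping rows themselves are not rescaled
        assert out.values.loc["H1", "L1"] == 50

    def test_missing_housekeeping_gene_errors(self):
        cm = make_counts({"L1": [1] * 11, "L2": [1] * 11},
                         state="background_corrected")
        cfg = NormalizationConfig(housekeeping_genes=("NOPE",))
        with pytest.raises(NormalizationError, match="NOPE"):
            housekeeping_normalize(cm, cfg)

    def test_recovers_planted_lane_factors_at_low_noise(self):
        design = ExperimentDesign(lane_factor_sd=0.4, nb_dispersion=0.001)
        cm, truth = simulate_experiment(design, seed=11)
        from hclsig.normalization import normalize_pipeline
        _, factors = normalize_pipeline(cm)
        L = pd.Series(truth.lane_factors)
        recovered = factors.table["positive_factor"]
        expected = (1.0 / L) * (1.0 / (1.0 / L).mean()) ** 0  # proportional to 1/L
        ratio = (recovered * L)
        # F_i proportional to 1/L_i: the product should be lane-independent
        assert ratio.std() / ratio.mean() < 0.1


class TestPipelineChain:
    def test_identical_lanes_reduce_to_background_subtraction(self):
        col = [25, 30, 40, 50, 60, 100, 400, 100, 200, 5, 5]
        cm = make_counts({"L1": col, "L2": col, "L3": col})
        out, factors = normalize_pipeline(cm, CFG)
        endo = [f"E{i}" for i in range(1, 6)]
        np.testing.assert_allclose(
            out.values.loc[endo, "L1"], np.array([25, 30, 40, 50, 60]) - 5.0)
        assert out.state == "normalized"

    def test_stage_order_sensitivity(self):
        """Permuting background and housekeeping stages changes the output."""
        rng = np.random.default_rng(9)
        vals = {f"L{i}": rng.integers(10, 2000, 11).tolist() for i in range(4)}
        cm = make_counts(vals)
        chained, _ = normalize_pipeline(cm, CFG)
        scaled, f = positive_control_scale(cm, CFG)
        # swapped order: housekeeping before background
        hk_first = scaled.with_values(scaled.values, "background_corrected", "forced")
        hk_done, f = housekeeping_normalize(hk_first, CFG, f)
        swapped = hk_done.with_values(hk_done.values, "positive_scaled", "forced")
        swapped_done, _ = background_correct(swapped, CFG, f)
        assert not np.allclose(chained.values.to_numpy(),
                               swapped_done.values.to_numpy())

    def test_deterministic_on_simulated_experiment(self):
        a, _ = simulate_experiment(seed=1)
        b, _ = simulate_experiment(seed=1)
        na, _ = normalize_pipeline(a)
        nb_, _ = normalize_pipeline(b)
        assert na.values.equals(nb_.values)

    def test_requires_raw_state(self, three_lane_counts):
        norm, _ = normalize_pipeline(three_lane_counts, CFG)
        with pytest.raises(NormalizationError, match="raw"):
            normalize_pipeline(norm, CFG)
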