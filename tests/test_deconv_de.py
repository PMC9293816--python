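"""Differential expression, BH adjustment and the signature set logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hclsig.deconv_de import (DEError, FilterCriteria, bh_adjust,
                              compare_chcl_vhcl, compare_groups,
                              derive_signatures, fold_change_correlation,
                              volcano_table)
from hclsig.normalization import normalize_pipeline
from hclsig.synthetic_data import ExperimentDesign, simulate_experiment

from conftest import brute_force_bh, make_counts, make_panel


def normalized_fixture(values, groups):
    cm = make_counts(values, panel=make_panel(), groups=groups, state="normalized")
    return cm


@pytest.fixture(scope="module")
def sim_norm():
    cm, truth = simulate_experiment(seed=1)
    norm, _ = normalize_pipeline(cm)
    return norm, truth


class TestBHAdjust:
    @pytest.mark.parametrize("p, expected", [
        ([0.03], [0.03]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.005, 0.9], [0.01, 0.9]),
    ])
    def test_hand_computed_cases(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(1, 501))
            p = rng.random(n)
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p),
                                       atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(DEError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_adjusted_at_least_raw_and_capped(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1.0).all()


class TestCompareGroups:
    def test_identical_groups_select_nothing(self):
        col = [100, 50, 30, 25, 40, 300, 400, 100, 200, 5, 5]
        norm = normalized_fixture(
            {"A1": col, "A2": col, "B1": col, "B2": col},
            groups={"A1": "nB", "A2": "nB", "B1": "nMNC", "B2": "nMNC"})
        res = compare_groups(norm, "nB", "nMNC")
        assert (res.table["fold_change"] == 1.0).all()
        assert not res.table["selected_up"].any()
        assert not res.table["selected_down"].any()

    def test_planted_fourfold_gene_p_matches_t_cdf(self):
        """p for a 4-fold gene equals a direct pooled-t CDF evaluation."""
        rng = np.random.default_rng(21)
        n = 5
        base = rng.normal(100, 3, size=(11, n))
        other = rng.normal(100, 3, size=(11, n))
        other[0] *= 4  # gene E1 four-fold up in group A
        values = {f"A{i}": np.round(other[:, i], 6).tolist() for i in range(n)}
        values |= {f"B{i}": np.round(base[:, i], 6).tolist() for i in range(n)}
        groups = {f"A{i}": "nB" for i in range(n)} | {f"B{i}": "nMNC" for i in range(n)}
        norm = normalized_fixture(values, groups)
        res = compare_groups(norm, "nB", "nMNC")
        assert res.table.loc["E1", "selected_up"]
        # independent oracle: pooled two-sample t and its CDF, by the formulas
        la = np.log2(other[0] + 1)
        lb = np.log2(base[0] + 1)
        sp2 = (((n - 1) * la.var(ddof=1) + (n - 1) * lb.var(ddof=1)) / (2 * n - 2))
        t = (la.mean() - lb.mean()) / np.sqrt(sp2 * (2 / n))
        p_expected = 2 * stats.t.sf(abs(t), 2 * n - 2)
        assert res.table.loc["E1", "p_raw"] == pytest.approx(p_expected, abs=1e-10)

    def test_antisymmetry_of_contrasts(self, sim_norm):
        norm, _ = sim_norm
        ab = compare_groups(norm, "nB", "nMNC")
        ba = compare_groups(norm, "nMNC", "nB")
        np.testing.assert_allclose(
            ab.table["fold_change"] * ba.table["fold_change"], 1.0, rtol=1e-9)
        np.testing.assert_allclose(ab.table["p_raw"], ba.table["p_raw"],
                                   rtol=1e-12)

    def test_selection_monotone_in_thresholds(self, sim_norm):
        norm, _ = sim_norm
        base = compare_groups(norm, ("cHCL", "vHCL"), "nMNC", FilterCriteria())
        stricter = [
            FilterCriteria(alpha=0.01),
            FilterCriteria(min_fold_change=4),
            FilterCriteria(min_expression=100),
        ]
        for crit in stricter:
            res = compare_groups(norm, ("cHCL", "vHCL"), "nMNC", crit)
            assert res.genes_up() <= base.genes_up()
            assert res.genes_down() <= base.genes_down()

    def test_single_lane_group_rejected(self):
        col = [1] * 11
        norm = normalized_fixture(
            {"A1": col, "B1": col, "B2": col},
            groups={"A1": "nB", "B1": "nMNC", "B2": "nMNC"})
        with pytest.raises(DEError, match=">= 2"):
            compare_groups(norm, "nB", "nMNC")

    def test_unknown_group_rejected(self, sim_norm):
        norm, _ = sim_norm
        with pytest.raises(DEError):
            compare_groups(norm, "nope", "nMNC")

    def test_p_adj_never_below_p_raw(self, sim_norm):
        norm, _ = sim_norm
        res = compare_groups(norm, "nB", "nMNC")
        assert (res.table["p_adj"] >= res.table["p_raw"] - 1e-15).all()


class TestSignatures:
    def test_intersection_construction(self, sim_norm):
        norm, _ = sim_norm
        sets = derive_signatures(norm)
        assert sets.hcl_signature == sets.hcl_over_vs_nmnc & sets.hcl_over_vs_nb
        universe = set(norm.panel.table.loc[norm.panel.endogenous, "gene_symbol"])
        for s in sets.as_dict().values():
            assert s <= universe

    def test_planted_signature_recovery_single_run(self, sim_norm):
        norm, truth = sim_norm
        sets = derive_signatures(norm)
        planted = set(truth.planted_up)
        assert len(sets.hcl_signature & planted) >= 15
        assert len(sets.hcl_signature - planted) <= 2

    def test_under_reference_switch(self, sim_norm):
        norm, _ = sim_norm
        nb = derive_signatures(norm, under_reference="nB", include_chcl_vhcl=False)
        nmnc = derive_signatures(norm, under_reference="nMNC", include_chcl_vhcl=False)
        both = derive_signatures(norm, under_reference="both", include_chcl_vhcl=False)
        assert both.hcl_under == nb.hcl_under & nmnc.hcl_under

    def test_empty_over_lists_give_empty_signature(self):
        col = [100, 50, 30, 25, 40, 300, 400, 100, 200, 5, 5]
        lanes = {f"L{i}": col for i in range(8)}
        groups = {"L0": "cHCL", "L1": "cHCL", "L2": "vHCL", "L3": "vHCL",
                  "L4": "nMNC", "L5": "nMNC", "L6": "nB", "L7": "nB"}
        norm = normalized_fixture(lanes, groups)
        sets = derive_signatures(norm)
        assert sets.hcl_signature == set()


class TestChclVhcl:
    def test_identical_duplicated_lanes_give_empty_sets(self):
        col = [100, 50, 30, 25, 40, 300, 400, 100, 200, 5, 5]
        norm = normalized_fixture(
            {"C1": col, "C2": col, "V1": col, "V2": col},
            groups={"C1": "cHCL", "C2": "cHCL", "V1": "vHCL", "V2": "vHCL"})
        _, over, under = compare_chcl_vhcl(norm)
        assert over == set() and under == set()

    def test_null_false_positive_rate_consistent_with_fdr_control(self):
        """With no planted classical/variant difference, the fraction of
        seeds yielding any selection must be consistent with BH control of
        the all-null family (binomial bound at alpha = 0.05)."""
        design = ExperimentDesign(n_chcl_vhcl_de=0)
        nonempty = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cm, _ = simulate_experiment(design, seed=seed)
            norm, _ = normalize_pipeline(cm)
            _, over, under = compare_chcl_vhcl(norm)
            nonempty += bool(over or under)
        # one-sided binomial 99.9% critical value for n=100, p=0.05
        assert nonempty <= stats.binom.ppf(0.999, n_seeds, 0.05)

    def test_planted_differences_detected(self, sim_norm):
        norm, truth = sim_norm
        _, over, under = compare_chcl_vhcl(norm)
        planted = set(truth.chcl_vhcl_de)
        assert (over | under) & planted


class TestFoldChangeCorrelation:
    def test_group_against_itself_is_perfectly_correlated(self, sim_norm):
        norm, _ = sim_norm
        out = fold_change_correlation(norm, "cHCL", "cHCL", "nB")
        assert out["r"] == pytest.approx(1.0)

    def test_correlated_subtypes_on_simulated_data(self, sim_norm):
        norm, _ = sim_norm
        out = fold_change_correlation(norm, "cHCL", "vHCL", "nB")
        assert out["n_genes"] >= 3
        assert out["r"] > 0.5  # shared malignant profile dominates

    def test_too_few_genes_errors(self):
        col = [100, 50, 30, 25, 40, 300, 400, 100, 200, 5, 5]
        norm = normalized_fixture(
            {"C1": col, "C2": col, "V1": col, "V2": col, "R1": col, "R2": col},
            groups={"C1": "cHCL", "C2": "cHCL", "V1": "vHCL", "V2": "vHCL",
                    "R1": "nB", "R2": "nB"})
        with pytest.raises(DEError, match=">= 3"):
            fold_change_correlation(norm, "cHCL", "vHCL", "nB")


class TestVolcanoTable:
    def test_rows_flags_and_p_transform(self, sim_norm):
        norm, _ = sim_norm
        res = compare_groups(norm, ("cHCL", "vHCL"), "nB")
        v = volcano_table(res)
        assert len(v) == len(norm.panel.endogenous)
        assert (v.loc[res.table["p_adj"] == 1.0, "neg_log10_p_adj"] == 0).all()
        assert (v["selected"] == (res.table["selected_up"]
                                  | res.table["selected_down"])).all()

    def test_boundary_values_are_selected_inclusively(self):
        """fold change exactly 2 and adjusted p exactly at alpha count as hits."""
        a = [40.0, 100, 100, 100, 100]
        b = [20.0, 100, 100, 100, 100]
        values = {"A1": a + [300, 400, 100, 200, 5, 5],
                  "A2": a + [300, 400, 100, 200, 5, 5],
                  "B1": b + [300, 400, 100, 200, 5, 5],
                  "B2": b + [300, 400, 100, 200, 5, 5]}
        groups = {"A1": "nB", "A2": "nB", "B1": "nMNC", "B2": "nMNC"}
        norm = normalized_fixture(values, groups)
        res = compare_groups(norm, "nB", "nMNC")
        row = res.table.loc["E1"]
        assert row["fold_change"] == pytest.approx(2.0)
        assert row["p_adj"] == 0.0  # zero within-group variance, unequal means
        assert row["selected_up"]
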