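import itertools

import numpy as np
import pandas as pd
import pytest

from insideout.containers import ResultTable, StudyDesign
from insideout.irreversibility import IrrevCurve
from insideout.stats import (
    cluster_perm_over_tau,
    fdr_adjust,
    normality_battery,
    paired_permutation,
    rm_anova,
    select_tau_crossval,
    select_tau_orthogonal,
)


def curve(values, fs=200.0):
    values = np.asarray(values, dtype=float)
    taus = np.arange(1, values.size + 1)
    return IrrevCurve(taus=taus, values=values, fs=fs,
                      total=float(np.trapezoid(values, taus / fs)))


def synthetic_curves(design, peak_by_drug, noise=0.0, seed=0, n_tau=30):
    """Analytic curve bank: a Gaussian bump whose height depends on drug."""
    rng = np.random.default_rng(seed)
    taus = np.arange(1, n_tau + 1)
    curves = {}
    for key in design.grid():
        _, drug, _ = key
        height, center = peak_by_drug[drug]
        vals = height * np.exp(-0.5 * ((taus - center) / 3.0) ** 2)
        vals = vals + 0.05 + noise * rng.standard_normal(n_tau)
        curves[key] = curve(np.abs(vals))
    return curves


class TestSelectTauOrthogonal:
    def test_single_peaked_curve(self):
        vals = np.zeros(20)
        vals[11] = 1.0  # tau = 12 on the 1-based grid
        sel = select_tau_orthogonal({("a", "control", "Open"): curve(vals)})
        assert sel.tau_optimal == 12

    def test_mean_of_two_curves_matches_scan_oracle(self):
        v1 = np.exp(-0.5 * (np.arange(1, 31) - 10.0) ** 2 / 9)
        v2 = np.exp(-0.5 * (np.arange(1, 31) - 14.0) ** 2 / 9)
        curves = {
            ("a", "control", "Open"): curve(v1),
            ("b", "control", "Open"): curve(v2),
        }
        oracle = 1 + int(np.argmax((v1 + v2) / 2))
        assert select_tau_orthogonal(curves).tau_optimal == oracle

    def test_flat_curves_tie_to_smallest_tau(self):
        sel = select_tau_orthogonal({("a", "c", "O"): curve(np.ones(15))})
        assert sel.tau_optimal == 1


class TestSelectTauCrossval:
    def test_study_scale_fold_sizes(self):
        """16 participants x 2 drugs x 4 conditions in 8 folds: 16 per fold."""
        design = StudyDesign(tuple(f"p{i:02d}" for i in range(16)))
        curves = synthetic_curves(
            design, {"control": (1.0, 10), "drug": (0.4, 10)}, noise=0.02
        )
        sel = select_tau_crossval(curves, design, n_folds=8, n_perm=200, seed=0)
        fold_sizes = np.bincount(list(sel.fold_assignments.values()))
        assert np.all(fold_sizes == 2)  # participants per fold
        # each fold therefore holds 2 x 2 x 4 = 16 datasets
        assert 2 * 2 * 4 == 16

    def test_recovers_contrast_peak_and_significance(self):
        design = StudyDesign(tuple(f"p{i}" for i in range(8)),
                             condition_levels=("Open",))
        curves = synthetic_curves(
            design, {"control": (1.0, 12), "drug": (0.3, 12)}, noise=0.01, seed=3
        )
        sel = select_tau_crossval(curves, design, n_folds=4, n_perm=500, seed=1)
        assert abs(sel.tau_optimal - 12) <= 2
        assert sel.p_value < 0.05

    def test_every_dataset_tested_exactly_once(self):
        design = StudyDesign(tuple(f"p{i}" for i in range(8)),
                             condition_levels=("Open",))
        curves = synthetic_curves(
            design, {"control": (1.0, 10), "drug": (0.5, 10)}, noise=0.01
        )
        sel = select_tau_crossval(curves, design, n_folds=4, n_perm=100, seed=2)
        assert sorted(sel.fold_assignments) == sorted(design.participant_ids)
        assert len(sel.fold_taus) == 4

    def test_indivisible_participants_rejected(self):
        design = StudyDesign(("a", "b", "c"))
        with pytest.raises(ValueError, match="divisible"):
            select_tau_crossval(
                synthetic_curves(design, {"control": (1, 5), "drug": (1, 5)}),
                design, n_folds=2,
            )


class TestPairedPermutation:
    def test_identical_samples_give_p_one(self):
        a = np.arange(6.0)
        assert paired_permutation(a, a.copy(), n_perm=200, seed=0) == 1.0

    def test_matches_exhaustive_enumeration(self, rng):
        a = rng.standard_normal(5) + 0.8
        b = rng.standard_normal(5)
        d = a - b
        obs = abs(d.mean())
        exact = sum(
            abs(np.mean(np.array(signs) * d)) >= obs
            for signs in itertools.product([-1, 1], repeat=5)
        ) / 2**5
        mc = paired_permutation(a, b, n_perm=4000, seed=1)
        assert abs(mc - exact) < 3 * np.sqrt(exact * (1 - exact) / 4000) + 1e-3

    def test_large_shift_is_highly_significant(self, rng):
        a = rng.standard_normal(16) + 10.0
        b = rng.standard_normal(16)
        assert paired_permutation(a, b, n_perm=10000, seed=2) <= 0.001

    def test_small_n_perm_warns(self):
        with pytest.warns(UserWarning, match="n_perm"):
            paired_permutation(np.arange(4.0), np.arange(4.0) + 1, n_perm=50, seed=0)


class TestClusterPermutation:
    def test_identical_curves_no_clusters(self, rng):
        a = rng.standard_normal((10, 40))
        res = cluster_perm_over_tau(a, a.copy(), np.arange(1, 41), n_perm=100, seed=0)
        assert res.clusters == []

    def test_detects_injected_cluster_support(self, rng):
        n, n_tau = 12, 60
        a = rng.standard_normal((n, n_tau))
        b = a + rng.standard_normal((n, n_tau)) * 0.3
        b[:, 20:41] += 1.5  # contrast confined to tau indices 20..40
        res = cluster_perm_over_tau(a, b, np.arange(n_tau), n_perm=300, seed=1)
        sig = [c for c, p in zip(res.clusters, res.p_values) if p < 0.05]
        assert sig, "no significant cluster found"
        lo = min(c[0] for c in sig)
        hi = max(c[1] for c in sig)
        assert lo >= 15 and hi <= 45  # overlaps the injected support

    def test_single_point_cluster_permitted(self, rng):
        n = 12
        a = rng.standard_normal((n, 5)) * 0.1
        b = a.copy()
        b[:, 2] += 2.0
        res = cluster_perm_over_tau(a, b, np.arange(5), n_perm=200, seed=0)
        assert (2, 2) in res.clusters

    def test_familywise_error_controlled(self, rng):
        """Max-null calibration: few false clusters on pure noise."""
        hits = 0
        n_sim = 60
        for s in range(n_sim):
            r = np.random.default_rng(s)
            a = r.standard_normal((8, 30))
            b = r.standard_normal((8, 30))
            res = cluster_perm_over_tau(a, b, np.arange(30), n_perm=120, seed=s)
            hits += any(p < 0.05 for p in res.p_values)
        assert hits / n_sim <= 0.12


class TestRmAnova:
    def test_label_permutation_invariance(self, mini_cohort_metrics):
        table, design = mini_cohort_metrics
        out = rm_anova(table, "r")
        df = table.df[table.df["metric_name"] == "r"].copy()
        # consistent relabeling of participants leaves F untouched
        mapping = {p: f"z{p}" for p in design.participant_ids}
        df["participant"] = df["participant"].map(mapping)
        out2 = rm_anova(ResultTable(df), "r")
        assert np.allclose(out["F"], out2["F"])

    def test_detects_drug_effect_on_cohort(self, mini_cohort_metrics):
        table, _ = mini_cohort_metrics
        out = rm_anova(table, "r")
        drug_p = float(out.loc[out["factor"] == "drug", "p"].iloc[0])
        assert drug_p < 0.05

    def test_unbalanced_design_rejected(self, mini_cohort_metrics):
        table, _ = mini_cohort_metrics
        df = table.df[table.df["metric_name"] == "r"].iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            rm_anova(ResultTable(df), "r")


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_computed_bh_example(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_ones(self):
        assert np.allclose(fdr_adjust(np.ones(5)), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestNormalityBattery:
    def test_normal_samples_mostly_pass(self):
        passes = 0
        for seed in range(60):
            x = np.random.default_rng(seed).standard_normal(500)
            passes += normality_battery(x).attrs["majority_normal"]
        assert passes / 60 >= 0.9

    def test_exponential_samples_mostly_fail(self):
        fails = 0
        for seed in range(60):
            x = np.random.default_rng(seed).exponential(size=500)
            fails += not normality_battery(x).attrs["majority_normal"]
        assert fails / 60 >= 0.9

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normality_battery(np.ones(20))

    def test_reports_all_four_tests(self, rng):
        df = normality_battery(rng.standard_normal(100))
        assert set(df["test"]) == {
            "shapiro_wilk", "dagostino_k2", "anderson_darling", "jarque_bera",
        }
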