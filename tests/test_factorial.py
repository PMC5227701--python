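import numpy as np
import pandas as pd
import pytest

from psifactor import (
    COMPARISONS,
    FactorialDesign,
    SimulationConfig,
    classify_events,
    concordance_regression,
    condition_psi_means,
    cumulative_delta,
    interaction_lrt,
    run_five_comparisons,
    simulate_factorial_experiment,
    trajectory_table,
)

# Condition mean PSI values realizing the printed worked-example deltas on
# the skipping-positive scale: mut effect under vehicle 0.205, drug effect in
# WT 0.188, drug effect in mutant 0.204, cumulative 0.409.
WORKED_EXAMPLE_MEANS = {
    "WT_Veh": 0.700,
    "WT_Drug": 0.700 - 0.188,
    "MT_Veh": 0.700 - 0.205,
    "MT_Drug": 0.700 - 0.205 - 0.204,
}


class TestCumulativeDelta:
    def test_worked_example(self):
        means = pd.Series(WORKED_EXAMPLE_MEANS)
        cum = cumulative_delta(means, skipping_positive=True)
        np.testing.assert_allclose(cum, 0.409, atol=1e-12)

    def test_all_equal_zero(self):
        means = pd.Series({c: 0.5 for c in WORKED_EXAMPLE_MEANS})
        assert cumulative_delta(means) == 0.0

    def test_decomposition_paths_agree(self):
        means = pd.Series(WORKED_EXAMPLE_MEANS)
        path1 = (means["MT_Veh"] - means["WT_Veh"]) + (means["MT_Drug"] - means["MT_Veh"])
        path2 = (means["WT_Drug"] - means["WT_Veh"]) + (means["MT_Drug"] - means["WT_Drug"])
        np.testing.assert_allclose(path1, path2, atol=1e-15)
        np.testing.assert_allclose(cumulative_delta(means), path1, atol=1e-15)

    def test_missing_propagates(self):
        means = pd.Series({**WORKED_EXAMPLE_MEANS, "MT_Drug": np.nan})
        assert np.isnan(cumulative_delta(means))


class TestPathAdditivity:
    def test_exact_on_simulation(self, small_dataset):
        means = condition_psi_means(small_dataset.junction_counts).dropna()
        cum = means["MT_Drug"] - means["WT_Veh"]
        p1 = (means["MT_Veh"] - means["WT_Veh"]) + (means["MT_Drug"] - means["MT_Veh"])
        p2 = (means["WT_Drug"] - means["WT_Veh"]) + (means["MT_Drug"] - means["WT_Drug"])
        np.testing.assert_allclose(cum, p1, atol=1e-12)
        np.testing.assert_allclose(cum, p2, atol=1e-12)


class TestRunFiveComparisons:
    def test_five_frames_with_oriented_deltas(self, small_dataset):
        five = run_five_comparisons(small_dataset.junction_counts)
        assert set(five) == {c[0] for c in COMPARISONS}
        means = condition_psi_means(small_dataset.junction_counts)
        cum = five["cumulative"].set_index("event_id")["delta_psi"]
        direct = (means["MT_Drug"] - means["WT_Veh"]).dropna()
        common = cum.dropna().index.intersection(direct.index)
        np.testing.assert_allclose(
            cum.loc[common], direct.loc[common], atol=1e-12
        )

    def test_path_additivity_of_comparison_deltas(self, small_dataset):
        five = run_five_comparisons(small_dataset.junction_counts)
        d = {
            name: five[name].set_index("event_id")["delta_psi"]
            for name in five
        }
        lhs = d["cumulative"].dropna()
        rhs = (d["mut_vs_wt_Veh"] + d["drug_vs_veh_MT"]).dropna()
        common = lhs.index.intersection(rhs.index)
        np.testing.assert_allclose(lhs.loc[common], rhs.loc[common], atol=1e-12)

    def test_missing_cell_errors(self, small_dataset):
        table = small_dataset.junction_counts
        bad = {s: c for s, c in table.sample_conditions.items() if c != "MT_Drug"}
        with pytest.raises(ValueError):
            FactorialDesign(sample_conditions=bad)

    def test_all_null_few_significant_in_all_five(self, null_dataset):
        five = run_five_comparisons(null_dataset.junction_counts)
        cls = classify_events(five, fdr_max=0.10, min_abs_dpsi=0.01)
        assert cls["trajectory_eligible"].mean() < 0.01


class TestConcordanceRegression:
    def test_identity(self):
        x = np.linspace(-0.3, 0.3, 20)
        res = concordance_regression(x, x)
        np.testing.assert_allclose(res.slope, 1.0, atol=1e-12)
        np.testing.assert_allclose(res.r_squared, 1.0, atol=1e-12)

    def test_independent_noise_low_r2(self):
        rng = np.random.default_rng(3)
        res = concordance_regression(rng.normal(size=500), rng.normal(size=500))
        assert res.r_squared < 0.05

    def test_attenuation_recovery(self):
        """Planted slope 0.75 with small noise recovered within [0.70, 0.80]."""
        rng = np.random.default_rng(4)
        x = rng.normal(0, 0.15, 600)
        y = 0.75 * x + rng.normal(0, 0.03, 600)
        res = concordance_regression(x, y)
        assert 0.70 <= res.slope <= 0.80

    def test_degenerate_predictor(self):
        with pytest.raises(ValueError):
            concordance_regression(np.ones(10), np.arange(10.0))

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            concordance_regression([0.1, 0.2], [0.1, 0.2])


def _design(reps=5):
    conds = (
        ["WT_Veh"] * reps + ["WT_Drug"] * reps + ["MT_Veh"] * reps + ["MT_Drug"] * reps
    )
    samples = [f"s{i}" for i in range(len(conds))]
    return FactorialDesign(dict(zip(samples, conds))), samples, conds


class TestInteractionLrt:
    def test_statistic_nonnegative(self):
        rng = np.random.default_rng(5)
        design, samples, conds = _design()
        for _ in range(10):
            tots = rng.integers(20, 100, 20)
            inc = rng.binomial(tots, 0.5)
            p, sign, stat = interaction_lrt(inc, tots - inc, design, sample_order=samples)
            assert stat >= 0

    def test_factor_relabel_invariance(self):
        """Swapping genotype and treatment labels simultaneously leaves the
        interaction p unchanged (the product term is symmetric)."""
        rng = np.random.default_rng(6)
        design, samples, conds = _design()
        swapped = {
            s: {"WT_Veh": "WT_Veh", "WT_Drug": "MT_Veh",
                "MT_Veh": "WT_Drug", "MT_Drug": "MT_Drug"}[c]
            for s, c in zip(samples, conds)
        }
        design2 = FactorialDesign(swapped)
        tots = rng.integers(30, 90, 20)
        inc = rng.binomial(tots, np.repeat([0.3, 0.5, 0.6, 0.4], 5))
        p1 = interaction_lrt(inc, tots - inc, design, sample_order=samples)[0]
        p2 = interaction_lrt(inc, tots - inc, design2, sample_order=samples)[0]
        np.testing.assert_allclose(p1, p2, rtol=1e-6)

    def test_power_with_planted_interaction(self):
        from scipy.special import expit

        rng = np.random.default_rng(7)
        design, samples, conds = _design()
        rho = 0.02
        s = (1 - rho) / rho
        mus = {
            "WT_Veh": expit(0.0), "WT_Drug": expit(-0.5),
            "MT_Veh": expit(0.5), "MT_Drug": expit(0.0 + 1.5),
        }
        rej = 0
        n_sim = 150
        for _ in range(n_sim):
            tots = np.maximum(rng.poisson(60, 20), 1)
            mu = np.array([mus[c] for c in conds])
            p_i = rng.beta(mu * s, (1 - mu) * s)
            inc = rng.binomial(tots, p_i)
            p, sign, _ = interaction_lrt(inc, tots - inc, design, sample_order=samples)
            rej += p < 0.05
        assert rej / n_sim >= 0.7

    def test_degenerate_missing(self):
        design, samples, conds = _design()
        p, sign, stat = interaction_lrt(
            np.zeros(20), np.zeros(20), design, sample_order=samples
        )
        assert np.isnan(p)


class TestClassifyEvents:
    def _five(self, dpsi, fdr):
        names = [c[0] for c in COMPARISONS]
        return {
            name: pd.DataFrame(
                {"event_id": ["e"], "delta_psi": [dpsi[name]], "fdr": [fdr[name]]}
            )
            for name in names
        }

    def test_worked_example_classification(self):
        dpsi = {
            "mut_vs_wt_Veh": 0.205,
            "drug_vs_veh_WT": 0.188,
            "drug_vs_veh_MT": 0.204,
            "mut_vs_wt_Drug": 0.221,
            "cumulative": 0.409,
        }
        fdr = {k: 0.001 for k in dpsi}
        cls = classify_events(self._five(dpsi, fdr), fdr_max=0.10, min_abs_dpsi=0.01)
        row = cls.iloc[0]
        assert row["drug_concordant"]
        assert row["cumulative_exacerbated"]
        assert row["trajectory_eligible"]
        assert not row["drug_discordant"]

    def test_all_null_no_labels(self):
        dpsi = {c[0]: 0.0 for c in COMPARISONS}
        fdr = {c[0]: 1.0 for c in COMPARISONS}
        cls = classify_events(self._five(dpsi, fdr), 0.10, 0.01)
        row = cls.iloc[0]
        assert not row[["drug_concordant", "drug_discordant",
                        "cumulative_exacerbated", "trajectory_eligible"]].any()

    def test_discordant_not_exacerbated(self):
        dpsi = {
            "drug_vs_veh_WT": 0.2,
            "drug_vs_veh_MT": -0.2,
            "mut_vs_wt_Veh": 0.0,
            "mut_vs_wt_Drug": -0.4,
            "cumulative": 0.0,
        }
        fdr = {k: 0.001 for k in dpsi}
        cls = classify_events(self._five(dpsi, fdr), 0.10, 0.01)
        row = cls.iloc[0]
        assert row["drug_discordant"]
        assert not row["drug_concordant"]
        assert not row["cumulative_exacerbated"]


class TestTrajectoryTable:
    def test_baseline_zero_and_worked_example_row(self):
        means = pd.DataFrame([WORKED_EXAMPLE_MEANS], index=["ev"])
        traj = trajectory_table(means, ["ev"], skipping_positive=True)
        row = traj.loc["ev"]
        assert row["WT_Veh"] == 0.0
        np.testing.assert_allclose(row["WT_Drug"], 0.188, atol=1e-12)
        np.testing.assert_allclose(row["MT_Veh"], 0.205, atol=1e-12)
        np.testing.assert_allclose(row["MT_Drug"], 0.409, atol=1e-12)
        assert row["group"] == "increased-skipping"

    def test_recomputable_by_subtraction(self, small_dataset):
        means = condition_psi_means(small_dataset.junction_counts).dropna()
        ids = means.index[:20]
        traj = trajectory_table(means, ids)
        for cond in ("WT_Veh", "WT_Drug", "MT_Veh", "MT_Drug"):
            np.testing.assert_allclose(
                traj[cond], means.loc[ids, cond] - means.loc[ids, "WT_Veh"],
                atol=1e-12,
            )
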