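"""Generator calibration, structural validity and closed-form ground truth."""

from __future__ import annotations

import numpy as np
import pytest
from dataclasses import replace

from ohca_partition import (
    SyntheticConfig,
    apply_inclusion_cascade,
    apply_time_plausibility,
    expected_stratum_probabilities,
    generate_cohort,
)
from ohca_partition.registry_io import nearest_rank_quantile
from ohca_partition.synthetic_data import (
    ContaminationRates,
    OutcomeTargets,
    StepPenalties,
    SyntheticConfigError,
)


class TestDeterminism:
    def test_same_seed_identical_cohort(self):
        a, _ = generate_cohort(SyntheticConfig(n=500, seed=5))
        b, _ = generate_cohort(SyntheticConfig(n=500, seed=5))
        assert a.df.equals(b.df)

    def test_different_seeds_differ(self):
        a, _ = generate_cohort(SyntheticConfig(n=500, seed=5))
        b, _ = generate_cohort(SyntheticConfig(n=500, seed=6))
        assert not a.df.equals(b.df)


class TestStructuralValidity:
    def test_clean_cohort_satisfies_record_invariants(self, clean_cohort):
        clean_cohort.check_invariants()

    def test_hospital_after_ambulance_and_rosc(self, clean_cohort):
        df = clean_cohort.df
        assert (df["t_hosp"] > df["t_amb"]).all()
        rosc = df["t_rosc"].notna()
        assert (df.loc[rosc, "t_rosc"] <= df.loc[rosc, "t_hosp"]).all()

    def test_rosc_time_only_for_rosc_records(self, clean_cohort):
        # t_rosc missing exactly for the non-ROSC complement
        frac = clean_cohort.df["t_rosc"].notna().mean()
        assert 0.10 < frac < 0.20

    def test_contamination_free_cohort_passes_cascade(self, clean_cohort):
        kept, report = apply_inclusion_cascade(clean_cohort)
        assert len(kept) == len(clean_cohort)

    def test_zero_contamination_zero_injected_implausible(self, clean_cohort):
        _, report = apply_time_plausibility(clean_cohort)
        # only the laws' natural tail can be excluded, never negatives
        assert report.diagnostics["t_cpr_negative"] == 0
        assert report.diagnostics["t_hosp_negative"] == 0

    def test_cpc_distribution_consistent_with_survival(self, clean_cohort):
        df = clean_cohort.df
        assert (df.loc[df["cpc"].isin([1, 2, 3, 4]), "survival_1mo"]).all()
        assert (~df.loc[df["cpc"] == 5, "survival_1mo"]).all()


class TestCalibration:
    @pytest.fixture(scope="class")
    def big(self):
        return generate_cohort(SyntheticConfig(n=50_000, seed=1))

    def test_interval_medians_within_one_minute(self, big):
        cohort, _ = big
        targets = {"t_cpr": 1, "t_amb": 9, "t_hosp": 32, "t_rosc": 16}
        for col, target in targets.items():
            vals = cohort.df[col].dropna().astype(float).to_numpy()
            assert abs(nearest_rank_quantile(vals, 0.5) - target) <= 1, col

    def test_interval_iqrs_within_one_minute(self, big):
        cohort, _ = big
        targets = {
            "t_cpr": (0, 3),
            "t_amb": (7, 12),
            "t_hosp": (26, 41),
            "t_rosc": (10, 25),
        }
        for col, (q1, q3) in targets.items():
            vals = cohort.df[col].dropna().astype(float).to_numpy()
            assert abs(nearest_rank_quantile(vals, 0.25) - q1) <= 1, col
            assert abs(nearest_rank_quantile(vals, 0.75) - q3) <= 1, col

    def test_marginal_favorable_within_three_se(self, big):
        # the implied marginal is defined over the analysis (plausible) region
        cohort, truth = big
        analysis, _ = apply_time_plausibility(cohort)
        p = truth.expected_marginal_favorable
        observed = analysis.df["cpc"].isin([1, 2]).mean()
        se = np.sqrt(p * (1 - p) / len(analysis))
        assert abs(observed - p) < 3 * se

    def test_marginal_survival_within_three_se(self, big):
        cohort, truth = big
        analysis, _ = apply_time_plausibility(cohort)
        p = truth.expected_marginal_survival
        observed = analysis.df["survival_1mo"].mean()
        se = np.sqrt(p * (1 - p) / len(analysis))
        assert abs(float(observed) - p) < 3 * se


class TestGeneratorTruth:
    def test_solved_levels_hit_calibration_targets_at_published_mix(self):
        config = SyntheticConfig()
        truth = expected_stratum_probabilities(config)
        at_mix = truth.expectations_at_share(config.analysis_rosc_share)
        assert at_mix["marginal_favorable"] == pytest.approx(0.060, abs=1e-9)
        assert at_mix["final_node_favorable"] == pytest.approx(0.091, abs=1e-9)
        assert at_mix["subgroup_final_node_favorable"] == pytest.approx(0.521, abs=1e-9)
        assert at_mix["marginal_survival"] == pytest.approx(0.105, abs=1e-9)
        # a clean simulated cohort runs at a slightly lower ROSC share, so
        # its implied marginal sits a little below the published 6.0%
        assert 0.05 < truth.expected_marginal_favorable < 0.06

    def test_degenerate_single_level_config(self):
        flat = StepPenalties(1.0, 1.0, 1.0, 1.0, 1.0, 1.0, rho_rosc=None)
        config = SyntheticConfig(
            favorable_targets=OutcomeTargets(0.10, 0.10, 0.10),
            survival_targets=OutcomeTargets(0.20, 0.20, 0.20),
            favorable_penalties=flat,
            survival_penalties=flat,
        )
        truth = expected_stratum_probabilities(config)
        assert truth.favorable.base_no_rosc == pytest.approx(0.10, abs=1e-9)
        assert truth.favorable.base_rosc == pytest.approx(0.10, abs=1e-9)
        assert truth.favorable.rho_rosc == pytest.approx(1.0, abs=1e-6)
        assert truth.expected_marginal_favorable == pytest.approx(0.10, abs=1e-9)

    def test_monte_carlo_cross_check_of_marginal(self):
        config = SyntheticConfig(n=400_000, seed=17)
        cohort, truth = generate_cohort(config)
        p = truth.expected_marginal_favorable
        se = np.sqrt(p * (1 - p) / config.n)
        assert abs(cohort.df["cpc"].isin([1, 2]).mean() - p) < 3 * se

    def test_threshold_zero_mass_identity(self):
        # flat outcome levels keep the solve feasible at a degenerate threshold
        flat = StepPenalties(1.0, 1.0, 1.0, 1.0, 1.0, 1.0, rho_rosc=None)
        config = SyntheticConfig(
            thresholds=(("t_cpr", 0), ("t_amb", 11), ("t_hosp", 19), ("t_rosc", 18)),
            favorable_targets=OutcomeTargets(0.10, 0.10, 0.10),
            survival_targets=OutcomeTargets(0.20, 0.20, 0.20),
            favorable_penalties=flat,
            survival_penalties=flat,
        )
        truth = expected_stratum_probabilities(config)
        from ohca_partition.synthetic_data import _calibrated_laws

        laws = _calibrated_laws(config.interval_targets, config.p_rosc)
        # stratum masses are conditioned on the plausible region, so the
        # zero-threshold mass is the law's point mass at minute 0 within it
        expected = laws.pmf_cpr[0] / laws.pmf_cpr[:21].sum()
        assert truth.masses["p_cpr_within"] == pytest.approx(expected)

    def test_survival_dominates_favorable_in_every_stratum(self):
        truth = expected_stratum_probabilities(SyntheticConfig())
        for w in [(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)]:
            assert truth.survival.prob_no_rosc(*w) >= truth.favorable.prob_no_rosc(*w)

    def test_infeasible_targets_rejected(self):
        config = SyntheticConfig(
            favorable_targets=OutcomeTargets(marginal=0.5, final_node=0.01,
                                            subgroup_final_node=0.521)
        )
        with pytest.raises(SyntheticConfigError):
            expected_stratum_probabilities(config)


class TestContamination:
    def test_rates_validated(self):
        with pytest.raises(SyntheticConfigError):
            ContaminationRates(unwitnessed=0.7, no_cpr=0.4).validate()
        with pytest.raises(SyntheticConfigError):
            ContaminationRates(minor=-0.1).validate()

    def test_registry_preset_produces_expected_exclusion_mix(self, registry_cohort):
        _, report = apply_inclusion_cascade(registry_cohort)
        counts = dict((r[0], r[1]) for r in report.rows)
        n = len(registry_cohort)
        # binomial 4-sigma sanity bands around the preset rates
        for rule, rate in [
            ("not_witnessed", 326_191 / 547_218),
            ("no_bystander_cpr", 139_896 / 547_218),
        ]:
            se = np.sqrt(rate * (1 - rate) / n)
            assert abs(counts[rule] / n - rate) < 4 * se, rule

    def test_smooth_outcome_model_generates_valid_cohort(self):
        config = SyntheticConfig(n=2_000, seed=2, outcome_model="smooth")
        cohort, _ = generate_cohort(config)
        cohort.check_invariants()

    def test_smooth_model_probability_decreases_with_time(self):
        config = SyntheticConfig(outcome_model="smooth")
        truth = expected_stratum_probabilities(config)
        from ohca_partition.synthetic_data import _smooth_factor

        t = np.arange(0, 40)
        f = _smooth_factor(t, 11, 0.4, config.smooth_scale)
        assert (np.diff(f) <= 1e-12).all()
        assert f[0] == pytest.approx(1.0, abs=0.01)
        assert f[-1] == pytest.approx(0.4, abs=0.01)
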