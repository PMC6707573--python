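"""Decision analysis: SUR oracle equivalence, bootstrap, ICER, CEAC, plane."""

import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

import trialcea as t
from trialcea.cea_engine import (
    IncrementalCloud,
    WTP_GRID_QALY,
    bootstrap_cloud,
    ceac,
    effect_column,
    fit_sur,
    icer,
    icer_interval,
    percentile_ci,
    plane_distribution,
    run_scenario,
    scenario_spec,
    total_cost_column,
)


def _cloud(dc, de, kind="qaly"):
    dc = np.asarray(dc, dtype=float)
    de = np.asarray(de, dtype=float)
    return IncrementalCloud(dc, de, float(dc.mean()), float(de.mean()), kind, seed=0)


class TestFitSur:
    def test_arm_constant_data(self):
        arm = np.array([1.0] * 4 + [0.0] * 4)
        costs = np.where(arm == 1, 500.0, 800.0)
        effects = np.where(arm == 1, 2.0, 1.0)
        fit = fit_sur(costs, effects, arm)
        assert fit.delta_cost == -300.0
        assert fit.delta_effect == 1.0
        assert fit.residual_correlation == 0.0

    def test_equals_group_mean_difference_oracle(self, completed_frames, unit_costs):
        for frame in completed_frames:
            costs = total_cost_column(frame, unit_costs)
            effects = effect_column(frame, "qaly")
            arm = frame["arm01"].to_numpy()
            fit = fit_sur(costs, effects, arm)
            assert fit.delta_cost == pytest.approx(
                costs[arm == 1].mean() - costs[arm == 0].mean(), rel=1e-12
            )
            assert fit.delta_effect == pytest.approx(
                effects[arm == 1].mean() - effects[arm == 0].mean(), rel=1e-12
            )

    def test_independent_cost_effect_residual_correlation_null(self):
        rng = np.random.default_rng(42)
        n = 4000
        arm = np.repeat([1.0, 0.0], n // 2)
        costs = rng.exponential(1000, n)
        effects = rng.normal(5, 2, n)
        fit = fit_sur(costs, effects, arm)
        assert abs(fit.residual_correlation) < 3 / math.sqrt(n)

    def test_single_arm_rejected(self):
        with pytest.raises(ValueError, match="arms"):
            fit_sur(np.ones(4), np.ones(4), np.ones(4))


class TestBootstrap:
    def _triple(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        arm = np.repeat([1.0, 0.0], n // 2)
        return rng.exponential(1000, n), rng.normal(1, 0.5, n), arm

    def test_single_draw_reproducible(self):
        triple = self._triple()
        a = bootstrap_cloud([triple], "qaly", B=1, seed=9)
        b = bootstrap_cloud([triple], "qaly", B=1, seed=9)
        assert a.delta_costs[0] == b.delta_costs[0]
        assert a.delta_effects[0] == b.delta_effects[0]

    def test_arm_constant_data_zero_variance(self):
        arm = np.repeat([1.0, 0.0], 5)
        costs = np.where(arm == 1, 100.0, 400.0)
        effects = np.where(arm == 1, 3.0, 1.0)
        cloud = bootstrap_cloud([(costs, effects, arm)], "pss", B=50, seed=1)
        assert np.all(cloud.delta_costs == -300.0)
        assert np.all(cloud.delta_effects == 2.0)

    def test_cloud_mean_consistent_with_point_estimate(self):
        triple = self._triple(seed=3, n=200)
        cloud = bootstrap_cloud([triple], "qaly", B=1000, seed=2)
        for draws, hat in (
            (cloud.delta_costs, cloud.delta_cost_hat),
            (cloud.delta_effects, cloud.delta_effect_hat),
        ):
            tol = 3 * draws.std(ddof=1) / math.sqrt(cloud.B)
            assert abs(draws.mean() - hat) < tol

    def test_draws_stacked_equally_over_imputations(self):
        triples = [self._triple(seed=s) for s in (1, 2, 3)]
        cloud = bootstrap_cloud(triples, "qaly", B=10, seed=4)
        assert cloud.B == 10  # 4 + 3 + 3 allocation


class TestIcer:
    def test_dominance_and_ratio(self):
        assert icer(-386.0, 0.362) == "dominant"
        assert icer(500.0, 0.5) == 1000.0
        assert icer(100.0, -0.2) == "dominated"
        assert icer(-100.0, -0.2) == 500.0  # SW: plain ratio

    def test_zero_effect_signaled(self):
        with pytest.raises(ZeroDivisionError):
            icer(100.0, 0.0)

    def test_interval_labels(self):
        cloud = _cloud([-50, -10, 100, 200], [1.0, 2.0, 1.0, 2.0])
        out = icer_interval(cloud)
        assert out["lower"] == "dominant"
        assert isinstance(out["upper"], float)
        all_se = _cloud([-50, -10], [1.0, 2.0])
        assert icer_interval(all_se)["upper"] == "dominant"


class TestPlane:
    def test_one_draw_per_quadrant(self):
        cloud = _cloud([10, -10, -10, 10], [1, 1, -1, -1])
        assert plane_distribution(cloud).as_dict() == {
            "NE": 25.0, "SE": 25.0, "SW": 25.0, "NW": 25.0,
        }

    def test_all_dominant_draws(self):
        cloud = _cloud([-5, -1, -2], [1, 2, 3])
        assert plane_distribution(cloud).se == 100.0

    def test_percentages_sum_to_100(self, completed_frames, unit_costs):
        res = run_scenario(completed_frames, "main", unit_costs, B=300, seed=5)
        for r in res["effects"].values():
            assert sum(r["plane"].values()) == pytest.approx(100.0, abs=0.01)

    def test_quadrant_mass_matches_bivariate_normal_oracle(self):
        """A Gaussian cloud with moments matched to the published main
        QALY analysis lands within 2 points of the printed 26/69/2/3
        quadrant split, and within Monte-Carlo noise of the closed-form
        bivariate-normal orthant masses."""
        mu_e, sd_e = 0.0074, (0.016 + 0.0015) / 3.92
        mu_c, sd_c = -386.0, (1006 + 1794) / 3.92
        rho = -0.4
        rng = np.random.default_rng(77)
        z = rng.multivariate_normal(
            [0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=100_000
        )
        de = mu_e + sd_e * z[:, 0]
        dc = mu_c + sd_c * z[:, 1]
        quad = plane_distribution(_cloud(dc, de)).as_dict()

        # closed-form orthant masses (standardized)
        ze, zc = mu_e / sd_e, mu_c / sd_c
        p_sw = multivariate_normal([ze, zc], [[1, rho], [rho, 1]]).cdf([0, 0])
        p_se = norm.cdf(-zc) - p_sw
        p_nw = norm.cdf(-ze) - p_sw
        p_ne = 1 - p_se - p_sw - p_nw
        oracle = {"NE": p_ne, "SE": p_se, "SW": p_sw, "NW": p_nw}
        for q, printed in (("NE", 26), ("SE", 69), ("SW", 2), ("NW", 3)):
            assert quad[q] == pytest.approx(100 * oracle[q], abs=0.6)
            assert abs(quad[q] - printed) < 2.0


class TestCeac:
    def test_all_dominant_probability_one(self):
        cloud = _cloud([-5, -1], [1, 2])
        curve = ceac(cloud, [0, 1000, 50000])
        assert (curve.probability == 1.0).all()

    def test_single_draw_step_function(self):
        cloud = _cloud([1000.0], [1.0])
        curve = ceac(cloud, [0, 999, 1001, 5000])
        assert list(curve.probability) == [0.0, 0.0, 1.0, 1.0]

    def test_enumerated_draws_brute_force(self):
        dc = [100, -50, 800, 300, -10]
        de = [0.5, -0.1, 1.0, 0.2, 0.0]
        cloud = _cloud(dc, de)
        grid = [0, 500, 1000]
        curve = ceac(cloud, grid)
        for lam, prob in zip(grid, curve.probability):
            expected = sum(lam * e - c > 0 for c, e in zip(dc, de)) / 5
            assert prob == expected

    def test_at_zero_wtp_equals_cost_saving_share(self, completed_frames, unit_costs):
        res = run_scenario(completed_frames, "main", unit_costs, B=400, seed=6)
        for r in res["effects"].values():
            cloud = r["cloud"]
            curve = ceac(cloud, [0, 100])
            assert curve.probability[0] == (cloud.delta_costs < 0).mean()

    def test_monotone_when_effects_nonnegative(self):
        rng = np.random.default_rng(11)
        cloud = _cloud(rng.normal(0, 100, 500), rng.uniform(0, 1, 500))
        curve = ceac(cloud, WTP_GRID_QALY)
        assert (np.diff(curve.probability) >= 0).all()

    def test_rejects_bad_grid(self):
        with pytest.raises(ValueError):
            ceac(_cloud([1.0], [1.0]), [-5, 10])


class TestPercentileCi:
    def test_degenerate_cloud_zero_width(self):
        lo, hi = percentile_ci(np.full(100, 7.0))
        assert lo == hi == 7.0

    def test_order_statistic_oracle(self):
        values = np.arange(1.0, 101.0)
        lo, hi = percentile_ci(values)
        # linear interpolation between order statistics at ranks q*(n-1)
        assert lo == pytest.approx(1 + 0.025 * 99)
        assert hi == pytest.approx(1 + 0.975 * 99)

    def test_standard_normal_closed_form(self):
        rng = np.random.default_rng(13)
        lo, hi = percentile_ci(rng.standard_normal(200_000))
        assert lo == pytest.approx(-1.96, abs=0.03)
        assert hi == pytest.approx(1.96, abs=0.03)

    def test_small_cloud_warns(self):
        with pytest.warns(UserWarning, match="draws"):
            percentile_ci(np.arange(5.0))


class TestScenarios:
    def test_intervention_offset_shifts_cost_exactly(self, completed_frames, unit_costs):
        main = run_scenario(completed_frames, "main", unit_costs, B=200, seed=7)
        plus = run_scenario(
            completed_frames, "intervention_plus_100", unit_costs, B=200, seed=7
        )
        for kind in main["effects"]:
            dm = main["effects"][kind]
            dp = plus["effects"][kind]
            assert dp["delta_cost"] - dm["delta_cost"] == pytest.approx(100.0)
            np.testing.assert_allclose(
                dp["cloud"].delta_costs - dm["cloud"].delta_costs, 100.0
            )

    def test_no_inpatient_identical_without_inpatient_use(self, unit_costs):
        records = t.generate_trial(
            t.GeneratorConfig(n_per_arm=15, inpatient_admission_prob=0.0), seed=14
        )
        frame = t.impute_costs(t.build_analysis_frame(records, unit_costs))
        completed = t.impute_outcomes(frame, t.ImputationConfig(m_outcome=2, seed=15))
        a = run_scenario(completed, "main", unit_costs, B=100, seed=16)
        b = run_scenario(completed, "no_inpatient", unit_costs, B=100, seed=16)
        for kind in a["effects"]:
            np.testing.assert_array_equal(
                a["effects"][kind]["cloud"].delta_costs,
                b["effects"][kind]["cloud"].delta_costs,
            )

    def test_eq5d_scenario_switches_instrument(self, completed_frames, unit_costs):
        res = run_scenario(completed_frames, "eq5d", unit_costs, B=100, seed=17)
        assert list(res["effects"]) == ["qaly_eq5d"]
        frame = completed_frames[0]
        manual = effect_column(frame, "qaly_eq5d")
        auto = effect_column(frame, "qaly")
        assert not np.allclose(manual, auto)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            scenario_spec("employer_perspective")

    def test_eq5d_scenario_requires_columns(self, completed_frames, unit_costs):
        frames = [f.drop(columns=["eq5d_T1", "eq5d_T2", "eq5d_T3"]) for f in completed_frames]
        with pytest.raises(ValueError, match="eq5d"):
            run_scenario(frames, "eq5d", unit_costs, B=10, seed=18)

    def test_parameter_recovery_at_scale(self, big_records, unit_costs):
        """Cloud means recover the generator's configured incremental effect
        and cost (3 SE of the bootstrap distribution)."""
        cfg, records = big_records
        frame = t.build_analysis_frame(records, unit_costs)
        exp = t.expected_summaries(cfg, unit_costs)
        res = run_scenario([frame], "main", unit_costs, B=1000, seed=19)
        for kind, key in (("pss", "pss_improvement"), ("qaly", "qaly_sf6d")):
            r = res["effects"][kind]
            sd = r["cloud"].delta_effects.std(ddof=1)
            assert abs(r["delta_effect"] - exp["delta"][key]) < 3 * sd
        r = res["effects"]["qaly"]
        sd_c = r["cloud"].delta_costs.std(ddof=1)
        assert abs(r["delta_cost"] - exp["delta"]["total_cost"]) < 3 * sd_c


def test_end_to_end_seed_determinism(completed_frames, unit_costs):
    a = run_scenario(completed_frames, "main", unit_costs, B=150, seed=20)
    b = run_scenario(completed_frames, "main", unit_costs, B=150, seed=20)
    for kind in a["effects"]:
        np.testing.assert_array_equal(
            a["effects"][kind]["cloud"].delta_costs,
            b["effects"][kind]["cloud"].delta_costs,
        )
        assert a["effects"][kind]["plane"] == b["effects"][kind]["plane"]
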