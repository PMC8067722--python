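"""Calibration: node parameterization, objective, optimizer, CIs, sampling."""

import numpy as np
import pytest

import rtforecast as rt
from rtforecast.calibration import (CalibrationOptions, build_kp_parameterization,
                                    calibrate, confidence_intervals,
                                    evaluation_support, objective_rss,
                                    sample_parameters, scenario_visits,
                                    wald_intervals)
from rtforecast.models import ModelSpec
from rtforecast.solver import Schedule, SolverConfig, simulate

RTM3_C3 = ModelSpec(rtm=3, coupling="C3", kp_mode="global")


class TestKpParameterization:
    def test_single_block_has_five_nodes(self):
        grid = rt.Grid3D(3, 3, 1)
        mask = np.ones(grid.shape, bool)
        kp = build_kp_parameterization(mask, grid)
        assert kp.n_nodes == 5
        # corners + center are nodes; 4 edge midpoints are interpolated
        node_set = {tuple(n) for n in kp.node_indices}
        assert node_set == {(0, 0, 0), (0, 2, 0), (2, 0, 0), (2, 2, 0), (1, 1, 0)}

    def test_constant_nodes_reconstruct_constant_field(self):
        grid = rt.Grid3D(7, 7, 2)
        mask = np.zeros(grid.shape, bool)
        mask[1:6, 1:6, :] = True
        kp = build_kp_parameterization(mask, grid)
        field = kp.expand(np.full(kp.n_nodes, 1.3))
        np.testing.assert_allclose(field, 1.3)

    def test_nearest_node_assignment_matches_brute_force(self, rng):
        grid = rt.Grid3D(8, 8, 2)
        mask = np.zeros(grid.shape, bool)
        mask[1:7, 2:8, :] = True
        kp = build_kp_parameterization(mask, grid)
        values = rng.random(kp.n_nodes)
        field = kp.expand(values)
        spacing = np.asarray(grid.spacing)
        pos = kp.node_indices * spacing
        for vox in np.argwhere(mask):
            d2 = ((vox * spacing - pos) ** 2).sum(axis=1)
            expected = values[np.argmin(d2)]  # nodes sorted by linear index
            assert field[tuple(vox)] == expected

    def test_node_fraction_near_five_ninths(self):
        grid = rt.Grid3D(20, 20, 3)
        mask = np.zeros(grid.shape, bool)
        mask[2:17, 3:18, :] = True
        kp = build_kp_parameterization(mask, grid)
        frac = kp.n_nodes / mask.sum()
        assert 0.4 < frac < 0.7

    def test_empty_mask_raises(self):
        grid = rt.Grid3D(4, 4, 1)
        with pytest.raises(ValueError):
            build_kp_parameterization(np.zeros(grid.shape, bool), grid)


class TestObjective:
    def test_perfect_model_zero_rss(self, animal3_noiseless):
        ds, truth = animal3_noiseless
        rss, n_obs = objective_rss(truth.generating_params, truth.generating_spec,
                                   ds, [0, 1, 2], capacity=ds.capacity,
                                   config=SolverConfig(mechanics=False))
        assert rss == pytest.approx(0.0, abs=1e-16)
        assert n_obs > 0

    def test_matches_hand_looped_double_sum(self, animal3_noisy):
        ds, truth = animal3_noisy
        fitted = [0, 1, 2]
        cfg = SolverConfig(mechanics=False)
        mask = evaluation_support([ds.visits[i] for i in fitted], ds.grid)
        rss, n_obs = objective_rss(truth.generating_params, truth.generating_spec,
                                   ds, fitted, eval_mask=mask,
                                   capacity=ds.capacity, config=cfg)
        # naive re-computation: one forward run, explicit python loops
        sched = Schedule(rt_days=list(ds.rt_events),
                         output_days=[ds.visits[i].day for i in fitted[1:]])
        traj = simulate(ds.grid, ds.visits[0].phi_T, ds.visits[0].phi_V,
                        ds.capacity, truth.generating_params,
                        truth.generating_spec, sched, config=cfg)
        acc, count = 0.0, 0
        for i in fitted[1:]:
            v = ds.visits[i]
            for idx in np.argwhere(mask):
                t = tuple(idx)
                acc += (traj.phi_T[v.day][t] - v.phi_T[t]) ** 2
                acc += (traj.phi_V[v.day][t] - v.phi_V[t]) ** 2
                count += 2
        assert rss == pytest.approx(acc, rel=1e-12)
        assert n_obs == count

    def test_scenario_split_rule(self, animal3_noiseless):
        ds, _ = animal3_noiseless          # 6 visits
        fit1, held1 = scenario_visits(ds, 1)
        assert fit1 == [0, 1, 2, 3, 4, 5] and held1 == []
        fit2, held2 = scenario_visits(ds, 2)
        assert fit2 == [0, 1, 2] and held2 == [3, 4, 5]


class TestCalibrate:
    def _options(self, truth, free, x0=None):
        return CalibrationOptions(
            sa=None, free=free, base=truth.generating_params,
            x0=x0, solver_config=SolverConfig(mechanics=False),
            capacity=None)

    def test_truth_initialized_lm_reaches_zero_rss(self, animal3_noiseless):
        ds, truth = animal3_noiseless
        p = truth.generating_params
        opts = self._options(truth, free=["kp_T0", "SF"],
                             x0={"kp_T0": p.kp_T0, "SF": p.SF})
        opts.capacity = ds.capacity   # truth capacity: exact inverse problem
        res = calibrate(ds, RTM3_C3, seed=0, scenario=2, options=opts)
        assert res.RSS <= 1e-8

    def test_deterministic_given_seed(self, animal3_noisy):
        ds, truth = animal3_noisy
        opts = self._options(truth, free=["kp_T0"], x0={"kp_T0": 1.0})
        opts.sa = {"T0": 1.0, "ratio": 0.5, "iters_per_temp": 4,
                   "T_min": 0.4, "step_frac": 0.2}
        opts.solver_config = SolverConfig(dt=0.05, mechanics=False)
        opts.capacity = ds.capacity
        a = calibrate(ds, RTM3_C3, seed=11, scenario=2, options=opts)
        b = calibrate(ds, RTM3_C3, seed=11, scenario=2, options=opts)
        np.testing.assert_array_equal(a.x_hat, b.x_hat)
        assert a.RSS == b.RSS

    def test_single_parameter_recovery(self, animal3_noiseless):
        ds, truth = animal3_noiseless
        opts = self._options(truth, free=["kp_T0"], x0={"kp_T0": 0.6})
        opts.capacity = ds.capacity
        res = calibrate(ds, RTM3_C3, seed=0, scenario=2, options=opts)
        assert abs(res.x_hat[0] - truth.generating_params.kp_T0) / \
            truth.generating_params.kp_T0 < 0.05


class TestConfidenceIntervals:
    def test_zero_residual_gives_zero_width(self, animal3_noiseless):
        ds, truth = animal3_noiseless
        p = truth.generating_params
        opts = CalibrationOptions(sa=None, free=["kp_T0", "SF"],
                                  base=p, x0={"kp_T0": p.kp_T0, "SF": p.SF},
                                  solver_config=SolverConfig(mechanics=False),
                                  capacity=ds.capacity)
        res = calibrate(ds, RTM3_C3, seed=0, scenario=2, options=opts)
        widths = res.ci95[:, 1] - res.ci95[:, 0]
        assert np.all(widths < 1e-3)
        # symmetric about the estimate
        np.testing.assert_allclose(res.ci95.mean(axis=1), res.x_hat, atol=1e-12)
        np.testing.assert_allclose(confidence_intervals(res), res.ci95)

    def test_wald_matches_bootstrap_on_toy_exponential(self, rng):
        # 1-parameter regression y = exp(-theta x) + eps
        theta_true, sigma = 0.7, 0.02
        x = np.linspace(0.1, 4.0, 40)
        y = np.exp(-theta_true * x) + rng.normal(0, sigma, x.size)

        def fit(yy):
            from scipy.optimize import least_squares
            sol = least_squares(lambda th: np.exp(-th[0] * x) - yy,
                                x0=[0.5], method="lm")
            return sol

        sol = fit(y)
        theta_hat = sol.x[0]
        rss = float(2 * sol.cost)
        ci = wald_intervals(sol.jac, rss, x.size, sol.x)
        width = ci[0, 1] - ci[0, 0]
        boot = []
        resid = np.exp(-theta_hat * x) - y
        for _ in range(2000):
            yb = np.exp(-theta_hat * x) - rng.choice(resid, size=x.size, replace=True)
            boot.append(fit(yb).x[0])
        lo, hi = np.percentile(boot, [2.5, 97.5])
        assert abs(width - (hi - lo)) / (hi - lo) < 0.10
        assert ci[0, 0] < theta_true < ci[0, 1]

    def test_rank_deficient_direction_flagged_unbounded(self):
        # second column of J is identically zero -> no information
        jac = np.zeros((10, 2))
        jac[:, 0] = np.linspace(1, 2, 10)
        ci = wald_intervals(jac, rss=0.5, n_obs=10, theta=np.array([1.0, 2.0]))
        assert np.isfinite(ci[0]).all()
        assert np.isinf(ci[1]).all()


@pytest.fixture(scope="module")
def sampled_result(animal3_noiseless):
    ds, truth = animal3_noiseless
    p = truth.generating_params
    opts = CalibrationOptions(sa=None, free=["kp_T0", "SF"], base=p,
                              x0={"kp_T0": 1.2, "SF": 0.95},
                              solver_config=SolverConfig(dt=0.05, mechanics=False),
                              capacity=ds.capacity)
    return calibrate(ds, RTM3_C3, seed=0, scenario=2, options=opts)


class TestSampleParameters:
    def _result(self, sampled_result):
        return sampled_result

    def test_count_and_determinism(self, sampled_result):
        res = sampled_result
        sets_a = sample_parameters(res, count=100, seed=5)
        sets_b = sample_parameters(res, count=100, seed=5)
        assert len(sets_a) == 100
        for a, b in zip(sets_a, sets_b):
            assert a.SF == b.SF and np.all(a.kp_T0 == b.kp_T0)

    def test_samples_respect_ci_box_and_bounds(self, sampled_result):
        res = sampled_result
        lo = np.maximum(res.ci95[:, 0], res.bounds_lo)
        hi = np.minimum(res.ci95[:, 1], res.bounds_hi)
        for s in sample_parameters(res, count=50, seed=2):
            x = np.array([float(np.ravel(s.kp_T0)[0]), s.SF])
            assert np.all(x >= lo - 1e-12) and np.all(x <= hi + 1e-12)

    def test_degenerate_interval_returns_estimate(self, sampled_result):
        import copy
        res = copy.copy(sampled_result)
        res.ci95 = np.column_stack([res.x_hat, res.x_hat])
        for s in sample_parameters(res, count=5, seed=0):
            np.testing.assert_allclose(
                [float(np.ravel(s.kp_T0)[0]), s.SF], res.x_hat)
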