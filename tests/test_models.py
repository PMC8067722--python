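"""Model family enumeration, RT response operators, and PDE right-hand sides."""

import numpy as np
import pytest

import rtforecast as rt
from rtforecast.grids import CapacityState
from rtforecast.models import (ModelSpec, apply_rt_instantaneous, coupling_field,
                               effective_death, effective_proliferation,
                               enumerate_models, rhs_tumor, rhs_vasculature)


class TestEnumeration:
    def test_family_size_and_uniqueness(self):
        family = enumerate_models()
        assert len(family) == 18
        assert len({m.token for m in family}) == 18

    def test_local_block_first_and_death_models_7_to_9(self):
        family = enumerate_models()
        assert all(m.kp_mode == "local" for m in family[:9])
        assert all(m.kp_mode == "global" for m in family[9:])
        # models 7-9 (1-based) are the delayed-death members
        assert all(family[i].rtm == 3 for i in (6, 7, 8))
        assert family[7].rtm == 3  # index 7 of the local block

    def test_token_round_trip(self):
        for m in enumerate_models():
            assert ModelSpec.from_token(m.token) == m


class TestCouplingFields:
    shape = (2, 2, 1)

    def test_c1_packing_density(self):
        spec = ModelSpec(rtm=1, coupling="C1", kp_mode="global")
        C = coupling_field(spec, np.full(self.shape, 0.45), np.full(self.shape, 0.9),
                           np.zeros(self.shape), 0.3, 1.0)
        np.testing.assert_allclose(C, 0.5)

    def test_c2_vascularity(self):
        spec = ModelSpec(rtm=1, coupling="C2", kp_mode="global")
        C0 = coupling_field(spec, np.zeros(self.shape), np.full(self.shape, 0.9),
                            np.zeros(self.shape), 0.3, 4.0)
        np.testing.assert_allclose(C0, 1.0)
        # phi_V = theta_V with alpha1 = 4.00 (a reported estimate) -> e^-4
        C1 = coupling_field(spec, np.zeros(self.shape), np.full(self.shape, 0.9),
                            np.full(self.shape, 0.3), 0.3, 4.0)
        np.testing.assert_allclose(C1, np.exp(-4.0), rtol=1e-12)

    def test_c3_is_unity(self):
        spec = ModelSpec(rtm=1, coupling="C3", kp_mode="global")
        C = coupling_field(spec, np.zeros(self.shape), np.full(self.shape, 0.9),
                           np.zeros(self.shape), 0.3, 1.0)
        np.testing.assert_allclose(C, 1.0)

    def test_zero_capacity_raises(self):
        spec = ModelSpec(rtm=1, coupling="C1", kp_mode="global")
        with pytest.raises(ValueError):
            coupling_field(spec, np.full(self.shape, 0.4), np.zeros(self.shape),
                           np.zeros(self.shape), 0.3, 1.0)


class TestRTOperators:
    def test_instantaneous_kill(self):
        out = apply_rt_instantaneous(np.array(0.4), np.array(1.0), 0.8)
        np.testing.assert_allclose(out, 0.32)
        unchanged = apply_rt_instantaneous(np.array(0.4), np.array(1.0), 1.0)
        np.testing.assert_allclose(unchanged, 0.4)

    def test_kill_composed_with_c1(self):
        C = np.array(0.45 / 0.9)
        out = apply_rt_instantaneous(np.array(0.45), C, 0.8)
        np.testing.assert_allclose(out, 0.18)

    def test_effective_proliferation(self):
        kp = effective_proliferation(1.0, np.array(1.0), 0.9, 2)
        np.testing.assert_allclose(kp, 0.81)
        np.testing.assert_allclose(effective_proliferation(1.0, np.array(1.0), 1.0, 5), 1.0)

    def test_effective_proliferation_nonincreasing_in_n(self):
        vals = [effective_proliferation(1.3, np.array(0.7), 0.92, n) for n in range(1, 11)]
        assert all(b <= a for a, b in zip(vals, vals[1:]))
        assert all(0 <= v <= 1.3 for v in vals)

    def test_effective_death(self):
        np.testing.assert_allclose(effective_death(0.5, np.array(1.0), 1.0, 3), 0.0)
        # kd0 = 0.5 (a reported estimate), one fraction at SF = 0.9
        np.testing.assert_allclose(effective_death(0.5, np.array(1.0), 0.9, 1), 0.05)
        big_n = effective_death(0.5, np.array(1.0), 0.9, 500)
        np.testing.assert_allclose(big_n, 0.5, rtol=1e-10)

    def test_effective_rates_require_delivered_fraction(self):
        with pytest.raises(ValueError):
            effective_proliferation(1.0, np.array(1.0), 0.9, 0)
        with pytest.raises(ValueError):
            effective_death(0.5, np.array(1.0), 0.9, 0)


def _capacity(shape, theta=0.9, theta_V=0.3):
    return CapacityState(theta_T=np.full(shape, theta), theta_min=0.1,
                         theta_max=theta, theta_V=theta_V, phi_V_thresh=0.05)


def loop_rhs_tumor(phi_T, phi_V, cap, D, kp, kd, mask, spacing):
    """Independent per-voxel stencil oracle for the tumor right-hand side."""
    shape = phi_T.shape
    theta_TV = cap.theta_TV
    a = phi_T / theta_TV
    b = phi_V / theta_TV
    cA = 1.0 - phi_V / theta_TV
    cB = phi_T / theta_TV
    out = np.zeros(shape)
    offs = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if not mask[i, j, k]:
                    continue
                acc = 0.0
                for ax, off in enumerate(offs):
                    h = spacing[ax]
                    for sgn in (+1, -1):
                        ni, nj, nk = i + sgn * off[0], j + sgn * off[1], k + sgn * off[2]
                        if not (0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]):
                            continue
                        if not mask[ni, nj, nk]:
                            continue
                        Dv, Dn = D[i, j, k], D[ni, nj, nk]
                        Df = 2 * Dv * Dn / (Dv + Dn) if Dv + Dn > 0 else 0.0
                        cAf = 0.5 * (cA[i, j, k] + cA[ni, nj, nk])
                        cBf = 0.5 * (cB[i, j, k] + cB[ni, nj, nk])
                        flux = Df * (cAf * (a[ni, nj, nk] - a[i, j, k])
                                     + cBf * (b[ni, nj, nk] - b[i, j, k])) / h
                        acc += flux / h
                out[i, j, k] = acc + kp[i, j, k] * phi_T[i, j, k] * \
                    (1 - phi_T[i, j, k] / cap.theta_T[i, j, k]) - kd * phi_T[i, j, k]
    return out


class TestRightHandSides:
    def test_uniform_at_capacity_is_stationary(self):
        shape = (4, 4, 2)
        cap = _capacity(shape)
        phi_T = np.full(shape, 0.9)
        phi_V = np.full(shape, 0.1)
        f = rhs_tumor(phi_T, phi_V, cap, np.full(shape, 0.05), np.full(shape, 1.0),
                      0.0, np.ones(shape, bool), (0.25, 0.25, 1.0))
        np.testing.assert_allclose(f, 0.0, atol=1e-14)

    def test_uniform_below_capacity_is_pure_logistic(self):
        shape = (4, 4, 2)
        cap = _capacity(shape)
        phi_T = np.full(shape, 0.4)
        phi_V = np.full(shape, 0.1)
        f = rhs_tumor(phi_T, phi_V, cap, np.full(shape, 0.05), np.full(shape, 1.2),
                      0.0, np.ones(shape, bool), (0.25, 0.25, 1.0))
        np.testing.assert_allclose(f, 1.2 * 0.4 * (1 - 0.4 / 0.9), rtol=1e-12)

    def test_random_fields_match_loop_oracle(self, rng):
        shape = (5, 5, 3)
        spacing = (0.25, 0.25, 1.0)
        mask = np.ones(shape, bool)
        mask[0, 0, 0] = False  # irregular domain corner
        cap = _capacity(shape)
        phi_T = 0.2 + 0.5 * rng.random(shape)
        phi_V = 0.02 + 0.1 * rng.random(shape)
        D = 0.01 + 0.05 * rng.random(shape)
        kp = 0.5 + rng.random(shape)
        kd = 0.15
        f = rhs_tumor(phi_T, phi_V, cap, D, kp, kd, mask, spacing)
        oracle = loop_rhs_tumor(phi_T, phi_V, cap, D, kp, kd, mask, spacing)
        np.testing.assert_allclose(f, oracle, atol=1e-10)

    def test_vasculature_periphery_and_core_weighting(self):
        shape = (3, 3, 1)
        cap = _capacity(shape)
        phi_V = np.full(shape, 0.3)   # at theta_V: growth term vanishes
        phi_T = np.full(shape, 0.4)
        mask = np.ones(shape, bool)
        d_periphery = np.ones(shape)
        f = rhs_vasculature(phi_V, phi_T, cap, np.full(shape, 0.02), 0.8, 0.3,
                            d_periphery, mask, (0.25, 0.25, 1.0))
        np.testing.assert_allclose(f, 0.0, atol=1e-14)  # (1-d)=0 kills death
        d_core = np.zeros(shape)
        f = rhs_vasculature(phi_V, phi_T, cap, np.full(shape, 0.02), 0.8, 0.3,
                            d_core, mask, (0.25, 0.25, 1.0))
        np.testing.assert_allclose(f, -0.3 * 0.3, rtol=1e-12)

    def test_vasculature_matches_term_by_term_oracle(self, rng):
        shape = (5, 5, 3)
        spacing = (0.25, 0.25, 1.0)
        mask = np.ones(shape, bool)
        cap = _capacity(shape)
        phi_T = 0.2 + 0.5 * rng.random(shape)
        phi_V = 0.02 + 0.2 * rng.random(shape)
        D = 0.01 + 0.05 * rng.random(shape)
        d = rng.random(shape)
        kp_V, kd_V = 0.8, 0.3
        f = rhs_vasculature(phi_V, phi_T, cap, D, kp_V, kd_V, d, mask, spacing)
        # oracle: reuse the tumor-side loop stencil with the species swapped,
        # then add the distance-weighted reaction terms by hand
        diff_only = loop_rhs_tumor(phi_V, phi_T, cap, D, np.zeros(shape), 0.0,
                                   mask, spacing)
        reaction = kp_V * phi_V * (1 - phi_V / cap.theta_V) * d - kd_V * phi_V * (1 - d)
        np.testing.assert_allclose(f, diff_only + reaction, atol=1e-10)

    def test_cross_diffusion_is_conservative(self, rng):
        shape = (6, 6, 3)
        spacing = (0.25, 0.25, 1.0)
        mask = rng.random(shape) < 0.8
        mask[3, 3, 1] = True
        cap = _capacity(shape)
        phi_T = 0.2 + 0.6 * rng.random(shape)
        phi_V = 0.02 + 0.2 * rng.random(shape)
        D = 0.01 + 0.05 * rng.random(shape)
        f = rhs_tumor(phi_T, phi_V, cap, D, np.zeros(shape), 0.0, mask, spacing)
        total = np.abs(f[mask].sum())
        scale = np.abs(f[mask]).sum()
        assert total <= 1e-10 * max(scale, 1.0)

    def test_non_finite_input_raises(self):
        shape = (3, 3, 1)
        cap = _capacity(shape)
        bad = np.full(shape, np.nan)
        with pytest.raises(ValueError):
            rhs_tumor(bad, np.zeros(shape), cap, np.full(shape, 0.01),
                      np.zeros(shape), 0.0, np.ones(shape, bool), (0.25, 0.25, 1.0))
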