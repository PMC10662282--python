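"""Kinetic building blocks and the assembled ODE right-hand side."""

import numpy as np
import pytest

import codeal as cd
from codeal.kinetics import STATE_SIZE, compute_fluxes, rhs


def _uniform_forcing(t1=100.0, B=100.0, I1=0.0, I2=0.0, L=0.0, fplant=0.0):
    t = np.array([0.0, t1])
    ones = np.ones(2)
    return cd.Forcing(time=t, B=B * ones, I_NH4=I1 * ones, I_NO3=I2 * ones,
                      L=L * ones, fplant=fplant * ones)


def _quiet_params(**overrides):
    base = dict(
        Vmax=np.array([2.0, 1.5, 2.5, 4.0, 3.0, 0.3]),
        Ks=np.array([0.5, 8.0, 0.5, 0.3, 0.5, 50.0]),
        pEP=0.0, rE=0.0, kmin=0.0,
        Vup_NH4=0.0, Vup_NO3=0.0, Kup_NH4=1.0, Kup_NO3=2.0,
        gNO=0.0, gN2O=0.0, n2_boundary="dynamic", bnf_inhibition=True,
    )
    base.update(overrides)
    # zero rates are legal in the dataclass only where the field allows it
    if base["Vup_NH4"] == 0.0:
        base["Vup_NH4"] = 0.0
    return cd.KineticParams(**base)


class TestTransformationFlux:
    @pytest.mark.parametrize(
        "E, Vmax, N, Ks, expected",
        [(0.0, 1.0, 5.0, 1.0, 0.0),       # no enzyme, no flux
         (1.0, 2.0, 1.0, 1.0, 1.0),       # half saturation
         (1.0, 2.0, 1e9, 1.0, 2.0)],      # saturation asymptote
    )
    def test_known_values(self, E, Vmax, N, Ks, expected):
        assert cd.transformation_flux(E, Vmax, N, Ks) == pytest.approx(expected, rel=1e-6)

    def test_bounded_by_capacity(self, rng):
        for _ in range(100):
            E, N = rng.uniform(0, 10, 2)
            Vmax, Ks = rng.uniform(0.1, 10, 2)
            assert 0 <= cd.transformation_flux(E, Vmax, N, Ks) <= Vmax * E

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            cd.transformation_flux(-1.0, 1.0, 1.0, 1.0)


class TestBnfInhibition:
    @pytest.mark.parametrize(
        "NH4, Ks, expected", [(0.0, 1.0, 1.0), (1.0, 1.0, 0.5), (9.0, 1.0, 0.1)])
    def test_known_values(self, NH4, Ks, expected):
        assert cd.bnf_inhibition_factor(NH4, Ks) == pytest.approx(expected, abs=1e-12)

    def test_strictly_decreasing(self):
        vals = [cd.bnf_inhibition_factor(x, 2.0) for x in np.linspace(0, 100, 50)]
        assert np.all(np.diff(vals) < 0)

    def test_inhibition_never_increases_fixation(self, short_testbed):
        _, params, _, _ = short_testbed
        from dataclasses import replace
        N = np.array([3.0, 5.0, 0.3, 0.1, 0.2, 150.0])
        E = np.full(6, 1.0)
        on_ = compute_fluxes(N, E, 10.0, 0.5, params).F_fix
        off = compute_fluxes(N, E, 10.0, 0.5,
                             replace(params, bnf_inhibition=False)).F_fix
        assert on_ <= off
        # with inhibition off, fixation is the plain Michaelis-Menten form
        assert off == pytest.approx(
            cd.transformation_flux(E[5], params.Vmax[5], N[5], params.Ks[5]), rel=1e-12)


class TestEnzymeDerivatives:
    def test_uniform_production(self):
        d = cd.enzyme_derivatives(np.zeros(6), np.full(6, 1 / 6), 100.0, 0.01, 0.0)
        np.testing.assert_allclose(d, np.full(6, 1 / 6), rtol=1e-12)

    def test_pure_decay(self):
        d = cd.enzyme_derivatives(np.full(6, 2.0), np.full(6, 1 / 6), 0.0, 0.01, 0.1)
        np.testing.assert_allclose(d, np.full(6, -0.2), rtol=1e-12)

    def test_production_budget_identity(self, rng):
        # sum_i (dE_i/dt + rE*E_i) == pEP*B for any allocation
        for _ in range(50):
            w = rng.uniform(0, 1, 6)
            f = w / w.sum()
            E = rng.uniform(0, 5, 6)
            B, pEP, rE = rng.uniform(0.1, 100), rng.uniform(0, 0.1), rng.uniform(0, 1)
            d = cd.enzyme_derivatives(E, f, B, pEP, rE)
            assert (d + rE * E).sum() == pytest.approx(pEP * B, rel=1e-9)


class TestRhs:
    def test_dead_system_is_fixed_point(self):
        params = _quiet_params()
        forcing = _uniform_forcing()
        y0 = cd.ModelState(N=[1, 2, 0.1, 0.05, 0.02, 100.0],
                           E=np.zeros(6), ON=50.0).as_array()
        dy = rhs(10.0, y0, params, forcing, "A1")
        np.testing.assert_allclose(dy, np.zeros(STATE_SIZE), atol=1e-15)

    def test_closed_system_conserves_total_n(self, rng):
        # dynamic N2, no inputs/outputs: sum of N-pool derivatives is 0 exactly
        params = _quiet_params(pEP=2e-3, rE=0.02, kmin=1e-3)
        forcing = _uniform_forcing(B=100.0)
        for _ in range(20):
            y = np.concatenate([
                rng.uniform(0.01, 10, 6), rng.uniform(0, 2, 6),
                [rng.uniform(1, 100)], [0.0], [0.0]])
            dy = rhs(5.0, y, params, forcing, "A1")
            assert dy[:6].sum() + dy[12] == pytest.approx(0.0, abs=1e-12)

    def test_flux_bookkeeping_matches_hand_assembly(self):
        """Derivatives equal the hand-assembled balances from the flux vector."""
        params = _quiet_params(pEP=1e-3, rE=0.05, kmin=2e-3, Vup_NH4=0.3,
                               Vup_NO3=0.2, gNO=0.1, gN2O=0.05,
                               n2_boundary=150.0)
        forcing = _uniform_forcing(B=80.0, I1=0.02, I2=0.03, L=0.1, fplant=0.6)
        state = cd.ModelState(N=[2.0, 5.0, 0.3, 0.1, 0.2, 150.0],
                              E=np.array([0.5, 0.4, 0.3, 0.2, 0.1, 0.6]),
                              ON=80.0)
        y = state.as_array()
        t = 7.0
        fx = compute_fluxes(state.N, state.E, state.ON, 0.6, params)
        f = cd.compute_allocation("A1", state.N, params.Ks).values
        expected = np.array([
            fx.F_min + fx.F_fix - fx.F_nit - fx.U_NH4 + 0.02,
            fx.F_nit - fx.F_nar - fx.U_NO3 + 0.03,
            fx.F_nar - fx.F_nir,
            fx.F_nir - fx.F_nor - fx.G_NO,
            fx.F_nor - fx.F_nos - fx.G_N2O,
            0.0,
        ])
        dy = rhs(t, y, params, forcing, "A1")
        np.testing.assert_allclose(dy[:6], expected, rtol=1e-12)
        np.testing.assert_allclose(
            dy[6:12], f * params.pEP * 80.0 - params.rE * state.E, rtol=1e-12)
        assert dy[12] == pytest.approx(0.1 - fx.F_min, rel=1e-12)
        assert dy[13] == pytest.approx(0.02 + 0.03 + 0.1 + fx.F_fix, rel=1e-12)
        assert dy[14] == pytest.approx(
            fx.U_NH4 + fx.U_NO3 + fx.G_NO + fx.G_N2O + fx.F_nos, rel=1e-12)

    def test_all_fluxes_nonnegative(self, rng, short_testbed):
        _, params, _, _ = short_testbed
        for _ in range(100):
            N = rng.uniform(0, 20, 6)
            E = rng.uniform(0, 5, 6)
            fx = compute_fluxes(N, E, rng.uniform(0, 100), rng.uniform(0, 1), params)
            assert np.all(fx.as_array() >= 0)
            # flux bound by enzymatic capacity
            caps = params.Vmax * E
            assert np.all(np.array([fx.F_nit, fx.F_nar, fx.F_nir, fx.F_nor,
                                    fx.F_nos, fx.F_fix]) <= caps[[0, 1, 2, 3, 4, 5]] + 1e-12)

    def test_forcing_outside_span_rejected(self):
        params = _quiet_params()
        forcing = _uniform_forcing(t1=10.0)
        y = cd.ModelState(N=np.ones(6), E=np.zeros(6), ON=1.0).as_array()
        with pytest.raises(ValueError):
            rhs(50.0, y, params, forcing, "A1")

    def test_nan_state_rejected(self):
        params = _quiet_params()
        forcing = _uniform_forcing()
        y = np.full(STATE_SIZE, np.nan)
        with pytest.raises(FloatingPointError):
            rhs(1.0, y, params, forcing, "A1")
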