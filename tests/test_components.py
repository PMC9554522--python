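"""Constitutive relations: potentials, fluxes, powers and their identities."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bondflow import (
    FlowProfile,
    ReactionEdge,
    SpeciesState,
    advective_flux,
    advective_power,
    chemical_potential,
    mass_action_flux,
    pressure_drop,
    unified_flux,
)
from bondflow.components import CONC_FLOOR

conc = st.floats(min_value=1e-6, max_value=1e3)
flow = st.floats(min_value=-1e3, max_value=1e3)
positive = st.floats(min_value=1e-3, max_value=1e3)


class TestChemicalPotential:
    @pytest.mark.parametrize(
        "x, V, K, RT, expected",
        [
            (1.0, 1.0, 1.0, 1.0, 0.0),  # ln 1
            (0.5, 1.0, 2.0, 1.0, 0.0),  # K c = 1
            (math.e, 1.0, 1.0, 1.0, 1.0),  # ln e
            (math.e, 2.0, 2.0, 1.0, 1.0),  # K x / V = e
            (1.0, 1.0, 1.0, 2.5, 0.0),  # RT scales a zero log
        ],
    )
    def test_values(self, x, V, K, RT, expected):
        assert chemical_potential(x, V, K, RT) == pytest.approx(expected, abs=1e-14)

    def test_zero_amount_gives_documented_sentinel(self):
        mu = chemical_potential(0.0, 1.0, 1.0, 1.0)
        assert mu == pytest.approx(math.log(CONC_FLOOR))
        assert np.isfinite(mu)

    @pytest.mark.parametrize("bad", [dict(V=0.0), dict(V=-1.0), dict(K=0.0), dict(RT=0.0), dict(x=-0.1)])
    def test_invalid_parameters_raise(self, bad):
        kwargs = dict(x=1.0, V=1.0, K=1.0, RT=1.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            chemical_potential(**kwargs)


class TestAdvectiveFlux:
    @pytest.mark.parametrize(
        "Q, c_up, c_down, expected",
        [
            (0.0, 3.0, 1.0, 0.0),  # zero flow annihilates the flux exactly
            (2.0, 1.5, 9.0, 3.0),  # forward flow carries the upstream concentration
            (-2.0, 9.0, 1.5, -3.0),  # reverse flow carries the downstream one
        ],
    )
    def test_upwind_switch(self, Q, c_up, c_down, expected):
        assert advective_flux(Q, c_up, c_down) == expected

    @given(Q=flow, a=conc, b=conc)
    def test_upwind_antisymmetry(self, Q, a, b):
        assert advective_flux(Q, a, b) == -advective_flux(-Q, b, a)

    @given(a=conc, b=conc)
    def test_zero_flow_is_exactly_zero(self, a, b):
        assert advective_flux(0.0, a, b) == 0.0

    def test_smoothing_blends_branches(self):
        # far from the switch the smoothed flux matches the exact one
        assert advective_flux(5.0, 2.0, 7.0, smoothing=0.01) == pytest.approx(10.0)
        # at Q = 0 the blend is symmetric and the flux still vanishes
        assert advective_flux(0.0, 2.0, 7.0, smoothing=0.5) == 0.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            advective_flux(1.0, -1.0, 0.0)


class TestMassActionFlux:
    def unimolecular(self, kappa):
        return ReactionEdge("r", kappa, [("S", 1.0)], [("P", 1.0)])

    def test_equilibrium_gives_zero(self):
        r = self.unimolecular(1.0)
        assert mass_action_flux(r, {"S": 0.7, "P": 0.7}) == 0.0

    def test_unimolecular_net_flux(self):
        r = self.unimolecular(2.0)
        assert mass_action_flux(r, {"S": 2.0, "P": 0.5}) == pytest.approx(3.0)

    def test_bimolecular_binding(self):
        r = ReactionEdge("bind", 1.0, [("A", 1.0), ("E", 1.0)], [("C", 1.0)])
        v = mass_action_flux(r, {"A": 2.0, "E": 1.0, "C": 1.0})
        assert v == pytest.approx(1.0)

    @given(
        kappa=positive,
        Ks=positive,
        Kp=positive,
        cs=conc,
    )
    def test_detailed_balance(self, kappa, Ks, Kp, cs):
        """Flux is zero iff the substrate and product activities agree."""
        r = self.unimolecular(kappa)
        consts = {"S": Ks, "P": Kp}
        cp_eq = Ks * cs / Kp  # activity-matched product concentration
        assert mass_action_flux(r, {"S": cs, "P": cp_eq}, consts) == pytest.approx(
            0.0, abs=1e-12 * (1.0 + Ks * cs)
        )
        v = mass_action_flux(r, {"S": cs, "P": 2.0 * cp_eq + 1e-3}, consts)
        assert v < 0.0

    def test_stoichiometric_exponents(self):
        r = ReactionEdge("dimer", 1.0, [("S", 2.0)], [("P", 1.0)])
        assert mass_action_flux(r, {"S": 3.0, "P": 1.0}) == pytest.approx(8.0)


class TestUnifiedFlux:
    @pytest.mark.parametrize(
        "lam, kappa0, Q, K, c1, c2, expected",
        [
            (0.0, 123.0, 2.0, 1.0, 1.5, 7.0, 3.0),  # advection limit: Q c1
            (1.0, 1.0, 99.0, 1.0, 2.0, 0.5, 1.5),  # transformation limit
            (0.5, 1.0, 2.0, 1.0, 2.0, 1.0, 2.25),  # kappa = 1.5, v = 1.5 (2 - 0.5)
        ],
    )
    def test_values(self, lam, kappa0, Q, K, c1, c2, expected):
        assert unified_flux(lam, kappa0, Q, K, c1, c2) == pytest.approx(expected)

    @given(kappa0=positive, Q=positive, K=positive, c1=conc, c2=conc)
    def test_advection_limit_machine_precision(self, kappa0, Q, K, c1, c2):
        v = unified_flux(0.0, kappa0, Q, K, c1, c2)
        assert math.isclose(v, Q * c1, rel_tol=1e-13)

    @given(kappa0=positive, Q=positive, K=positive, c1=conc, c2=conc)
    def test_transformation_limit_machine_precision(self, kappa0, Q, K, c1, c2):
        v = unified_flux(1.0, kappa0, Q, K, c1, c2)
        r = ReactionEdge("r", kappa0, [("S", 1.0)], [("P", 1.0)])
        w = mass_action_flux(r, {"S": c1, "P": c2}, {"S": K, "P": K})
        assert abs(v - w) <= 1e-12 * (1.0 + kappa0 * K * (c1 + c2))

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            unified_flux(1.5, 1.0, 1.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            unified_flux(0.5, 1.0, 1.0, 0.0, 1.0, 1.0)


class TestPowerAndPressure:
    @pytest.mark.parametrize(
        "f, mu_up, mu_down, expected",
        [(0.0, 5.0, 1.0, 0.0), (3.0, 2.0, 2.0, 0.0), (3.0, 1.0, 1.5, -1.5)],
    )
    def test_advective_power(self, f, mu_up, mu_down, expected):
        # dissipation may be negative: transport is driven by the fluid
        assert advective_power(f, mu_up, mu_down) == pytest.approx(expected)

    @pytest.mark.parametrize("c, dmu, expected", [(2.0, 1.5, 3.0), (7.0, 0.0, 0.0)])
    def test_pressure_drop(self, c, dmu, expected):
        assert pressure_drop(c, dmu) == pytest.approx(expected)

    @given(Q=positive, c=conc, mu1=st.floats(-5, 5), mu2=st.floats(-5, 5))
    def test_transduction_power_identity(self, Q, c, mu1, mu2):
        """Q * dP equals f * dmu whenever f = Q c (lossless transduction)."""
        f = Q * c
        lhs = Q * pressure_drop(c, mu1 - mu2)
        rhs = advective_power(f, mu1, mu2)
        assert math.isclose(lhs, rhs, rel_tol=1e-12, abs_tol=1e-12)


class TestFlowProfile:
    def test_constant_step_sinusoid(self):
        assert FlowProfile.constant(2.0)(17.3) == 2.0
        step = FlowProfile.step(2.0, 10.0, 10.0)
        assert step(9.99) == 2.0 and step(10.0) == 10.0
        sine = FlowProfile.sinusoid(1.0, 0.5, 5.0)
        assert sine(0.0) == pytest.approx(1.0)
        assert sine(1.25) == pytest.approx(1.5)  # quarter period peak
        assert sine(5.0) == pytest.approx(1.0)

    def test_piecewise_zero_order_hold(self):
        pw = FlowProfile.piecewise([0.0, 1.0, 3.0], [5.0, 6.0, 7.0])
        assert pw(0.5) == 5.0 and pw(2.0) == 6.0 and pw(10.0) == 7.0

    def test_vector_evaluation(self):
        t = np.linspace(0.0, 10.0, 11)
        q = FlowProfile.sinusoid(1.0, 0.5, 5.0)(t)
        assert q.shape == t.shape

    def test_is_constant(self):
        assert FlowProfile.constant(1.0).is_constant
        assert not FlowProfile.step(1.0, 2.0, 5.0).is_constant
        assert FlowProfile.sinusoid(1.0, 0.0, 5.0).is_constant


class TestSpeciesState:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SpeciesState("s", V=0.0)
        with pytest.raises(ValueError):
            SpeciesState("s", K=-1.0)
        with pytest.raises(ValueError):
            SpeciesState("s", x0=-0.5)

    def test_chemostat_held_amount_follows_profile(self):
        s = SpeciesState("s", x0=3.0, chemostat=True, profile=FlowProfile.step(3.0, 0.0, 2.0))
        assert s.held_amount(1.0) == 3.0
        assert s.held_amount(2.5) == 0.0
        assert SpeciesState("t", x0=1.2, chemostat=True).held_amount(9.0) == 1.2
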