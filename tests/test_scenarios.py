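"""Coupled advection/transformation models: orifice system and circulation."""

from dataclasses import replace

import numpy as np
import pytest

from bondflow import (
    CirculationScenario,
    FlowProfile,
    ModelValidationError,
    OrificeScenario,
    build_circulation_model,
    build_orifice_model,
    build_rhs,
    compare_connections,
    simulate,
    steady_state,
    steady_state_large_flow,
)


class TestOrificeModel:
    def test_central_reactive_flux_vanishes_at_equal_concentrations(self):
        model = build_orifice_model(
            OrificeScenario(lam=1.0, flow=FlowProfile.constant(4.0))
        )
        rhs, compiled = build_rhs(model)
        fluxes = compiled.edge_fluxes(0.0, np.array([1.3, 1.3]))
        names = [e.name for e in compiled.edges]
        assert fluxes[names.index("r")] == pytest.approx(0.0, abs=1e-14)

    def test_central_advective_flux_is_q_c1(self):
        model = build_orifice_model(
            OrificeScenario(lam=0.0, flow=FlowProfile.constant(4.0))
        )
        rhs, compiled = build_rhs(model)
        names = [e.name for e in compiled.edges]
        for x1 in (0.3, 1.0, 2.5):
            fluxes = compiled.edge_fluxes(0.0, np.array([x1, 0.7]))
            assert fluxes[names.index("r")] == pytest.approx(4.0 * x1)

    @pytest.mark.parametrize("lam", [0.0, 0.5, 1.0])
    def test_assembled_derivatives_match_hand_coded_equations(self, lam):
        """x1' = v1 - v, x2' = v - v2 with the unified central flux."""
        Q, k0 = 3.0, 1.0
        scn = OrificeScenario(lam=lam, kappa0=k0, flow=FlowProfile.constant(Q))
        rhs, _ = build_rhs(build_orifice_model(scn))
        rng = np.random.default_rng(1)
        for _ in range(5):
            x1, x2 = rng.uniform(0.05, 3.0, size=2)
            v1 = 2.0 - x1
            v2 = x2 - 1.0
            kap = lam * k0 + (1.0 - lam) * Q
            v = kap * (x1 - lam * x2)
            assert rhs(0.0, np.array([x1, x2])) == pytest.approx([v1 - v, v - v2])

    @pytest.mark.parametrize("lam", [0.0, 1.0])
    def test_steady_state_sum_rule(self, lam):
        """With equal boundary rate constants, c1 + c2 = (K_A cA + K_B cB)/K_C."""
        scn = OrificeScenario(lam=lam, flow=FlowProfile.constant(7.0))
        ss = steady_state(build_orifice_model(scn))
        assert ss["C1"] + ss["C2"] == pytest.approx(3.0, abs=1e-6)

    @pytest.mark.parametrize("lam", [0.0, 1.0])
    def test_large_flow_asymptotics_convergence(self, lam):
        """Simulated steady states approach the closed form as Q grows."""
        c1_inf, c2_inf = steady_state_large_flow(lam)
        errs = []
        for Q in (10.0, 100.0, 1000.0):
            scn = OrificeScenario(lam=lam, flow=FlowProfile.constant(Q))
            ss = steady_state(build_orifice_model(scn))
            errs.append(abs(ss["C2"] - c2_inf) + abs(ss["C1"] - c1_inf))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-2
        # at Q = 10 the asymptote is within the finite-flow correction O(k/Q)
        assert errs[0] < 0.4

    def test_orifice_and_pipe_share_steady_states(self):
        """Replacing the orifice by any N-lump pipe leaves the steady state unchanged."""
        flow = FlowProfile.constant(7.0)
        base = steady_state(build_orifice_model(OrificeScenario(lam=0.0, flow=flow)))
        for N in (1, 3, 5):
            scn = OrificeScenario(lam=0.0, flow=flow, pipe_V=5.0, pipe_N=N)
            ss = steady_state(build_orifice_model(scn))
            assert ss["C1"] == pytest.approx(base["C1"], abs=1e-8)
            assert ss["C2"] == pytest.approx(base["C2"], abs=1e-8)

    def test_pipe_connection_requires_pure_advection(self):
        with pytest.raises(ValueError, match="lam"):
            OrificeScenario(lam=0.5, pipe_V=5.0)


class TestSteadyStateLargeFlow:
    @pytest.mark.parametrize(
        "lam, expected",
        [(0.0, (0.0, 3.0)), (1.0, (1.5, 1.5))],
    )
    def test_worked_values(self, lam, expected):
        assert steady_state_large_flow(lam) == pytest.approx(expected)

    def test_empty_boundaries_give_zero(self):
        assert steady_state_large_flow(0.5, cA=0.0, cB=0.0) == pytest.approx((0.0, 0.0))


class TestCirculationModel:
    def test_enzyme_moiety_conserved(self):
        res = simulate(build_circulation_model(CirculationScenario()), 40.0)
        total = res.amounts[["E1", "E2", "C1", "C2"]].sum(axis=1)
        assert np.allclose(total, total.iloc[0], atol=1e-8)

    def test_enzyme_moiety_conserved_with_pipes(self):
        model = build_circulation_model(CirculationScenario(connection="pipe"))
        res = simulate(model, 20.0)
        total = res.amounts.sum(axis=1)  # all carrier states incl. pipe lumps
        assert np.allclose(total, total.iloc[0], atol=1e-8)

    def test_bound_and_free_states_approach_steady_state(self):
        res = simulate(build_circulation_model(CirculationScenario()), 60.0)
        # location 1 binds (A1 rich): complex accumulates there, enzyme at 2
        last = res.amounts.iloc[-1]
        assert last["C1"] > last["C2"]
        assert last["E2"] > last["E1"]
        tail = res.amounts.iloc[-50:]
        assert float(tail.std().max()) < 1e-6

    def test_orifice_and_re_equivalent_trajectories_agree(self):
        """Identical opposed orifices are exactly a reaction element."""
        ro = simulate(build_circulation_model(CirculationScenario()), 40.0)
        rr = simulate(
            build_circulation_model(CirculationScenario(connection="re_equivalent")),
            40.0,
        )
        assert np.allclose(ro.amounts.values, rr.amounts.values, atol=1e-7)

    def test_unequal_orifices_break_the_equivalence(self):
        fast = CirculationScenario(flow_cf=FlowProfile.constant(2.0))
        ro = simulate(build_circulation_model(fast), 40.0)
        rr = simulate(
            build_circulation_model(CirculationScenario(connection="re_equivalent")),
            40.0,
        )
        assert not np.allclose(ro.amounts.values, rr.amounts.values, atol=1e-3)

    def test_re_equivalent_rejects_unequal_flows(self):
        scn = CirculationScenario(
            connection="re_equivalent", flow_cf=FlowProfile.constant(2.0)
        )
        with pytest.raises(ModelValidationError, match="identical"):
            build_circulation_model(scn)


class TestCompareConnections:
    def test_pipe_delays_ligand_release_by_transit_time(self):
        out = compare_connections(t_end=40.0)
        assert out["delay_difference"] == pytest.approx(5.0, abs=1.5)
        assert len(out["table"]) == len(out["results"][0].times)

    def test_zero_volume_pipe_is_transparent(self):
        scn_o = CirculationScenario()
        scn_p = CirculationScenario(connection="pipe", pipe_V=1e-3, pipe_N=2)
        out = compare_connections(scn_o, scn_p, t_end=40.0)
        assert abs(out["delay_difference"]) < 0.1

    def test_sinusoidal_flow_modulates_output_at_drive_period(self):
        sin = FlowProfile.sinusoid(1.0, 0.5, 5.0)
        scn = CirculationScenario(
            connection="pipe", flow_cf=sin, flow_cr=sin, flow_ef=sin, flow_er=sin
        )
        res = simulate(build_circulation_model(scn), 40.0, n_samples=1601)
        f = np.asarray(res.fluxes["r2"])[800:]
        t = res.times[800:]
        spec = np.abs(np.fft.rfft(f - f.mean()))
        freq = np.fft.rfftfreq(f.size, d=t[1] - t[0])
        period = 1.0 / freq[np.argmax(spec)]
        assert period == pytest.approx(5.0, rel=0.05)
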