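"""Pump-and-leak steady state, Ponder relation, and shock dynamics."""

import dataclasses
import math

import numpy as np
import pytest

from osmovol import (ConvergenceError, IonTransportParams, ShockProtocol,
                     StabilityError, adaptation_rate, bulk_modulus,
                     contractility_volume_bound, default_hela_params,
                     estimate_permeability, flux_residuals, laplace_pressure,
                     ponder_passive_volume, simulate_osmotic_shock,
                     solve_steady_state, trapped_pressure_change)
from osmovol.pump_leak import NERNST_MV, RT_PA_PER_MM, _interior_at_vm


def brute_force_steady_volume(params, n_coarse=120, refinements=3):
    """Independent 2-D grid search over (Vm, Vw) minimizing the residuals.

    Concentrations at each grid node follow from the zero-flux conditions;
    the score combines the electroneutrality and osmotic-balance residuals.
    """
    lo_vm, hi_vm = -150.0, 50.0
    lo_vw, hi_vw = 10.0, 1e5
    best = None
    for _ in range(refinements):
        vms = np.linspace(lo_vm, hi_vm, n_coarse)
        vws = np.geomspace(lo_vw, hi_vw, n_coarse)
        score = np.full((n_coarse, n_coarse), np.inf)
        for i, vm in enumerate(vms):
            try:
                cNa, cK, cCl = _interior_at_vm(params, vm)
            except ConvergenceError:
                continue
            electro = cNa + cK - cCl + params.zX * params.nX / vws
            osm = cNa + cK + cCl + (params.nX + params.nY) / vws - params.osm_ext
            score[i] = electro**2 + osm**2
        i, j = np.unravel_index(np.argmin(score), score.shape)
        best = (vms[i], vws[j], score[i, j])
        dvm = (hi_vm - lo_vm) / (n_coarse - 1)
        lo_vm, hi_vm = vms[i] - 2 * dvm, vms[i] + 2 * dvm
        lo_vw = vws[max(j - 2, 0)]
        hi_vw = vws[min(j + 2, n_coarse - 1)]
    vw = best[1]
    return vw / (1.0 - params.excluded_fraction)


class TestSteadyState:
    def test_default_composition(self, hela_params, hela_steady):
        s = hela_steady
        assert s.cNa + s.cK + s.cCl == pytest.approx(200.0, abs=1e-6)
        osm_int = s.cNa + s.cK + s.cCl + (hela_params.nX + hela_params.nY) / s.Vw
        assert osm_int == pytest.approx(300.0, abs=1e-6)
        assert (s.cNa, s.cK, s.cCl) == pytest.approx((15.0, 120.0, 65.0), abs=1e-6)
        # all three net fluxes vanish
        assert flux_residuals(hela_params, s) == pytest.approx((0, 0, 0), abs=1e-8)

    def test_no_impermeant_osmolytes_is_an_error(self, hela_params):
        p = dataclasses.replace(hela_params, nX=0.0, nY=0.0)
        with pytest.raises(ConvergenceError, match="undetermined"):
            solve_steady_state(p)

    def test_pump_off_divergence(self, hela_params):
        with pytest.raises(ConvergenceError):
            solve_steady_state(dataclasses.replace(hela_params, pump_rate=0.0))

    def test_doubling_neutral_osmolyte_grid_oracle(self, hela_params):
        p = dataclasses.replace(hela_params, nY=hela_params.nX * 0.5)
        s = solve_steady_state(p)
        assert s.V > solve_steady_state(hela_params).V
        assert s.V == pytest.approx(brute_force_steady_volume(p), rel=0.01)

    def test_grid_oracle_on_random_parameter_sets(self, rng):
        base = default_hela_params()
        n_ok = 0
        while n_ok < 20:
            p = dataclasses.replace(
                base,
                gNa=base.gNa * rng.uniform(0.5, 2.0),
                gK=base.gK * rng.uniform(0.5, 2.0),
                gCl=base.gCl * rng.uniform(0.5, 2.0),
                pump_rate=base.pump_rate * rng.uniform(0.6, 1.5),
                nX=base.nX * rng.uniform(0.5, 1.5),
                nY=base.nX * rng.uniform(0.0, 0.3),
                zX=rng.uniform(-1.2, -0.4),
            )
            try:
                s = solve_steady_state(p)
            except ConvergenceError:
                continue
            n_ok += 1
            assert s.V == pytest.approx(brute_force_steady_volume(p), rel=0.01)

    def test_external_electroneutrality_enforced(self):
        with pytest.raises(ValueError, match="electroneutral"):
            IonTransportParams(cNa_ext=145.0, cK_ext=5.0, cCl_ext=100.0)


class TestPonder:
    def test_identity_and_reference_points(self):
        assert ponder_passive_volume(1.0, 0.67) == pytest.approx(1.0)
        assert ponder_passive_volume(0.6, 0.67) == pytest.approx(0.732)
        # infinite-osmolarity limit leaves the inactive fraction
        assert ponder_passive_volume(1e-12, 0.67) == pytest.approx(0.33, abs=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            ponder_passive_volume(0.0, 0.67)
        with pytest.raises(ValueError):
            ponder_passive_volume(1.0, 1.5)


def _passive_params():
    return dataclasses.replace(default_hela_params(), k_reg=0.0)


def _run_shock(params, ratio, duration=600.0, dt=1.0, t_shock=10.0):
    state0 = solve_steady_state(params)
    protocol = ShockProtocol(events=((t_shock, ratio),), duration=duration, dt=dt)
    return simulate_osmotic_shock(params, state0, protocol), state0


class TestShockSimulation:
    def test_no_shock_is_flat(self):
        traj, s0 = _run_shock(_passive_params(), 1.0)
        assert np.max(np.abs(traj.V / s0.V - 1.0)) < 1e-3

    @pytest.mark.parametrize("ratio", [0.4, 0.6, 0.82, 1.11, 1.5, 2.0])
    def test_passive_limit_matches_ponder(self, ratio):
        params = _passive_params()
        traj, s0 = _run_shock(params, ratio)
        expected = ponder_passive_volume(ratio, 1.0 - params.excluded_fraction)
        assert traj.V[-1] / s0.V == pytest.approx(expected, rel=5e-3)

    def test_ion_content_conserved_without_regulation(self):
        traj, _ = _run_shock(_passive_params(), 1.5)
        totals = traj.n_ions.sum(axis=1)
        assert np.max(np.abs(totals / totals[0] - 1.0)) < 1e-7

    def test_regulated_volume_recovers(self, hela_params):
        traj, s0 = _run_shock(hela_params, 1.5, duration=1200.0)
        i_peak = int(np.argmax(traj.V))
        assert traj.V[i_peak] / s0.V > 1.25
        assert abs(traj.V[-1] / s0.V - 1.0) < abs(traj.V[i_peak] / s0.V - 1.0) / 2

    def test_adaptation_faster_for_larger_shocks(self, hela_params):
        rates = []
        for ratio in (1.2, 1.5, 1.9):
            traj, _ = _run_shock(hela_params, ratio, duration=900.0)
            rates.append(adaptation_rate(traj))
        assert all(r < 0 for r in rates)  # recovery downward after swelling
        assert abs(rates[0]) < abs(rates[1]) < abs(rates[2])

    def test_coarse_output_grid_rejected(self, hela_params):
        state0 = solve_steady_state(hela_params)
        protocol = ShockProtocol(events=((10.0, 1.5),), duration=1200.0, dt=600.0)
        with pytest.raises(StabilityError):
            simulate_osmotic_shock(hela_params, state0, protocol)

    def test_requires_steady_initial_state(self, hela_params):
        s0 = solve_steady_state(hela_params)
        bad = dataclasses.replace(s0, cNa=s0.cNa * 2)
        protocol = ShockProtocol(events=((10.0, 1.5),), duration=60.0, dt=1.0)
        with pytest.raises(ValueError, match="steady state"):
            simulate_osmotic_shock(hela_params, bad, protocol)


class TestPonderRegressionInvariance:
    def _passive_extrema(self, params, ratios):
        out = []
        for r in ratios:
            traj, s0 = _run_shock(params, r)
            out.append(traj.V[-1] / s0.V)
        return np.array(out)

    def test_linearity_and_transport_invariance(self):
        ratios = np.array([0.4, 0.6, 0.82, 1.0, 1.11, 2.0])
        base = _passive_params()
        v = self._passive_extrema(base, ratios)
        slope, intercept = np.polyfit(ratios, v, 1)
        assert slope == pytest.approx(1.0 - base.excluded_fraction, abs=1e-5)
        assert intercept == pytest.approx(base.excluded_fraction, abs=1e-5)
        # passive response independent of transport rates: scale g, pump x10
        scaled = dataclasses.replace(
            base, gNa=base.gNa * 10, gK=base.gK * 10, gCl=base.gCl * 10,
            pump_rate=base.pump_rate * 10)
        v10 = self._passive_extrema(scaled, ratios)
        slope10 = np.polyfit(ratios, v10, 1)[0]
        assert slope10 == pytest.approx(slope, abs=1e-5)


class TestPermeabilityAndAdaptation:
    def test_permeability_round_trip(self):
        params = _passive_params()
        ratio = 1.3
        state0 = solve_steady_state(params)
        protocol = ShockProtocol(events=((5.0, ratio),), duration=120.0, dt=30.0)
        ts = np.union1d(np.arange(0.0, 120.0, 10.0), np.arange(5.0, 8.0, 0.1))
        traj = simulate_osmotic_shock(params, state0, protocol, sample_times=ts)
        delta_pi = params.osm_ext * (1 - 1 / ratio) * RT_PA_PER_MM
        lp = estimate_permeability(traj, area=state0.A, delta_Pi=delta_pi,
                                   region=(5.0, 5.25))
        assert lp == pytest.approx(params.Lp_in, rel=0.02)

    def test_flat_trace_gives_zero(self):
        traj, s0 = _run_shock(_passive_params(), 1.0)
        lp = estimate_permeability(traj, area=s0.A, delta_Pi=1e5,
                                   region=(100.0, 300.0))
        assert lp == pytest.approx(0.0, abs=1e-9)

    def test_hyper_permeability_smaller_than_hypo(self):
        params = _passive_params()
        state0 = solve_steady_state(params)
        lps = {}
        for name, ratio in (("hypo", 1.3), ("hyper", 0.77)):
            protocol = ShockProtocol(events=((5.0, ratio),), duration=120.0,
                                     dt=30.0)
            ts = np.union1d(np.arange(0.0, 120.0, 10.0), np.arange(5.0, 8.0, 0.1))
            traj = simulate_osmotic_shock(params, state0, protocol,
                                          sample_times=ts)
            dpi = params.osm_ext * (1 - 1 / ratio) * RT_PA_PER_MM
            lps[name] = estimate_permeability(traj, area=state0.A, delta_Pi=dpi,
                                              region=(5.0, 5.25))
        assert lps["hyper"] < lps["hypo"]
        assert lps["hyper"] == pytest.approx(params.Lp_out, rel=0.05)

    def test_adaptation_rate_on_exact_linear_recovery(self):
        # passive swelling for one minute, then exact -4 µm³/min recovery
        t = np.arange(0.0, 900.0, 10.0)
        ext = np.where(t >= 60.0, 250.0, 300.0)
        V = np.where(t < 60.0, 1000.0,
                     np.where(t < 120.0, 1000.0 + 5.0 * (t - 60.0),
                              1300.0 - 4.0 * (t - 120.0) / 60.0))
        from osmovol import OsmoticTrajectory
        traj = OsmoticTrajectory(times=t, V=V, n_ions=np.zeros((len(t), 3)),
                                 osm_ext=ext)
        assert adaptation_rate(traj) == pytest.approx(-4.0, rel=1e-6)

    def test_adaptation_rate_zero_when_constant_after_extremum(self):
        t = np.arange(0.0, 900.0, 10.0)
        ext = np.where(t >= 60.0, 250.0, 300.0)
        V = np.where(t < 60.0, 1000.0,
                     np.where(t < 120.0, 1000.0 + 5.0 * (t - 60.0), 1300.0))
        from osmovol import OsmoticTrajectory
        traj = OsmoticTrajectory(times=t, V=V, n_ions=np.zeros((len(t), 3)),
                                 osm_ext=ext)
        assert adaptation_rate(traj) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_trace_rejected(self):
        t = np.arange(0.0, 900.0, 10.0)
        ext = np.where(t >= 60.0, 250.0, 300.0)
        V = 1000.0 + 0.5 * t
        from osmovol import OsmoticTrajectory
        traj = OsmoticTrajectory(times=t, V=V, n_ions=np.zeros((len(t), 3)),
                                 osm_ext=ext)
        with pytest.raises(ValueError, match="monotone"):
            adaptation_rate(traj)


class TestPressureEstimates:
    def test_bulk_modulus_definition(self):
        assert bulk_modulus(2000.0, 1e4, 200.0) == pytest.approx(1e5)
        with pytest.raises(ValueError):
            bulk_modulus(2000.0, 1e4, 0.0)

    def test_bulk_modulus_small_shock_limit(self):
        # small pressure increase dPi: Ponder gives dV = Viso R dPi/Pi_iso,
        # so B = RT Pi_iso / R (the analytic small-perturbation limit)
        R, pi_iso, V_iso = 0.67, 300.0, 2000.0
        d = 1e-4
        ratio = 1.0 / (1.0 + d)  # hyper: external pressure up by d
        v = ponder_passive_volume(ratio, R)
        delta_V = V_iso * (1.0 - v)
        delta_P = pi_iso * d * RT_PA_PER_MM
        B = bulk_modulus(V_iso, delta_P, delta_V)
        assert B == pytest.approx(RT_PA_PER_MM * pi_iso / R, rel=1e-3)

    def test_laplace_pressure(self):
        assert laplace_pressure(1.0, 10.0) == pytest.approx(200.0)
        assert laplace_pressure(0.0, 5.0) == 0.0
        assert laplace_pressure(2.0, 10.0) == pytest.approx(laplace_pressure(1.0, 5.0))

    def test_trapped_pressure_change(self):
        assert trapped_pressure_change(1e5, 0.10) == pytest.approx(1e4)
        assert trapped_pressure_change(1e5, 0.0) == 0.0
        assert trapped_pressure_change(1e5, 0.10, exact=True) == pytest.approx(
            1.0 / 0.9 * 1e5 - 1e5, rel=1e-12)

    def test_contractility_volume_bound(self):
        assert contractility_volume_bound(10.0, 100.0, 1e5) == pytest.approx(0.01)
        assert contractility_volume_bound(1.0, 100.0, 1e5) == pytest.approx(1e-3)
        assert contractility_volume_bound(0.0, 100.0, 1e5) == 0.0
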