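"""Integration, spike detection, phase protocol and numerical soundness."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from crnet import (CRProtocol, IntegrationConfig, NetworkParams,
                   ProtocolSchedule, STDPParams, build_coupling,
                   detect_spikes, firing_rates, hh_rates, init_network,
                   run_protocol)
from crnet.simulation import run_phase


def set_uniform_state(state, ic):
    for key, val in ic.items():
        getattr(state, key)[:] = val
    return state


class TestDetectSpikes:
    def test_interpolated_time(self):
        ev = detect_spikes([-10.0], [10.0], 0.0, 100.0, 0.05)
        assert ev == [(0, pytest.approx(100.025))]

    def test_no_crossing_no_event(self):
        assert detect_spikes([-10.0], [-5.0], 0.0, 0.0, 0.05) == []
        assert detect_spikes([10.0], [20.0], 0.0, 0.0, 0.05) == []

    def test_plateau_at_threshold_not_a_spike(self):
        assert detect_spikes([0.0], [0.0], 0.0, 0.0, 0.05) == []

    def test_refractory_guard(self):
        last = np.array([99.5])
        assert detect_spikes([-10.0], [10.0], 0.0, 100.0, 0.05, last) == []
        last = np.array([90.0])
        assert len(detect_spikes([-10.0], [10.0], 0.0, 100.0, 0.05, last)) == 1


class TestSingleNeuron:
    def _uncoupled(self, rest_ic, dt=0.05, method="rk4"):
        p = NetworkParams(N=2, sigma_I=0.0)
        prof = build_coupling(p)
        cfg = IntegrationConfig(dt=dt, method=method, startup_ms=0.0)
        state = init_network(p, 0)
        state.c[:] = 0.0
        state.I[:] = 11.0
        set_uniform_state(state, rest_ic)
        return p, prof, cfg, state

    def test_matches_adaptive_reference(self, rest_ic):
        """Uncoupled RK4 trajectory vs scipy adaptive solve: < 0.5 mV
        over 100 ms, sampled every ms."""
        def rhs(t, y):
            V, m, h, n, s = y
            am, bm, ah, bh, an, bn = hh_rates(V)
            dV = (11.0 - 120 * m**3 * h * (V - 50) - 36 * n**4 * (V + 77)
                  - 0.3 * (V + 54.4))
            rise = 0.5 / (1 + np.exp(-(V + 5) / 12))
            return [dV, am * (1 - m) - bm * m, ah * (1 - h) - bh * h,
                    an * (1 - n) - bn * n, rise * (1 - s) - 2 * s]

        y0 = [rest_ic["V"], rest_ic["m"], rest_ic["h"], rest_ic["n"], 0.0]
        ref = solve_ivp(rhs, (0, 100), y0, rtol=1e-11, atol=1e-12,
                        dense_output=True, method="LSODA")
        p, prof, cfg, state = self._uncoupled(rest_ic)
        err = 0.0
        for _ in range(100):
            run_phase(state, prof, p, cfg, 1.0)
            err = max(err, abs(state.V[0] - ref.sol(state.t)[0]))
        assert err < 0.5

    def test_table_rates_match_exact_rates(self, rest_ic):
        """The production lookup-table kernel stays within 0.05 mV of the
        exact-exponential kernel on a 100 ms spiking trajectory."""
        trajs = {}
        for method in ("rk4", "rk4-exact"):
            p, prof, cfg, state = self._uncoupled(rest_ic, method=method)
            vs = []
            for _ in range(100):
                run_phase(state, prof, p, cfg, 1.0)
                vs.append(state.V[0])
            trajs[method] = np.array(vs)
        assert np.abs(trajs["rk4"] - trajs["rk4-exact"]).max() < 0.05

    def test_periodic_firing_low_cv(self, rest_ic):
        """An uncoupled neuron at I = 11.0 fires periodically: CV of the
        inter-spike intervals < 1% after the transient."""
        p, prof, cfg, state = self._uncoupled(rest_ic)
        run_phase(state, prof, p, cfg, 500.0)
        _, _, st, si = run_phase(state, prof, p, cfg, 3000.0)
        isi = np.diff(st[si == 0])
        assert len(isi) > 100
        assert isi.std() / isi.mean() < 0.01
        # intrinsic rate ~71 Hz at the center of the drive distribution
        assert 1000.0 / isi.mean() == pytest.approx(71.0, abs=3.0)


class TestLeakOnlyRelaxation:
    def test_relaxes_to_leak_drive_fixed_point(self):
        """With (numerically) zero Na/K conductances the membrane relaxes to
        V* = V_l + I/g_l."""
        p = NetworkParams(N=2, g_Na=1e-9, g_K=1e-9, sigma_I=0.0)
        prof = build_coupling(p)
        cfg = IntegrationConfig()
        state = init_network(p, 1)
        state.c[:] = 0.0
        state.I[:] = 11.0
        run_phase(state, prof, p, cfg, 200.0)
        v_star = -54.4 + 11.0 / 0.3
        assert np.allclose(state.V, v_star, atol=1e-3)


class TestStepProperties:
    def test_k0_equals_stimulation_off_bitwise(self, params20, profile20):
        cfg = IntegrationConfig()
        base = init_network(params20, 5)
        run_phase(base, profile20, params20, cfg, 100.0)   # absorb transient

        proto = CRProtocol(T_s=16.0, K=0.0, seed=9)
        a, b = base.copy(), base.copy()
        run_phase(a, profile20, params20, cfg, 200.0, stdp=STDPParams(),
                  protocol=proto)
        run_phase(b, profile20, params20, cfg, 200.0, stdp=STDPParams())
        for name in ("V", "m", "h", "n", "s", "c", "last_spike_times"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_determinism_under_fixed_seed(self, params20, profile20):
        outs = []
        for _ in range(2):
            cfg = IntegrationConfig(seed=3)
            state = init_network(params20, 3)
            run_phase(state, profile20, params20, cfg, 300.0)
            _, rc, st, si = run_phase(state, profile20, params20, cfg, 300.0,
                                      stdp=STDPParams())
            outs.append((state.V.copy(), rc.copy(), st.copy(), si.copy()))
        for x, y in zip(*outs):
            assert np.array_equal(x, y)

    def test_dt_halving_convergence(self, params20, profile20):
        """C_av after 1 s changes by < 1e-3 when dt is halved."""
        vals = {}
        for dt in (0.05, 0.025):
            cfg = IntegrationConfig(dt=dt)
            state = init_network(params20, 7)
            run_phase(state, profile20, params20, cfg, 200.0)
            _, rc, _, _ = run_phase(state, profile20, params20, cfg, 1000.0,
                                    stdp=STDPParams())
            vals[dt] = rc[-1]
        assert abs(vals[0.05] - vals[0.025]) < 1e-3

    def test_gating_variables_stay_in_unit_interval(self, params20, profile20):
        cfg = IntegrationConfig()
        state = init_network(params20, 2)
        run_phase(state, profile20, params20, cfg, 500.0, stdp=STDPParams())
        state.validate(tol=1e-9)

    def test_rotation_equivariance_one_step(self, rest_ic):
        """With homogeneous drive and weights, one integration step commutes
        with a ring rotation of the state."""
        p = NetworkParams(N=20, sigma_I=0.0, sigma_c=0.0)
        prof = build_coupling(p)
        cfg = IntegrationConfig(startup_ms=0.0)
        state = init_network(p, 4)
        state.c[:] = 0.5
        np.fill_diagonal(state.c, 0.0)
        # smooth, non-stiff but spatially structured initial conditions
        state.V = np.linspace(-70.0, -20.0, p.N)
        for name in ("m", "h", "n"):
            getattr(state, name)[:] = rest_ic[name]
        state.s = np.linspace(0.0, 0.5, p.N)

        rot = state.copy()
        for name in ("V", "m", "h", "n", "s", "I"):
            setattr(rot, name, np.roll(getattr(state, name), 3))
        rot.c = np.roll(np.roll(state.c, 3, axis=0), 3, axis=1)

        run_phase(state, prof, p, cfg, cfg.dt)
        run_phase(rot, prof, p, cfg, cfg.dt)
        for name in ("V", "m", "h", "n", "s"):
            assert np.allclose(np.roll(getattr(state, name), 3),
                               getattr(rot, name), atol=1e-11)

    def test_blowup_detected(self, params20, profile20):
        cfg = IntegrationConfig(dt=0.05, startup_ms=0.0)
        state = init_network(params20, 0)   # stiff random ICs, no refinement
        state.m[:] = 1.0
        state.h[:] = 1.0
        state.V[:] = -65.0
        with pytest.raises(FloatingPointError):
            run_phase(state, profile20, params20, cfg, 10.0)


class TestRunProtocol:
    def test_zero_durations_empty_result(self, params20):
        sched = ProtocolSchedule(0.0, 0.0, 0.0, 0.0)
        res = run_protocol(params20, STDPParams(), None, sched,
                           IntegrationConfig(seed=1))
        assert res.times.size == 0
        assert "initial" in res.snapshots

    def test_smoke_four_phases(self, params20):
        sched = ProtocolSchedule(500.0, 1000.0, 2000.0, 1000.0)
        proto = CRProtocol(T_s=16.0, K=0.3, mode="rvs", seed=2)
        res = run_protocol(params20, STDPParams(), proto, sched,
                           IntegrationConfig(seed=2))
        # series bounds
        valid = np.isfinite(res.R)
        assert np.all((res.R[valid] >= 0) & (res.R[valid] <= 1 + 1e-12))
        assert np.all((res.C_av >= -1) & (res.C_av <= 1))
        assert np.all(np.diff(res.times) > 0)
        # STDP frozen during equilibration: C_av exactly constant there
        t0, t1 = res.phase_bounds["equilibration"]
        eq = res.C_av[res.times <= t1]
        assert np.all(eq == eq[0])
        # endpoint summaries present
        for key in ("C_av_on_end", "R_av_on_end", "C_av_off_end",
                    "R_av_off_end"):
            assert key in res.summary
        # weight snapshots at every phase boundary
        assert set(res.snapshots) == {"initial", "end_equilibration",
                                      "end_kindling", "end_cr_on",
                                      "end_cr_off"}

    def test_result_io_roundtrip(self, tmp_path, params20):
        sched = ProtocolSchedule(200.0, 200.0, 400.0, 200.0)
        proto = CRProtocol(T_s=16.0, K=0.2, seed=1)
        res = run_protocol(params20, STDPParams(), proto, sched,
                           IntegrationConfig(seed=1))
        res.save(tmp_path / "run.h5")
        res.export_spikes_csv(tmp_path / "spikes.csv")
        import h5py
        with h5py.File(tmp_path / "run.h5") as f:
            assert np.array_equal(f["C_av"][...], res.C_av)
            assert "snapshots/end_cr_on" in f
        raster = np.loadtxt(tmp_path / "spikes.csv", delimiter=",", skiprows=1)
        assert raster.shape[0] == res.spike_times.size


class TestFiringRates:
    def test_simple_counts(self):
        trains = [np.linspace(0, 999, 71), np.array([])]
        rates, summary = firing_rates(trains, (0.0, 1000.0))
        assert rates[0] == pytest.approx(71.0)
        assert rates[1] == 0.0
        assert summary["mean"] == pytest.approx(35.5)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            firing_rates([np.array([1.0])], (5.0, 5.0))


def test_grid_alignment_validation():
    cfg = IntegrationConfig(dt=0.05)
    cfg.check_protocol_grid(CRProtocol(T_s=10.0, K=0.2))   # 2.5 / 0.05 ok
    with pytest.raises(ValueError):
        cfg.check_protocol_grid(CRProtocol(T_s=0.3, K=0.2))
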