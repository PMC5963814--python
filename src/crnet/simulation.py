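"""Time-stepping of the coupled network and the four-phase protocol.

The standard numerical experiment runs four phases back to back:

1. *equilibration* (2 s): network dynamics without STDP or stimulation, so the
   random initial state relaxes onto the network's own attractor;
2. *kindling* (60 s): STDP switched on, no stimulation — the synchronized,
   strongly coupled baseline state develops;
3. *CR-on* (128 s): STDP plus coordinated-reset stimulation with 3:2 ON:OFF
   cycling (the clock of the stimulus pattern starts at this phase boundary);
4. *CR-off* (128 s): STDP continues, stimulation off — probes whether the
   stimulation effect persists (anti-kindling) or the network relapses.

Integration is fixed-step classical Runge-Kutta (RK4) at ``dt = 0.05`` ms by
default.  Spikes are upward crossings of 0 mV with linearly interpolated onset
times and a 2 ms refractory guard; each detected spike triggers the
event-driven STDP update at the end of the step in which it was detected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from . import _kernel
from .cr_stimulation import CRProtocol, sequence_stream
from .measures import order_parameter_series, r_av
from .network_model import (CouplingProfile, NetworkParams, NetworkState,
                            build_coupling, init_network)
from .plasticity import STDPParams

__all__ = [
    "IntegrationConfig", "ProtocolSchedule", "SimulationResult",
    "step", "detect_spikes", "run_phase", "run_protocol", "firing_rates",
]


@dataclass
class IntegrationConfig:
    """Fixed-step integrator settings.

    ``method`` is ``"rk4"`` (tabulated rate functions, the production default)
    or ``"rk4-exact"`` (exact exponentials, for verification runs).
    ``record_stride`` is the number of steps between measure samples.
    """

    dt: float = 0.05
    method: str = "rk4"
    spike_threshold: float = 0.0
    refractory: float = 2.0
    record_stride: int = 20
    seed: int = 0
    #: random gating initial conditions (m, h, n uniform on [0, 1]) can put
    #: the membrane in a regime with ~10 us effective time constant; the
    #: first startup_ms of a run started at t = 0 are therefore integrated
    #: at startup_dt before switching to dt.  The transient decays within
    #: a few ms and never recurs.
    startup_dt: float = 0.002
    startup_ms: float = 5.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.method not in ("rk4", "rk4-exact"):
            raise ValueError("unknown integration method")
        if self.record_stride < 1:
            raise ValueError("record_stride must be at least 1")

    def check_protocol_grid(self, protocol: CRProtocol) -> None:
        """dt must divide the slot length T_s/N_s so boundaries land on steps."""
        slot = protocol.T_s / protocol.N_s
        ratio = slot / self.dt
        if abs(ratio - round(ratio)) > 1e-9 * ratio:
            raise ValueError(
                f"dt={self.dt} must divide the slot length T_s/N_s={slot}"
            )


@dataclass
class ProtocolSchedule:
    """Durations of the four protocol phases, in ms."""

    equilibration: float = 2_000.0
    kindling: float = 60_000.0
    cr_on: float = 128_000.0
    cr_off: float = 128_000.0

    def __post_init__(self) -> None:
        for name in ("equilibration", "kindling", "cr_on", "cr_off"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} duration must be non-negative")

    def scaled(self, duration_scale: float) -> "ProtocolSchedule":
        """Scale the CR-on/CR-off epochs; equilibration and kindling keep
        their full length so the kindled baseline is unchanged."""
        return ProtocolSchedule(
            equilibration=self.equilibration,
            kindling=self.kindling,
            cr_on=self.cr_on * duration_scale,
            cr_off=self.cr_off * duration_scale,
        )


@dataclass
class SimulationResult:
    """Recorded time series, spike trains and endpoint summaries of one run.

    Times are global simulation time in ms (the equilibration phase starts at
    0); ``phase_bounds`` maps phase names to (start, end).  ``spike_times`` /
    ``spike_neurons`` hold all spikes in detection order (neurons 0-based
    internally; exports are 1-based).
    """

    times: np.ndarray
    C_av: np.ndarray
    R: np.ndarray
    spike_times: np.ndarray
    spike_neurons: np.ndarray
    phase_bounds: dict
    snapshots: dict
    summary: dict
    provenance: dict

    def spike_trains(self) -> list:
        """Per-neuron sorted spike-time arrays (index 0 = neuron 1)."""
        N = self.provenance["params"]["N"]
        trains = [[] for _ in range(N)]
        for t, i in zip(self.spike_times, self.spike_neurons):
            trains[i].append(t)
        return [np.asarray(tr) for tr in trains]

    def export_spikes_csv(self, path) -> None:
        """Two-column CSV export: neuron (1-based), time-ms."""
        arr = np.column_stack([self.spike_neurons + 1, self.spike_times])
        np.savetxt(path, arr, delimiter=",", fmt=("%d", "%.6f"),
                   header="neuron,time_ms", comments="")

    def save(self, path) -> None:
        """HDF5 container: series, spikes, snapshots + JSON summary sidecar."""
        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=self.times)
            f.create_dataset("C_av", data=self.C_av)
            f.create_dataset("R", data=self.R)
            f.create_dataset("spike_times", data=self.spike_times)
            f.create_dataset("spike_neurons", data=self.spike_neurons)
            for name, snap in self.snapshots.items():
                f.create_dataset(f"snapshots/{name}", data=snap)
            f.attrs["phase_bounds"] = json.dumps(self.phase_bounds)
            f.attrs["summary"] = json.dumps(self.summary)
            f.attrs["provenance"] = json.dumps(self.provenance)


def detect_spikes(V_prev, V_now, threshold: float, t: float, dt: float,
                  last_spike_times=None, refractory: float = 2.0):
    """Spike events from one integration step.

    Strict upward crossings ``V_prev < threshold < V_now``; onset times
    linearly interpolated within the step; a neuron that spiked less than
    ``refractory`` ms ago (per ``last_spike_times``) is skipped.  Returns a
    list of ``(neuron_0based, time_ms)`` sorted by time.
    """
    V_prev = np.asarray(V_prev, dtype=float)
    V_now = np.asarray(V_now, dtype=float)
    crossed = (V_prev < threshold) & (V_now > threshold)
    idx = np.nonzero(crossed)[0]
    events = []
    for i in idx:
        ts = t + dt * (threshold - V_prev[i]) / (V_now[i] - V_prev[i])
        if last_spike_times is not None and ts - last_spike_times[i] < refractory:
            continue
        events.append((int(i), float(ts)))
    events.sort(key=lambda e: (e[1], e[0]))
    return events


class _KernelRun:
    """Shared plumbing between :func:`step`/:func:`run_phase` calls."""

    def __init__(self, params: NetworkParams, profile: CouplingProfile,
                 cfg: IntegrationConfig):
        self.params = params
        self.profile = profile
        self.cfg = cfg
        self.table = _kernel.rate_table()
        self.use_table = 1 if cfg.method == "rk4" else 0
        self.sgn = np.ascontiguousarray(profile.sign, dtype=np.float64)
        self.absM = np.ascontiguousarray(profile.abs_M, dtype=np.float64)

    def weight_products(self, c: np.ndarray):
        Wp = np.where(self.sgn > 0, c * self.absM, 0.0)
        Wm = np.where(self.sgn < 0, c * self.absM, 0.0)
        return np.ascontiguousarray(Wp), np.ascontiguousarray(Wm)


def run_phase(state: NetworkState, profile: CouplingProfile,
              params: NetworkParams, cfg: IntegrationConfig,
              duration: float, *, stdp: STDPParams | None = None,
              protocol: CRProtocol | None = None,
              stream: np.ndarray | None = None,
              stim_t0: float | None = None):
    """Advance ``state`` in place by ``duration`` ms.

    STDP is active iff ``stdp`` is given; stimulation iff ``protocol`` is
    given (its clock starts at ``stim_t0``, default the phase start, which
    must coincide with it for the slot grid to be exact).  Returns
    ``(rec_times, rec_C_av, spike_times, spike_neurons)``.

    A phase started from a fresh random state (``state.t == 0``) integrates
    its first ``cfg.startup_ms`` at the refined ``cfg.startup_dt`` to absorb
    the stiff transient of the random gating initial conditions (only
    without stimulation; the standard protocol never stimulates at t = 0).
    """
    if (state.t == 0.0 and protocol is None and duration > 0
            and cfg.startup_ms > 0 and cfg.dt > cfg.startup_dt):
        fine = dataclasses.replace(
            cfg, dt=cfg.startup_dt, startup_ms=0.0,
            record_stride=max(1, int(round(
                cfg.record_stride * cfg.dt / cfg.startup_dt))))
        d0 = min(cfg.startup_ms, duration)
        out0 = _run_phase_core(state, profile, params, fine, d0, stdp,
                               None, None, None)
        out1 = _run_phase_core(state, profile, params, cfg, duration - d0,
                               stdp, None, None, None)
        return tuple(np.concatenate([a, b]) for a, b in zip(out0, out1))
    return _run_phase_core(state, profile, params, cfg, duration, stdp,
                           protocol, stream, stim_t0)


def _run_phase_core(state, profile, params, cfg, duration, stdp, protocol,
                    stream, stim_t0):
    n_steps = int(round(duration / cfg.dt))
    if n_steps == 0:
        empty = np.empty(0)
        return empty, empty.copy(), empty.copy(), np.empty(0, dtype=np.int32)

    p = params
    sp = stdp if stdp is not None else STDPParams()
    stdp_on = 1 if stdp is not None else 0

    if protocol is not None:
        cfg.check_protocol_grid(protocol)
        if stim_t0 is None:
            stim_t0 = state.t
        if abs(stim_t0 - state.t) > 1e-9:
            raise ValueError("stimulation clock must start at the phase start")
        steps_per_Ts = int(round(protocol.T_s / cfg.dt))
        slot_steps = steps_per_Ts // protocol.N_s
        if stream is None:
            n_on = -(-n_steps // steps_per_Ts) * protocol.m  # safe upper bound
            stream = sequence_stream(protocol, n_on)
        seq = np.ascontiguousarray(stream, dtype=np.int64)
        D = np.ascontiguousarray(
            _decay(protocol, p), dtype=np.float64)
        stim_on, K = 1, protocol.K
        Vr_stim, tau_stim = protocol.V_r_stim, protocol.tau_stim
        m_on, n_off = protocol.m, protocol.n
    else:
        stim_on, K = 0, 0.0
        seq = np.zeros((1, 1), dtype=np.int64)
        D = np.zeros((1, p.N))
        Vr_stim, tau_stim = 20.0, 1.0
        steps_per_Ts, slot_steps, m_on, n_off = 1, 1, 1, 0

    runner = _KernelRun(params, profile, cfg)
    Wp, Wm = runner.weight_products(state.c)

    n_rec = n_steps // cfg.record_stride + 1
    rec_t = np.empty(n_rec)
    rec_cav = np.empty(n_rec)
    spk_cap = int(p.N * (duration / 1000.0) * 200) + 1000
    spike_t = np.empty(spk_cap)
    spike_i = np.empty(spk_cap, dtype=np.int32)

    last = state.last_spike_times
    if not np.all(np.isfinite(last)):
        last = np.where(np.isfinite(last), last, -1.0e18)
        state.last_spike_times = last

    status, t_end, rec_count, spk_count, _ = _kernel._run_phase(
        state.V, state.m, state.h, state.n, state.s, state.I, state.c, last,
        runner.absM, runner.sgn, Wp, Wm, p.V_r_exc, p.V_r_inh,
        p.g_Na, p.g_K, p.g_l, p.V_Na, p.V_K, p.V_l, p.C_m,
        state.t, n_steps, cfg.dt,
        runner.table, runner.use_table,
        stdp_on, sp.beta_1, sp.beta_2, sp.gamma_1 * sp.tau, sp.gamma_2 * sp.tau,
        sp.tau, sp.delta, sp.c_min, sp.c_max,
        stim_on, K, seq, D, Vr_stim, tau_stim, steps_per_Ts, slot_steps,
        m_on, n_off,
        cfg.spike_threshold, cfg.refractory,
        cfg.record_stride, rec_t, rec_cav, spike_t, spike_i,
    )
    state.t = t_end
    if status == 1:
        raise FloatingPointError(
            f"numerical blow-up (|V| > 200 mV) at t = {t_end:.3f} ms; "
            "reduce dt or check parameters")
    if status == 2:
        raise RuntimeError("spike buffer overflow: firing rate far above "
                           "the physiological range")
    return (rec_t[:rec_count], rec_cav[:rec_count],
            spike_t[:spk_count], spike_i[:spk_count])


def _decay(protocol: CRProtocol, params: NetworkParams) -> np.ndarray:
    from .cr_stimulation import decay_matrix
    return decay_matrix(protocol, params.N, params.d)


def step(state: NetworkState, profile: CouplingProfile, params: NetworkParams,
         cfg: IntegrationConfig, *, stdp: STDPParams | None = None,
         protocol: CRProtocol | None = None, stream: np.ndarray | None = None,
         stim_t0: float | None = None):
    """Advance the state by a single step ``dt``; returns emitted spike events
    as ``(neuron_0based, time_ms)`` pairs."""
    _, _, st, si = run_phase(state, profile, params, cfg, cfg.dt, stdp=stdp,
                             protocol=protocol, stream=stream, stim_t0=stim_t0)
    return list(zip(si.tolist(), st.tolist()))


def run_protocol(params: NetworkParams, stdp: STDPParams,
                 protocol: CRProtocol | None, schedule: ProtocolSchedule,
                 cfg: IntegrationConfig, *,
                 initial_state: NetworkState | None = None,
                 skip_to_cr: bool = False) -> SimulationResult:
    """Execute equilibration -> kindling -> CR-on -> CR-off.

    The network is drawn from ``cfg.seed`` unless ``initial_state`` is given.
    With ``skip_to_cr`` the given state is taken to be an already kindled
    network and the first two phases are skipped (used by parameter sweeps
    that stimulate the same kindled networks in every grid cell).

    Returns a :class:`SimulationResult` whose time axis is global (t = 0 at
    equilibration start; the stimulation clock is re-zeroed internally at the
    CR-on boundary).
    """
    profile = build_coupling(params)
    if initial_state is None:
        state = init_network(params, cfg.seed)
    else:
        state = initial_state.copy()

    times_l, cav_l, spk_t_l, spk_i_l = [], [], [], []
    snapshots = {"initial": state.c.copy()}
    phase_bounds = {}

    def _run(name, duration, *, use_stdp, proto):
        t_start = state.t
        rt, rc, st, si = run_phase(
            state, profile, params, cfg, duration,
            stdp=stdp if use_stdp else None, protocol=proto)
        times_l.append(rt); cav_l.append(rc)
        spk_t_l.append(st); spk_i_l.append(si)
        phase_bounds[name] = (t_start, state.t)
        snapshots[f"end_{name}"] = state.c.copy()

    if not skip_to_cr:
        _run("equilibration", schedule.equilibration, use_stdp=False, proto=None)
        _run("kindling", schedule.kindling, use_stdp=True, proto=None)
    else:
        phase_bounds["equilibration"] = (state.t, state.t)
        phase_bounds["kindling"] = (state.t, state.t)
    _run("cr_on", schedule.cr_on, use_stdp=True, proto=protocol)
    _run("cr_off", schedule.cr_off, use_stdp=True, proto=None)

    times = np.concatenate(times_l) if times_l else np.empty(0)
    C_av = np.concatenate(cav_l) if cav_l else np.empty(0)
    spike_times = np.concatenate(spk_t_l) if spk_t_l else np.empty(0)
    spike_neurons = (np.concatenate(spk_i_l) if spk_i_l
                     else np.empty(0, dtype=np.int32))

    trains = [[] for _ in range(params.N)]
    for t, i in zip(spike_times, spike_neurons):
        trains[i].append(t)
    trains = [np.asarray(tr) for tr in trains]
    R = (order_parameter_series(trains, times) if times.size
         else np.empty(0))

    summary = {}
    if protocol is not None and schedule.cr_on > 0:
        for name, key in (("cr_on", "on_end"), ("cr_off", "off_end")):
            t0, t1 = phase_bounds[name]
            if t1 <= t0:
                continue
            sel = times <= t1
            summary[f"C_av_{key}"] = float(C_av[sel][-1])
            try:
                summary[f"R_av_{key}"] = r_av(
                    times[sel], R[sel], protocol.T_s, t1)
            except ValueError:
                summary[f"R_av_{key}"] = float("nan")
    if schedule.kindling > 0 and not skip_to_cr:
        t0, t1 = phase_bounds["kindling"]
        win = (max(t0, t1 - 5000.0), t1)
        rates, _ = firing_rates(trains, win)
        summary["mean_rate_kindling_end"] = float(np.mean(rates))
        sel = times <= t1
        if sel.any():
            summary["C_av_kindling_end"] = float(C_av[sel][-1])

    provenance = {
        "params": vars(params).copy(),
        "stdp": vars(stdp).copy(),
        "protocol": (None if protocol is None else
                     {k: (list(v) if isinstance(v, tuple) else v)
                      for k, v in vars(protocol).items()}),
        "schedule": vars(schedule).copy(),
        "integration": vars(cfg).copy(),
    }
    return SimulationResult(
        times=times, C_av=C_av, R=R, spike_times=spike_times,
        spike_neurons=spike_neurons, phase_bounds=phase_bounds,
        snapshots=snapshots, summary=summary, provenance=provenance,
    )


def firing_rates(spike_trains, window):
    """Per-neuron firing rates (Hz) over ``window = (t0, t1)`` ms and their
    network mean/standard deviation."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty window")
    span_s = (t1 - t0) / 1000.0
    rates = np.array([
        np.count_nonzero((tr >= t0) & (tr < t1)) / span_s
        if len(tr) else 0.0
        for tr in spike_trains
    ])
    return rates, {"mean": float(rates.mean()), "std": float(rates.std())}
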