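"""Asymmetric spike-timing-dependent plasticity with event-driven updates.

Every weight update is triggered by a spike.  When neuron ``k`` fires at time
``t`` the weights of its incoming connections are updated using the timing of
the most recent spike of each presynaptic partner (nearest-spike pairing,
``dt = t - t_j >= 0``, potentiation branch of the kernel) and the weights of
its outgoing connections using the most recent spike of each postsynaptic
partner (``dt = t_i - t < 0``, depression branch).  Excitatory connections add
the increment ``delta * dc``; inhibitory connections subtract it.  Weights are
clipped to ``[c_min, c_max]`` after every update and the diagonal stays zero.

Nearest-spike pairing is a deliberate modelling choice (each spike pairs with
the single most recent partner spike, keeping per-event work and state
bounded); an all-pairs-within-window variant can be had by replaying
:func:`stdp_oracle` with a custom pairing, but the simulator uses
nearest-spike throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_model import CouplingProfile, NetworkState

__all__ = ["STDPParams", "SpikeEvent", "stdp_increment", "apply_spike_update",
           "stdp_oracle"]


@dataclass
class STDPParams:
    """Constants of the plasticity kernel.

    ``beta_1/gamma_1`` shape the potentiation branch, ``beta_2/gamma_2`` the
    depression branch, ``tau`` (ms) sets the overall time window, ``delta`` is
    the learning rate and ``c_min/c_max`` the hard weight bounds (mS/cm^2).
    The depression amplitude is 16x the potentiation amplitude, so moderate
    negative lags dominate positive ones of equal size.
    """

    beta_1: float = 1.0
    beta_2: float = 16.0
    gamma_1: float = 0.12
    gamma_2: float = 0.15
    tau: float = 14.0
    delta: float = 0.002
    c_min: float = 0.0
    c_max: float = 1.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.c_min >= self.c_max:
            raise ValueError("require c_min < c_max")


@dataclass
class SpikeEvent:
    """A spike of ``neuron`` (1-based index) at ``time`` ms."""

    neuron: int
    time: float


def stdp_increment(dt, p: STDPParams = STDPParams()):
    """STDP kernel value for post-minus-pre lag ``dt`` (ms), before the learning rate.

    ``dt >= 0`` (pre before post, or coincident): ``beta_1 exp(-dt/(gamma_1 tau))``.
    ``dt < 0`` (post before pre): ``beta_2 (dt/tau) exp(dt/(gamma_2 tau))``,
    which is negative.  Both branches decay to zero at large |dt|.
    """
    dt = np.asarray(dt, dtype=float)
    if not np.all(np.isfinite(dt)):
        raise ValueError("spike-time difference must be finite")
    pot = p.beta_1 * np.exp(-dt / (p.gamma_1 * p.tau))
    dep = p.beta_2 * (dt / p.tau) * np.exp(dt / (p.gamma_2 * p.tau))
    out = np.where(dt >= 0, pot, dep)
    return float(out) if out.ndim == 0 else out


def apply_spike_update(event: SpikeEvent, state: NetworkState,
                       profile: CouplingProfile, p: STDPParams) -> np.ndarray:
    """Apply the event-driven weight updates triggered by one spike, in place.

    Uses (and then records into) ``state.last_spike_times``.  Raises if the
    event predates recorded history (non-causal update).  Returns ``state.c``.
    """
    k = event.neuron - 1
    if not 0 <= k < state.N:
        raise IndexError("neuron index out of range")
    last = state.last_spike_times
    recorded = np.isfinite(last)
    if recorded.any() and event.time < last[recorded].max():
        raise ValueError("spike event earlier than recorded history")

    c = state.c
    sgn = profile.sign
    partners = recorded.copy()
    partners[k] = False

    # incoming k <- j : dt = t - t_j >= 0 (potentiation branch)
    j = np.nonzero(partners)[0]
    if j.size:
        dc = stdp_increment(event.time - last[j], p)
        c[k, j] = np.clip(c[k, j] + sgn[k, j] * p.delta * dc, p.c_min, p.c_max)
        # outgoing i <- k : dt = t_i - t < 0 strictly (depression branch);
        # dt == 0 (simultaneous) is handled by the other neuron's incoming update
        neg = last[j] < event.time
        i = j[neg]
        if i.size:
            dc = stdp_increment(last[i] - event.time, p)
            c[i, k] = np.clip(c[i, k] + sgn[i, k] * p.delta * dc, p.c_min, p.c_max)

    last[k] = event.time
    return c


def stdp_oracle(spike_trains, c0: np.ndarray, profile: CouplingProfile,
                p: STDPParams) -> np.ndarray:
    """Brute-force reference: replay all spikes in global time order.

    ``spike_trains`` is a sequence of per-neuron spike-time lists (index 0 =
    neuron 1).  For every spike, the most recent earlier spike of each partner
    is looked up directly in the full trains (no incremental history), the same
    nearest-spike pairing rule as :func:`apply_spike_update`.  Test-only
    reference implementation; returns the final weight matrix.
    """
    N = c0.shape[0]
    trains = [np.sort(np.asarray(tr, dtype=float)) for tr in spike_trains]
    events = sorted(
        ((t, j) for j, tr in enumerate(trains) for t in tr),
        key=lambda e: (e[0], e[1]),
    )
    c = c0.copy()
    sgn = profile.sign
    for t, k in events:
        for j in range(N):
            if j == k:
                continue
            # most recent spike of j at or before t, excluding j's own spike
            # at exactly t only if j fires at t and is ordered after k
            idx = np.searchsorted(trains[j], t, side="right") - 1
            while idx >= 0 and trains[j][idx] == t and (j > k):
                idx -= 1  # j's simultaneous spike not yet "recorded"
            if idx < 0:
                continue
            tj = trains[j][idx]
            dc_in = stdp_increment(t - tj, p)
            c[k, j] = np.clip(c[k, j] + sgn[k, j] * p.delta * dc_in,
                              p.c_min, p.c_max)
            if tj < t:
                dc_out = stdp_increment(tj - t, p)
                c[j, k] = np.clip(c[j, k] + sgn[j, k] * p.delta * dc_out,
                                  p.c_min, p.c_max)
    np.fill_diagonal(c, np.diag(c0))
    return c
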