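"""Coordinated Reset (CR) stimulation: sequences, timing, currents.

CR stimulation delivers phase-resetting stimuli through ``N_s`` equidistant
sites (default: neurons 25, 75, 125, 175 on the 200-neuron ring).  Within one
ON cycle of length ``T_s`` each site is activated exactly once, for one slot of
length ``T_s/N_s``; the activation order is the *sequence*.  RVS draws a fresh
random permutation every ON cycle; SVS-l repeats each random permutation for
``l`` consecutive ON cycles before switching.  ON cycles come in blocks of
``m`` followed by ``n`` silent OFF cycles (default 3:2).

Each activation evokes a normalized alpha-function conductance
``G_stim(t) = ((t-t_k)/tau_stim) exp(-(t-t_k)/tau_stim)`` with time-to-peak
``tau_stim = T_s/(6 N_s)``, spread over the ring by the quadratic decay profile
``D(i, x_k) = 1/(1 + d^2 (i-x_k)^2 / sigma_d^2)``.  The total current into
neuron ``i`` is ``F_i = (V_r - V_i) K sum_k D(i, x_k) rho_k(t) G_stim(t)``.

Slot windows are half-open ``[start, end)`` so exactly one site is active at
any ON instant; OFF cycles have no active site.  Sequence draws are indexed by
the global ON-cycle ordinal, so OFF cycles do not consume sequences.  Onsets
sit deterministically on the slot grid; the only randomness is the sequence
stream, reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network_model import NetworkState

__all__ = [
    "CRProtocol", "rvs_stream", "svs_stream", "sequence_stream", "onoff_cycle",
    "indicator", "gstim", "spatial_profile", "stimulation_current",
    "decay_matrix", "active_site",
]


@dataclass
class CRProtocol:
    """One CR stimulation protocol.

    ``T_s`` is the cycle period in ms, ``K`` the dimensionless intensity,
    ``mode`` either ``"rvs"`` or ``"svs"`` (with ``l`` repetitions per
    sequence), ``m:n`` the ON:OFF cycle ratio and ``seed`` the sequence-stream
    seed.  ``site_positions`` are 1-based neuron indices.
    """

    T_s: float
    K: float
    mode: str = "rvs"
    l: int = 100
    N_s: int = 4
    site_positions: tuple = (25, 75, 125, 175)
    m: int = 3
    n: int = 2
    V_r_stim: float = 20.0
    sigma_d: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        self.mode = self.mode.lower()
        if self.mode not in ("rvs", "svs"):
            raise ValueError("mode must be 'rvs' or 'svs'")
        if self.T_s <= 0:
            raise ValueError("T_s must be positive")
        if self.K < 0:
            raise ValueError("K must be non-negative")
        if self.l < 1:
            raise ValueError("l must be at least 1")
        if self.m < 0 or self.n < 0:
            raise ValueError("m, n must be non-negative")
        if len(set(self.site_positions)) != self.N_s:
            raise ValueError("site positions must be N_s distinct indices")

    @property
    def tau_stim(self) -> float:
        """Time-to-peak of the alpha function, T_s/(6 N_s) ms."""
        return self.T_s / (6.0 * self.N_s)

    @property
    def slot(self) -> float:
        """Duration of one site-activation slot, T_s/N_s ms."""
        return self.T_s / self.N_s


def rvs_stream(seed: int, N_s: int, count: int) -> np.ndarray:
    """Rapidly varying sequences: one independent uniform random permutation
    of the site indices ``1..N_s`` per ON cycle.  Shape ``(count, N_s)``."""
    if N_s < 1:
        raise ValueError("N_s must be at least 1")
    rng = np.random.default_rng(seed)
    out = np.empty((count, N_s), dtype=np.int64)
    for r in range(count):
        out[r] = rng.permutation(N_s) + 1
    return out


def svs_stream(seed: int, N_s: int, l: int, count: int) -> np.ndarray:
    """Slowly varying sequences: each random permutation occupies exactly ``l``
    consecutive ON cycles before the next draw.  Shape ``(count, N_s)``."""
    if l < 1:
        raise ValueError("l must be at least 1")
    n_blocks = math.ceil(count / l) if count else 0
    blocks = rvs_stream(seed, N_s, n_blocks)
    return np.repeat(blocks, l, axis=0)[:count]


def sequence_stream(protocol: CRProtocol, count: int) -> np.ndarray:
    """The protocol's sequence stream, one row per global ON-cycle ordinal."""
    if protocol.mode == "rvs":
        return rvs_stream(protocol.seed, protocol.N_s, count)
    return svs_stream(protocol.seed, protocol.N_s, protocol.l, count)


def onoff_cycle(t: float, T_s: float, m: int, n: int):
    """Phase descriptor at time ``t`` (ms from stimulation onset).

    Returns ``(is_on, on_ordinal)``: the schedule is periodic with period
    ``(m+n) T_s``, ON for the first ``m`` cycles of each block; ``on_ordinal``
    counts completed ON cycles globally (it indexes the sequence stream) and is
    ``None`` during OFF cycles.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    block = (m + n) * T_s
    b, r = divmod(t, block)
    cyc = int(r // T_s)
    if cyc < m:
        return True, int(b) * m + cyc
    return False, None


def indicator(t: float, site: int, protocol: CRProtocol,
              stream: np.ndarray) -> int:
    """Indicator rho_k(t): 1 iff ``site`` (1-based) is active at ``t``."""
    return int(active_site(t, protocol, stream)[0] == site)


def active_site(t: float, protocol: CRProtocol, stream: np.ndarray):
    """The active site and its activation onset at time ``t``.

    Returns ``(site, onset_ms)`` with ``site`` a 1-based site index, or
    ``(0, nan)`` during OFF cycles.  Raises if the stream does not cover the
    ON-cycle ordinal at ``t``.
    """
    is_on, ordinal = onoff_cycle(t, protocol.T_s, protocol.m, protocol.n)
    if not is_on:
        return 0, math.nan
    if ordinal >= len(stream):
        raise IndexError("sequence stream exhausted")
    within = t % protocol.T_s
    p = min(int(within // protocol.slot), protocol.N_s - 1)
    onset = t - (within - p * protocol.slot)
    return int(stream[ordinal, p]), onset


def gstim(t: float, t_k: float, tau_stim: float) -> float:
    """Normalized alpha-function conductance of an activation with onset ``t_k``.

    ``((t - t_k)/tau_stim) exp(-(t - t_k)/tau_stim)``; zero at onset, maximum
    ``1/e`` at ``t = t_k + tau_stim``.
    """
    if t < t_k:
        raise ValueError("t must not precede the activation onset")
    u = (t - t_k) / tau_stim
    return u * math.exp(-u)


def spatial_profile(i, x_k, d: float, sigma_d: float):
    """Quadratic spatial decay ``1/(1 + d^2 (i - x_k)^2 / sigma_d^2)``.

    Equals 1 at the site and is symmetric in ``i - x_k`` (lattice index
    difference, not the ring metric, matching the stimulus spread model).
    """
    i = np.asarray(i, dtype=float)
    out = 1.0 / (1.0 + (d * (i - x_k)) ** 2 / sigma_d**2)
    return float(out) if out.ndim == 0 else out


def decay_matrix(protocol: CRProtocol, N: int, d: float) -> np.ndarray:
    """Decay profiles of all sites, shape ``(N_s, N)`` (0-based neuron axis)."""
    idx = np.arange(1, N + 1)
    return np.stack([
        spatial_profile(idx, x_k, d, protocol.sigma_d)
        for x_k in protocol.site_positions
    ])


def stimulation_current(state: NetworkState, t: float, protocol: CRProtocol,
                        stream: np.ndarray, d: float) -> np.ndarray:
    """Total stimulation current ``F_i`` at time ``t`` (ms from stim onset).

    ``F_i = (V_r - V_i) K D(i, x_k) G_stim(t)`` for the single active site
    ``k``; identically zero during OFF cycles or when ``K = 0``.
    """
    F = np.zeros(state.N)
    if protocol.K == 0:
        return F
    site, onset = active_site(t, protocol, stream)
    if site == 0:
        return F
    x_k = protocol.site_positions[site - 1]
    D = spatial_profile(np.arange(1, state.N + 1), x_k, d, protocol.sigma_d)
    g = gstim(t, onset, protocol.tau_stim)
    return (protocol.V_r_stim - state.V) * protocol.K * D * g
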