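"""Hodgkin-Huxley ring network: geometry, coupling, dynamics primitives.

The network places ``N`` conductance-based Hodgkin-Huxley neurons on a ring of
physical length ``d_0`` and couples them through chemical synapses whose spatial
profile is a Mexican hat of the ring distance: strong short-range excitation,
weak long-range inhibition.  Each synapse carries a plastic weight ``c_ij`` in
[0, 1]; the sign (excitatory/inhibitory) of a connection is fixed by the sign
of the spatial profile and determines its reversal potential (20 mV / -40 mV).

Public indexing convention: neurons are 1-based ``1..N`` (so the default
stimulation sites sit at neurons 25, 75, 125, 175).  Internally all arrays are
0-based numpy arrays; the translation happens only at the public index-taking
functions (:func:`ring_distance`, site positions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "NetworkParams",
    "NetworkState",
    "CouplingProfile",
    "ring_distance",
    "mexican_hat",
    "build_coupling",
    "hh_rates",
    "psp_derivative",
    "synaptic_input",
    "init_network",
    "save_state",
    "load_state",
]

#: half-width of the window around a removable singularity of the HH rate
#: functions inside which the analytic limit is substituted (mV)
_SINGULARITY_TOL = 1e-7


@dataclass
class NetworkParams:
    """Model constants of the ring network.

    Units follow the conductance-based convention: conductances in mS/cm^2,
    potentials in mV, capacitance in uF/cm^2, drive currents in uA/cm^2.
    """

    N: int = 200
    g_Na: float = 120.0
    g_K: float = 36.0
    g_l: float = 0.3
    V_Na: float = 50.0
    V_K: float = -77.0
    V_l: float = -54.4
    C_m: float = 1.0
    I_0: float = 11.0
    sigma_I: float = 0.45
    mu_c: float = 0.5
    sigma_c: float = 0.01
    d_0: float = 10.0
    sigma_1: float = 3.5
    sigma_2: float = 2.0
    V_r_exc: float = 20.0
    V_r_inh: float = -40.0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be at least 2")
        if min(self.g_Na, self.g_K, self.g_l) <= 0:
            raise ValueError("conductances must be positive")
        if not (self.sigma_1 > self.sigma_2 > 0):
            raise ValueError("require sigma_1 > sigma_2 > 0")
        if not (0 <= self.sigma_I < self.I_0):
            raise ValueError("require 0 <= sigma_I < I_0")
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")

    @property
    def d(self) -> float:
        """Lattice spacing between neighbouring neurons, d_0/(N-1)."""
        return self.d_0 / (self.N - 1)


@dataclass
class NetworkState:
    """Dynamical variables of the network at time ``t`` (ms).

    ``c`` is the full N x N weight matrix with ``c[i, j]`` the weight of the
    connection j -> i (0-based); the diagonal is identically zero (no
    self-connections).  ``last_spike_times`` holds the most recent spike onset
    of each neuron in ms, ``-inf`` for neurons that have not spiked.
    """

    V: np.ndarray
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    s: np.ndarray
    I: np.ndarray
    c: np.ndarray
    last_spike_times: np.ndarray = field(default=None)  # type: ignore[assignment]
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.last_spike_times is None:
            self.last_spike_times = np.full(self.V.shape[0], -np.inf)

    @property
    def N(self) -> int:
        return self.V.shape[0]

    def copy(self) -> "NetworkState":
        return NetworkState(
            V=self.V.copy(), m=self.m.copy(), h=self.h.copy(), n=self.n.copy(),
            s=self.s.copy(), I=self.I.copy(), c=self.c.copy(),
            last_spike_times=self.last_spike_times.copy(), t=self.t,
        )

    def validate(self, tol: float = 1e-9) -> None:
        """Raise if a state invariant is violated beyond ``tol``."""
        for name in ("m", "h", "n", "s"):
            x = getattr(self, name)
            if x.min() < -tol or x.max() > 1 + tol:
                raise ValueError(f"gating/PSP variable {name} left [0, 1]")
        if self.c.min() < -tol or self.c.max() > 1 + tol:
            raise ValueError("weights left [0, 1]")
        if np.abs(np.diag(self.c)).max() > tol:
            raise ValueError("non-zero self-connection weight")


@dataclass
class CouplingProfile:
    """Spatial coupling profile of the ring.

    ``M`` is the signed Mexican-hat profile matrix, ``sign = sgn(M)`` fixes the
    excitatory/inhibitory class of each connection for the whole run, and
    ``V_r`` holds the per-connection reversal potential implied by that class.
    """

    M: np.ndarray
    sign: np.ndarray
    V_r: np.ndarray

    @property
    def abs_M(self) -> np.ndarray:
        return np.abs(self.M)


def ring_distance(i, j, N: int, d_0: float):
    """Distance between neurons ``i`` and ``j`` (1-based) on the ring.

    Equals ``d * min(|i-j|, N-|i-j|)`` with lattice spacing ``d = d_0/(N-1)``,
    i.e. the shorter arc; symmetric, and zero iff ``i == j``.
    """
    i = np.asarray(i)
    j = np.asarray(j)
    if np.any((i < 1) | (i > N) | (j < 1) | (j > N)):
        raise IndexError(f"neuron indices must lie in 1..{N}")
    steps = np.abs(i - j)
    steps = np.minimum(steps, N - steps)
    out = (d_0 / (N - 1)) * steps
    return float(out) if out.ndim == 0 else out


def mexican_hat(dist, sigma_1: float, sigma_2: float):
    """Mexican-hat coupling weight ``(1 - dist^2/sigma_1^2) exp(-dist^2/(2 sigma_2^2))``.

    Positive (excitatory) for ``dist < sigma_1``, zero at ``sigma_1``, negative
    (inhibitory) beyond.
    """
    dist = np.asarray(dist, dtype=float)
    if np.any(dist < 0):
        raise ValueError("distance must be non-negative")
    out = (1.0 - dist**2 / sigma_1**2) * np.exp(-(dist**2) / (2.0 * sigma_2**2))
    return float(out) if out.ndim == 0 else out


def build_coupling(params: NetworkParams) -> CouplingProfile:
    """Build the ring's spatial profile matrix and connection classes.

    ``M[i, j] = mexican_hat(ring_distance(i+1, j+1))`` (0-based storage); the
    per-connection reversal potential is ``V_r_exc`` where ``M > 0`` and
    ``V_r_inh`` where ``M < 0``.  The diagonal of ``M`` is 1 (distance zero) but
    never enters the dynamics because ``c_ii = 0``.
    """
    idx = np.arange(1, params.N + 1)
    dist = ring_distance(idx[:, None], idx[None, :], params.N, params.d_0)
    M = mexican_hat(dist, params.sigma_1, params.sigma_2)
    sign = np.sign(M)
    V_r = np.where(M >= 0, params.V_r_exc, params.V_r_inh)
    return CouplingProfile(M=M, sign=sign, V_r=V_r)


def hh_rates(V):
    """The six Hodgkin-Huxley rate functions at membrane potential ``V`` (mV).

    Returns ``(alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n)`` in 1/ms.
    The removable singularities of alpha_m (V = -40) and alpha_n (V = -55) are
    replaced by their analytic limits (1.0 and 0.1) within a 1e-7 mV window.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    scalar = V.ndim == 0
    V = np.atleast_1d(V)

    with np.errstate(divide="ignore", invalid="ignore"):
        u = 0.1 * V + 4.0
        alpha_m = np.where(
            np.abs(V + 40.0) < _SINGULARITY_TOL, 1.0, u / (1.0 - np.exp(-u))
        )
        w = 0.1 * V + 5.5
        alpha_n = np.where(
            np.abs(V + 55.0) < _SINGULARITY_TOL, 0.1, 0.1 * w / (1.0 - np.exp(-w))
        )
    beta_m = 4.0 * np.exp(-(V + 65.0) / 18.0)
    alpha_h = 0.07 * np.exp(-(V + 65.0) / 20.0)
    beta_h = 1.0 / (1.0 + np.exp(-0.1 * V - 3.5))
    beta_n = 0.125 * np.exp(-(V + 65.0) / 80.0)

    out = (alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n)
    if scalar:
        return tuple(float(x[0]) for x in out)
    return out


def psp_derivative(s, V):
    """Time derivative of the postsynaptic-potential variable ``s``.

    ``ds/dt = 0.5 (1 - s) / (1 + exp(-(V + 5)/12)) - 2 s`` with ``V`` the
    presynaptic membrane potential.  Maps [0, 1] into itself: the rise term
    vanishes at ``s = 1`` and the decay term at ``s = 0``.
    """
    s = np.asarray(s, dtype=float)
    V = np.asarray(V, dtype=float)
    out = 0.5 * (1.0 - s) / (1.0 + np.exp(-(V + 5.0) / 12.0)) - 2.0 * s
    return float(out) if out.ndim == 0 else out


def synaptic_input(state: NetworkState, profile: CouplingProfile) -> np.ndarray:
    """Per-neuron synaptic current ``S_i`` (uA/cm^2).

    ``S_i = N^-1 sum_j (V_r,j - V_i) c_ij |M_ij| s_j`` where the reversal
    potential of each connection follows its excitatory/inhibitory class.
    The self term is absent because ``c_ii = 0``.
    """
    if state.c.shape != profile.M.shape:
        raise ValueError("state and coupling profile dimensions disagree")
    W = state.c * profile.abs_M
    drive = (profile.V_r - state.V[:, None]) * W
    return drive @ state.s / state.N


def init_network(params: NetworkParams, seed: int) -> NetworkState:
    """Draw a random initial network state, reproducibly for a given seed.

    Draw order (documented for reproducibility): drive currents ``I_i`` uniform
    on [I_0 - sigma_I, I_0 + sigma_I]; ``V_i`` uniform on [-65, 5] mV; ``m, h,
    n, s`` uniform on [0, 1]; weights ``c_ij`` normal(mu_c, sigma_c) clipped to
    [0, 1] with zero diagonal.
    """
    rng = np.random.default_rng(seed)
    N = params.N
    I = rng.uniform(params.I_0 - params.sigma_I, params.I_0 + params.sigma_I, N)
    V = rng.uniform(-65.0, 5.0, N)
    m = rng.uniform(0.0, 1.0, N)
    h = rng.uniform(0.0, 1.0, N)
    n = rng.uniform(0.0, 1.0, N)
    s = rng.uniform(0.0, 1.0, N)
    c = rng.normal(params.mu_c, params.sigma_c, (N, N))
    np.clip(c, 0.0, 1.0, out=c)
    np.fill_diagonal(c, 0.0)
    return NetworkState(V=V, m=m, h=h, n=n, s=s, I=I, c=c)


def save_state(state: NetworkState, path, *, seed: int | None = None,
               config: dict | None = None) -> None:
    """Save a network state to an HDF5 container with named datasets."""
    with h5py.File(path, "w") as f:
        for name in ("V", "m", "h", "n", "s", "I", "c", "last_spike_times"):
            f.create_dataset(name, data=getattr(state, name))
        f.attrs["t"] = state.t
        if seed is not None:
            f.attrs["seed"] = seed
        for key, val in (config or {}).items():
            f.attrs[f"config/{key}"] = val


def load_state(path) -> NetworkState:
    """Load a network state previously written by :func:`save_state`."""
    with h5py.File(path, "r") as f:
        arrays = {
            name: f[name][...]
            for name in ("V", "m", "h", "n", "s", "I", "c", "last_spike_times")
        }
        t = float(f.attrs["t"])
    return NetworkState(t=t, **arrays)


def export_weights_csv(state: NetworkState, path) -> None:
    """Write the weight matrix as CSV (row i = postsynaptic neuron i, 1-based)."""
    np.savetxt(path, state.c, delimiter=",", fmt="%.8g")
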