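"""Macroscopic outcome measures: mean synaptic weight and synchrony.

Two scalars summarize the network state.  The sign-weighted mean synaptic
weight ``C_av = N^-2 sum_ij sgn(M_ij) c_ij`` tracks the balance of excitatory
versus inhibitory coupling strength (anti-kindling shows up as a drop of
``C_av``).  The Kuramoto order parameter ``R = |N^-1 sum_j exp(i phi_j)|``
measures in-phase spike synchrony, with ``phi_j`` the linearly interpolated
spike phase of neuron ``j``: 0 means no in-phase synchronization, 1 perfect
synchrony.

A neuron without a bracketing spike pair at a sample time has no defined
phase; such neurons are excluded from that sample's phasor mean (the number
of valid neurons per sample is available from
:func:`order_parameter_series` via ``return_counts``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "mean_synaptic_weight", "linear_phase", "order_parameter",
    "order_parameter_series", "r_av", "moving_average_R",
    "subpopulation_order_parameters",
]


def mean_synaptic_weight(c: np.ndarray, sign: np.ndarray) -> float:
    """``C_av = N^-2 sum_ij sgn(M_ij) c_ij`` (the diagonal contributes zero
    because ``c_ii = 0``)."""
    if c.shape != sign.shape:
        raise ValueError("weight and sign matrices must have equal shape")
    N = c.shape[0]
    return float(np.sum(sign * c) / N**2)


def linear_phase(spike_train, t: float) -> float:
    """Linearly interpolated phase ``phi_j(t)`` in [0, 2*pi).

    ``phi = 2 pi (t - t_m) / (t_{m+1} - t_m)`` for ``t_m <= t < t_{m+1}``;
    raises if ``t`` is not bracketed by two spikes of the train.
    """
    tr = np.asarray(spike_train, dtype=float)
    idx = np.searchsorted(tr, t, side="right") - 1
    if idx < 0 or idx >= len(tr) - 1:
        raise ValueError("t is not bracketed by two spikes of this neuron")
    return float(2.0 * np.pi * (t - tr[idx]) / (tr[idx + 1] - tr[idx]))


def order_parameter(phases) -> float:
    """Modulus of the mean unit phasor over the given phases."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("no valid phases")
    return float(np.abs(np.mean(np.exp(1j * phases))))


def _phasor_sums(spike_trains, times) -> tuple:
    """Complex phasor sum and valid-neuron count at each sample time,
    vectorized over the time axis; silent/unbracketed neurons are skipped."""
    times = np.asarray(times, dtype=float)
    z = np.zeros(times.shape, dtype=complex)
    counts = np.zeros(times.shape, dtype=np.int64)
    for tr in spike_trains:
        tr = np.asarray(tr, dtype=float)
        if len(tr) < 2:
            continue
        idx = np.searchsorted(tr, times, side="right") - 1
        valid = (idx >= 0) & (idx < len(tr) - 1)
        iv = idx[valid]
        phase = 2.0 * np.pi * (times[valid] - tr[iv]) / (tr[iv + 1] - tr[iv])
        z[valid] += np.exp(1j * phase)
        counts[valid] += 1
    return z, counts


def order_parameter_series(spike_trains, times) -> np.ndarray:
    """Order parameter R at each sample time; NaN where no neuron has a
    defined phase."""
    z, counts = _phasor_sums(spike_trains, times)
    with np.errstate(invalid="ignore"):
        R = np.abs(z) / counts
    R[counts == 0] = np.nan
    return R


def r_av(times, R, T_s: float, t_end: float) -> float:
    """Mean of the R samples over the trailing window ``[t_end - 100 T_s,
    t_end]`` (NaN samples from phase-less instants are ignored)."""
    times = np.asarray(times, dtype=float)
    R = np.asarray(R, dtype=float)
    t_lo = t_end - 100.0 * T_s
    if times.size == 0 or times[0] > t_lo + 1e-9:
        raise ValueError("series does not cover the averaging window")
    sel = (times >= t_lo) & (times <= t_end)
    if not sel.any():
        raise ValueError("no samples inside the averaging window")
    return float(np.nanmean(R[sel]))


def moving_average_R(times, R, T_s: float) -> np.ndarray:
    """Centered moving average <R> over a ``400 T_s`` window (edge windows
    truncated to the available samples), smoothing the strong fluctuations
    of the raw order parameter."""
    times = np.asarray(times, dtype=float)
    R = np.asarray(R, dtype=float)
    if times.size < 2:
        return R.copy()
    dt_sample = np.median(np.diff(times))
    win = max(1, int(round(400.0 * T_s / dt_sample)))
    return (
        pd.Series(R)
        .rolling(window=win, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def subpopulation_order_parameters(phases, site_positions, N: int) -> np.ndarray:
    """Order parameter of each site's receptive field.

    The ring is split into ``N_s`` contiguous blocks of ``N/N_s`` neurons
    centered on the equidistant sites (default geometry: neurons 1-50, 51-100,
    101-150, 151-200 for sites 25/75/125/175).  ``phases`` may contain NaN for
    neurons without a defined phase; those are excluded per block.
    """
    N_s = len(site_positions)
    if N % N_s != 0:
        raise ValueError("N must be divisible by the number of sites")
    block = N // N_s
    phases = np.asarray(phases, dtype=float)
    out = np.empty(N_s)
    for k, x_k in enumerate(sorted(site_positions)):
        lo = k * block  # 0-based start of the block centered on site x_k
        ph = phases[lo:lo + block]
        ph = ph[np.isfinite(ph)]
        out[k] = order_parameter(ph) if ph.size else np.nan
    return out
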