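"""Parameter sweeps over (K, T_s) and the descriptive/inferential statistics.

A sweep runs the four-phase protocol for every combination of stimulation
mode, intensity ``K``, period ``T_s`` and replicate network, and collects the
endpoint measures into a flat table (one record per cell x network).  Since
the kindling phase is independent of the stimulation parameters, each
replicate network is equilibrated and kindled exactly once and every grid
cell branches from that kindled snapshot — the same networks are stimulated
in every cell.

Descriptive statistics follow boxplot conventions: median, interpolated
quartiles, IQR, and 1.5 IQR outlier fences.  Two-sample comparisons use the
Wilcoxon rank-sum (Mann-Whitney U) test, exact for small tie-free samples.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cr_stimulation import CRProtocol
from .network_model import NetworkParams
from .plasticity import STDPParams
from .simulation import (IntegrationConfig, ProtocolSchedule, init_network,
                         run_phase, run_protocol)
from .network_model import build_coupling

__all__ = [
    "SweepSpec", "BoxplotStats", "frequency_ratio_conversion",
    "period_for_ratio", "run_sweep", "boxplot_stats", "rank_sum_test",
    "sample_size_estimate", "TABLE1_TS",
]

#: the standard stimulation-period grid (ms), an approximately equidistant
#: grid in frequency from 25% to 175% of the 62.5 Hz reference
TABLE1_TS = (64, 40, 29, 23, 19, 16, 14, 12, 11, 10, 9)

#: reference stimulation frequency (Hz), 1000 / (16 ms)
F_REF = 62.5

#: intrinsic firing frequency of the kindled network (Hz), 1000 / (14 ms)
F_INT = 1000.0 / 14.0


@dataclass
class SweepSpec:
    """Grid specification for a (mode, K, T_s) x replicate sweep."""

    K_values: tuple = (0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50)
    T_s_values: tuple = TABLE1_TS
    modes: tuple = ("rvs",)
    l: int = 100
    replicates: int = 11
    master_seed: int = 1000
    duration_scale: float = 1.0

    def __post_init__(self) -> None:
        if any(k < 0 for k in self.K_values):
            raise ValueError("K values must be non-negative")
        if any(ts <= 0 for ts in self.T_s_values):
            raise ValueError("T_s values must be positive")
        if self.replicates < 1:
            raise ValueError("at least one replicate network required")

    def network_seed(self, network_id: int) -> int:
        """Seed of replicate network ``network_id`` (0-based)."""
        return self.master_seed + network_id

    def stream_seed(self, network_id: int, mode: str, K: float,
                    T_s: float) -> int:
        """Sequence-stream seed; deterministic and distinct per network and
        grid cell (CRC32 of the cell key, independent of process state)."""
        key = f"{self.master_seed}|{network_id}|{mode}|{K:.6f}|{T_s:.6f}"
        return zlib.crc32(key.encode()) % (2**31 - 1)


_RECORD_COLS = ["mode", "K", "T_s", "network_id", "C_av_on_end",
                "R_av_on_end", "C_av_off_end", "R_av_off_end", "mean_rate"]


def run_sweep(spec: SweepSpec, *, params: NetworkParams | None = None,
              stdp: STDPParams | None = None,
              schedule: ProtocolSchedule | None = None,
              cfg: IntegrationConfig | None = None,
              out_csv=None, progress=None) -> pd.DataFrame:
    """Run the whole sweep; returns the endpoint table.

    If ``out_csv`` exists, completed records are loaded and skipped, making
    the sweep resumable and idempotent.  Individual-run failures are recorded
    (NaN endpoints) and the sweep continues.
    """
    params = params or NetworkParams()
    stdp = stdp or STDPParams()
    schedule = (schedule or ProtocolSchedule()).scaled(spec.duration_scale)
    cfg = cfg or IntegrationConfig()

    def _key(mode, K, T_s, net_id):
        return (str(mode), round(float(K), 9), round(float(T_s), 9),
                int(net_id))

    done = set()
    records = []
    if out_csv is not None and Path(out_csv).exists():
        prev = pd.read_csv(out_csv, float_precision="round_trip")
        records = prev.to_dict("records")
        done = {_key(r["mode"], r["K"], r["T_s"], r["network_id"])
                for r in records}

    profile = build_coupling(params)
    kindled = {}

    def _kindled_state(net_id):
        if net_id not in kindled:
            state = init_network(params, spec.network_seed(net_id))
            run_phase(state, profile, params, cfg, schedule.equilibration)
            _, cav, st, si = run_phase(state, profile, params, cfg,
                                       schedule.kindling, stdp=stdp)
            t1 = state.t
            trains = [st[si == i] for i in range(params.N)]
            span = min(5000.0, schedule.kindling) / 1000.0
            rate = float(np.mean([
                np.count_nonzero(tr >= t1 - span * 1000.0) / span
                for tr in trains
            ])) if schedule.kindling > 0 else float("nan")
            kindled[net_id] = (state, rate)
        return kindled[net_id]

    for mode in spec.modes:
        for K in spec.K_values:
            for T_s in spec.T_s_values:
                for net_id in range(spec.replicates):
                    key = _key(mode, K, T_s, net_id)
                    if key in done:
                        continue
                    if progress:
                        progress(key)
                    rec = dict(mode=mode, K=float(K), T_s=float(T_s),
                               network_id=net_id)
                    try:
                        base, rate = _kindled_state(net_id)
                        proto = CRProtocol(
                            T_s=float(T_s), K=float(K), mode=mode, l=spec.l,
                            seed=spec.stream_seed(net_id, mode, K, T_s))
                        res = run_protocol(
                            params, stdp, proto, schedule, cfg,
                            initial_state=base, skip_to_cr=True)
                        rec.update(
                            C_av_on_end=res.summary.get("C_av_on_end"),
                            R_av_on_end=res.summary.get("R_av_on_end"),
                            C_av_off_end=res.summary.get("C_av_off_end"),
                            R_av_off_end=res.summary.get("R_av_off_end"),
                            mean_rate=rate,
                        )
                    except (FloatingPointError, RuntimeError) as err:
                        rec.update({k: float("nan")
                                    for k in _RECORD_COLS[4:]})
                        rec["error"] = str(err)
                    records.append(rec)
                    if out_csv is not None:
                        pd.DataFrame(records).to_csv(out_csv, index=False,
                                                     float_format="%.17g")

    return pd.DataFrame(records)


def frequency_ratio_conversion(T_s: float, f_ref: float = F_REF) -> int:
    """Stimulation frequency as an integer percentage of ``f_ref``.

    ``r = (1000/T_s) / f_ref * 100`` rounded to the nearest integer percent
    (``T_s`` in ms, ``f_ref`` in Hz).
    """
    if T_s <= 0 or f_ref <= 0:
        raise ValueError("T_s and f_ref must be positive")
    return int(round((1000.0 / T_s) / f_ref * 100.0))


def period_for_ratio(r: float, f_ref: float = F_REF,
                     T_min: int = 1, T_max: int = 200) -> int:
    """Integer period T_s (ms) whose frequency ratio is closest to ``r`` %."""
    cand = np.arange(T_min, T_max + 1)
    ratios = (1000.0 / cand) / f_ref * 100.0
    return int(cand[np.argmin(np.abs(ratios - r))])


@dataclass
class BoxplotStats:
    """Median, interpolated quartiles, IQR, 1.5-IQR fences and outliers."""

    median: float
    Q1: float
    Q3: float
    IQR: float
    lower_fence: float
    upper_fence: float
    outliers: np.ndarray = field(default_factory=lambda: np.empty(0))


def boxplot_stats(values) -> BoxplotStats:
    """Boxplot summary of a sample.

    Quartiles use linear interpolation between order statistics (the numpy
    default); an outlier lies below ``Q1 - 1.5 IQR`` or above
    ``Q3 + 1.5 IQR``.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return BoxplotStats(
        median=float(med), Q1=float(q1), Q3=float(q3), IQR=float(iqr),
        lower_fence=float(lo), upper_fence=float(hi),
        outliers=np.sort(x[(x < lo) | (x > hi)]),
    )


def rank_sum_test(sample_a, sample_b, alternative: str = "two-sided"):
    """Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact small-sample null when both samples have at most 12 observations
    and the pooled data are tie-free; normal approximation (with tie
    correction) otherwise.  Returns ``(statistic, p_value)``.  Degenerate
    all-tied inputs are rejected.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        raise ValueError("degenerate samples: all observations tied")
    exact = (a.size <= 12 and b.size <= 12
             and np.unique(pooled).size == pooled.size)
    res = sps.mannwhitneyu(a, b, alternative=alternative,
                           method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def sample_size_estimate(alpha_s: float, beta_s: float, sd: float,
                         delta_s: float, dist: str = "normal") -> int:
    """Rough sample-size estimate for detecting a location shift.

    ``n = ceil((x_{1-alpha/2} + x_{1-beta})^2 (sd/delta)^2)`` with ``x`` the
    normal quantile function by default; with ``dist="t"`` Student-t
    quantiles are iterated (df = n - 1) to a fixed point.  ``sd`` is the
    (assumed) standard deviation and ``delta_s`` the shift to detect.
    """
    if not (0 < alpha_s < 1 and 0 < beta_s < 1):
        raise ValueError("alpha_s and beta_s must lie in (0, 1)")
    if sd <= 0 or delta_s <= 0:
        raise ValueError("sd and delta_s must be positive")
    ratio2 = (sd / delta_s) ** 2

    def _n(quantile):
        x1 = quantile(1 - alpha_s / 2)
        x2 = quantile(1 - beta_s)
        return max(1, math.ceil((x1 + x2) ** 2 * ratio2))

    if dist == "normal":
        return _n(sps.norm.ppf)
    if dist == "t":
        n = _n(sps.norm.ppf)
        for _ in range(100):
            df = max(n - 1, 1)
            n_new = _n(lambda q: sps.t.ppf(q, df))
            if n_new == n:
                return n
            n = n_new
        return n
    raise ValueError("dist must be 'normal' or 't'")
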