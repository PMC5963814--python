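"""Numba-compiled fixed-step integration core.

One kernel call advances a whole protocol phase: 4th-order Runge-Kutta on the
5N-dimensional state, upward-crossing spike detection with linear
interpolation and a refractory guard, event-driven STDP updates, CR
stimulation currents and recording of the sign-weighted mean synaptic weight.

Numerical layout (see docs/methods.md):

* The presynaptic-conductance matrix-vector products ``Wp @ s`` (excitatory)
  and ``Wm @ s`` (inhibitory) are computed once per step from the step-start
  PSP variables and held across the four RK4 stages; the driving-force factors
  ``(V_r - V_i)`` use the stage-local membrane potential.
* The active stimulation site and its onset are resolved once per step by
  exact integer arithmetic on the step index (the step size divides the slot
  length); the alpha-function conductance is evaluated at each stage time.
* HH rate functions are evaluated either from a dense lookup table
  (0.02 mV grid, linear interpolation; ``use_table=1``) or from the exact
  exponential formulas (``use_table=0``).  The table error is below 1e-5 1/ms,
  far under the RK4 truncation error at the default step.

Status codes returned by the kernel: 0 ok, 1 numerical blow-up (|V| > 200 mV),
2 spike buffer overflow.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .network_model import hh_rates

#: table grid (mV); covers every potential short of the blow-up guard
TABLE_V_MIN = -210.0
TABLE_V_MAX = 210.0
TABLE_DV = 0.02

_RATE_TABLE: np.ndarray | None = None


def rate_table() -> np.ndarray:
    """Lazily built lookup table, shape (n_grid, 8).

    Columns: alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n, PSP rise rate
    ``0.5/(1+exp(-(V+5)/12))``, padding.
    """
    global _RATE_TABLE
    if _RATE_TABLE is None:
        V = np.arange(TABLE_V_MIN, TABLE_V_MAX + TABLE_DV / 2, TABLE_DV)
        am, bm, ah, bh, an, bn = hh_rates(V)
        rise = 0.5 / (1.0 + np.exp(-(V + 5.0) / 12.0))
        _RATE_TABLE = np.ascontiguousarray(
            np.stack([am, bm, ah, bh, an, bn, rise, np.zeros_like(V)], axis=1)
        )
    return _RATE_TABLE


@njit(cache=True, inline="always")
def _rates_exact(v):
    if abs(v + 40.0) < 1e-7:
        am = 1.0
    else:
        u = 0.1 * v + 4.0
        am = u / (1.0 - np.exp(-u))
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-0.1 * v - 3.5))
    if abs(v + 55.0) < 1e-7:
        an = 0.1
    else:
        w = 0.1 * v + 5.5
        an = 0.1 * w / (1.0 - np.exp(-w))
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    rise = 0.5 / (1.0 + np.exp(-(v + 5.0) / 12.0))
    return am, bm, ah, bh, an, bn, rise


@njit(cache=True, inline="always")
def _rates_table(v, table, inv_dv):
    u = (v - TABLE_V_MIN) * inv_dv
    i0 = int(u)
    if i0 < 0:
        i0 = 0
    nmax = table.shape[0] - 2
    if i0 > nmax:
        i0 = nmax
    f = u - i0
    r0 = table[i0]
    r1 = table[i0 + 1]
    g = 1.0 - f
    return (
        g * r0[0] + f * r1[0], g * r0[1] + f * r1[1],
        g * r0[2] + f * r1[2], g * r0[3] + f * r1[3],
        g * r0[4] + f * r1[4], g * r0[5] + f * r1[5],
        g * r0[6] + f * r1[6],
    )


@njit(cache=True)
def _run_phase(
    # state (modified in place)
    V, m, h, n, s, I, c, last,
    # coupling
    absM, sgn, Wp, Wm, Vr_exc, Vr_inh,
    # membrane constants
    gNa, gK, gl, VNa, VK, Vl, Cm,
    # integration
    t0, n_steps, dt,
    # rates
    table, use_table,
    # plasticity (active if stdp_on != 0)
    stdp_on, b1, b2, g1t, g2t, tau, delta, cmin, cmax,
    # stimulation (active if stim_on != 0); seq rows are ON-cycle ordinals
    stim_on, K, seq, D, Vr_stim, tau_stim, steps_per_Ts, slot_steps,
    m_on, n_off,
    # spike detection
    thr, refract,
    # recording buffers
    rec_stride, rec_t, rec_cav, spike_t, spike_i,
):
    N = V.shape[0]
    inv_dv = 1.0 / TABLE_DV
    NN = float(N) * float(N)

    kV = np.empty((4, N)); km = np.empty((4, N)); kh = np.empty((4, N))
    kn = np.empty((4, N)); ks = np.empty((4, N))
    Vst = np.empty(N); mst = np.empty(N); hst = np.empty(N)
    nst = np.empty(N); sst = np.empty(N)
    V_prev = np.empty(N)
    ev_i = np.empty(N, dtype=np.int64)
    ev_t = np.empty(N)

    # sign-weighted weight sum for C_av recording, resynced periodically
    cav_sum = 0.0
    for i in range(N):
        for j in range(N):
            cav_sum += sgn[i, j] * c[i, j]
    resync = 20000

    rec_count = 0
    spk_count = 0
    spk_cap = spike_t.shape[0]
    status = 0

    for step in range(n_steps):
        t = t0 + step * dt

        # presynaptic conductance drives, frozen across the four stages
        P = np.dot(Wp, s)
        Q = np.dot(Wm, s)

        # active stimulation slot for this step (exact integer arithmetic)
        site = -1
        t_off0 = 0.0
        if stim_on != 0 and K > 0.0:
            cyc = step // steps_per_Ts
            bpos = cyc % (m_on + n_off)
            if bpos < m_on:
                ordinal = (cyc // (m_on + n_off)) * m_on + bpos
                if ordinal < seq.shape[0]:
                    within = step % steps_per_Ts
                    p_slot = within // slot_steps
                    if p_slot >= seq.shape[1]:
                        p_slot = seq.shape[1] - 1
                    site = seq[ordinal, p_slot] - 1
                    t_off0 = (within - p_slot * slot_steps) * dt

        for stage in range(4):
            if stage == 0:
                for i in range(N):
                    Vst[i] = V[i]; mst[i] = m[i]; hst[i] = h[i]
                    nst[i] = n[i]; sst[i] = s[i]
                dto = 0.0
            elif stage == 1:
                for i in range(N):
                    Vst[i] = V[i] + 0.5 * dt * kV[0, i]
                    mst[i] = m[i] + 0.5 * dt * km[0, i]
                    hst[i] = h[i] + 0.5 * dt * kh[0, i]
                    nst[i] = n[i] + 0.5 * dt * kn[0, i]
                    sst[i] = s[i] + 0.5 * dt * ks[0, i]
                dto = 0.5 * dt
            elif stage == 2:
                for i in range(N):
                    Vst[i] = V[i] + 0.5 * dt * kV[1, i]
                    mst[i] = m[i] + 0.5 * dt * km[1, i]
                    hst[i] = h[i] + 0.5 * dt * kh[1, i]
                    nst[i] = n[i] + 0.5 * dt * kn[1, i]
                    sst[i] = s[i] + 0.5 * dt * ks[1, i]
                dto = 0.5 * dt
            else:
                for i in range(N):
                    Vst[i] = V[i] + dt * kV[2, i]
                    mst[i] = m[i] + dt * km[2, i]
                    hst[i] = h[i] + dt * kh[2, i]
                    nst[i] = n[i] + dt * kn[2, i]
                    sst[i] = s[i] + dt * ks[2, i]
                dto = dt

            g_stim = 0.0
            if site >= 0:
                u = (t_off0 + dto) / tau_stim
                g_stim = K * u * np.exp(-u)

            for i in range(N):
                v = Vst[i]
                if use_table != 0:
                    am, bm, ah, bh, an, bn, rise = _rates_table(v, table, inv_dv)
                else:
                    am, bm, ah, bh, an, bn, rise = _rates_exact(v)
                mi = mst[i]; hi = hst[i]; ni = nst[i]; si = sst[i]
                S = ((Vr_exc - v) * P[i] + (Vr_inh - v) * Q[i]) / N
                F = 0.0
                if site >= 0:
                    F = (Vr_stim - v) * g_stim * D[site, i]
                kV[stage, i] = (
                    I[i]
                    - gNa * mi * mi * mi * hi * (v - VNa)
                    - gK * ni * ni * ni * ni * (v - VK)
                    - gl * (v - Vl)
                    + S + F
                ) / Cm
                km[stage, i] = am * (1.0 - mi) - bm * mi
                kh[stage, i] = ah * (1.0 - hi) - bh * hi
                kn[stage, i] = an * (1.0 - ni) - bn * ni
                ks[stage, i] = rise * (1.0 - si) - 2.0 * si

        blowup = False
        for i in range(N):
            V_prev[i] = V[i]
            V[i] += dt / 6.0 * (kV[0, i] + 2.0 * kV[1, i] + 2.0 * kV[2, i] + kV[3, i])
            m[i] += dt / 6.0 * (km[0, i] + 2.0 * km[1, i] + 2.0 * km[2, i] + km[3, i])
            h[i] += dt / 6.0 * (kh[0, i] + 2.0 * kh[1, i] + 2.0 * kh[2, i] + kh[3, i])
            n[i] += dt / 6.0 * (kn[0, i] + 2.0 * kn[1, i] + 2.0 * kn[2, i] + kn[3, i])
            s[i] += dt / 6.0 * (ks[0, i] + 2.0 * ks[1, i] + 2.0 * ks[2, i] + ks[3, i])
            if V[i] > 200.0 or V[i] < -200.0 or V[i] != V[i]:
                blowup = True
        if blowup:
            status = 1
            return status, t + dt, rec_count, spk_count, cav_sum / NN

        # spike detection: strict upward crossing, linear interpolation,
        # refractory guard; events processed in ascending interpolated time
        n_ev = 0
        for i in range(N):
            if V_prev[i] < thr and V[i] > thr:
                ts = t + dt * (thr - V_prev[i]) / (V[i] - V_prev[i])
                if ts - last[i] >= refract:
                    ev_i[n_ev] = i
                    ev_t[n_ev] = ts
                    n_ev += 1
        # insertion sort by (time, neuron)
        for a in range(1, n_ev):
            ti = ev_t[a]; ii = ev_i[a]
            b = a - 1
            while b >= 0 and (ev_t[b] > ti or (ev_t[b] == ti and ev_i[b] > ii)):
                ev_t[b + 1] = ev_t[b]; ev_i[b + 1] = ev_i[b]
                b -= 1
            ev_t[b + 1] = ti; ev_i[b + 1] = ii

        for e in range(n_ev):
            k = ev_i[e]
            ts = ev_t[e]
            if stdp_on != 0:
                for j in range(N):
                    if j == k:
                        continue
                    lj = last[j]
                    dt_in = ts - lj
                    if dt_in > 500.0:  # kernel support exhausted (< 1e-100)
                        continue
                    sg = sgn[k, j]
                    if sg != 0.0:
                        dc = b1 * np.exp(-dt_in / g1t)
                        old = c[k, j]
                        new = old + sg * delta * dc
                        if new > cmax:
                            new = cmax
                        elif new < cmin:
                            new = cmin
                        if new != old:
                            c[k, j] = new
                            cav_sum += sg * (new - old)
                            w = new * absM[k, j]
                            if sg > 0.0:
                                Wp[k, j] = w
                            else:
                                Wm[k, j] = w
                    if lj < ts:
                        sg2 = sgn[j, k]
                        if sg2 != 0.0:
                            d_out = lj - ts
                            dc2 = b2 * (d_out / tau) * np.exp(d_out / g2t)
                            old = c[j, k]
                            new = old + sg2 * delta * dc2
                            if new > cmax:
                                new = cmax
                            elif new < cmin:
                                new = cmin
                            if new != old:
                                c[j, k] = new
                                cav_sum += sg2 * (new - old)
                                w = new * absM[j, k]
                                if sg2 > 0.0:
                                    Wp[j, k] = w
                                else:
                                    Wm[j, k] = w
            last[k] = ts
            if spk_count < spk_cap:
                spike_t[spk_count] = ts
                spike_i[spk_count] = k
                spk_count += 1
            else:
                status = 2
                return status, t + dt, rec_count, spk_count, cav_sum / NN

        if (step + 1) % resync == 0:
            cav_sum = 0.0
            for i in range(N):
                for j in range(N):
                    cav_sum += sgn[i, j] * c[i, j]

        if (step + 1) % rec_stride == 0 and rec_count < rec_t.shape[0]:
            rec_t[rec_count] = t + dt
            rec_cav[rec_count] = cav_sum / NN
            rec_count += 1

    return status, t0 + n_steps * dt, rec_count, spk_count, cav_sum / NN
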