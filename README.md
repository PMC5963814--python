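# crnet

Simulation of **Coordinated Reset (CR) stimulation** in a plastic spiking
network: 200 conductance-based Hodgkin–Huxley neurons on a ring with
Mexican-hat coupling (short-range excitation, long-range inhibition) and
asymmetric spike-timing-dependent plasticity (STDP). The package is for
computational neuroscientists studying desynchronizing brain stimulation —
in particular how the *stimulation frequency* (cycle period T_s) and
*intensity* (K) of CR stimulation determine whether a pathologically
synchronized, strongly coupled network is driven into a lasting
desynchronized, weakly coupled state (**anti-kindling**) or relapses after
stimulation ends.

## Model

Each neuron obeys the Hodgkin–Huxley equations

    C dV_i/dt = I_i − g_Na m_i³ h_i (V_i − V_Na) − g_K n_i⁴ (V_i − V_K)
                − g_l (V_i − V_l) + S_i + F_i

with heterogeneous drive I_i ~ U[I₀−σ_I, I₀+σ_I] (I₀ = 11.0, σ_I = 0.45
µA/cm²). Synaptic input is a weighted ensemble average of postsynaptic
currents,

    S_i = N⁻¹ Σ_j (V_r,j − V_i) c_ij |M_ij| s_j,

where the spatial profile M_ij = (1 − d_ij²/σ₁²) exp(−d_ij²/2σ₂²) is a
Mexican hat of the ring distance d_ij, the connection class (excitatory
V_r = 20 mV for M_ij > 0, inhibitory V_r = −40 mV for M_ij < 0) is fixed by
sign(M_ij), and the PSP variable s_j is driven by presynaptic spiking.
Weights c_ij ∈ [0, 1] evolve event-wise under the asymmetric STDP kernel

    Δc = β₁ e^(−Δt/γ₁τ)          for Δt ≥ 0   (potentiation)
    Δc = β₂ (Δt/τ) e^(Δt/γ₂τ)    for Δt < 0   (depression)

with β₁ = 1, β₂ = 16, γ₁ = 0.12, γ₂ = 0.15, τ = 14 ms and learning rate
δ = 0.002 (excitatory connections add δ·Δc, inhibitory subtract it).

CR stimulation delivers α-function current pulses
(time-to-peak τ_stim = T_s/6N_s) through N_s = 4 equidistant sites (neurons
25/75/125/175) with quadratic spatial decay; each site is activated exactly
once per ON cycle of length T_s, in an order (the *sequence*) that is
redrawn every cycle (**RVS**) or repeated l times before switching
(**SVS-l**). ON cycles run in 3:2 ON:OFF blocks.

Outcomes are the sign-weighted mean synaptic weight
C_av = N⁻² Σ sgn(M_ij) c_ij and the Kuramoto order parameter
R = |N⁻¹ Σ_j e^(iφ_j)| of linearly interpolated spike phases (R_av =
mean over the last 100·T_s).

The standard numerical experiment runs 2 s equilibration → 60 s kindling
(STDP only; the synchronized, strongly coupled baseline develops, firing at
~71 Hz) → 128 s CR-on → 128 s CR-off.

## Worked example

Kindle a network and stimulate with RVS CR at K = 0.20, T_s = 10 ms,
using quarter-length CR epochs (32 s on, 32 s off; ~3 minutes on one CPU):

```python
from crnet import (NetworkParams, STDPParams, CRProtocol, ProtocolSchedule,
                   IntegrationConfig, run_protocol)

params = NetworkParams()                    # 200 HH neurons, Mexican-hat ring
proto = CRProtocol(T_s=10.0, K=0.20, mode="rvs", seed=101)
schedule = ProtocolSchedule().scaled(0.25)  # 2 s + 60 s + 32 s on + 32 s off
res = run_protocol(params, STDPParams(), proto, schedule,
                   IntegrationConfig(seed=1))
print({k: round(v, 3) for k, v in res.summary.items()})
```

prints

```
{'C_av_on_end': -0.155, 'R_av_on_end': 0.347, 'C_av_off_end': -0.055,
 'R_av_off_end': 0.297, 'mean_rate_kindling_end': 71.621,
 'C_av_kindling_end': 0.178}
```

Reading: kindling produced a synchronized network firing at 71.6 Hz with
strong net coupling (C_av = 0.178). CR stimulation reversed the coupling
balance (C_av = −0.155 at stimulation end — the acute anti-kindling
effect), and 32 s after stimulation ceased the network remained weakly
coupled and desynchronized (C_av = −0.055, R_av = 0.30) — a long-lasting
after-effect. Running the same protocol with T_s = 64 ms instead leaves
the network kindled (C_av ≈ 0.19, R_av ≈ 0.85 after CR-off): the
stimulation frequency decides the outcome.

Parameter sweeps over (mode, K, T_s) × replicate networks, with boxplot
statistics and Wilcoxon rank-sum comparisons, are driven by
`crnet.run_sweep` or the CLI (`crnet sweep configs/full_sweep_rvs_svs.yaml`,
then `crnet stats` / `crnet compare` / `crnet heatmap`). The shipped config
is the full cluster-scale grid; reduce `replicates` and set
`duration_scale: 0.25` for desk-scale runs.

## Layout

- `crnet.network_model` — ring geometry, Mexican-hat coupling, HH rate
  functions, random initialization, HDF5 state I/O
- `crnet.plasticity` — STDP kernel, event-driven updates, brute-force
  replay oracle
- `crnet.cr_stimulation` — RVS/SVS sequence streams, ON/OFF cycling,
  indicator functions, α-function stimulus, spatial decay
- `crnet.simulation` — RK4 stepping (numba kernel), spike detection,
  four-phase protocol driver
- `crnet.measures` — C_av, spike phases, order parameter, window averages
- `crnet.experiments_stats` — sweeps, boxplot/rank-sum statistics,
  frequency-ratio conversions, sample-size estimate
- `docs/methods.md` — modelling and numerical choices in detail
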