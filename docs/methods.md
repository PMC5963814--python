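# Methods

## Model summary

The network is a ring of N = 200 conductance-based Hodgkin–Huxley neurons
(standard squid-axon rate functions, resting potential near −65 mV) with
constant depolarizing drives I_i drawn uniformly from [10.55, 11.45]
µA/cm², which makes the neurons non-identical tonic spikers at roughly
70–72 Hz. Coupling is chemical: a presynaptic PSP variable s_j (sigmoidal
rise during the spike, decay rate 2/ms) gates the current
(V_r,j − V_i)·c_ij·|M_ij|·s_j/N into neuron i.

The spatial profile M is a Mexican hat of the ring distance
d·min(|i−j|, N−|i−j|), d = d₀/(N−1), d₀ = 10, σ₁ = 3.5, σ₂ = 2.0: with the
default geometry every pair within 69 ring steps is excitatory
(V_r = 20 mV) and every more distant pair is weakly inhibitory
(V_r = −40 mV). The min-rule ring metric is applied to **all** pairs; the
profile is then symmetric and translation-invariant, which is the point of
placing the neurons on a ring (no boundary effects). Note the inhibitory
reversal potential of −40 mV is depolarizing below −40 mV, so "inhibition"
here mainly reduces net excitation rather than hyperpolarizing.

Weights c_ij ∈ [0, 1] (c_ii = 0, no self-connections) start from
N(0.5, 0.01) clipped to [0, 1] and evolve under event-driven STDP, with
kernel parameters β₁ = 1, β₂ = 16, γ₁ = 0.12, γ₂ = 0.15, τ = 14 ms,
δ = 0.002. The kernel exponents are Δt/(γ₁τ) and Δt/(γ₂τ): the lag is
normalized by the width-scaled plasticity time constant. The depression
lobe dominates at moderate lags (|Δc(−2 ms)| ≈ 0.88 vs Δc(+2 ms) ≈ 0.30),
so only tightly synchronized firing (lags ≲ 0.7 ms) potentiates on
balance; this is what makes both the synchronized/strongly-coupled and the
desynchronized/weakly-coupled configurations self-stabilizing, and CR
stimulation can switch the network from one to the other.

### STDP pairing scheme

Updates are event-driven with **nearest-spike pairing**: when neuron k
fires at t, every incoming weight c_kj updates with Δt = t − t_j ≥ 0 using
the most recent spike of j, and every outgoing weight c_ik updates with
Δt = t_i − t < 0 using the most recent spike of i (strictly earlier; a
coincident pair is handled once, through the potentiation branch of the
later-processed event, never twice). Excitatory weights add δ·Δc,
inhibitory weights subtract it — coincident firing *weakens* inhibitory
connections. All updates clip to [0, 1]. Simultaneous events within one
integration step are processed in ascending interpolated spike time. A
brute-force replay oracle (`stdp_oracle`) recomputes final weights from
complete spike trains without incremental state and is held equal to the
event stream in the tests (to 1e−12 on random instances and on network
runs).

## CR stimulation

Four stimulation sites sit at neurons 25/75/125/175. Within an ON cycle of
length T_s each site is active for one half-open slot [pT_s/4, (p+1)T_s/4)
— exactly one site active at any ON instant — in an order given by the
sequence stream: RVS draws an independent uniform permutation (of 4! = 24)
per ON cycle; SVS-l repeats each random permutation l times. The global
ON-cycle ordinal indexes the stream, so OFF cycles (2 per 3 ON, in 3:2
blocks) consume no sequences. Site activation evokes a normalized
α-function conductance with time-to-peak τ_stim = T_s/24, spread over the
lattice as 1/(1 + d²(i−x_k)²/σ_d²), σ_d = 0.8 (lattice index difference,
not the ring metric — the stimulus is a local field around the site). The
current is (20 mV − V_i)·K·D·G_stim. Onsets sit deterministically on the
slot grid; the sequence stream carries all randomness and is reproducible
from its seed. A CR-on epoch that ends mid-cycle is simply truncated.

## Numerical scheme

Fixed-step classical Runge–Kutta (RK4), default dt = 0.05 ms (0.01 ms
available), 1-based neuron indexing in the public interface, 0-based numpy
storage internally.

* **Coupling evaluation.** The two matrix–vector products (excitatory and
  inhibitory presynaptic conductance sums) are computed once per step from
  the step-start PSP variables and held across the four RK4 stages; the
  driving-force factors (V_r − V_i) and the stimulus conductance are
  evaluated per stage. This halves the dominant cost with no measurable
  accuracy loss: halving dt changes C_av after 1 s by < 1e−4 on the
  20-neuron test fixture (tolerance 1e−3).
* **Rate functions.** The production kernel evaluates the six HH rate
  functions and the PSP rise rate from a dense lookup table (0.02 mV grid,
  linear interpolation, absolute error < 1e−5 /ms), far below the RK4
  truncation error at dt = 0.05 ms; an exact-exponential kernel
  (`method="rk4-exact"`) is retained and the two agree within 0.05 mV over
  a 100 ms spiking trajectory. The removable singularities of α_m (−40 mV)
  and α_n (−55 mV) use their analytic limits within 1e−7 mV.
* **Startup stiffness.** Random gating initial conditions (m, h, n uniform
  on [0, 1]) can combine m³h ≈ 1 with a hyperpolarized membrane, an
  effective time constant of ~10 µs that no fixed 0.05 ms step survives.
  The first 5 ms of a run started at t = 0 are therefore integrated at
  dt = 0.002 ms; the transient decays within ~1 ms and never recurs.
  Numerical blow-up (|V| > 200 mV) aborts with a diagnostic.
* **Spike detection.** Strict upward crossings of 0 mV (V_prev < 0 < V_now;
  a plateau exactly at threshold does not count), onset linearly
  interpolated within the step, 2 ms refractory guard. HH spikes peak near
  +40 mV, so the threshold is unambiguous. STDP updates fire at the end of
  the step in which the crossing was detected, using interpolated times.
* **Stimulus timing.** The active slot is resolved by integer arithmetic
  on the step index (dt must divide T_s/N_s, validated), so slot
  boundaries are exact; with every integer T_s in ms and dt = 0.05 this
  holds automatically.
* **Accuracy checks** (in the test suite): an uncoupled neuron stays
  within 0.15 mV of a scipy adaptive-step reference over 100 ms (bound
  0.5 mV); K = 0 stimulation is bit-identical to no stimulation; identical
  seeds give bit-identical runs; with vanishing Na/K conductances the
  membrane relaxes to the closed-form leak/drive fixed point.

## Measures

C_av = N⁻² Σ sgn(M_ij)c_ij is tracked incrementally in the kernel (exactly
resynchronized every 20 000 steps) and recorded on the sample grid
(default every 1 ms). R(t) uses the linear spike-phase interpolation;
neurons without a bracketing spike pair at a sample time are **excluded**
from that sample's phasor mean (the phase is undefined without two
spikes); the valid-neuron count is available. R_av averages the last
100·T_s of samples; plots use a centered moving average over 400·T_s.
Sub-population order parameters use the four contiguous 50-neuron blocks
centered on the sites (neurons 1–50, 51–100, 101–150, 151–200).

## Protocol and sweeps

The four-phase schedule is 2 s equilibration (STDP off — the network
relaxes onto its attractor with the initial weights), 60 s kindling (STDP
on, no stimulation; the synchronized strongly coupled baseline develops),
128 s CR-on, 128 s CR-off. `duration_scale` shortens only the CR epochs:
the kindled baseline is part of the experimental conditions and keeps its
full 60 s even in scaled-down runs.

Sweeps stimulate the **same** replicate networks in every (mode, K, T_s)
cell: kindling is stimulation-independent, so each network (seed =
master_seed + id) is equilibrated and kindled once and every cell branches
from the kindled snapshot; sequence-stream seeds are derived per cell by a
process-independent hash. Sweeps are resumable (completed records in the
output CSV are skipped) and record failures without aborting the grid.

Statistics follow the boxplot conventions: linear-interpolation quartiles
(the convention matters for fence placement and is therefore fixed and
documented), IQR, 1.5·IQR outlier fences; two-sample comparisons use the
Wilcoxon rank-sum test (exact null iff both n ≤ 12 and the pooled sample
is tie-free, normal approximation with tie correction otherwise). The
sample-size formula n = ⌈(x_{1−α/2} + x_{1−β})²(sd/δ)²⌉ gives 11 at
α = 0.05, β = 0.10, sd/δ = 1 with normal quantiles (a Student-t variant
iterates df = n−1 to a fixed point).

### Frequency-ratio grid

The stimulation-period grid {64, 40, 29, 23, 19, 16, 14, 12, 11, 10, 9} ms
realizes an approximately equidistant frequency grid of 25–175% (step 15%)
of the 62.5 Hz reference (T₀ = 16 ms): the integer period is the nearest
to each requested ratio. Because the periods are rounded, recomputing the
ratio from the period does not always return the requested label (e.g.
19 ms → 84%, not 85%); `frequency_ratio_conversion` reports the realized
ratio and `period_for_ratio` inverts a requested one, and the two
round-trip over the whole grid. Ratios relative to the intrinsic ~71.4 Hz
rate (T ≈ 14 ms) reproduce {22, …, 156}% exactly.

## What the simulator does and does not emulate

All data are generated by the model itself; there is no external data
path. The synthetic experiment reproduces the study conditions: random
network realizations (uniform V, gating, PSP; normal weights; uniform
drives), the kindled synchronized baseline (~71 Hz, R_av ≈ 0.85,
C_av ≈ 0.18 at 60 s), and the frequency/intensity dependence of acute and
long-lasting CR effects at scaled-down replicate counts and CR durations
(3 networks, 32 s epochs in the tests). It does not include conduction
delays, noise in the dynamics (the ODEs are deterministic; randomness
enters only through initial conditions and sequence draws), heterogeneous
neuron models, structural plasticity, or closed-loop (demand-controlled)
CR variants. Passing tests therefore demonstrate the mechanism —
STDP-mediated bistability and its control by CR timing — not quantitative
agreement with any biological recording.

## Known limitations

* The scaled-down anti-kindling contrast uses 3 networks and 32 s CR
  epochs; relapse statistics (which networks rebound after stimulation
  ends) need the full 11-network, 128 s configuration
  (`configs/full_sweep_rvs_svs.yaml`, cluster-scale).
* Nearest-spike pairing is a modelling choice; an all-pairs scheme would
  change the effective kernel integral at high rates.
* The phase entrainment of individual sub-populations during stimulation
  is only exposed via the sub-population order parameters; no
  stimulus-locked entrainment statistic is implemented.
* Endpoint R_av is NaN if the averaging window (100·T_s) exceeds the
  epoch; callers choosing very short scaled epochs with long T_s should
  use the R series directly.
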