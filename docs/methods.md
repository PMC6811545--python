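# Models and methods

`barrel4` simulates how layer 4 of mouse barrel cortex transforms
thalamocortical (TC) input into spike output, comparing wild-type (WT) and
Fmr1-knockout (KO) parameter sets measured at postnatal day 10–11. This
note documents the models, the provenance and role of every tunable
parameter, the numerical choices, and what the synthetic benchmarks do and
do not establish.

## Unit system

All quantities use mV, ms, nS, pA, pF and MΩ. These combine without
conversion factors (nS·mV = pA; pA/pF = mV/ms) except for two centralized
rules in `barrel4.units`: MΩ·pF = µs (so τ_m = R·C/1000 ms) and
MΩ·nS = 10⁻³ (dimensionless conductance load).

## Short-term depression (`barrel4.stp`)

Synaptic amplitudes follow a two-factor depression model: the normalized
amplitude of response *k* is A_k = D₁·D₂ read out at the stimulus time;
each stimulus then multiplies D₁ and D₂ by per-spike factors d₁, d₂ ∈
(0, 1], and between stimuli each D relaxes exponentially back to 1 with its
own recovery constant τ_D1, τ_D2. Recovery uses the exact exponential
solution (the relaxation ODE is linear, so exactness is free). Depression
accumulates whenever the inter-stimulus interval is short relative to
recovery.

Fitting minimizes equally weighted squared residuals across normalized
depression curves at 5, 10, 20 and 50 Hz simultaneously
(Levenberg–Marquardt, three starts, bounds enforced by logistic/log
reparameterization). The two factors are exchangeable; fits report the
slow-recovering factor first. **Identifiability caveat:** from 4
frequencies × 5 stimuli with additive noise of SD 0.05, the fast recovery
constant is essentially unidentifiable (its Cramér–Rao relative SD exceeds
100%), so noisy-fixture benchmarks measure recovery of the predicted
depression *curves* (median worst-point error ≈ 6% at that noise), not of
each parameter. Noiseless fixtures recover all four parameters to < 1%.

Bi-exponential decay fits (`fit_biexponential`) use the stimulus index as
abscissa, report τ₁ ≤ τ₂ by convention, and flag non-convergence.

## Synapses (`barrel4.synapses`)

Conductances are delayed differences of exponentials, normalized so the
peak equals 1 at t_peak = τ_r·τ_d/(τ_d−τ_r)·ln(τ_d/τ_r) after onset, and
causal (zero before spike time + conduction delay). Currents follow
I = A·ḡ·s(t)·(v−E_rev), positive outward; the injected current in the
membrane equation is −I, so excitation (E_rev = 0 mV) depolarizes. NMDA
currents carry the sigmoidal magnesium unblock factor
G(v) = 1/(1 + exp(−a·v)·[Mg²⁺]/b) with a = 0.062 mV⁻¹, b = 3.57 mM and
[Mg²⁺] = 1.3 mM. Multi-spike inputs superpose linearly, each event frozen
at its depression amplitude; the production implementation keeps two
exponential state variables per class, which is algebraically identical to
the explicit per-event sum (asserted in tests).

## Single-cell feed-forward-inhibition model (`barrel4.ffi`)

A single-compartment leaky integrate-and-fire (LIF) cell receives a TC
glutamatergic synapse (E_rev 0 mV, peak 1 nS, ≈60 pA inward from the
−60 mV leak reversal) and a feed-forward inhibitory (FFI) GABAergic
synapse (E_rev −71 mV) whose peak is the TC peak times the G/A ratio,
activated at each stimulus plus the excitation–inhibition onset lag. The
original construction used a soma-plus-dendrite morphology tuned to match
measured R_in and C_m; because both synapses are somatic, a single
compartment with R_in and C_m set directly has the identical input–output
mapping and removes an unobservable morphology parameter.

**Spike threshold.** With a 1 nS TC input a unitary EPSP is only a few mV,
yet with FFI silenced the model must fire at every frequency from 5 to
50 Hz — including 5 Hz, where no summation is possible — so the threshold
must sit within reach of a single EPSP. The threshold depth above the
leak reversal is therefore modelled as a fixed fraction (0.1375,
calibrated once) of the measured rheobase depolarization R_in × rheobase
current (WT: 412 MΩ × 72 pA → depth 4.08 mV; KO: 609 MΩ × 44 pA →
3.68 mV). The genotype *contrast* thus comes entirely from printed
measurements; only the common scale is a calibrated placeholder. Reset is
to the leak reversal; the refractory period is 1.5 ms.

Integration is exponential Euler at dt = 0.025 ms (the sweep claims are
threshold-sensitive; results are unchanged at dt 0.05 and 0.0125). Sweeps
run all (G/A × frequency) conditions in one vectorized pass. The default
grid is G/A 0–10 in steps of 0.5 by 5–50 Hz in steps of 5 (the source
grid density between 5 and 50 Hz is not printed; condition-count contrasts
are grid-sensitive).

**Rescue scenarios.** Four parameter groups — short-term plasticity (d's
and τ_D's of both synapses), E–I input delay (the lag), intrinsic
excitability (R_in, C_m and the rheobase-scaled threshold), synaptic
kinetics (rise/decay of both synapses) — are independently assignable to
WT or KO values, giving 16 scenarios. The summary reports firing-condition
counts and total spike output over the grid relative to the all-WT
scenario. In the calibrated model the KO's longer E–I lag is *suppressive*
(the crossing occurs after the IPSC peak, so a later IPSC is fresher at
crossing time), which is why rescuing the delay on the KO background
raises spike output — one of the antagonistic interactions the model
exists to expose; conversely rescuing intrinsic excitability lowers it.

**Known limitation.** The calibrated model fires *earlier* in the KO
(shallower rheobase-scaled threshold), whereas the source recordings and
model report later, jitterier KO first spikes. The condition-count and
rescue contrasts take precedence in the calibration; the latency direction
could not be reproduced simultaneously and is not asserted.

## Layer-4 network (`barrel4.network`)

800 excitatory (Ex) and 150 inhibitory (In) LIF neurons (v_rest −64 mV,
placeholder threshold −40 mV, reset −60 mV, refractory 1.5 ms) are
randomly connected without autapses. Ex axons carry AMPA + NMDA (shared
depression state, NMDA/AMPA peak ratio 0.35, NMDA kinetics 2/60 ms);
In axons carry GABA_A. Ex–Ex weights are log-normal (median
ḡ·exp(−σ²), σ = 1); other classes draw uniform fractional weights on
(0, 1]·ḡ. Connection probabilities (placeholders read from graphical
data): Ex–Ex 0.20 both genotypes; Ex→In 0.45/0.25 and In→Ex 0.55/0.35
(WT/KO); In–In is undescribed in the source and defaults to 0 with a
config hook.

External TC input reaches 80% of each population, with per-neuron peak
conductances up to 3 × the measured 1 nS unitary peak (a placeholder
convergence factor), jittered multiplicatively per trial (CV 0.2,
per synapse) and with the thalamorecipient subset reshuffled per trial.
Per-neuron R_in and C_m are sampled from a zero-truncated bivariate
Gaussian with correlation 0.5 (private plus shared variance; the
correlation is a placeholder argument); SDs derive from printed SEM×√N.

Integration is forward Euler at 0.5 ms over 1000 ms; spike times are
floored to 1 ms. Cells whose sampled time constant falls below 20·dt have
their capacitance raised to that bound (~1% of draws): under synaptic
conductance load the effective time constant shrinks by 1 + R·g·10⁻³, and
forward Euler is unstable below ≈2 steps. A blow-up guard aborts with a
diagnostic if |v| exceeds 200 mV. Halving dt changes feed-forward
population counts by <10%; with recurrence, synchronous volleys amplify
step sensitivity (documented bound 35% — the price of the prescribed
integrator).

## Spike metrics (`barrel4.metrics`)

Spike density functions convolve 1 ms-discretized spikes with a Gaussian
kernel (SD 5 ms, truncated at ±3 SD, per-spike mass renormalized to 1,
including at raster edges). The van Rossum distance maps trains to sums
of causal exponentials (τ = 50 ms) with D² = (1/τ)∫(f_A−f_B)²dt, the
convention making a lone spike versus silence distance √½; the
implementation uses the closed-form pairwise exponential sum and is
checked against a fine-grid numerical integral. (The source's worked
illustration of a ~0.1 probability contribution at 30 ms is inconsistent
with a 5 ms kernel truncated at 3 SD; the formula is implemented as
stated and the discrepancy left unreconciled.)

## Decoding (`barrel4.decode`)

Covariates are per-neuron spike counts in 10 ms bins over the 1000 ms
trial, concatenated over the ensemble (the covariate construction is not
specified at the source; 10 ms preserves first-spike timing without
singular covariances). Classification is a linear discriminant from class
means and the pooled within-class covariance shrunk as
Σ_reg = (1−λ)Σ + λc̄·I with λ = 0.05 and c̄ the mean diagonal
(scale-preserving shrinkage; "regularised by a factor of 0.05 on the
identity" is ambiguous, and the additive variant Σ + λI is available as an
option). Because features far outnumber trials, the discriminant solve
uses the Woodbury identity on the n×n dual system. Accuracy is
leave-one-out cross-validation over trials (the primary reported metric;
a 70/30 split evaluation can be obtained by subsetting trials), with a
label-permutation null for chance comparison. Oddball stimuli are inserted
at the midpoint of a chosen inter-stimulus interval (positions 1–4 of a
5-stimulus train), preserving the regular scaffold.

## Impedance (`barrel4.impedance`)

ZAP stimuli are ±40 pA chirps sweeping 0.5→50 Hz over 25 s with phase
2π∫f(t)dt (the literal A·sin(2πf(t)·t) sweeps at twice the intended rate;
a comparison utility is provided). Impedance is the ratio of
Fourier-transformed voltage and current on the swept band; smoothing (a
0.25 Hz boxcar) is applied to the complex ratio, never to the raw spectra,
whose chirp phase rotates too fast to average. Phase uses the
four-quadrant angle, voltage lag negative. For a passive cell the profile
follows |Z| = R/√(1+(2πfRC)²) with cutoff 1/(2πRC); Bode gain is
20·log₁₀ relative to the lowest tested frequency (identical to the
10·log₁₀ power-ratio convention). Spike phase locking assigns each spike
the analytic (Hilbert) phase of the injected sinusoid, in the convention
where a spike at the current peak maps to π/2, and reports the circular
mean and resultant length.

## Parameter provenance and calibration

Printed, measured values: Ex passive properties (R_in 412/609 MΩ, C_m
94/89 pF, v_rest −64 mV, rheobase 72/44 pA for WT/KO), reversal potentials
(0/−71 mV), the 1 nS TC peak, the −60 mV leak reversal of the single-cell
model, Mg-block constants, the 1.5 ms refractory period, and all protocol
constants (grid ranges, trial counts, dt values, kernel widths, τ = 50 ms,
λ = 0.05, ZAP parameters).

Everything else — synaptic kinetics, depression coefficients, the E–I
lag, In passive properties, connection probabilities, the TC convergence
factor, jitter CV, the log-normal shape and the threshold scale — was
published only in supplementary material not reproduced here and is a
**placeholder**: fixed once to satisfy the qualitative findings (KO:
slower FFI kinetics, longer E–I lag, stronger depression of both TC
inputs with the IPSC affected more, reduced FS↔SC connectivity, unchanged
SC–SC connectivity and unchanged EPSC/unitary strengths) and calibrated so
the single-cell model reproduces the reported model-level contrasts. All
placeholders are logged at WARNING level whenever a default genotype set
is constructed, so runs that rely on them are self-documenting.

## What the synthetic benchmarks show

The depression fixtures, RC voltage responses and labelled spike-train
ensembles are generated by the package itself with known ground truth.
They establish that each analysis stage is numerically faithful (fits
recover generating parameters or curves; the van Rossum closed form
matches numerical integration; the simulated LIF matches its closed-form
rate; measured impedance matches the first-order filter algebra; the
decoder is exact on separable data and at chance under permutation). They
do not validate the placeholder parameter values against recordings, and
the genotype contrasts of the network (more KO spiking at low input
frequencies, poorer KO oddball decoding) are demonstrated on the default
parameter sets and fixed seeds, not across the placeholder space.

## Problem sizes

Default analyses use the full 21×10 single-cell grid, all 16 rescue
scenarios, and full-size (800+150) networks. Network regression checks
run 2 network seeds × 10 trials per condition with ensembles of 10–20
neurons and 5 random ensembles per size; decoding curves support up to
500-neuron ensembles, 10 ensemble draws, four oddball positions and five
network seeds for full-scale runs.
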