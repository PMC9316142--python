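# Methods

## Scientific setting

Loss-of-function variants of KCNQ1 (Kv7.1), the pore-forming subunit of
the slow delayed rectifier current IKs, delay ventricular repolarisation
and underlie type-1 long-QT syndrome. The canonical functional workup of
such a variant is (i) whole-cell voltage clamp of the channel expressed
heterologously (here: CHO cells co-expressing KCNE1) in wild-type,
homozygous-mutant and 1:1 heterozygous configurations, (ii) summary of
the voltage dependence of activation by Boltzmann fits of peak tail
current densities, and (iii) injection of the fitted channel parameters
into a human ventricular myocyte model to read out the consequences for
the action potential. `ikslab` implements this chain end to end, with a
synthetic-data generator standing in for raw recordings, which are not
publicly deposited for studies of this kind.

## Voltage-clamp protocol and analysis

The activation protocol holds at −80 mV, applies 6 s depolarising steps
from −60 to +80 mV in 20 mV increments and repolarises to −40 mV
(3 s tail by default, 100 ms recorded pre-segment; all configurable).
Analysis steps:

* **Tail peak.** Signed extremum of the current in a 100 ms window
  starting 5 ms after the step to −40 mV (blanking the capacitive
  transient). The window segment is first low-pass filtered with a
  centered 25 ms boxcar (configurable, 0 disables): the IKs tail decays
  with a time constant of hundreds of ms and is essentially flat on the
  window scale, so the raw per-sample extremum would report
  `signal + max(noise)` — an upward bias of roughly 2.5 standard
  deviations that selectively distorts the small tails at the foot of
  the activation curve and inflates the fitted slope factor. Measuring
  peaks on filtered traces is standard practice on real rigs.
* **Density.** Peak divided by cell capacitance (pA/pF).
* **Tail I–V.** Per-cell densities at every step potential; group
  summaries as mean ± SEM (sd/√n, ddof = 1). Inferential statistics are
  deliberately out of scope.
* **Boltzmann fit.** `y = Imax / (1 + exp((V50 − V)/k))` by
  Levenberg–Marquardt (lmfit), initialised at the half-range crossing
  (V50), 15 mV (k) and 1.1× the observed maximum (Imax), with five
  jittered restarts before a flagged failure. Normalised activation
  curves divide by the fitted Imax rather than the observed maximum,
  because mutant curves need not saturate within the protocol range.
* **Kinetics.** Activation and tail deactivation time courses are fitted
  with a single exponential `offset + amplitude·exp(−t/τ)`; constant or
  zero-amplitude series are flagged as τ-unidentifiable rather than
  returned silently.

## Synthetic recordings

Each cell is a single Hodgkin–Huxley activation gate
`dx/dt = (x∞(V) − x)/τ(V)` with Boltzmann `x∞` and a bell-shaped
`τ(V) = 100 + 900/cosh((V + 10)/30)` ms (peak ≈ 1 s near −10 mV, the
characteristic slow IKs activation; the constants are configuration,
not claims about the real channel). Current is
`g·C·x^p·(V − EK)` with gate power p = 1 for recordings, EK ≈ −83.4 mV
from the Nernst equation at the recording solutions (140 mM internal /
5.4 mM external K⁺, 24 °C), plus white Gaussian noise (5 pA default).
Capacitance is log-normal (median 10 pF, σ = 0.3, typical CHO values);
sampling is 1 kHz; the default seed is 2022, and every per-cell stream
derives from (seed, cell index) so that populations are reproducible and
paired across groups.

Group parameterisation (generator truth):

| group | v_half (mV) | k (mV) | g (nS/pF) |
|-------|------------:|-------:|----------:|
| WT    | +25         | 17     | 0.80      |
| HOM   | +40         | 23     | 0.25      |

The heterozygous group models dominant-negative suppression: tetramers
assemble binomially from a 1:1 subunit pool, and under the default
all-WT-required rule only the fraction `(1 − f_mut)⁴` (= 0.0625 at
f_mut = 0.5) gates like WT at the WT conductance density; every
mutant-containing tetramer is assumed to behave like the mutant
homotetramer at the mutant conductance density. This keeps the
heterozygous I–V and activation curves superposed on the homozygous
ones — the observable signature of dominant negativity — rather than
midway between WT and mutant. A proportional rule (conductance scaling
with the WT subunit fraction) is available for sensitivity analysis.

What the generator does **not** emulate: leak and seal conductance,
series-resistance and space-clamp errors, rundown, capacitive
transients, inactivation, KCNE1 stoichiometry or PIP₂ dependence, and
single-channel stochasticity. Passing tests therefore demonstrate the
correctness and statistical behaviour of the analysis chain under the
stated model, not robustness to every artefact of real recordings.

## Ventricular AP model

The full ten Tusscher–Panfilov (2006) epicardial human ventricular
myocyte model is implemented as published (constants and initial state
from the authors' code/CellML encoding, including the erratum values
k4 = 0.005 ms⁻¹ and V_rel = 0.102 mM/ms), with the three IKs parameters
injectable: maximal conductance g_Ks (published 0.392 mS/μF), and the
midpoint V50 (−5 mV) and slope (14 mV) of the xs activation curve
`xs∞(V) = 1/(1 + exp((V50 − V)/slope))`, with
`IKs = g_Ks·xs²·(V − E_Ks)`. The xs time constant keeps its published
voltage dependence; an optional multiplicative τ-scale exists but is off
(1.0) by default, since the experimental kinetics show no group
differences. The right-hand side is jit-compiled with numba when
available (a pure-Python fallback runs the identical function).

Pacing: 1 Hz, 100 beats to steady state, stimulus −52 A/F for 1 ms
(conventional for this model; configurable). Integration uses an
adaptive stiff solver (LSODA, rtol 1e−7, atol 1e−9), beat by beat with
the stimulus window integrated as its own segment so it can never be
stepped over. The final beat is sampled at 1 ms with all membrane
currents; APD90 is measured on every beat for convergence checks.

Biomarkers: RMP is the pre-stimulus voltage, APA = Vpeak − RMP, and
APDx runs from the time of maximum upstroke velocity to the linearly
interpolated downward crossing of RMP + (1 − x/100)·APA. Degenerate
traces (no upstroke) raise instead of returning numbers.

## IKs parameter fitting

The forward model propagates the isolated xs gate through the clamp
protocol analytically (the voltage is constant within each segment, so
each segment is a single exponential relaxation — no ODE solver), and
predicts peak tail densities `g_Ks·xs²·(V_tail − E_Ks)` after the same
5 ms blanking the measurement applies. E_Ks during clamp simulation uses
the experimental solutions (5.4/140 mM K⁺, 150/0.6 mM Na⁺, 24 °C,
E_Ks ≈ −67.8 mV), not the model's in-vivo concentrations, because the
target data come from CHO recordings. Peak tail densities across step
potentials are the fit target (the quantity the study plots); a
full-trace objective was considered and rejected as it adds kinetics
information the three parameters cannot absorb with τ fixed.

Fitting is bounded trust-region least squares (scipy, TRF) over
g_Ks ∈ [0, 2] mS/μF, V50 ∈ [−50, 60] mV, slope ∈ [5, 40] mV,
initialised at the published original triple with jittered multi-starts
on failure. Weights are uniform by default; inverse-SEM weights are
available when group SEMs exist, and inverse-magnitude weights are the
appropriate (GLS) choice under multiplicative noise.

Two numerical conventions worth stating:

* **Recovery error for V50.** In parameter-recovery experiments, errors
  for g_Ks and slope are relative (they are ratio-scale quantities);
  V50 is an interval-scale midpoint whose zero is an arbitrary point on
  the voltage axis, so "percent of the true value" diverges for truths
  near 0 mV even when the absolute error is a fraction of a millivolt.
  V50 recovery is therefore assessed relative to the width of its fit
  bounds (110 mV).
* **Conductance anchoring.** Conductance fitted to heterologous-cell
  densities reflects an arbitrary expression level, not myocyte channel
  density. Before AP simulation the pipeline multiplies every group's
  fitted g_Ks by the single factor that maps the WT fit onto the
  published epicardial 0.392 mS/μF, preserving the relative reduction
  between groups — the quantity the recordings actually constrain.
  V50 and slope transfer unchanged.

Because the myocyte model gates with xs² while the recordings are
described with a first-power gate, the fitted (V50, slope) are the
model's reparameterisation of the measured curve, not numerically equal
to the Boltzmann parameters of the tail I–V; the fit, not an identity,
makes the model reproduce the observed activation.

## Auxiliary quantifiers

* **Membrane localisation.** A 1-D fluorescence line profile is split
  15%/70%/15%; each end segment holds round-half-up(0.15·n) samples
  (M1 and M2, the membrane), the middle is cytosol. Segment means are
  reported raw and normalised to the whole-profile mean, plus a
  membrane index mean(M1, M2)/cytosol. Normalised outputs are invariant
  to uniform intensity rescaling. The module consumes extracted
  profiles, not images. The profile generator places Gaussian peaks at
  7.5% and 92.5% of the profile and calibrates their amplitude so the
  membrane-segment mean equals the `membrane_peak` parameter, making
  the generator ratio directly recoverable by the quantifier.
* **Conservation logo.** Per alignment column: residue frequencies
  (gaps excluded, renormalised; all-gap columns flagged with zero
  stack), Shannon entropy H = −Σp·log₂p, stack height
  R = log₂(20) − H (information content, the standard concrete reading
  of "stack height inversely related to entropy"), letter heights
  frequency·R in descending order. No small-sample correction by
  default (an alphabet-size argument allows variants). Fully conserved
  positions are those with entropy ≤ 0.

## Problem sizes and defaults used in verification

The shipped test suite and the acceptance script use the study's scale:
15/17/16 cells (WT/HOM/HET), 50 cells for the Boltzmann-recovery study,
20 ground-truth triples for fit recovery, 100 paced beats at 1 Hz, and
a 120-point intensity profile; a handful of structural tests use 2-cell
/ 2-beat configurations where only plumbing is exercised.

## Known limitations

* The generator's τ(V) and group parameters are plausible, not fitted
  to any published recording; conclusions from synthetic data are about
  the pipeline, not the channel.
* Only the epicardial parameterisation of the myocyte model is exposed;
  no tissue coupling, pseudo-ECG or rate-dependence studies.
* The three-parameter IKs update cannot represent kinetic (τ) effects
  of a variant; the τ-scale knob exists but is untouched by the fit.
* No quality control of recordings (leak, rundown, seal) is attempted.
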