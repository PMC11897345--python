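# Methods

## Scope and design

`neuroexhaust` is an analysis library plus a synthetic-data generator.
The analysis side (feature extraction, typing, I–V, EPSC, tracing) makes
no assumptions about where traces come from; the generator exists because
the phenotype the pipeline targets — progressive action-potential
amplitude loss with reduced sodium current density — needs ground truth
to validate detectors and classifiers against. Everything is
deterministic given a seed.

The package is used from Python; `examples/` holds one narrative script
per capability and serves as the command-line surface (each script is
directly runnable). Trace interchange uses a plain-text bundle format
(`meta.json` + per-sweep `time_s,value` CSVs) with an equivalent HDF5
container; vendor binary formats are out of scope.

## Acquisition conventions

* Units are fixed: mV, pA, pF, ms for reporting; seconds and Hz in
  protocol metadata. No unit inference.
* Standard protocols: current clamp 2-s steps, 5-pA increments, −20 to
  +60 pA (17 sweeps); voltage clamp 1-s steps, 10-mV increments, −80 to
  +60 mV from −80 mV holding (15 sweeps); spontaneous EPSCs 120 s
  gap-free at −80 mV.
* Liquid-junction correction subtracts the junction potential (default
  +12 mV) from recorded voltages (current clamp) or command levels
  (voltage clamp) — the standard convention for a positive pipette-to-bath
  junction potential; the sign is configurable. A flag guards against
  double application, and the correction is a pure shift (sample
  differences are preserved exactly).
* Time is implicit (sample index / sampling rate); the CSV bundle carries
  an explicit seconds column for portability.

## The conductance-model neuron

Single compartment, five state variables:

C_m dV/dt = −rho·g_Na·m³·h·s·(V−E_Na) − g_K·n⁴·(V−E_K) − g_L·(V−E_L) + I + noise

The fast gates use the classic squid-axon rate forms with per-gate
voltage offsets (h shifted +2 mV, n +16 mV relative to m) and a
temperature-like factor on all three gates — the standard fast-spiking
parameterisation, which rests near −65 mV and fires repetitively from a
low rheobase (class 1). Defaults (stand-ins, not fits to any real cell):
C_m = 30 pF, g_Na = 4000 nS, g_K = 270 nS, g_L = 3 nS, E_Na = +55 mV,
E_K = −90 mV, E_L = −65 mV, rate scale 5, activation frame shifted to
−56 mV.

Two quantities plant the exhaustion phenotype:

* **rho ∈ [0, 1]** scales sodium availability. Clamped currents are
  exactly linear in rho, so voltage-clamp density ratios equal rho
  ratios by construction.
* **The slow availability gate s** has steady state
  s∞(V) = 1/(1+exp((V−V_s)/k_s)) and a voltage-dependent time constant
  τ(V) = τ_entry + (τ_s − τ_entry)·s∞(V): entry into unavailability is
  fast at depolarised potentials (τ_entry), recovery at rest is slow
  (τ_s, default 2000 ms). A single voltage-independent time constant
  cannot make slower recovery worsen attenuation (it would only slow the
  decline during the step); splitting entry from recovery restores the
  physiological direction: with V_s = −35 mV, k_s = 4 mV the gate loses
  availability during each spike and recovers between spikes, so longer
  τ_s accumulates more loss over a 2-s train.

Archetypes (the cohort generator's defaults):

| archetype   | rho  | other changes                         | phenotype |
|-------------|------|---------------------------------------|-----------|
| T3-control  | 1.00 | —                                     | repetitive firing, mild attenuation |
| T3-patient  | 0.35 | V_s = −57, k_s = 10, τ_entry = 150 ms | fires, then exhausts mid-train |
| T2          | 0.25 | g_K = 60 nS                           | exactly one spike (depolarisation block) |
| T1          | 0.05 | —                                     | never fires |

The patient archetype combines reduced availability with a
depolarised-shifted, shallower slow-inactivation curve, so a fraction of
its channels is unavailable even at −80 mV holding (s∞(−80) ≈ 0.91) and
availability collapses during sustained depolarisation. This models the
disease's compound effect on the sodium conductance; it is why the
measured control/patient peak-density ratio (≈ 3.2) exceeds the bare
1/rho = 2.9, while pure-rho comparisons remain exactly linear. The T2
single-spike class uses a weak delayed rectifier: above rheobase the
membrane cannot repolarise after the first spike and blocks, giving one
spike at every suprathreshold current — robust to parameter jitter.

Integration: fixed-step classical Runge–Kutta (RK4) at dt = 0.01 ms
(hard cap 0.05 ms), with a divergence guard that aborts with advice to
reduce dt. Voltage-clamp gating uses the exact exponential update of the
linear gate ODEs at the clamped potential. Each sweep starts from the
settled resting state (300 ms settle, slow gate at its steady state).
Gaussian current noise is available but off by default, so validation
conditions are noise-free unless a plan says otherwise. Cohort jitter is
multiplicative lognormal (default 5%) on C_m, g_Na, g_K, g_L and rho
(clipped to [0, 1]).

The simulator embeds ground truth in each recording's metadata: exact
parameters, per-sweep spike counts from an integration-resolution
threshold-crossing log (upward V crossings of −10 mV, 2-ms refractory),
and per-step peak inward currents.

## Current-clamp features

AP detection: threshold = first sample where the centred-difference
dV/dt crosses 10 mV/ms upward on the way to a peak ≥ −10 mV; 2-ms
refractory. All criteria are configurable (published analyses used
unspecified custom routines; these are this package's conventions).
Amplitude = peak − threshold. FWHM is measured at threshold + half
amplitude between the rising and falling crossings with linear
interpolation between samples. AHP depth/time use the post-spike minimum
within 50 ms. No smoothing is added by default (acquisition-filtered
data is assumed, e.g. 2.7 kHz low-pass).

Passive properties come from non-spiking sweeps: RMP = median
pre-stimulus voltage; R_in = regression slope of steady-state ΔV on ΔI;
τ_m from a mono-exponential fit of the charging transient on the most
hyperpolarising step; C_m = τ_m/R_in; sag = (peak − steady)/peak
deflection. When recorded capacitance is present in metadata it takes
precedence over the estimate.

The 31-feature vector (21 primary + 10 secondary: F–I slope,
threshold/amplitude/FWHM drift across the train, last-AP metrics, total
AP count) is a reconstruction organised around the quantities the
phenotype requires; the original study's exact supplementary list is not
reproduced here. Train metrics use the analysis sweep = maximal AP count
(ties → lowest current; "first sweep with ≥ 3 APs" selectable).
AP-dependent features of non-firing cells are NaN with an explicit mask;
they are median-imputed only inside the typing stage, with indicator
columns retained.

## Typing and statistics

Rule typing is purely count-based (0/1/≥2 APs). Unguided structure
discovery z-scores the median-imputed primary features, then applies
full-SVD PCA (component signs fixed by making each loading vector's
largest-magnitude entry positive) and agglomerative Ward/Euclidean
clustering cut at k = 3, with clusters relabelled by ascending mean
max-AP count. Agreement between rule labels and clusters is the adjusted
Rand index. Correlation matrices are pairwise-complete Pearson with
two-sided p from the t distribution (n−2 df) and a display mask at
α = 0.01. Group comparisons use Welch t, Mann–Whitney or Kruskal–Wallis
with Holm step-down adjustment over the feature family; the
metabolite-panel path (`compare_panels`) gates parametric vs rank tests
on Shapiro–Wilk normality per group and reports raw p without post hoc
correction, matching common metabolomics practice.

## Voltage clamp and EPSCs

I–V reduction: per-step baseline = median of the 100 ms before the step;
peak inward = minimum baseline-subtracted current within 50 ms of onset;
steady outward = mean over the last 100 ms of the step; densities divide
by whole-cell capacitance. The 50-ms peak window and baseline rules are
package conventions, configurable. Capacitance estimation integrates the
baseline- and steady-state-subtracted test-pulse transient: C = Q/ΔV.

EPSC detection is deterministic Clements–Bekkers template matching in
place of learned detectors: a peak-normalised inward biexponential
template (defaults τ_rise = 1 ms, τ_decay = 10 ms, 40 ms long) is fitted
at every offset by least squares with free scale and offset (rolling
sums via FFT convolution); the criterion is fitted scale / residual SD,
thresholded at 4, with criterion local maxima separated by ≥ 10 ms. The
residual SD is floored at 1e-9 of the trace range so noise-free
stretches cannot produce unbounded criteria. Raising the threshold can
only remove events. Per event: amplitude = the fitted template scale
(the matched-filter estimate of baseline-to-peak; a raw argmin over a
noisy window overestimates amplitude by the noise extreme), local
baseline = the same fit's offset (robust to a neighbouring event sitting
inside a fixed pre-onset window), charge = ∫ baseline-subtracted current
from onset to min(100 ms, next event), 10–90% rise time on a 1-ms
smoothed copy, and a mono-exponential decay fit from the peak. A
rolling-percentile global detrend is available but off by default: a
percentile baseline is biased by the events themselves, and the fitted
per-event baseline already absorbs slow drift.

The EPSC generator draws Poisson onsets and lognormal amplitudes with a
narrow spread (log-SD 0.12) so that the plan's single signal-to-noise
ratio (mean amplitude / noise SD) describes essentially every event.
Real spontaneous-EPSC amplitude distributions are broader (CV 0.3–0.6);
detector performance quoted here therefore characterises the
well-defined-SNR regime, not a heavy-tailed amplitude mixture.

## Isotope tracing

Single-turn model only: uniformly labelled glutamine appears as M+5
glutamate/2-oxoglutarate; oxidative flux yields citrate M+4 and
malate/aspartate M+4, reductive carboxylation citrate M+5 and
malate/aspartate M+3; labelled mass splits f_red : (1−f_red) with an M0
dilution pool. Multi-turn isotopomer convolution is deliberately out of
scope, so ratios read out f_red exactly as r/(1+r) only under this
approximation. Natural-abundance correction (optional, off by default —
whether published fractions were corrected is typically unstated) solves
the binomial ¹³C convolution by non-negative least squares and
renormalises; only ¹³C is modelled. Flux ratios with a denominator
fraction below 1e-6 are flagged undefined and excluded from statistics
rather than reported as infinite. Carbon counts are fixed in a config
table (glutamine/glutamate/2-OG 5, citrate 6, malate/aspartate 4).

## Numerical choices and degenerate inputs

* Protocol construction requires the level range to be an integer
  multiple of the increment (both ends included) and rejects anything
  else.
* AP detection requires ≥ 10 kHz sampling; attenuation ratio is NaN
  (missing), not an error, below 2 APs.
* Sub-sample interpolation is linear everywhere (FWHM, rise times).
* Zero-variance features are dropped with a warning before PCA and
  clustering; constant features yield masked correlations.
* The bundle reader validates sweep counts against the protocol and
  strict monotonicity of the time column.

## Validation problem sizes

The test and acceptance workloads are sized for a single CPU: cohorts of
12–60 cells at dt = 0.01 ms, 60–120-s EPSC traces at 20 kHz, 100–1000
Monte-Carlo seeds for the statistical calibration checks (display-mask
and Kruskal–Wallis type-I error, power of planted shifts), and 3-point
parameter grids for the monotonicity properties (attenuation
non-increasing in exhaustion severity and in slow-gate recovery time;
peak density linear in rho).

## Known limitations

* All simulator constants are stand-ins chosen so the archetypes express
  their defining phenotypes; none estimates a real neuron, and absolute
  simulated current densities are larger than typical published values.
* Passing validation on this generator demonstrates correctness of the
  pipeline's computations, not robustness to everything real recordings
  contain (seal instability, series-resistance artefacts, overlapping
  bursts, electrical noise structure, multi-turn labelling).
* The single-compartment model has no morphology and no synaptic
  conductances; EPSC traces are statistically, not mechanistically,
  generated.
* NWB/ABF import is not implemented; the bundle format is the interchange.
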