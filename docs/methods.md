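# Methods

## The model and what it is for

Extracellular field potentials have power spectra that decay approximately
as a power law, P(f) ∝ 1/f^χ, with oscillations (beta, gamma) superimposed.
The package separates the two with the model

    log10 P(f) = b − log10(k + f^χ) + Σ_i a_i · N(f; c_i, σ_i)

where the first term is the aperiodic component (offset b in log10 power,
knee k ≥ 0, exponent χ) and each N is a Gaussian in log10 power with centre
frequency c_i (Hz), height a_i (log10 units above the background) and SD σ_i
(reported bandwidth bw = 2σ). *Fixed* mode pins k = 0 and is used whenever
the spectrum is close to a single straight line in log-log space; *knee*
mode is used for wide fit ranges (5–90 Hz) where a single slope cannot hold.

The scientific quantity is χ. Under the E/I interpretation, inhibitory
(GABAergic) synaptic currents decay more slowly than excitatory ones, so a
shift of the synaptic input mix toward inhibition steepens the field
potential spectrum: higher χ ⇒ more inhibition. The package tests this
association in two regimes:

1. **Rodent spike-state contrast.** During slow-wave activity under
   anaesthesia, STN firing waxes and wanes with the ~1 Hz cortical
   oscillation, anti-phase to the GABAergic GPe-Ti population that inhibits
   STN. Epochs of high STN unit firing therefore index
   excitation-dominated states and low-firing epochs inhibition-dominated
   states. The contrast of χ between these states, with animal as the
   grouping level, is the E/I validation.
2. **Patient treatment contrasts.** Dopaminergic medication and 130 Hz STN
   stimulation both reduce STN firing; under the hypothesis both should
   raise χ in paired ON/OFF recordings.

## Processing chains and their parameters

Rodent chain: lowpass 300 Hz (3rd-order Butterworth) → resample to
2048 Hz → optional local-average re-referencing (mean of six neighbouring
contacts subtracted) → Morlet decomposition 1–100 Hz → 250 ms epoch PSDs,
each normalised by its mean 1–100 Hz power → per-unit 25th/75th-percentile
firing labels → state-average PSDs → fixed-mode fit 30–100 Hz and mean
30–100 Hz band power → random-intercept mixed model (value ~ state,
intercept per animal, maximum likelihood; p from t with residual degrees of
freedom) and Spearman correlations.

Human chain: highpass 1 Hz → Morlet 1–90 Hz → 60 s time-average PSD
normalised by mean 1–90 Hz power → 47–53 Hz excised and linearly
interpolated → (a) fixed-mode exponent over 40–90 Hz (medication) or
10–50 Hz (stimulation); (b) knee-mode model over 5–90 Hz for the periodic
beta peak (largest peak with centre in 13–35 Hz; the 8–35 Hz variant is
exposed as a setting) and for the aperiodic correction of band powers;
(c) six band powers (beta 13–35, low beta 13–20, high beta 21–35, gamma
35–90, low gamma 35–50, high gamma 51–90 Hz) as the mean flattened
(log-residual) power; (d) paired permutation t-tests, 50 000 sign-flip
permutations, add-one p. The exponent and periodic-beta contrasts are
tested singly; the six band powers form one max-|t|-corrected family.

Key defaults, with reasons:

| parameter | default | why |
|---|---|---|
| wavelet cycles | 50, fixed across frequency | narrow spectral smoothing (σ_f = f/50 ≈ 1–2 Hz) so 1 Hz-grid fits are meaningful; the cost is long temporal support |
| epoch length | 250 ms | four epochs per ~1 Hz slow-oscillation cycle, resolving its active/inactive phases |
| firing percentiles | <25th = low, >75th = high, strict inequalities; Hazen (k−0.5)/n convention | extreme quartiles give clearly separated states; the percentile convention fixes label sets exactly and is also used for IQRs |
| rodent fit range | 30–100 Hz fixed | below 30 Hz the slow oscillation and beta contaminate the slope; above 100 Hz plateaus loom |
| medication fit range | 40–90 Hz fixed | high-amplitude beta peaks reach past 30 Hz in patients; 100 Hz is the first mains harmonic |
| stimulation fit range | 10–50 Hz fixed | stimulation artefacts flatten the spectrum above ~50 Hz (see plateau below) |
| mains band | 47–53 Hz, linear interpolation in linear power | removes the 50 Hz line and its skirts without a time-domain notch |
| permutations | 50 000, seeded; p = (1+#{|t*|≥|t|})/(N+1) | matches the permutation budget used for such contrasts; p is never 0 |
| FDR | two-stage adaptive linear step-up at q = 0.05 (q′ = q/(1+q) in both stages) | the adaptive modification of the linear step-up procedure |
| R² floor | 0.9, flag not exclude | goodness of fit is reported; no exclusion rule is imposed |

## Numerical choices

- **Morlet implementation.** Unit-energy wavelets truncated at ±3.5 σ_t,
  applied by FFT convolution to the full-length signal *before* any
  epoching, so epoch PSDs do not carry per-epoch edge transients. A signal
  shorter than the wavelet at the lowest frequency is an error. For 60 s
  windows, per-frequency time-averages exclude samples within 2 σ_t of the
  window ends (capped at a quarter of the window per side).
- **Robust aperiodic fit.** Initial least squares on log10 power; positive
  residuals are clipped at zero and points above the 2.5th percentile of
  the clipped residuals are dropped before the refit, which discounts grid
  points sitting on oscillatory peaks. Knee-mode fits start from a ladder
  of knee guesses (0–1000) and keep the best, since the knee SSE surface
  has local minima. Solver tolerances are 1e-12 so that fits are stable to
  global rescaling of the input (scale affects only b, by log10 of the
  factor).
- **Peak extraction.** Greedy: take the flattened-spectrum maximum while it
  exceeds 2 SD of the current flattened spectrum (and an absolute numerical
  floor of 1e-6 log10 units), guess σ from the half-height width, subtract,
  repeat; "unlimited" peaks are capped at 50 as a termination guard.
  Overlapping guesses (closer than 0.75 summed SDs) keep the taller peak.
  Joint bounded refit of all Gaussians (cf within ±2 guess-SDs, σ within
  1–6 Hz from the 2–12 Hz bandwidth limits), then a final non-robust
  aperiodic refit on the peak-removed spectrum. Ties for the largest peak
  in a band break toward the lower centre frequency.
- **Degenerate inputs.** All-equal spike counts → all epochs "mid" with a
  warning; all-zero paired differences → t = 0, p = 1; zero IQR → one
  histogram bin; a singular mixed-model fit falls back to zero intercept
  variance (OLS) with a warning; undefined Spearman correlations (constant
  input, n < 3) are reported as NaN with a warning rather than aborting a
  cohort run.

## The synthetic data: what it emulates, and what it does not

The rodent generator crossfades two unit-variance 1/f^χ Gaussian processes
(χ_high = 1.0 on the active phase of the slow oscillation, χ_low = 1.3 on
the inactive phase) with 25 ms cosine ramps at the state boundaries, adds
the ~1 Hz slow sinusoid, and draws STN spike trains as inhomogeneous
Poisson processes with rate r(t) = r₀(1 + m cos 2πf_slow t) (r₀ = 12 sp/s,
m = 0.9, 3 ms absolute refractory period so isolation QC — <1% of
inter-spike intervals under 2 ms — passes as for well-sorted units); GPe
trains are the same in anti-phase at r₀ = 24 sp/s. Default dimensions
mirror the study design: 8 animals, 28 LFP channels (4/3 alternating per
animal), 20 STN units (3/2), ~100 s of slow-wave activity per session, at
2048 Hz (the post-resampling rate; synthetic channels are emitted already
re-referenced).

The patient generator draws, per hemisphere, a baseline exponent
χ_OFF ~ N(1.2, 0.25) and a treatment effect Δχ ~ N(0.15, 0.25) for
medication (chosen so the generative effect size matches the reported
paired d of 0.6 at n = 30) or Δχ ~ N(0.30, 0.244) for stimulation
(d = 1.23 at n = 26); a beta peak (cf ~ U(15, 30) Hz, OFF height
~ N(0.35, 0.12) log10 units, ON lower by N(0.10, 0.26) for medication,
N(0.15, 0.26) for stimulation); 50 Hz mains; and, for the stimulation ON
condition, artefact tones at 65 and 130 Hz plus a band-limited white floor
(highpassed at 52 Hz, level pinned to the background near 50 Hz) that
produces the >50 Hz spectral plateau. Oscillatory components are FFT-shaped
with exact spectral amplitudes (random phases) against the signal's own
measured background, so an injected peak height is the height the
parameterisation should recover.

Two honest caveats about what passing tests show. First, per-hemisphere
exponent estimation from 60 s carries noise of roughly 0.1–0.15 SD in the
40–90 Hz range, so the *measured* paired effect size of the synthetic
medication cohort (~0.45) is smaller than the generative one — direction
and significance, not the printed effect size, are the reproducible
quantities at cohort scale. Second, the 50-cycle wavelet kernel smears
power across neighbouring 250 ms epochs in a frequency-dependent way; for
state schedules alternating at ~1 Hz this *amplifies* the measured
state difference in χ relative to the generative Δχ (leakage from the
flatter state is itself spectrally steepened by the kernel), so the rodent
contrast estimate is a method-specific quantity, not an unbiased estimate
of Δχ. The generators also omit non-stationarities of real recordings:
movement and cardiac artefacts, electrode drift, unit loss, and any true
coupling between spikes and the LFP beyond the shared slow-oscillation
phase.

## Problem sizes in tests and the acceptance script

The acceptance script runs the full study-condition sizes (above). The test
suite uses reduced sizes chosen as the smallest that still exercise each
property: rodent end-to-end runs use 4–8 animals × 1–2 channels at 20–30 s
and fs 512 Hz with the decomposition grid restricted to the 30–100 Hz fit
band (exponent fits are unchanged by this; the band-power measure then uses
65–100 Hz because the whole-band mean is normalised to 1); the null
calibration of the state contrast repeats 200 such runs; patient mini
cohorts use 8 hemispheres with a tightened between-hemisphere spread so
that direction and significance are decided by the machinery rather than
sampling luck.

## Known limitations

- Wide fit ranges with strong low-frequency oscillations can defeat the
  robust aperiodic fit; the shipped fit ranges avoid this by construction,
  and R² flags (< 0.9) mark fits needing inspection.
- The permutation contrast treats hemispheres as exchangeable; patients
  contributing two hemispheres are not modelled as a clustering level.
- Readers for deposited wideband datasets are best-effort (EDF and the
  flat-binary dialect); proprietary acquisition formats are out of scope,
  as is spike sorting — inputs are sorted event times.
- The two-state E/I construction is specific to slow-wave regimes; the
  package does not attempt cycle-resolved or time-resolved exponents.
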