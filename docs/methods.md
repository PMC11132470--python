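# Methods

## Stimulus model

A stimulus is band-limited noise whose amplitude envelope carries a
designed modulation spectrum. The spectrum model is a shifted lognormal in
modulation frequency x:

    L(x; μ, σ², b) = 1 / ((x − b) σ √(2π)) · exp(−(ln(x − b) − μ)² / 2σ²)

with two free scientific parameters — the peak (mode) frequency m in Hz
and the regularity σ (the log-SD; smaller σ concentrates power near the
peak, making the envelope more isochronous) — and two derived ones:
b = −1.2813·m (an x-shift that lets the curve keep a nonzero intercept,
matching averaged modulation spectra of natural recordings) and
μ = ln(m − b) + σ². With these derivations the mode identity
b + exp(μ − σ²) = m holds exactly, which the property suite asserts.

The synthesis chain is: evaluate L on the FFT bin grid (spacing
1/20 s = 0.05 Hz) from 0.05 to 64 Hz; multiply by 1/x (the inverse of the
f-weighting used when modulation spectra of natural sound are computed);
impose i.i.d. uniform phases and inverse-FFT to a 20-s signal; min–max
rescale to [0, 1] to obtain an amplitude envelope; upsample to the audio
rate; multiply with a low-noise-noise (LNN) carrier; extract the middle
4 s; RMS-equalize within an experiment.

Parameters that matter, with defaults:

| parameter | default | meaning / rationale |
|---|---|---|
| audio rate | 44 100 Hz | delivery rate; 16-bit PCM WAV output |
| envelope rate | 1 000 Hz | internal synthesis grid; AM content is < 64 Hz, so a full-rate FFT would be wasteful; polyphase resampling (441/10) upsamples to audio rate, clipped back to [0, 1] to remove ringing overshoot |
| spectrum support | 0.05–64 Hz | FFT bins of the 20-s signal; DC forced to 0 |
| carrier band | 20–20 000 Hz | 4th-order Butterworth, applied forward–backward |
| LNN iterations | 10 | envelope-division + re-bandpass rounds; envelope CV decreases monotonically (tested) |
| target RMS | 0.05 full scale | leaves headroom so modulation never clips in 16-bit output |

Two places where the procedure is a design choice rather than a stated
fact: (1) the inverse-FFT signal is zero-mean, and we map it to a
nonnegative envelope by min–max rescaling, which preserves the designed
spectrum shape up to affine terms (a Hilbert-magnitude transform would
distort it); (2) the designated peak is defined on the 1/f-*compensated*
spectrum (power × x), because the ×1/x step exists precisely to reverse
the analysis-side normalization.

## Verifying designated peaks from audio

`estimate_am_spectrum` recovers the raw modulation magnitude spectrum:
analytic-signal envelope, 64-Hz low-pass, decimation, mean removal, Hann
window, zero-padded FFT. For a line spectrum (e.g. sinusoidal AM) the
compensated argmax suffices and is tested to one bin.

For the lognormal stimuli the raw argmax is not a usable read-out at the
low end: a 4-s excerpt holds ~2.4 cycles of a 0.6-Hz modulation, so the
per-excerpt compensated argmax is dominated by window leakage from the
strong sub-resolution components the 1/x tilt creates (empirically
+15–20% bias and bin-hopping variance, however the periodogram is smoothed
or averaged). `estimate_designed_peak` therefore reads the peak out
parametrically: average the Hann periodograms across seeds of one
condition, and fit the designed family propagated through the *exact*
linear response of the measurement chain — for every design bin, the
periodogram footprint of a randomly phased sinusoid after segment
extraction, mean subtraction, windowing and zero-padding is precomputed
into a kernel — with σ fixed at the designed value, amplitude solved
analytically, and residuals weighted relative to the model (periodogram
noise scales with signal). Validated on full-rate stimuli: designated
peaks 0.6–6 Hz are recovered within ±1.3% from 20 seeds per condition.

## Headphone screening

Three 1-s, 200-Hz tones with 100-ms raised-cosine ramps: in-phase loud
(amplitude 0.5 full scale), antiphase loud (right = −left), in-phase quiet
with gain exactly 10^(−6/20) (so the −6 dB target is exact rather than the
half-amplitude ≈ −6.02 dB convention). Loudspeaker playback is modelled as
the ideal mono sum (L+R)/2, which nulls the antiphase tone; scoring is
ordinal on RMS, and passing requires ≥ 5/6. The six trials counterbalance
all six permutations of the three positions. Room acoustics beyond ideal
summation, absolute level, and inter-stimulus timing are out of scope.

## Designs

Only the extreme stimulus levels (0.6 and 6.0 Hz) and Experiment 2's three
peak frequencies (1, 2.5, 4 Hz) are fixed by the study; interior levels
are this package's choice: log-spaced grids (10 peak levels for
Experiment 1, 5 for Experiment 3; 5 σ levels on [0.10, 1.00] around the
0.35 used elsewhere for Experiments 2 and 4), all config-overridable.
Pools hold 100 stimuli per condition (Experiment 1) or 50 (2–4); a
participant draws 15 (Experiments 1/3/4) or 10 (Experiment 2) per
condition without replacement. Judgment experiments present each of 150
unique stimuli once per half (300 testing trials, independent random order
per half); detection experiments present the same 75 stimuli in each of 4
blocks (music/speech, order randomized within each half; 150 trials per
task). Twelve probe trials (1–4 brief tones in a 2-s window, non-overlapping
onsets) are placed one per consecutive stratum of 25 testing trials —
"roughly even" is enforced as max gap ≤ 2 × mean gap. Breaks fall every 10
trials. Practice uses 4 trials at geometric midpoints between adjacent
levels: inside the tested range, never equal to a tested value.

## Participant model

Responses are Bernoulli with p = clip(α + β(x − x_ref), 0, 1), then mixed
with a lapse: p ← λ/2 + (1−λ)p. The generative rule is linear (not
logistic) because that is the model the behavioural data favour; a
logistic generator would invert the model-comparison outcome by
construction. Defaults: β ~ N(0.05, 0.07) per Hz; α ~ N(0.5, 0.12); λ ~
U(0, 0.1); sophistication ~ N(81.58, 20.62) truncated to [18, 126] by
resampling (no boundary atoms), correlated ρ = 0.2 with β via a bivariate
normal. The α spread is anchored to the observed prevalence of response
bias: with SD 0.12, about 21% of responders fall outside the 50 ± 15%
window, matching the fraction the bias filter removes in the detection
experiments. This heterogeneity is also what gives the linear model its
R² advantage over the bounded logistic: a participant who never crosses
50% cannot be fitted by a logistic whose midpoint must lie inside the
stimulus range and whose asymptotes are fixed at 0 and 1.

Non-compliant archetypes (constant responders, 50% probe failure, 90%
response bias) are assigned to disjoint random subsets and exist solely to
exercise the exclusion filters. One RNG stream per participant is spawned
from (master seed, participant index), so populations are reproducible and
participants independent.

What the generator does not emulate: sequential dependencies, reaction
times, drift or learning across blocks, task-specific slopes in the
detection experiments, and any cognitive process beyond the static
psychometric rule. Passing tests therefore validate the *analysis
machinery* — recovery, calibration, exclusion logic — not claims about
human listeners.

## Analysis

Exclusions run in a fixed order, each participant counted under the first
matching criterion: incomplete session/questionnaire → failed headphone
screening → identical response on all testing trials → probe accuracy
< 90% → (detection experiments only) response-1 rate outside [35%, 65%] in
any task.

Per-participant fits use trial-level data (for slopes this is numerically
identical to fitting level means under these balanced designs — asserted
to 1e−10 — but R² differs, and trial-level is the default). The logistic
f(x; a, s) = 1/(1 + exp(−s(x − a))) is fitted by least squares, not
maximum likelihood, so its R² shares the linear fit's error basis;
the midpoint a is bounded to the extreme stimulus levels and the optimizer
multi-starts from 5 (a, s) combinations. R² for zero-variance responses is
defined as 0 (such participants are excluded anyway). Grouped designs
(slopes on σ under each peak frequency) produce one fit per
(participant, group).

Group inference: one-sample t with d = mean/SD; Pearson correlations with
df = n − 2, reported both with and without outliers, where an outlier is
|standardized residual| > 3 from the bivariate OLS line (the criterion is
config-overridable; both estimates are always reported); subscale
screening at the Bonferroni-corrected threshold 0.01 (five subscales at
α = 0.05); slope-split comparisons use Welch's t with fractional
Welch–Satterthwaite df and pooled-SD Cohen's d. All of these are
property-tested against brute-force evaluations of the definitional
formulas.

Power analysis is exact noncentral-t: required n is the smallest integer
whose two-tailed one-sample t-test with noncentrality d√n and df = n−1
reaches the target power, verified against a Monte-Carlo oracle. At
d = 0.68 the solution is 19 at (α = .05, power = .8) — a knife edge, since
power(19) = 0.8004; standard tools disagree at the fourth decimal and
planning practice rounds to 20 — and exactly 36 at (α = .01, power = .9).

## Numerical and calibration notes

* Null calibration: with β ≡ 0, 2,000 simulated 48-participant
  experiments put the slope test's rejection rate at ≈ 0.049 (asserted
  within [0.035, 0.065]). The repeated-experiment path is vectorized
  closed-form OLS over the same generative rule as the per-trial
  simulator.
* Recovery: lapse-free responders at 10× the usual trial count recover the
  generating slope with < 5% bias.
* Determinism: every synthesis, scheduling and simulation function is
  deterministic given its seed; per-stimulus seeds live in the manifest so
  audio can be re-rendered instead of stored; pipeline reruns are
  byte-identical.
* Problem sizes in the test suite: the peak-recovery contract uses 20
  seeds per condition at the full audio rate (the measured estimator SD
  there is ≈ 3–5%, comfortably inside the ±10% band); carrier unit tests
  run at reduced rates since the algorithm is rate-agnostic.

## Deposited-data ingestion

`read_s1_data` ingests a locally exported copy of the study's deposited
per-participant level means (CSV or XLSX) in a documented long-format
column map (experiment, participant_id, level, mean_response, optional
task and covariate columns) and feeds the same slope pipeline. The tests
exercise this path with synthetic files in that layout; no network access
is assumed anywhere in the package.
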