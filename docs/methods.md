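# Methods

`hrvcross` implements the analysis chain of a randomized within-subject
(crossover) stimulation study of cardiac autonomic function: single-lead ECG
→ R-peak / RR-interval extraction → heart-rate-variability (HRV) indices →
baseline-corrected condition contrasts with bootstrap and Bayesian
inference. Because raw study recordings are rarely redistributable, the
package ships a synthetic generator with exactly known ground truth; every
stage is validated against it.

## The generative model

RR intervals are realized beat by beat:

    RR(t_i) = mean_rr + lf_amp·sin(2π·lf_freq·t_i)
            + hf_amp·sin(2π·resp_freq·t_i) + e_i,     e_i ~ N(0, broadband_sd²)

with the next beat at `t_{i+1} = t_i + RR(t_i)/1000`. The low-frequency (LF)
modulator stands in for baroreflex-band rhythms (default 0.1 Hz), the
high-frequency (HF) modulator for respiratory sinus arrhythmia at the
respiration frequency (default 0.25 Hz). Sampling the modulators at beat
onsets — rather than integral-pulse-frequency modulation — is a deliberate
simplification; it is adequate for band-power and time-domain targets, which
is what the downstream pipeline estimates.

Closed-form index values follow from the components (these are the "ground
truth" the tests score against):

- SDRR² = lf_amp²/2 + hf_amp²/2 + broadband_sd²
- RMSSD² = 2·broadband_sd² + Σ_k (2·A_k·sin(π·f_k·r̄))², with r̄ the mean
  beat period in seconds (successive differences of a sinusoid sampled at
  the beat rate),
- band power = A²/2 plus the white-jitter floor 2·broadband_sd²·r̄·bandwidth
  (beat-level white noise spreads a flat tachogram PSD up to the beat
  Nyquist).

ECG waveforms place a symmetric Mexican-hat (Gaussian second-derivative)
template of ~80 ms support at every beat time — the central peak is the
R wave, the side lobes play Q and S — plus additive 50 Hz mains, slow
sinusoidal baseline wander, and optional 1–3 s saturating square segments
emulating movement artifacts. The template is symmetric on purpose: with
zero-phase filtering, the apex marks the true beat time, so detector timing
can be scored exactly.

**Default study conditions.** 36 subjects, 4 sessions each (condition
taVNS/sham × side left/right, side held fixed across sessions 1–2 and
flipped for 3–4), 3 phases per session (baseline, stimulation, caloric
load). Baseline defaults: mean RR 850 ms (≈71 bpm), lf_amp 30 ms, hf_amp
45 ms (HF ≈ 1000 ms², a realistic resting value for young adults — and large
enough that HF effects of a few hundred ms² remain realizable for
low-variability subjects), broadband jitter 20 ms, 15% between-subject
coefficient of variation on the amplitudes and 60 ms SD on mean RR. Default
injected effects mirror the magnitudes reported for auricular stimulation
crossovers: stimulation lowers HR by ~0.8 bpm in both conditions, the
caloric load raises it by ~3.3 bpm, and the active condition lowers
RMSSD/SDRR by ~4–5 ms and HF by ~175–270 ms².

**Effect injection.** Effects are additive on the *index* scale relative to
the same subject's baseline parameters. The generator inverts the
closed-form equations: HR sets the mean beat period; an HF target sets
hf_amp; an RMSSD target sets the broadband jitter; an SDRR target sets
lf_amp. The equations couple (jitter leaks into the HF band; every amplitude
enters RMSSD/SDRR), so they are iterated to a joint fixed point. When RMSSD
is targeted *without* an explicit HF target, all three variability sources
are scaled by a common factor — RMSSD is homogeneous of degree one in them,
so the target is exact, and the scaling mimics global vagal withdrawal
rather than an implausible jitter-only change. Unrealizable tables (e.g. an
HF reduction below the broadband floor) raise instead of silently clipping.

**What the simulator does not emulate:** ectopic beats and their
compensatory pauses, non-stationary drift of autonomic tone within a phase,
QRS morphology variation, respiratory frequency drift, and any coupling
between HR and HRV beyond the injected effects. Passing tests therefore
demonstrate correctness of the estimators and inference under a stationary,
well-behaved cardiac process — not robustness to every pathology of real
recordings.

## Preprocessing

Linear detrend → zero-phase low-pass → zero-phase 0.5 Hz high-pass →
polyphase decimation to 1000 Hz. The low-pass is a 19th-order Butterworth
whose −1 dB point is pinned at the 40 Hz passband edge (the cutoff is solved
analytically from order + edge + ripple; a printed pass/stop quadruple
over-determines a Butterworth, and order + passband is the reproducible
reading). Single-pass attenuation at 50 Hz is ≈31 dB; the forward–backward
application used throughout doubles it. Filtering before downsampling is the
default (anti-aliasing safety); the swapped order is available and changes
downstream R-peak recall by < 0.5% on synthetic data. All filtering is
zero-phase so R-peak latencies are preserved (< 2 ms shift on synthetic
ECG).

## R-peak detection and artifact screening

A Pan–Tompkins-style detector: 5–15 Hz band-pass, derivative, squaring,
150 ms moving-window integration, block-adaptive threshold, 200 ms
refractory period, then snapping each detection to the local waveform
extremum (polarity chosen by the median local extremum over candidate
windows, which is immune to filter edge transients). On the synthetic suite
with mains + wander the detector reaches 100% recall/precision with ~0.2 ms
median timing error.

RR screening uses a deviation-deletion rule: an interval is deviant if it
leaves [300, 2000] ms or deviates > 30% from an 11-beat running median; the
deviant interval *and the interval immediately following it* are deleted
(a missed or spurious peak corrupts two consecutive intervals). The retained
fraction is retained time / total time; below 50% a quality warning is
attached. The thresholds are configurable defaults, not a reproduction of
any particular lab's unpublished screening procedure.

Mean HR is 60000 / mean(retained RR): the time-weighted rate matching
bpm-scale phase effects, not the mean of instantaneous rates.

## HRV indices

SDRR (sample SD, n−1) and RMSSD are computed over the whole phase; RMSSD
differences never span a deleted interval. Spectral indices use 6-min
windows advanced in 30-s steps; a window is rejected when > 20% of its time
was deleted. Within each accepted window the retained beats are cubic-spline
interpolated to a uniform 4 Hz tachogram (Nyquist 2 Hz ≫ 0.4 Hz) and a
mean-removed Welch PSD (120 s Hann segments, 50% overlap → ≥ 5 averages at
1/120 Hz resolution) is integrated over half-open bands LF [0.04, 0.15) and
HF [0.15, 0.40) Hz. Phase values are arithmetic means over accepted windows;
LF/HF is formed per window and then averaged (the ratio of averaged powers
is available by flag). With no accepted window the spectral fields are None
and time-domain indices are still reported.

Respiration rate is the dominant tachogram frequency in 0.12–0.5 Hz per
window (the lower edge sits above the 0.1 Hz LF rhythm so its spectral main
lobe cannot masquerade as breathing), flagged reliable only when the peak
exceeds 5× the median in-band PSD and lies in 6–30 cpm. The granularity of
the estimate is the Welch resolution, 1/120 Hz = 0.5 cpm.

## Inference

Per session, each index is baseline-corrected (phase − baseline); the net
stimulation effect is delta(taVNS) − delta(sham) per subject × side × phase.
Main effects across sides average each subject's two side estimates first.

The mean net effect is tested with a **studentized (percentile-t) bootstrap**
(default 50,000 resamples): resample the pivot t* = (mean* − b)/se*, CI
b − se·[q_hi, q_lo](t*), p = 2·min tail of t* around t0 = b/se, clipped to
[1/B, 1]. We chose the studentized variant over the raw percentile method
because the raw percentile test of a mean is anticonservative at crossover
sample sizes (it implicitly uses a z rather than a t reference and a
downward-biased scale), while the pivot restores near-nominal size and
coverage; the test suite verifies the calibration by simulation at n = 36.
The percentile variant remains available via ``method="percentile"``. p-values are Benjamini–Hochberg
adjusted within each phase across indices (statsmodels). Effect size is
Cohen's dz = mean/SD of the paired differences.

The JZS Bayes factor of the one-sample t-test uses a Cauchy(0, 0.5) prior on
the standardized effect — the width reflecting that small-to-moderate
effects are the plausible alternative. BF10 = ∫ f_nct(t; ν, δ√n) dC(δ) /
f_t(t; ν), evaluated by adaptive quadrature under δ = r·tan(θ), which maps
the Cauchy measure to the uniform measure on (−π/2, π/2); agreement with a
fine-grid quadrature oracle is 1e−6 relative.

The multivariate gate is Pillai's trace from a general linear model: V =
tr(H(H+E)⁻¹) with the standard F approximation; within-subject factors
(stimulation, side, phase, stimulation × phase) enter as effect-coded
columns on the per-observation delta vectors of the four HRV indices. The
per-observation (rather than subject-aggregated) coding treats session-level
deltas as exchangeable replicates; exact error-stratum bookkeeping differs
between software packages and is deliberately kept simple here.

Side consistency: per index, the correlation across subjects between left-
and right-side induced changes is Fisher z-transformed and the paired
z differences (active − sham) are tested with a one-sample t-test.

Inference refuses to run with fewer than 5 complete subjects.

## Power and blinding

The a priori sample size uses the noncentral-F model of G*Power's
"repeated measures, within factors" procedure: λ = f²·N·m·ε/(1−ρ),
df1 = (m−1)·ε, df2 = (N−groups)(m−1)·ε with ε = 1. Because groups are filled
equally, the required *total* N is searched in multiples of the number of
groups — with f = 0.15, α = 0.05, power 0.90, 2 groups, 4 measurements,
ρ = 0.8 this gives N = 34 (power 0.911; N = 32 reaches only 0.891). Note
that without the equal-allocation constraint the first N reaching 0.90 would
be 33. Blinding accuracy is 100·correct/total with a two-sided exact
binomial test against chance.

## Reproducibility and problem sizes

A single root seed is fanned out per stage via `numpy.random.SeedSequence`;
reruns are byte-identical. The test suite validates statistical calibration
at reduced problem sizes chosen to keep the suite fast while leaving Monte
Carlo error well inside the asserted bands: type-I calibration with 2,000
null replicates × 2,000 resamples; effect recovery with 100 replicate
studies of 36 subjects at 300-s phases (time-domain indices only — spectral
windows need ≥ 360 s); spectral recovery on 30-min single phases. Degenerate
inputs (all-zero differences, zero-variance indices, flat signals, all-
deviant RR series) return the documented degenerate results or raise with a
specific message rather than propagating NaNs.

## Known limitations

- The artifact rule's thresholds are conventions; real studies tune them.
- The respiration estimator reports the RSA spectral peak; when RSA is weak
  (low HF) it abstains rather than guessing.
- MANOVA degrees of freedom follow the per-observation GLM coding above;
  software that models explicit subject error strata will print slightly
  different df.
- The EDF writer quantizes to int16 over the observed range and pads to
  whole-second records (plain-EDF limitation); WFDB support covers only
  single-channel format-16 records.
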