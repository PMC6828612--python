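# Methods

This note documents the models, algorithms, parameter choices and
known limitations of `peritheta`. It states no empirical result beyond
what the test suite and `scripts/acceptance.py` compute.

## Trial classification

An *isolated* commission error is an incorrect keypress preceded and
followed by at least three correct trials within the same block. Its
six correct neighbours are labelled ER−3…ER−1 and ER+1…ER+3; correct
trials more than three positions from every error are *error-free*;
all other trials (non-isolated errors, misses, trials near non-isolated
errors) are excluded. Design choices where the definition leaves room:

* **Block boundaries are opaque.** Blocks are separated in time, so no
  classification window crosses them. An error within three positions
  of a block edge cannot be isolated (its required neighbours do not
  all exist); a correct trial near a block edge can still be error-free
  if no error lies within distance 3 inside the block (edge context is
  treated as error-free).
* **Misses** (omissions) break correct runs and disqualify neighbouring
  errors from isolation but are never themselves isolated errors —
  only commission errors are analysed.
* **Overlapping neighbourhoods.** Two isolated errors can sit exactly
  four to six trials apart, in which case a correct trial is claimed as
  ER+k by one and ER−m by the other. Such trials are excluded, since
  their RT would mix pre- and post-error effects. Both errors remain
  isolated.

Standardization divides by the error-free sample SD (ddof = 1) after
subtracting the error-free mean, per subject; it runs after
classification and before the subject-inclusion rule (≥5 isolated
errors). The streaming classifier is verified against a brute-force
O(n²) implementation of the definitions on 1,000 random sequences.

## Mixed models

RT models are linear mixed models with a single random intercept per
subject, fitted by **maximum likelihood** (not REML) so that
likelihood-ratio tests on fixed effects between nested fits are valid.
The likelihood is profiled: with V_i = σ²(I + ψ11ᵀ) per subject,
fixed effects and σ² have closed-form GLS solutions at each variance
ratio ψ, reducing the fit to a one-dimensional search over log ψ
(coarse grid + bounded refinement, 1e-10 tolerance; ψ = 0 — ordinary
regression — is always evaluated and reported when it wins). The
optimiser is validated against statsmodels `MixedLM(reml=False)` and a
dense 2-D grid over (ψ, σ²).

Trial position is coded −3, −2, −1 (pre) and 1, 2, 3 (post) and fitted
in separate pre/post models, centred within each period so the
intercept is the period mean. Groups use treatment coding with TD as
reference; post-hoc contrasts refit on subsets (e.g. ADHD only). No
multiple-testing correction is applied — each LRT is reported at its
nominal level, and the results table makes that explicit by carrying
raw p-values only.

Accuracy is modelled with a random-intercept logistic mixed model.
The marginal likelihood integrates the subject intercept by **adaptive
Gauss–Hermite quadrature** (21 nodes; each subject's integrand is
re-centred at its conditional mode and re-scaled by the local
curvature). It is validated against R's `lme4::glmer(nAGQ = 21)` on a
frozen fixture and against plain logistic regression at τ → 0. Large
coefficients (|β| > 10) trigger a separation warning and are clipped.

The 2×2 split-plot ANOVA (group × trial position on subject means)
follows the conventional decomposition — between-subject effect from
subject averages, within and interaction effects from within-subject
differences, denominator df = n−2 throughout — and matches
`pingouin.mixed_anova` numerically (the within main effect tests the
sample-weighted grand mean under unequal group sizes).

Power for the two-sided two-sample t-test uses the noncentral t
distribution with ncp = d·√(n₁n₂/(n₁+n₂)) and df = n₁+n₂−2; the
minimum detectable effect inverts it by bisection (1e-4 tolerance).
Group t-tests use pooled variance (Student), matching the df a
complete-case two-group comparison reports.

## EEG preprocessing

Filters are 4th-order Butterworth run forward–backward
(`sosfiltfilt`), so they are zero-phase and the effective attenuation
is the squared one-pass magnitude — the documented magnitude-response
tests account for this. Notch 48.5–51.5 Hz, band-pass 0.3–40 Hz. The
acquisition-stage filter and reference of a real amplifier are not
simulated; the analysis is band-limited anyway.

Blinks are detected on VEOG as local maxima of |x − median| above k
(default 5) times the MAD-based robust SD (1.4826·MAD), with a 300 ms
refractory period — a threshold rule standing in for per-recording
visual verification, and configurable where a recording needs it.

Ocular cleaning uses joint decorrelation: the generalized
eigendecomposition of the covariance of ±300 ms blink-centred windows
against the whole-recording covariance ranks spatial components by
blink-to-total power ratio; the top component (configurable, or all
components above a ratio threshold) is projected out and the data
reconstructed in sensor space. The decomposition runs over all ten
channels including EOG: with VEOG in the mix the blink component loads
dominantly on it, which keeps the spatial filter nearly orthogonal to
fronto-central theta — with scalp channels alone, a frontal blink
pattern overlaps the FMΘ topography enough to bleed genuine theta out
of Fz/Cz. Rank-deficient covariances are ridge-regularized
(1e-9 × mean channel power).

Epochs are cut −2…+2 s around each response (2001 samples at 500 Hz;
sample 1000 is the response); responses too close to the recording
edges are dropped and logged. Rejection marks any epoch whose scalp
channels (EOG exempt) exceed ±80 µV after cleaning. The stage order is
fixed: notch → band-pass → blink detection → joint decorrelation →
epoch → reject.

## Time–frequency analysis

Power is computed by FFT over 0.5 s Hann-tapered windows centred on a
−1.5…+1.5 s grid in 50 ms steps, at 2–36 Hz in 2 Hz steps. A 0.5 s
window at 500 Hz gives exactly 2 Hz bin spacing (250 samples, no zero
padding; bins 1–18). The periodic ("DFT-even") Hann window makes the
on-bin response exact: a sinusoid of amplitude A on a bin centre
yields power A²/2 (its mean square, in µV²) independent of phase,
which the closed-form tests exploit. Power is expressed as
10·log₁₀(µV²) with a −300 dB floor guarding silent segments.

Baseline correction subtracts, per trial and frequency, the mean
log-power of the 11 windows whose centres fall in −0.75…−0.25 s
relative to that trial's prime onset, computed from the same
response-locked epoch via the stored prime offset (numerically
equivalent to re-epoching on the prime, given the stated windows).
Trials whose baseline windows do not fit in the epoch are flagged and
excluded from summaries. FMΘ is the arithmetic dB mean over the 4, 6
and 8 Hz bins and electrodes Fz and Cz; the per-trial scalar summary
averages over −0.4…+0.4 s (17 grid points). Group statistics run on
participant-wise mean summaries, appropriate for the low isolated-
error counts the design produces.

## The synthetic cohort

The generator emulates a two-group (TD / ADHD) masked-priming session:
288 trials in three blocks per subject, prime→target SOA 150 ms (a
typical value for this paradigm; not rendered in the EEG),
inter-trial interval jittered uniformly 1.5–2.0 s — chosen so a
pre-prime baseline window can never overlap the previous response's
±0.4 s theta burst. Defaults: error rates 6.8% (TD) / 9.7% (ADHD);
error-free RT 427 ± 31 ms (TD), 459 ± 41 ms (ADHD); error trials at
−1.39 SD; pre-error offsets (−0.16, −0.26, −0.36) SD at ER−3…ER−1 in
both groups; post-error offsets (0, 0, 0) in TD and (−0.44, −0.02, 0)
in ADHD — immediate recovery in TD, recovery delayed by one trial in
ADHD; compatibility effect 20 ms (+27 ms extra in ER+1); subject
random intercepts N(0, 0.05) in SD units (kept small so fixed effects
dominate; no between-subject variance is separately specified by the
emulated design). The trial-level residual is scaled so error-free
trials have unit variance *including* the compatibility term, making
the standardized scale exact by construction. Correctness layouts are
redrawn (bounded retries) until a subject has ≥5 isolated errors,
mirroring the analysis inclusion rule; error/miss draws are i.i.d. per
trial, and feedback-driven trial repetition at block ends is not
modelled — it would change trial counts, not the peri-error logic
under test.

EEG is rendered at 500 Hz on F3, Fz, F4, C3, Cz, C4, O1, O2 plus
bipolar VEOG/HEOG: per-channel 1/f Gaussian background (10 µV RMS,
spectrally synthesized, flattened below 0.5 Hz), a 2 µV 50 Hz line
component, Poisson eyeblinks (0.2 Hz; biphasic ~400 ms template,
200 µV on VEOG, frontally weighted on scalp), response-locked 6 Hz
bursts under a ±0.4 s Hann envelope (Fz/Cz weight 1, neighbours 0.5),
and occasional 150 µV artifact segments to exercise rejection.

**Burst calibration.** The injected dB values are defined in terms of
the *pipeline's own measure*, so burst amplitudes are calibrated, not
assumed: noise-only 4 s epochs sliced from a long stream with the
generator's PSD are passed through the package's STFT → baseline →
FMΘ → ±0.4 s summary, a candidate burst is added, and the amplitude is
bisected until the measure hits the target. Because the null measure
is zero in expectation (baseline and activation windows are
exchangeable without a burst), the same noise realisation's null
measure is subtracted as a control variate, which removes most of the
Monte-Carlo error; 384 epochs leave a residual calibration uncertainty
of roughly ±0.1 dB at the 3 dB target. Calibration uses a fixed
internal seed and is cached per parameter set, so generation stays
deterministic.

What the generator does **not** emulate: evoked (phase-locked)
stimulus responses, topographically realistic volume conduction,
saccades/HEOG structure, non-stationary arousal drifts, or any
feedback dependence of behaviour. Passing recovery tests therefore
demonstrates that the pipeline measures what it claims on data obeying
its assumptions — not that those assumptions hold for any particular
real recording.

## Problem sizes in the tests

Behavioural parameter recovery runs at 200 subjects per group (fixed
seed), where mixed-model estimate noise is ~0.01–0.03 SD. EEG recovery
runs 20 replicate cohorts of 40 subjects with one 96-trial block each —
enough isolated errors per subject (≥5 by construction) for the
group-separation test, with the ±0.3 dB recovery check pooled across
replicates. The LRT calibration simulation uses 1,000 null cohorts of
20 subjects × 20 trials.

## Known limitations

* Random intercepts only; no random slopes, crossed effects, or
  Satterthwaite/Kenward-Roger df. LRT p-values on variance components
  at the ψ = 0 boundary would be conservative; the package only tests
  fixed effects.
* The logistic mixed model optimises a numerically-differentiated
  likelihood; for very large cohorts an analytic-gradient
  implementation would be faster.
* The EDF writer supports exactly the features the simulator needs
  (one rate, 1 s records, µV, 16-bit); recordings are zero-padded to
  whole records.
* Joint decorrelation removes a fixed number of components (default 1);
  recordings with multiple strong artifact sources need the ratio
  threshold mode.
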