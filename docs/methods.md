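# Methods

`qeeglda` implements a quantitative-EEG analysis chain for dementia group
discrimination: spectral parameterization of resting EEG into six
channel-level features, regularized linear discriminant analysis (RLDA)
with analytic covariance shrinkage, and repeated cross-validated ROC
evaluation. Because the clinical recordings this design targets are not
publicly available, the package ships a synthetic cohort generator whose
ground truth lives in the same six-parameter space the pipeline estimates;
every end-to-end claim in the test suite is therefore a parameter-recovery
or calibration statement against known truth.

## Spectral model

Each channel's average power spectrum over 0.5–30 Hz is modeled as

    P(f) = b + S · f^(−k) + A · exp(−(f − c)² / (2 w²))

with `S` (µV² per 0.5-Hz bin) scaling low-frequency (delta) power, `k`
(dimensionless, bounded [0, 5]) the 1/f decay exponent, `A`/`c`/`w` the
amplitude (µV²), center (Hz, bounded [6, 14]) and dispersion (Hz, bounded
[0.3, 5]) of the alpha peak, and `b` (µV²) a broadband baseline. The model
deliberately carries a single oscillatory component: theta or beta peaks are
outside its scope, and `k` and `b` jointly control the high-frequency floor,
which induces the well-known coupling between their estimates.

Fitting is bounded trust-region nonlinear least squares in linear power
space (so that R² reads as fraction of data variance explained), with an
analytic Jacobian. Initialization: `b` from the 25–30 Hz minimum, `k` from a
log–log regression after subtracting it, `S` from 1-Hz power, `c`/`A` from
the residual maximum in 7–13 Hz, `w` = 1.5 Hz. If the first solution's R²
falls below 0.95 — on this data a signature of a bad basin rather than of
noise, whose ceiling is higher — up to four jittered restarts (deterministic
from the fit seed) are tried and the best-R² solution kept. Fits never
raise: non-convergence is flagged and the best attempt returned, so a cohort
run cannot be lost to one bad channel. A log-power fitting space is
available as an option.

## Spectral estimation

The pre-processing chain mirrors standard clinical qEEG practice:

* polyphase resampling to 256 Hz (accepted input rates 128/256/500 Hz);
* zero-phase band-pass 0.5–50 Hz built as a 1536-order least-squares
  linear-phase FIR high-pass cascaded with a 256-order least-squares
  low-pass. The two halves are designed separately because a single
  least-squares design spanning both edges at this length is numerically
  ill-conditioned. The symmetric kernel is applied forward and
  time-reversed via FFT overlap-add convolution with reflect padding —
  identical to filtfilt for a linear-phase FIR but far faster at ~1800 taps
  on minutes of 22-channel data;
* artifact screening on non-overlapping 1-s epochs with three criteria:
  max |amplitude| > 100 µV; broadband-power z-score (across epochs) > 4;
  spatial-STD (sSTD) z-score > 3. The sSTD index of an epoch is the standard
  deviation across the 22 channels of per-channel log10 broadband power —
  an interpretation chosen because it flags epochs whose spatial power
  profile departs from the record's norm (localized artifacts), while being
  insensitive to global power shifts already caught by the power criterion.
  Surviving epochs are re-concatenated before segmentation;
* segmentation into 2-s epochs with 1-s overlap and rectangular-window FFT —
  Welch's method with 50% overlap. Per-bin power is total power per 0.5-Hz
  bin, normalized so the sum over all non-DC bins equals the epoch's
  time-domain variance (Parseval); the 100 bins at 0.5–50 Hz are retained;
* arithmetic averaging over epochs, truncated to the first 334 epochs
  (~5.5 min of clean data) to standardize the amount of data per subject.

Since the z-score criteria are calibrated cutoffs on a continuous
distribution, they reject a small fraction (≈0.1–0.5%) of genuinely clean
epochs; recordings are generated a few seconds longer than the 335 s that
334 epochs require.

## Synthetic cohorts

Group profiles start from a healthy-control base (anterior/posterior alpha
asymmetry, per-channel signal SD ≈ 12–15 µV — a realistic resting-EEG
amplitude scale that keeps clean-epoch peaks below the 100 µV screening
threshold) and deviate in the directions reported for dementia spectra, all
linear in `effect_scale`:

| group | delta scale S | alpha amplitude A | alpha center c |
|---|---|---|---|
| AD-like | × 1.3 globally | × 0.7 posterior | − 1.0 Hz posterior |
| VaD-like | × 1.8 globally | × 0.8 globally | − 1.0 Hz posterior |

The posterior alpha slowing is shared by both dementia profiles (reduced
posterior dominant rhythm frequency is described for both), which — together
with the shared delta increase and alpha reduction — makes the pooled
HC-vs-dementia contrast (Model 4) separate better than AD-vs-VaD (Model 3)
by construction. At `effect_scale = 0` the three groups are identical, giving
the exchangeable null cohort used for chance-level calibration.

Between-subject variability is a per-parameter normal deviation shared
across all channels of a subject (SDs: S 5, k 0.4, A 2.5, c 1.0 Hz, w 0.3 Hz,
b 0.25) plus a smaller independent per-channel deviation (S 2, k 0.15,
A 1.2, c 0.4, w 0.15, b 0.08), clipped at the parameter bounds. The shared
component is deliberate: if all 22 channels varied independently, a global
group effect would accumulate discriminability ∝ √22 and every contrast
would saturate at AUC ≈ 1; with a dominant subject-level component the
ideal two-class separations land in the fair-to-good AUC range that
clinical spectral features actually achieve. These scales were fixed once
from that separation argument.

Time series are colored noise built by inverse FFT: sinusoidal components at
the signal's frequency resolution over 0.5–50 Hz with deterministic
amplitudes matching the model curve (interpreted as power per 0.5-Hz bin)
and i.i.d. uniform phases, so the expected Welch spectrum equals the model
curve exactly. Artifacts are 300-ms Gaussian-envelope transients (~600 µV
peak, random polarity per channel) injected with a per-second Bernoulli
probability. The generator does not emulate ocular/muscle artifact
morphology, age or sex structure, eyes-open/closed alternation, or
within-recording nonstationarity — recordings are treated as stationary —
so passing tests demonstrate correctness of the estimation machinery under
the stated model, not robustness to every property of clinical EEG.

A direct-spectra mode bypasses time-series synthesis for cohort-scale runs:
each bin of the model curve is multiplied by an independent Gamma(m, 1/m)
variate with m = ⌈n_epochs/2⌉, the effective number of independent
periodograms among n_epochs half-overlapping ones. This reproduces the
first two moments of Welch noise at a tiny fraction of the cost.

## Features, normalization, screening

Each subject contributes 6 parameters × 22 channels = 132 predictors in
channel-major order. Columns are mapped toward normality by a per-column
Box–Cox transform whose λ is estimated by maximizing the profile
log-likelihood with a bounded scalar search (agrees with scipy's ML
estimate to <0.01 but is ~100× faster, which matters because the transform
is refitted on every training fold); non-positive columns receive a recorded
shift, and zero-variance columns pass through flagged.

The reduced-feature mode screens columns by point-biserial correlation with
the binary labels, computed on training rows only: p-values come from
t = r√((n−2)/(1−r²)) on n−2 df, two-tailed. Stated thresholds of |r| < 0.15 and p < 0.01 can be read as either a
single magnitude criterion or a conjunction; the default here rejects on
|r| < 0.15 alone (at n ≈ 198 the two nearly coincide), and a conjunction
rule (keep iff |r| ≥ 0.15 and p < 0.01) is available. Both the transform
and the screen are leakage-free by construction — a property the test suite
asserts by mutating held-out rows. A global-transform mode reproducing a
single whole-sample Box–Cox is provided for fidelity comparisons.

## Regularized LDA

The binary discriminant uses the pooled within-class covariance S (classes
centered on their own means) shrunk analytically toward the scaled identity:

    Σ̂ = (1 − λ) S + λ ν I,   ν = trace(S)/p,
    λ* = clip( Σᵢⱼ V̂ar(sᵢⱼ) / Σᵢⱼ (sᵢⱼ − ν δᵢⱼ)² , 0, 1 )

with entry variances estimated from the centered cross-products
(V̂ar(sᵢⱼ) = n/(n−1)³ · Σₜ(xₜᵢxₜⱼ − mean)²). This is the Ledoit–Wolf-style
closed form: eigenvalues are compressed toward their mean, Σ̂ is positive
definite whenever ν > 0 (including p ≫ n), and λ tracks scikit-learn's
`ledoit_wolf` intensity (asserted in tests). One consequence worth knowing:
when the true covariance is isotropic the target coincides with the truth
and λ correctly approaches 1 — λ → 0 at large n holds only for anisotropic
truth. Weights are w = Σ̂⁻¹(μ₁ − μ₀) via a positive-definite solve; the bias
is the midpoint wᵀ(μ₀+μ₁)/2, i.e. equal priors, appropriate for the
balanced designs used throughout. A nested-CV λ grid search is available as
the alternative the analytic estimator replaced.

## Evaluation protocol

10-fold cross-validation with stratified, seeded, near-equal folds (a
228-subject contrast yields folds of 22–23: a fixed fold size of 22 with
198 training rows cannot tile 228 subjects, since 10 × 22 = 220, so
near-equal partitioning is used). Per fold: Box–Cox on the
training rows, optional screening, RLDA fit, held-out scores and
ACC/TPR/FPR. The robustness ("bootstrap") loop repeats the whole CV 20
times with freshly randomized fold assignments — robustness to the data
permutation, not resampling of subjects; true resampling with replacement
exists behind a flag. Per repeat, cv-ACC is the mean fold accuracy and AUC
comes from the repeat's pooled held-out scores via a threshold sweep whose
trapezoid area equals the midrank Mann–Whitney U/(n₀n₁) (asserted to 1e-12
against scipy). Summaries report mean and SEM over repeats plus a
vertically averaged ROC (TPR interpolated on a 101-point FPR grid with an
SEM band). The four diagnostic contrasts are HC–AD, HC–VaD, AD–VaD, and
HC vs pooled dementia, with the patient group (VaD in Model 3) as the
positive class.

## Problem sizes and determinism

Everything is reproducible from single master seeds fanned out through
`numpy.random.SeedSequence`; all derived seeds stay below 2³¹. The shipped
acceptance script and the heavier tests run cohorts at the study's sample
size (114 per group; 228- and 342-subject predictor matrices) in
direct-spectra mode, and exercise the full time-series chain on 50 subjects
× 334 epochs for parameter recovery — sizes chosen so a complete
verification pass stays in the minutes range on one CPU while still
operating at the design's native n.

## Known limitations

* The spectral-model equation, the sSTD index and the shrinkage variant
  each follow one concrete reading of practices that appear in the clinical
  qEEG and BCI literature in several variants; the choices here realize the
  stated parameter semantics and are pinned by recovery/oracle tests rather
  than by comparison with any reference implementation.
* Clinical headline performance is not a target: synthetic cohorts have no
  claim to the original patients' effect sizes, so AUC/cv-ACC values are
  comparable in structure (orderings, calibration) but not in magnitude.
* `k` and `b` are weakly identified from 0.5–30 Hz data alone; their
  estimates co-vary even on noiseless input. This is a property of the
  model family, reported via the parameter-correlation audit.
* EDF input is a thin optional reader (requires `mne`); no attempt is made
  to handle referencing schemes beyond channel-name matching.
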