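# Methods

This note records the models implemented, the defaults chosen where the
methodology left them open, and what the synthetic tests do and do not show.

## Data model and conventions

The central object is the three-way cube `X[i, j, k]` — sample, excitation
wavelength, emission wavelength — with strictly increasing, uniformly spaced
wavelength axes in nm. All public indices are 0-based; wavelengths are the
coordinate system users see. The canonical interchange format is a plain-text
archive (TSV manifest + one CSV per sample, emission rows × excitation
columns, masked cells as `NaN`); an HDF5 bundle exists for speed. Numeric
text is written with ≥ 12 significant digits so a round trip is lossless to
1e-9.

## Scatter excision and gap filling

Cells within a half-width of three ridges are masked: first-order Rayleigh
(|em − ex| ≤ 12 nm), second-order Rayleigh (|em − 2·ex| ≤ 15 nm), and the
water Raman band at `em = 1/(1/ex − ν̃·1e-7)` with ν̃ = 3400 cm⁻¹
(half-width 10 nm). The half-widths are configurable; these defaults are
common EEM practice. The physically signal-free region below the first
Rayleigh line (emission < excitation) is zeroed by default rather than
interpolated. Masked cells are filled by monotone piecewise-cubic (PCHIP)
interpolation along the emission axis — emission is the densely sampled mode
(1 nm vs 10 nm) — with nearest-value constant extension where a masked run
reaches the end of the vector. If the mask ever covers an entire emission
vector the code refuses with the offending excitation named, since
interpolation would be unconstrained.

## MSC

MSC operates on the unfolded whole-EEM vector (length J·K), not per emission
spectrum, so that the correction, the Kennard–Stone distances, and the
decomposition all see the same vectorization. The reference defaults to the
mean of the *training* samples; a `msc_reference: all` switch reproduces the
global-mean alternative. MSC exactly inverts any per-sample affine distortion
of the reference; a fitted slope within 1e-12 of zero is an error, not a
silent pass-through.

## Splitting

Kennard–Stone is run within each class (stratified); role quotas are the
largest-remainder rounding of the requested fractions, ties resolved in role
order. The ordering is consumed train → validation → test, so the extreme,
space-covering picks train the model and the later, more central picks
evaluate it. The module contains no randomness.

One ordering question is genuinely circular in the methodology as stated:
distances "should" be computed on MSC-corrected data, but the MSC reference
is the training mean, which requires the split. The pipeline therefore splits
on the scatter-excised, interpolated, *pre-MSC* vectors and applies MSC with
the training-mean reference afterwards. This also makes the leakage guarantee
provable: removing the test rows (with per-class train/validation quotas held
fixed) cannot change any training or validation artifact, because the greedy
max-min selection of the surviving samples is a prefix-stable function of the
candidate pool — samples picked after rank r never influence picks 1..r.

## PARAFAC

Alternating least squares on the three mode unfoldings, with deterministic
initialization from the leading singular vectors of each unfolding (random
restarts are available behind an explicit seed). Convergence is declared when
the relative SSE change drops below 1e-8 (max 2000 iterations);
non-convergence sets a flag rather than raising. After convergence the score
matrix A is refreshed once against the final loadings, so that scoring a
training sample by least-squares projection reproduces its score row to
machine precision. Normalization convention: B and C columns unit-norm, scale
carried by A; the largest-magnitude element of each loading column is made
positive, signs compensated in A. This absorbs the scale/sign indeterminacy
completely — two runs from the same initialization are bit-comparable. No
non-negativity or unimodality constraints are imposed: MSC-corrected
intensities can legitimately be negative.

## Tucker3

Higher-order orthogonal iteration from a truncated higher-order SVD start;
A, B, C orthonormal, magnitudes in the core G, same sign convention with
signs absorbed into G. "F factors" maps to the cubic rank triple (F, F, F)
truncated per mode where a mode is smaller, since nothing in the methodology
fixes the three ranks separately. As with PARAFAC, a final A-refresh against
the converged loadings makes the projection identity exact. The SSE equals
‖X‖² − ‖G‖² by orthogonality, which the reconstruction-based explained
variance cross-checks.

## Projection of held-out samples

Validation and test samples are scored by ordinary least squares with the
loadings (and core) fixed: PARAFAC regresses each unfolded sample on the
Khatri–Rao basis `C ⊙ B`; Tucker3 on `(B ⊗ C)·G₍₁₎ᵀ`. This is the standard
choice and the one consistent with least-squares fitting of the training
scores themselves.

## QDA

The discriminant is the standard Mahalanobis form
`Q_k(x) = (x − x̄_k)ᵀ Σ_k⁻¹ (x − x̄_k) + ln|Σ_k| − 2 ln π_k`, with unbiased
per-class covariances and empirical priors `π_k = n_k/n`. (The printed
source formula carries a transposed covariance and a stray transpose on the
second difference vector; the standard form is what "classification scores
using Mahalanobis distance" describes, and it is what reproduces the
published metric values.) A ridge `ε·I` is added only when the smallest
eigenvalue falls below 1e-10 of the largest, and the affected class is
recorded on the model. Predictions are invariant under any invertible linear
map of the score space — every Q shifts by the same `2 ln|det M|` — so the
decomposition's scale indeterminacy cannot leak into the classification.

## Figures of merit

All of: per-class and overall correct-classification rate, accuracy,
sensitivity, specificity, precision, F_β (default β = 2, weighting recall
twice as much as precision: a false negative is an undiagnosed patient), MCC,
Youden's γ, likelihood ratios ρ± and test effectiveness
`δ = (√3/π)[logit(SENS) + logit(SPEC)]`. The overall rate is computed with
the two error counts *summed* (the subtracted form seen in print is treated
as a typo; summing makes it equal accuracy, which holds for every confusion
table and is asserted property-wise). Boundary cases are total: a perfect
specificity yields ρ+ = δ = ∞, serialized as the literal `Inf`. Percentages
are reported at 2 decimals; full precision is kept internally.

## Synthetic cohorts

The generator emulates what the analysis assumes, not real plasma spectra:
an exactly trilinear signal from Gaussian-band fluorophores, log-normal
concentrations (positive, right-skewed; CV 0.25), a log-normal per-sample
gain (CV 0.10), scatter ridges, and i.i.d. Gaussian noise (SD 0.02 against
band amplitudes of order 1). Defaults: 83 diseased / 147 control samples on
the 11 × 551 grid; four bands — tyrosine-like (ex 275/em 305 nm),
glycated-amyloid-like (335/399), NADH-like (350/465), broad
collagen/elastin-like (310/400) — with widths 15–22 nm (excitation) and
30–60 nm (emission). The disease effect is a 2-SD downward shift of the
NADH-like concentration mean, producing the expected intensity decrease in
the ~360–470 nm emission region.

Two generator choices matter for testability and are deliberate:

* **Distinct excitation bands.** Two components sharing an identical
  excitation profile violate the k-rank condition for trilinear uniqueness;
  no algorithm could separate them. The presets therefore stagger the
  excitation centers.
* **Ridge widths consistent with excision.** Scatter ridge widths (4/5/3.5 nm
  Gaussian σ) follow the few-nm spectral bandwidth of a scanning instrument,
  so the default excision half-widths cover > 3σ of every ridge. Broader
  ridges would leave structured tails that no downstream step models.

What passing synthetic tests show: the pipeline recovers known low-rank
structure through realistic scatter/noise, respects the train/test
discipline, and its metrics are exactly right on known confusion tables.
What they do not show: performance on real plasma EEMs, whose effective rank,
inner-filter effects and batch structure the generator does not attempt to
mimic.

## Numerical and scaling choices

* ALS/HOOI tolerance 1e-8 relative SSE change, max 2000 iterations.
* Ill-conditioned ALS grams (condition > 1e12) fall back to the
  pseudo-inverse.
* Kennard–Stone ties break toward the lowest index; the first pair is the
  lexicographically smallest maximizer.
* The test suite exercises the full 230 × 11 × 551 cohort in the end-to-end
  and leakage checks, and a coarse 11 × 111 grid with 50 samples elsewhere;
  the five-seed end-to-end check uses 4 factors, which captures the four
  generating bands.
* Exact-100% explained-variance claims are verified at the decomposition
  layer; through the full pipeline, band interpolation and the MSC offset are
  mildly lossy for an exactly trilinear cube (≈ 99.96% observed at the true
  rank), which the pipeline tests assert explicitly.

## Known limitations

* No inner-filter or quenching correction, no blank subtraction.
* No missing-data (EM) variant of ALS — excised cells are interpolated
  upstream; no CORCONDIA diagnostic.
* Two-class problems only; no probability calibration (hard labels).
* The "canonical scores" sometimes plotted for such models have no defined
  transform here; raw factor scores are the stand-in.
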