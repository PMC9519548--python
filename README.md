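# eemqda

Classification of blood-plasma **excitation–emission matrix (EEM) fluorescence**
spectra for two-class diagnostic problems (diseased vs. healthy control), built
around multiway tensor decomposition and quadratic discriminant analysis.

An EEM is a fluorescence landscape measured over a grid of excitation ×
emission wavelengths; one matrix per sample, stacked into a three-way cube
`X (I samples × J excitation × K emission)`. The package implements the full
workflow a chemometrician would apply to such a cube:

1. **Scatter excision** — first/second-order Rayleigh ridges (emission ≈
   excitation, ≈ 2 × excitation) and the water Raman band (a fixed
   wavenumber shift from the excitation line) are masked and interpolated;
   they carry no fluorophore information.
2. **Multiplicative scatter correction (MSC)** — each sample's unfolded
   spectrum `x_i` is regressed on a reference `m` by OLS,
   `x_i ≈ a_i + b_i·m`, and corrected to `(x_i − a_i)/b_i`.
3. **Kennard–Stone splitting** — a deterministic max-min-distance ordering,
   stratified per class, assigns samples to training/validation/test with
   largest-remainder quotas (the 83/147 cohort at 162/34/34 fractions gives
   exactly (59, 12, 12) and (103, 22, 22)).
4. **Decomposition** — PARAFAC,
   `x_ijk = Σ_f a_if·b_jf·c_kf + e_ijk`, fitted by alternating least squares;
   or Tucker3, `x_ijk = Σ_rst a_ir·b_js·c_kt·g_rst + e_ijk`, fitted by
   higher-order orthogonal iteration. Held-out samples are scored by least
   squares against the fixed loadings.
5. **QDA** — class k is assigned by minimizing
   `Q_k(x) = (x − x̄_k)ᵀ Σ_k⁻¹ (x − x̄_k) + ln|Σ_k| − 2 ln π_k`
   on the decomposition scores.
6. **Figures of merit** — accuracy, sensitivity, specificity, precision,
   F_β (β = 2 by default: a missed patient costs more than a false alarm),
   MCC, Youden's γ, likelihood ratios ρ±, and the test effectiveness
   `δ = (√3/π)[ln(SENS/(1−SENS)) + ln(SPEC/(1−SPEC))]`, with exact ∞
   handling at boundary rates.

Because clinical cohorts of this kind are rarely public, the package ships a
**synthetic cohort generator**: trilinear mixtures of Gaussian-band
fluorophores with log-normal concentrations, a class-dependent decrease of an
NADH-like marker band (emission ~465 nm), scatter ridges, per-sample gain and
additive noise — with full ground truth for recovery testing.

## Worked example

```bash
eemqda run --seed 2 --out results/demo
```

simulates the default cohort (83 diseased + 147 controls on the
250–350 × 300–850 nm grid), runs the full pipeline with a 6-factor PARAFAC,
and prints:

```
explained variance: 99.41%
                AD   other
train        86.44   87.38
validation  100.00   95.45
test         91.67  100.00
                 parafac
Accuracy (%)       97.06
Sensitivity (%)    91.67
Specificity (%)   100.00
Precision (%)     100.00
F_beta-score (%)   93.22
MCC                 0.94
gamma (%)          91.67
rho+                 Inf
rho-               0.083
delta                Inf
```

The first table is the per-stage correct-classification rate per class; the
second the test-set figures of merit. `rho+ = Inf` and `delta = Inf` signal a
test set with zero false positives (specificity 100%), and MCC 0.94 a
near-perfect classifier on this synthetic draw. Library use mirrors the CLI:

```python
from eemqda import PipelineConfig, CohortSpec, run

report = run(PipelineConfig(synthetic=CohortSpec(seed=2), factors=6, seed=2))
print(report.merits["test"].mcc)
```

Other subcommands: `simulate` (cohort → CSV archive), `preprocess`, `split`,
and `select-factors` (validation metrics per candidate factor count — never
touches the test set).

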