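# Methods

## Signal models and units

Three representations of the per-voxel DWI decay are implemented in
`signal_models`: the two-point ADC `(1/b)·ln(S₀/S)`, the monoexponential
model `S₀·exp(−b·ADC_total)` over all b-values, and the biexponential
IVIM model `S₀·(f·exp(−b·ADC_fast) + (1−f)·exp(−b·ADC_slow))`. The IVIM
model assumes two non-exchanging pools — tissue water diffusing at
`ADC_slow` and capillary blood whose incoherent microcirculation appears
as a fast pseudo-diffusion `ADC_fast` occupying a fraction `f` of the
b=0 signal — and ignores relaxation differences between the pools (both
share one S₀).

All coefficients are stored in mm²/s internally; the serialization and
report layers multiply by 10³ to the conventional ×10⁻³ mm²/s scale. `f`
is a fraction in [0, 1] everywhere. The default acquisition scheme is
b = 0, 20, 50, 100, 200, 400, 600, 800, 1000 s/mm².

The two-point ADC of a noisy voxel can be negative (S(b) > S₀); such
values are retained and flagged rather than clamped, so ROI statistics
stay unbiased while quality masks remain available.

## Fitting

`fit_monoexp` takes a log-linear fit as the starting point and refines it
by nonlinear least squares in the signal domain, so high-b samples are not
over-weighted; on noiseless monoexponential input the log-linear step is
already exact.

`fit_biexp_segmented` is the field-standard two-stage estimator with one
refinement: (1) log-linear fit over b ≥ `split_b` gives `ADC_slow` and an
intercept, (2) `f = 1 − intercept/S₀`, (3) bounded 1-D least squares gives
`ADC_fast`. Because pancreatic tumors can have `ADC_fast` small enough
(≈6×10⁻³ mm²/s) that ~20% of the b=200 signal is still perfusion, the
plain two-stage fit is biased by tens of percent in that regime. The
three stages are therefore iterated (default 10 sweeps), each sweep
subtracting the current fast-compartment estimate from the high-b samples
before re-fitting the slow compartment. On noiseless input this converges
to a few percent of truth in the slow-perfusion tumor regime and to
~10⁻⁵ relative in the fast-perfusion healthy regime; `split_b` stays at
200 s/mm² (one of the scheme's values; the perfusion exponential is below
0.3 of its b=0 value there for typical pseudo-diffusion coefficients).

`fit_biexp_full` is a bound-constrained trust-region nonlinear least
squares over (S₀, f, ADC_slow, ADC_fast), initialized from the segmented
result; its residual sum of squares never exceeds the initializer's. S₀
is free by default; a pinned-S₀ mode (S₀ fixed to the measured b=0
signal) is provided because vendor implementations differ and neither
choice is derivable from the data alone.

Bounds: f ∈ [0, 1], ADC_slow ∈ [10⁻⁵, 3×10⁻³], ADC_fast ∈ [3×10⁻³,
5×10⁻²] mm²/s — brackets both tissue classes' means ± 2 SD while keeping
the compartments separated; when the optimum collapses the compartments a
monoexponential-collapse quality code is reported instead of a spurious f.
Solver tolerances are set to 10⁻¹⁵ so noiseless recovery reaches ~10⁻⁶
relative or better for well-separated compartments (fast/slow ≥ 5,
f ≥ 0.1); outside that identifiability region the quality code, not the
number, carries the message.

`fit_volume` applies all three estimators voxel-wise over a foreground
mask (b=0 signal above `noise_floor`, default 0 since phantoms are
clean). Per-voxel failures set quality codes and never abort the volume.

## Digital phantoms and cohorts

The patient images behind the modeled study are not public, so
`phantom` generates inputs with the same statistical structure: an
axial ellipsoidal "pancreas" (semi-axes 26×18×12 mm) with an optional
embedded spherical "tumor" (radius 8 mm) on a 32×32×6 grid at
2×2×5 mm spacing (5 mm slices as in the emulated protocol), one
trace-weighted signal per voxel, and Rician magnitude noise
`sqrt((S+n₁)² + n₂²)` with a single sigma per stack defined by the b=0
SNR (default 40 — an assumption surfaced in configuration, not a claim
about any scanner).

Cohorts default to 51 tumor / 57 healthy subjects. Per-subject IVIM
parameters are drawn from truncated Gaussians with the group means/SDs
(tumor: f 0.42±0.15, ADC_slow 0.84±0.32, ADC_fast 6.39±5.55 ×10⁻³ mm²/s;
healthy: 0.39±0.12, 0.92±0.26, 14.05±8.31), truncated at the fit bounds
because the reported spreads would otherwise produce negative
coefficients; the truncation shifts the ADC_fast means upward by a few
percent, which the tests quantify against the analytic truncated-normal
mean rather than the raw mean. Tumor attributes (grade 14/51 poor,
location 30/51 head, stage 38/51 T3/T4, nodes 29/51 positive, size
35±12 mm in [15, 90]) are sampled independently of the parameters: the
generator builds the study's null findings in by construction, which
makes the statistics layer's type-I behavior a testable property. The
truth table also carries the per-b ADCs and ADC_total implied by each
subject's noiseless signal, so generator → fitter round trips can be
scored column by column.

What the phantom does **not** emulate: anatomy (ducts, vessels, atrophy),
partial-volume mixtures, EPI distortion, motion/misregistration across
b-values, multi-coil noise statistics, or any dependence of diffusion
parameters on tumor attributes. Passing tests therefore demonstrate the
correctness and calibration of the estimators and statistics on data
satisfying the models' assumptions — not performance on real abdominal
DWI.

## ROIs

Ovals are rasterized by the voxel-center rule (a voxel belongs iff its
center is inside the ellipse), which is deterministic and
orientation-independent at these grid scales; area is voxel count ×
in-plane voxel area, pooled over slices for multi-slice masks. On
phantoms the placement is programmatic — an oval centered on the lesion
label, shrunk one voxel from the boundary — standing in for manual
placement on the solid tumor portion; the default tumor ROI lands inside
the emulated per-lesion range (55–308 mm²) and the gland ROI inside
35–108 mm². ROI means average quality-OK voxels (negative but flagged
two-point ADCs included, since they are measurements) and report the
excluded fraction; an ROI with no usable voxel raises instead of
yielding NaN.

## Statistics

Group comparisons use the Mann-Whitney U test (exact enumeration when
n₁·n₂ ≤ 400 and tie-free, otherwise the tie-corrected normal
approximation). The per-b ADC decline is tested with a Friedman rank test
over the eight non-zero b-values, followed by all 28 pairwise Wilcoxon
signed-rank tests at the Bonferroni-corrected threshold 0.05/28 ≈ 0.0018;
zero differences are discarded (Wilcoxon's convention) and an all-zero
pair is flagged degenerate. Multiplicity correction applies **only** to
this post-hoc family; the attribute-strata comparisons are reported
uncorrected, preserving the emulated analysis plan. Spearman correlation
(average-rank ties) relates parameters to tumor size and raises on
constant input.

ROC analysis fixes the orientation to "lower value ⇒ cancer" for every
parameter — auto-orientation would silently flip weakly separated
variables such as f. AUC is the trapezoidal area, which equals the
tie-corrected U/(n₁n₂); the optimal cutoff maximizes Youden's
J = sensitivity + specificity − 1 over observed values, ties broken
toward higher sensitivity, and a subject is called positive when its
value is ≤ the cutoff. Predictive values and accuracy come from the
confusion matrix at sample prevalence; published PPV/NPV/accuracy tables
based on other (unstated) conventions will not match cell-for-cell.

## Pipeline and determinism

`simulate → fit → stats` communicate only through files (float64 NIfTI
stacks so noiseless round trips stay exact, FSL-dialect bval lists, CSV
tables, JSON summaries). Every stochastic routine takes an explicit seed;
one master seed makes a whole run reproducible, and each output manifest
records the seed and a configuration hash. The fit stage caches
per-subject results and resumes; a failing subject is isolated and
logged. The `roi_only` mode fits just a box around each subject's ROI —
the downstream statistics consume only ROI means, so this trades map
completeness for an order-of-magnitude speedup and is what the test
suite and examples use for cohort-scale runs.

## Problem sizes used in validation

The test suite and acceptance script run: single-voxel recoveries at the
nine-point scheme; 20-voxel comparisons against a 50³ grid-search oracle;
200-replicate Monte-Carlo checks at SNR 40; cohorts of 4–108 subjects
through the file-based pipeline (noiseless, ROI-only fitting); 500
null-cohort replicates (51/57 subjects each) for type-I calibration; and
1000 random small samples for the AUC↔U identity. These sizes keep the
full validation in the tens of seconds while leaving every statistical
check comfortably powered.

## Known limitations

- The segmented fit's iterative de-biasing assumes the biexponential
  model holds; on tissues with a third compartment it converges to a
  model-misspecified optimum like any IVIM fitter.
- ADC_fast is weakly identified at low f or low SNR; expect wide spreads
  (the generating populations themselves have SD ≈ mean for ADC_fast).
- The cohort generator samples parameters independently within a subject;
  real tissue parameters are correlated.
- `simulate_cohort` uses the default phantom geometry for every subject;
  only the noise level of the template is honored per-subject.
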