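# Methods

This note records the models implemented by `tissuemetrics`, their
assumptions, the defaults and why they were chosen, the numerical
conventions, and what the synthetic validation does and does not
establish about real tissue images.

## Imaging model and preprocessing

The analyses assume transmission (brightfield) imaging, where the
recorded intensity is, to first order, linear in the local optical path:
denser, more refractile tissue transmits less light. Intensity is
therefore treated as a proxy for local mass density throughout; no
stain-specific modeling is attempted.

Images are converted to luminance with the ITU-R BT.601 weights
(0.299, 0.587, 0.114) and resampled bilinearly to a 512×512 grid, whose
side is divisible by every dyadic sub-box size used downstream. 16-bit
rasters are rescaled onto [0, 255] by the exact ratio 65535/255.

**Foreground convention.** Binarization marks pixels *strictly below*
`threshold_fraction × 255` as foreground: in transmission, optically
dense tissue is dark, so the "occupied" phase for box-counting is the
dark one. The fraction refers to the full 8-bit range, not the per-image
maximum, so one threshold means the same physical cut across a cohort.
`invert=True` flips the convention for stains where the structure of
interest is bright. Default threshold: 0.65, the value at which the
between-group mean-D_f contrast is largest in this style of analysis
(0.45 maximizes the STD contrast; `sweep_threshold` recomputes both
optima for any data set).

## Box-counting dimension

Per 32×32 sub-box, occupied-cell counts N(ε) are taken at the dyadic
scales ε ∈ {2, 4, 8, 16}. The top scale ε = 32 would give N ≡ 1 for any
non-empty block and carries no information, so it is excluded. D_f is
the OLS slope of ln N(ε) on ln(1/ε) over scales with N > 0, clipped to
[0, 2] to guard against floating-point noise. Blocks with fewer than two
usable scales (empty, or occupied at one scale only) are *missing*, not
zero: a zero would drag group means toward bare glass. Group statistics
pool all defined sub-box values across a group's images.

Validation: the estimator is exact on space-filling blocks (D_f = 2),
single pixels (D_f = 0) and recovers ln8/ln3 on the Sierpinski carpet
and ln5/ln3 on the Vicsek cross to better than 0.05 at level 5
(243×243, scales 3^k); the counting kernel is checked cell-for-cell
against a brute-force double loop on random blocks.

## Transforms and distribution summaries

`Dtf = Df / (df_max + guard − Df)` with `df_max` the maximum D_f pooled
over *all* images analyzed together (both groups — a per-group maximum
would make the transforms incomparable) and `guard = 1e-6` so the
sub-box attaining the maximum maps to a large finite value rather than
infinity. The transform is strictly increasing, hence rank-preserving;
it widens spacing near `df_max`, which is where disordered cohorts
concentrate.

Histograms use 70 equal-width bins spanning [min, max] of the pooled
values. Polynomial smoothing uses least squares of degree 8 — high
enough to follow multi-lobed shapes on 70 bins, low enough not to
oscillate — with fitted values floored at zero; the degree is
configurable. The Gaussian fit is nonlinear least squares (height, peak,
sigma), seeded from histogram moments, with a moments fallback flagged
via `converged=False` if the optimizer fails. Its goodness score is
`100·(1 − SS_res/SS_tot)` clipped to [0, 100] — an R²-style percentage;
this scoring convention is this package's, chosen for interpretability,
and is documented rather than inherited from any external definition.

## Chhabra–Jensen spectrum

The measure is the raw grayscale intensity mass (the analysis reads the
density distribution, so it runs on the grayscale raster, not a binary
mask). For each q in −10…+10 (step 0.5), weights
μ_i = P_i^q / Σ P_j^q are formed in log space (stable for |q| ≤ 10 and
P_i ≥ 1e-300), zero-mass boxes dropped. α(q) and f(q) are cross-scale
regression slopes of Σ μ ln P and Σ μ ln μ against ln ε over the dyadic
scales {8, 16, 32, 64, 128} at 512 px (side/64 … side/4 generally;
at least three scales required); per-q R² is recorded as a diagnostic.
Regressing over scales, rather than evaluating a single-scale ratio,
suppresses lattice effects. τ(q) = q·α − f; the identities τ(1) = 0 and
f(α(1)) = α(1) hold to 1e-6 by construction and are asserted in tests.

Validation: on randomized quadrant cascades the estimator matches the
closed form τ(q) = −log₂ Σ p_i^q essentially exactly, because dyadic box
masses of a conservative cascade are exact products of the weights at
every level — the spectrum check is an equality up to float error, well
inside the 0.1 tolerance asserted.

Spectrum summaries: width = α_max − α_min over the q grid, peak α taken
at q = 0, asymmetry = (α_max − peak) − (peak − α_min).

## Tight-binding IPR

Per block, the optical potential is ε_i = (I_i − I₀)/I₀ with I₀ the
*block mean* intensity — this makes the potential zero-mean and blocks
mutually comparable, at the cost of filtering out fluctuations with
wavelength comparable to the block (see limitations). Blocks with zero
mean intensity are skipped and recorded as missing. The Hamiltonian is
dense L²×L², diagonal ε_i, hopping t = 1 (the energy unit) on the
2L(L−1) nearest-neighbor bonds of the open (hard-wall) L×L grid; blocks
are independent lattices. All L² eigenstates of the full `eigh`
diagonalization enter the block mean — no energy windowing.

**Normalization.** Reported IPR = L²·Σψ⁴ (area-normalized), so the
extended-state floor is O(1) — exactly 1.0 for a uniform eigenvector —
and a delta-localized state reports L². The raw Σψ⁴ is emitted
alongside. The disorder-free 32×32 lattice has mean reported IPR
2.48215738…, frozen in the tests as a direct-diagonalization constant;
disordered blocks sit above this floor.

Blocks with bit-identical potentials within one image (uniform glass,
saturated regions) share a single diagonalization via memoization; this
changes nothing numerically.

**Disorder response.** Mean block IPR grows with the relative
fluctuation strength ⟨dn⟩ and, for correlation lengths small compared
with the block, with l_c — the linear disorder-parameter regime
IPR ∼ ⟨dn⟩·l_c. Because I₀ is the block mean, variance at wavelengths
≳ L is removed from the potential: the l_c response flattens and then
reverses once l_c approaches the block side (measured turnover near
l_c ≈ L/8 at L = 32 under strong disorder). The monotonicity tests
therefore ladder l_c over 1–3 px at L = 32, inside the regime the linear
law describes, and ⟨dn⟩ over 0.02–0.10 at fixed l_c = 3.

## Synthetic data

The generators define the study conditions for all cohort-level claims:

* **Disorder field**: stationary Gaussian field with exponential
  correlation exp(−r/l_c) — the simplest single-parameter correlation
  family — synthesized spectrally (FFT of the periodic kernel embedding,
  negative spectral weights clipped, white noise filtered by the
  root spectrum) and standardized sample-wise, so field std/mean equals
  ⟨dn⟩ exactly before clipping to [0, 255].
* **Cascade texture**: conservative four-weight quadrant cascade with
  per-cell shuffled weight positions; shuffling randomizes the geometry
  while leaving the analytic spectrum (a function of the weights only)
  unchanged.
* **Cohort images**: `I = clip(base · (cascade mass / mean) ·
  (1 + dn·g))` at base intensity 180. The base sits just above the 0.65
  threshold cut (165.75), so the foreground fraction — and with it the
  fractal statistics — responds to the fluctuation amplitude.
* **Presets** (chosen once as the package's default study conditions):
  control dn = 0.05, l_c = 2 px, weights (0.28, 0.26, 0.24, 0.22);
  disease dn = 0.10 (doubled), l_c = 4 px (doubled), weights
  (0.31, 0.27, 0.23, 0.19) (wider spread). These are directionally
  disease-like: stronger, longer-ranged density fluctuations and more
  heterogeneous multi-scale mass allocation. Amplitudes keep 3·dn·base
  within the dynamic range, so clipping touches well under 1% of pixels.
  Default study size: 10 + 10 images at 512 px.

Per-image seeds are spawned from the master seed via `SeedSequence`, so
every generator is bit-reproducible.

**What the synthetic cohorts do not emulate**: staining variability,
optical artifacts (vignetting, defocus), nuclei-scale morphology,
spatial nonstationarity within a core, and inter-patient heterogeneity.
Passing cohort tests therefore demonstrates that the estimators detect
the *kind* of disorder contrast the presets encode, not that real
control/disease cohorts separate at any particular effect size.

## Group statistics

Comparison rows report pooled sub-box means and *population* standard
deviations (divide by n; configurable via `ddof`), absolute differences
(disease − control) and percentages relative to control. Pooling
concatenates all defined sub-box values of a group before taking
moments; a per-image-mean pathway is available by feeding per-image
aggregates to `compare_groups` directly.

On the shipped presets the percentage mean-contrast ordering
D_f < ln D_f < ln D_tf holds in every tested seed: for D_f ∈ (1, 2) the
log map amplifies relative differences (|ln x| < x there), and the
functional transform's divergence near df_max amplifies them further.

## Problem sizes in tests and the acceptance script

The validation suite runs cohort-level checks at 128 px with 4 + 4
images (10 seeds) and the acceptance script's cohort study at 256 px
with 5 + 5 images, with the IPR lattice at L = 16 in both — sizes chosen
so the full suite completes in minutes on one CPU while leaving every
directional conclusion unchanged; the monotonicity and oracle tests use
L = 32 lattices and 512-px cascades as stated above. The package
defaults (512 px, 10 + 10, L = 32) remain the recommended analysis
conditions.

## Known limitations

* The box-counting scale list for 32-px blocks is fixed at {2,4,8,16};
  very sparse blocks (one or two occupied cells) estimate D_f with high
  variance, and the [0,2] clip truncates such noise rather than
  modeling it.
* The l_c–IPR linearity regime is bounded by the block side (above);
  comparisons between cohorts with l_c ≳ L/8 should use larger blocks.
* The Gaussian goodness score is a descriptive convention, not a formal
  normality test.
* `df_max` is realization-dependent; ln D_tf values are comparable only
  within the image set that defined the maximum.
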