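# Methods

This note documents the models, parameter choices and numerical conventions
behind `mcpratio`, in the spirit of a statistical software methods appendix.

## The biomarker pipeline

The standardized T1w/T2w ratio is computed per subject as
`(T1w − sT2) / (T1w + sT2)` with `sT2 = s·T2w` and
`s = median(T1w|GM) / median(T2w|GM)`. White-matter medians are computed and
logged for QC but do not enter `s`. The stage order is: bias correction of
both contrasts → (co-registration) → tissue masks → scaling factor → ratio
map in subject space → transform to the common/atlas space → 8-mm FWHM
Gaussian smoothing → left/right MCP medians at the 90% atlas-probability
threshold → their mean. In the phantom world the subject-to-atlas transform
is the identity; `process_subject` keeps the stage order with that identity
hook, where a real deformable normalization would slot in.

Properties relied on downstream and enforced by tests:

* **Standardization invariance.** Multiplying T1w and T2w by arbitrary
  positive constants (and recomputing `s`) leaves the map unchanged to
  ~1e-10. This is the defining feature of the standardization.
* **Boundedness.** A voxel is *valid* only where both T1w and sT2 are
  positive; valid ratios lie strictly in (−1, 1). This is deliberately
  stricter than requiring a positive denominator: with a positive
  denominator but a negative operand (possible in noise-dominated
  background) the ratio would escape (−1, 1). Invalid voxels carry NaN and
  an explicit mask — never a silent zero — and are excluded from smoothing
  through mask-normalized convolution and from ROI medians.
* **Threshold semantics.** Atlas parcellation keeps voxels with membership
  probability ≥ 0.90 (inclusive; the source analyses do not state
  inclusivity).
* **ICV.** Defined as the brain-mask volume, since the original ICV
  estimator is unspecified. The normalized MCP volume is
  `mean(left, right) / ICV × 10³`. The atlas-derived volume is the
  thresholded-mask volume; no deformation Jacobian is involved (whether the
  original measurement reflected one is not stated).

## Synthetic phantoms

The generator builds a stylized, non-anatomical head: an ellipsoidal brain
(radii ≈ 60×52×52 mm on the default 64³ grid of 2-mm voxels) with a thin CSF
shell, a GM ribbon and a WM core; an ellipsoidal brainstem/cerebellum block
in the inferior WM; and two lateral MCP ellipsoids inside the block. The
pipeline is geometry-agnostic given masks and an atlas, so a stylized shape
with exact ground truth is the more informative test fixture.

**Calibration.** The intended scaling factor is known from the GM tissue
means, so T2w inside the calibrated region is back-solved as
`T2 = T1·(1−r*)/(1+r*)/s`, making the noiseless ratio exactly the target
`r*`. The calibrated region is the whole stem block, not just the MCP
ellipsoids: the 8-mm kernel (σ ≈ 1.7 voxels, truncated at 4σ) then sees a
homogeneous ratio throughout its support around the 90%-probability core,
and the noise-free pipeline reproduces `r*` to ~1e-6 (float and voxelization
error only). The MCP ellipsoid radii are sized so the thresholded core gives
an ICV-normalized volume ≈ 0.34 × 10⁻³, the healthy-control value.

**Default parameters.**

| parameter | default | rationale |
|---|---|---|
| grid / voxel | 64³ at 2 mm | desk-scale; large enough for the kernel-support margins above |
| T1w tissue means (CSF/GM/WM) | 100/140/180 a.u. | ordering CSF < GM < WM as on T1; background/brain bimodality dominates the histogram so Otsu skull-stripping finds the brain, not a tissue boundary (a stylized choice — real T1 CSF is darker) |
| T2w tissue means | 180/100/60 a.u. | ordering reversed as on T2 |
| `mcp_target_ratio` | 0.07 | the MSA-C group mean; cohort drivers draw per-subject targets from the per-group Normal moments (0.07±0.06, 0.17±0.03, 0.18±0.03, 0.19±0.03) |
| `bias_amplitude` | 0.1 | ~10% peak coil inhomogeneity, typical of 1.5 T acquisitions |
| `noise_sigma` | 4 a.u. | ≈3% of GM intensity; with it the oracle-mask pipeline recovers targets within ±0.02 and estimated preprocessing stays within the same band |
| noise model | Gaussian | simplicity; Rician magnitude noise available (`noise_model="rician"`) but not default, a documented deviation from true magnitude MRI statistics |

The bias field is `exp(a·q)` with `q` a random order-2 polynomial normalized
to [−1, 1] in-brain and `a = log(1 + amplitude)`, then normalized to
in-brain mean 1 — smooth, positive and identifiable by the order-2 log-domain
fit. The optional anisotropic-T2 mode (6-mm slabs via z box-averaging, plus
a rigid offset) emulates thick-slice 2D acquisitions and exercises
registration/resampling.

**What the phantoms do not emulate:** anatomy, partial-volume mixing,
k-space/scanner physics, cross-contrast misregistration, pathology other
than a uniform ratio shift in the pontocerebellar block. Passing tests
therefore demonstrate correctness of the *computational* pipeline and the
statistical machinery under the stated noise model, not clinical
performance on real scans.

**Value-level cohort.** Per-subject biomarker values are drawn directly
from the published per-group Gaussian moments (sizes 32/8/16/17). Gaussian
within-group distributions are an assumption; the original outlier handling
hints at heavier tails, which is why Grubbs screening is part of the
evaluation surface. The normalized volume is drawn jointly with the ratio at
correlation 0.6 (the reported MSA-C ratio–volume association is strong and
positive), and the ordinal 0–3 hyperintensity-extent score is generated from
a latent severity equal to the negative standardized ratio mixed with noise
(weight 0.8, quartile cuts), giving the strong inverse rank association seen
clinically. Reviewer ratings are Bernoulli flips of per-subject truth at
per-reviewer sensitivity/specificity; ordinal grades move to an adjacent
grade with a small transition probability.

## Preprocessing stand-ins

The external tools the original pipeline delegates to are replaced by the
simplest algorithms honoring the same output contracts (their outputs enter
the analysis only as masks and medians):

* **Bias field:** least-squares polynomial (default order 2) fit to
  log-intensity, exponentiated and normalized to in-mask mean 1. The
  single-mask fit expects a homogeneous tissue; the pipeline itself uses the
  multiclass variant — per-tissue median-log residuals with 2.5-robust-SD
  trimming — which has full-brain support and ignores focal signal change
  such as the degenerated MCP region.
* **Registration:** 6-parameter rigid, mean-squared intensity difference,
  Powell search seeded by a coarse ±6-mm translation scan, two passes
  (2×-subsampled then full grid) on σ=2-voxel smoothed volumes. MSE is a
  same-contrast cost; cross-contrast co-registration (the original T1-to-T2
  step) is out of scope and the generator's transform suite is
  same-contrast. Recovers 5°/3-mm offsets to ≲0.35° and ≲0.05 mm on default
  phantoms.
* **Skull-stripping:** Otsu threshold → largest connected component →
  two-iteration closing → hole filling. Works because the phantom histogram
  is dominated by the background/brain split (see tissue means above).
* **Segmentation:** deterministic 1-D k-means (Lloyd), centers initialized
  on a grid between the 2nd and 98th intensity percentiles, classes
  relabeled by ascending mean. Deterministic by construction; invariant to
  global intensity rescaling.
* **Oracle-mask mode:** every preprocessing output can be replaced by
  generator truth (`mode="oracle"`), isolating ratio/statistics testing from
  segmentation error; parameter-recovery contracts are stated in this mode,
  with estimated preprocessing held to the same ±0.02 band on defaults.

## Diagnostic statistics

* **ROC.** Thresholds at midpoints between distinct scores (±∞ endpoints);
  tied scores contribute half-steps on both axes, so the trapezoid AUC
  equals the tie-corrected Mann–Whitney probability exactly. For the ratio
  and the volume, lower score = diseased (`direction="lower"`).
* **DeLong.** Structural components V10/V01; single-AUC SE and the paired
  two-AUC normal test with the components' covariance. Identical paired
  scores return z = 0, p = 1; a zero variance with a nonzero AUC difference
  raises a diagnostic error rather than dividing by zero.
* **Cutoff.** Closest-to-upper-left-corner, minimizing
  √((1−TPR)² + FPR²) over finite thresholds; ties break toward higher
  specificity, then the lower threshold.
* **Proportion CIs.** Clopper–Pearson beta quantiles (`lo=0` at x=0,
  `hi=1` at x=n). Chosen because it reproduces the published "(75.0–98.0)"
  interval for 29/32; the original CI method is unnamed. Metrics with a zero
  denominator are reported as undefined, never 0.
* **Binomial accuracy comparison.** Exact tail probability; one-sided lower
  tail by default (consistent with the published p = 0.042 for 32/40 against
  0.90), minimum-likelihood two-sided optional. Sidedness is a documented
  choice, not a source fact.
* **ICC.** Two-way random effects, absolute agreement, single measure
  (ICC(2,1)) by default — the conventional model for a fixed panel of
  interchangeable reviewers; ICC(3,1) optional. The source does not state
  its variant.
* **Group suite.** One-way ANCOVA (common age slope) via OLS with a type-II
  F-test; Kruskal–Wallis with pairwise Mann–Whitney post-hocs (exact
  enumeration for small tie-free samples) at the Bonferroni level α/3;
  chi-square for sex; Spearman (extent vs ratio) and Pearson (ratio vs
  volume) within the MSA-C group.
* **Grubbs.** G = max|x−x̄|/s against the t-based critical value
  ((n−1)/√n)·√(t²/(n−2+t²)), t = t₁₋α/(2n),n₋₂; optional iterative removal.
  Two-sided masking (opposite extreme outliers) is a known limitation of the
  single-outlier test and is left as such.

## Numerical conventions

Voxel indices are 0-based; world coordinates are RAS mm through the affine;
resampling is trilinear with zeros plus an out-of-field mask beyond the
source grid. Gaussian smoothing uses σ = FWHM/(2√(2 ln 2)) per axis in voxel
units, kernel truncated at 4σ, computed as a mask-normalized convolution so
constant valid regions are exactly preserved. CSVs are UTF-8 with a header
row and full-precision floats (percent tables additionally printed to one
decimal). All stochastic components accept a single seed; child streams are
spawned deterministically, and identical seeds give bit-identical phantoms,
cohorts and output files.

## Problem sizes

The default analysis sizes are chosen at desk scale: 64³ phantoms, eight
phantom subjects in the demo run, 2000 replicate cohorts for the simulated
AUC summaries, 10⁴ draws for bootstrap/coverage checks. These are the sizes
the test suite and the acceptance script run at.

## Known limitations

The phantom's stylized geometry and Gaussian noise make the parameter-
recovery results a verification of the software, not a validation on
patient data; the published patient-level point estimates that depend on
unpublished raw values (exact AUC CIs, ICC values, correlation
coefficients) are reproduced in structure, not value. The registration cost
is same-contrast MSE. Percent cells whose denominator is zero (a reviewer
making no positive calls) have no defined point estimate and are reported
as undefined, although the source prints 0 with a (0–100) interval for
those cells.
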