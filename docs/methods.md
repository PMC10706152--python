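# Methods

`lungvox` implements a voxel-wise comparison between hyperpolarised-gas
diffusion-weighted MRI (DW-MRI) microstructural maps and quantitative-CT
parenchymal pattern maps in fibrotic lung disease, together with a fully
synthetic multi-modal phantom that makes every stage testable against a
known ground truth. This note records the models, the numerical choices,
and what the phantom does and does not emulate.

## Diffusion models

Per voxel, two models are fitted to the multi-b-value magnitude signal:

* **Two-point ADC.** `ADC = ln(S(0)/S(b1)) / b1` from b = 0 and the first
  nonzero b-value (1.6 s/cm^2 for helium-3). Voxels with non-positive or
  increasing signal are noise-dominated and flagged invalid rather than
  raising; values are clamped to the gas free-diffusion ceiling D0
  (0.88 cm^2/s for helium-3, 0.14 cm^2/s for xenon-129).
* **Stretched exponential model (SEM).** `S(b) = S0 exp(-(b DDC)^alpha)`
  over all b-values, with the distributed diffusion coefficient
  DDC in (0, D0] and heterogeneity index alpha in (0.01, 1]. Fitting is a
  batched, bounds-projected Levenberg–Marquardt on the linear-domain
  residuals with analytic Jacobians, multi-started from
  alpha in {0.6, 0.8, 1.0} with DDC initialised at the two-point ADC —
  the (DDC, alpha) objective has a shallow ridge and a single start is not
  reliable. Fits pinned at the lower DDC or alpha bound (no measurable
  decay) are flagged invalid, as are voxels whose S(0) falls below twice
  the background noise estimate (unventilated lung).

### Mean acinar dimension Lm_D

For 0 < alpha < 1 the stretched exponential is the Laplace transform of a
one-sided alpha-stable density over diffusivities, `p(u; alpha)` with
u = D/DDC. Lm_D is the mean of the diffusive length scale
`l(D) = sqrt(2 n D Delta)` over that distribution, truncated at the free
diffusion ceiling:

    Lm_D = sqrt(2 n Delta DDC) * E[sqrt(u)],   u ~ p(u; alpha) on [1e-4, D0/DDC]

with Delta the diffusion time (1.6 ms helium-3, 8.5 ms xenon-129,
converted ms -> s explicitly) and n the number of diffusion-sensitised
directions (default 1, configurable; every contract below is preserved
under any fixed n). At alpha = 1 the density collapses to a point mass and
Lm_D reduces *exactly* to `sqrt(2 n Delta DDC)`; this limit is special-cased
and tested to 1e-9.

`p(u; alpha)` is evaluated with Kanter's single-integral representation of
the positive stable density, computed entirely in log space (stable for
alpha up to at least 0.995; verified against the defining Laplace transform
to better than 5e-5 absolute). Two evaluation paths exist:

* `method="quadrature"`: the spectral integral on a 2000-point log-spaced
  diffusivity grid per call (reference path, scalar);
* `method="table"` (default, vectorised): bilinear interpolation of a
  precomputed `E[sqrt(u)]` table over 140 alpha values x 100 log-spaced
  truncation ratios D0/DDC, computed once per process. The two paths agree
  to better than 0.1%. For alpha in (0.995, 1] the integral representation
  degenerates and the moment is blended linearly into the exact alpha = 1
  limit; the interval is narrow enough that the blend error is far below
  the fitting noise.

The truncation at D0 matters: the stable density has a heavy `u^-(1+alpha)`
tail, and the untruncated sqrt-moment would be dominated by unphysical
diffusivities above free diffusion.

The helium-3 and xenon-129 protocols were designed so that the same
microstructure yields comparable Lm_D from either gas; with DDC scaled by
the ratio of diffusion times, the two protocols agree within 5% through the
full simulate-fit-derive chain (tested).

## Registration

Each leg of the indirect CT <-> DW-MRI alignment is a three-stage
registration over an image pyramid (downsampling x4 / x2 / x1):

1. rigid (6 parameters) at x4, driven by 32-bin joint-histogram mutual
   information, Powell optimisation;
2. affine (12 parameters) at x2, same metric, seeded by the rigid result;
3. a demons-style diffeomorphic stage at full resolution driven by an
   Avants-style local normalised cross-correlation force (Gaussian window
   sigma = 2 voxels), with Gaussian smoothing of the update (sigma = 1
   voxel) and of the accumulated field (sigma = 1.5 voxels), up to 50
   iterations, step halving on cost increase. Updates are *composed* with
   the running field rather than added, preserving invertibility; the
   finite-difference Jacobian determinant of the total field is verified
   positive in the tests.

Numerical choices that proved load-bearing:

* All transforms act in physical millimetres; displacement fields live on
  the fixed image's grid and map fixed points into the moving frame.
* During optimisation the moving image is sampled with *edge extension*
  rather than zero fill: a zero background fabricates a spurious
  high-contrast boundary at the volume border (phantom CT air is
  -1000 HU) that traps the similarity metrics. The public warping API
  keeps the zero-background contract for label and metric maps.
* The local-CC cost and force are restricted to voxels whose local
  variance exceeds 1% of the global variance: noise-only regions carry no
  alignment information and dilute the metric; both images are
  pre-smoothed (sigma = 1 voxel) for the demons stage only.
* Nearest-neighbour resampling rounds exact half-voxel points toward the
  lower index, for cross-platform determinism.

The indirect path registers DW-MRI to the same-breath ventilation image
and CT to the structural image; ventilation and structural frames are
treated as exactly aligned (same breath-hold), so no direct CT-to-DW-MRI
registration is ever attempted. Metric maps ride the DW leg and pattern
maps the CT leg, both warped nearest-neighbour onto a common grid
(default 1.8 x 1.8 x 5 mm, configurable; adopted as the working resolution
of the co-registered maps).

## Pattern maps and statistics

The 7-class CT texture map (normal, mild/moderate/severe low-attenuation
areas, ground-glass, reticular, honeycomb) is consolidated to 5 patterns:
normal + mild LAA -> non-involved (mild LAA occurs in healthy deep
inhalation), moderate + severe LAA -> hyperlucent (emphysema-like).
Consolidating an already-consolidated map is rejected, never silently
re-mapped. The texture classification itself is upstream: label maps are
inputs (phantom-generated in the tests).

Statistics operate on a flat voxel table (subject, raster voxel index,
pattern, ADC, Lm_D, timepoint), decimated to every 20th row per subject
and timepoint (first retained row at position 0; the cohort-scale analyses
kept 5% of roughly four million overlapping voxels). Voxels are pooled
across subjects, ignoring within-subject correlation, replicating the
published analysis; this overstates the effective sample size and the
p-values should be read accordingly.

* One-way ANOVA by direct sums of squares; Tukey–Kramer pairwise CIs with
  the studentized-range quantile (scipy), supporting unequal group sizes.
  The tests validate the CIs against an independent quantile computed by
  numerical integration of the studentized-range CDF.
* **Relevance rule.** A statistically significant difference is
  *practically relevant* when the bound of its 95% CI farthest from zero
  exceeds the a-priori same-day reproducibility half-width
  (±0.041 cm^2/s for ADC, ±18.5 µm for Lm_D). This operator reproduces
  every labelled annotation in the published pairwise tables (26 cases,
  tested), including the discriminating case of a CI (0.033, 0.043)
  marked relevant against ±0.041.
* **Abnormality threshold.** The Lm_D threshold is the empirical 95th
  percentile (order-statistic interpolation) of healthy voxel values; a
  parametric mean + 1.645 SD mode is provided but not the default, since
  healthy voxel distributions are skewed and the empirical percentile is
  the safer reading.
* **Bland–Altman.** Differences are CT-percentage minus Lm_D-percentage,
  so a negative bias means the diffusion metric flags more of the lung
  than CT; limits are bias ± 1.96 x sample SD (n−1). Hyperlucent voxels
  are never counted on the CT side (emphysema is structurally abnormal
  but not interstitial).
* Group comparisons use Welch's unequal-variance t-test (pooled-variance
  mode available). The longitudinal report stratifies both timepoints by
  the pattern observed on the *baseline* CT, mirrors the published table
  layout (baseline mean ± SD, year-1 mean ± SD, difference with CI,
  significance, relevance), and emits an NaN row for patterns absent at a
  timepoint.

## The phantom

The phantom defines the study conditions for every test. In a canonical
physical frame shared by ventilation and structural MRI it builds: a
thorax and two ellipsoidal lungs (analytic); pattern regions grown as
unions of balls around centroids sampled with a basal/peripheral bias,
with radii set by bisection so the parenchymal fractions hit the cohort's
published voxel shares (non-involved 78.9%, ground-glass 12.4%, reticular
5.5%, hyperlucent 2.7%, honeycomb 0.5%; reproduced within ±1 percentage
point, usually ±0.1). Rarer patterns claim voxels first so their quotas
survive overlap.

Per-pattern stretched-exponential parameters (DDC, alpha) are chosen so
the two-point ADC ordering matches the published per-pattern means
(honeycomb largest, non-involved smallest); the paper cannot provide
per-pattern ground-truth microstructure, so these defaults reproduce the
ordering, not the exact means. A smooth log-normal heterogeneity field
(sigma = 0.4, shared between timepoints) gives within-pattern dispersion
comparable to the published per-pattern SDs (~0.4 of the mean); without
it, thresholding and agreement analyses degenerate.

DW-MRI signals follow the SEM forward model with Rician noise
(sigma = S0/SNR per b-volume, default SNR 20, complex-channel magnitude).
CT is a pattern-wise attenuation model plus Gaussian texture (sigma = 25
HU), used only as a registration target, never classified. Misalignments
between each modality frame and the canonical frame combine a bulk rigid
offset (translation of the stated magnitude, rotation up to 2°) with a
smooth random field of the same peak magnitude (Gaussian-filtered noise,
verified invertible); a purely smooth zero-mean field barely displaces
the lung masks and would make registration recovery untestable. The
follow-up acquisition shares the baseline anatomy and heterogeneity field
and increases DDC only inside ground-glass (+0.045 cm^2/s) and reticular
(+0.06 cm^2/s) regions; these increments are sized so the stratum-level
changes recovered through the full, misregistration-diluted pipeline land
at the published year-1 differences (reticular ADC ≈ +0.04 cm^2/s,
Lm_D ≈ +20–25 µm) — an undiluted increment equal to the printed
stratum-level change under-produces it after registration mixing.

The healthy reference cohort is simulated as uniformly non-involved lungs
under the xenon-129 protocol at DDC = 0.032 cm^2/s, alpha = 0.95, chosen
so the healthy-to-fibrotic Lm_D voxel-mean ratio matches the published
cohorts (~0.79); its fitted Lm_D voxels define the abnormality threshold.

Default problem sizes are desk-scale: canonical/structural grid 48^3 at
4 x 4 x 5 mm, CT at 3 mm isotropic, DW at 6 x 6 x 10 mm, preserving the
inter-modality resolution ratios of the clinical protocols (CT
1 x 1 x 1.25 mm, ventilation/structural 4 x 4 x 5 mm, DW-MRI
4.17 x 4.17 x 12 mm) at roughly one-quarter of the field of view. The
clinical spacings remain reachable through `PhantomSpec`. Tests and the
acceptance script use two-subject cohorts and a 64^3 canonical grid where
a criterion names one.

### What the phantom does not emulate

Ellipsoidal lungs (no airways, fissures or vasculature); piecewise-
constant pattern cores with smooth heterogeneity rather than true UIP
texture; no ventilation defects beyond reduced signal in hyperlucent
regions; no k-space or compressed-sensing reconstruction effects; no
inflation-level differences between CT (full inspiration) and DW-MRI
(FRC + 1 L); no CT dose or kernel variation. Passing tests therefore
demonstrate correctness of the algorithms under known geometry and noise,
not clinical performance on patient data.

## Known limitations

* At SNR 20, two-b-value ADC error propagation gives a voxel-wise error
  SD of about 0.06 cm^2/s at the fibrotic mean ADC (median |error|
  ≈ 0.04 cm^2/s); this is a property of the two-point estimator at
  b1 = 1.6 s/cm^2, not of the implementation, and the corresponding
  acceptance check documents it.
* Alpha estimates at SNR 20 carry a small negative bias (~0.02) from the
  alpha ≤ 1 bound and the Rician noise floor.
* The demons stage optimises image similarity, not mask overlap; for the
  coarse DW grid the mask Dice is discretisation-limited near 0.95
  regardless of registration quality.
* Voxel pooling across subjects ignores clustering; a per-subject summary
  mode exists but is not the default, to match the published analysis.
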