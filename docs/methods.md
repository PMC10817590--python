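# Methods

`oculotex` implements an interocular (right-vs-left eye) asymmetry analysis
of neuroretinal texture from segmented OCT macular volumes, together with a
synthetic-data generator that emulates the inputs the analysis assumes.
This note documents the models, the conventions that the published
descriptions of each step leave open, and what the synthetic validation
studies do and do not demonstrate.

## 1. The analysis pipeline

### 1.1 Mean value fundus projection

An OCT macular cube is stored as `(b-scan, depth, a-scan)` with a
512 × 128 en-face grid. For each of the six neuroretinal layers (RNFL,
GCL, IPL, INL, OPL, ONL), delimited by seven ordered interface surfaces
`z_0 ≤ … ≤ z_6` (fractional voxels), the mean value fundus (MVF) image
assigns to each en-face position the depth-wise average of the voxels
between the layer's two interfaces.

Conventions fixed here:

* **Fractional interfaces.** The depth span of a pixel is the half-open
  integer range `[ceil(z_top), ceil(z_bottom))`; there is no sub-voxel
  interpolation. This is the simplest testable rule and matches ordinary
  A-scan averaging.
* **Zero-thickness pixels** (inner layers collapse at the foveal centre)
  are masked invalid and carry NaN — never a silent 0, which would corrupt
  downstream block means. The fovea is excluded from the analysis anyway.
* **Axis convention.** MVF images are stored with rows = B-scans
  (superior → inferior) and columns = A-scans (temporal → nasal for a right
  eye). Left-eye images are flipped along the column axis so the
  temporal/nasal sides coincide across eyes; block features are invariant
  under this flip (see §1.3), which is what makes OD/OS features
  comparable.

### 1.2 Texture features

Each MVF image is mean-pooled 4:1 along the A-scan axis to an isotropic
128 × 128 image (a pooled pixel is invalid only if all four sources are),
quantized to 16 grey levels, and split into a 7 × 7 grid of 18 × 18-pixel
blocks anchored at the top-left (the trailing 2 rows/columns are unused).
The central (4th) block row and column cover the fovea and are discarded;
the remaining 36 blocks form four 3 × 3 quadrants (Q1 temporal-superior,
Q2 nasal-superior, Q3 temporal-inferior, Q4 nasal-inferior).

Per block, symmetric grey-level co-occurrence matrices (GLCMs) are
accumulated at distance d = 1 for orientations 0°, 45°, 90° and 135°,
with opposite directions pooled (making P symmetric); pairs touching an
invalid pixel are skipped rather than imputed. 21 Haralick-family features
are evaluated per orientation; the block value is the per-feature maximum
over the four orientations; the quadrant value is the mean over its nine
blocks (invalid blocks skipped). This yields 21 × 6 × 4 = 504 features per
eye.

Conventions fixed here (the classical feature definitions leave them open):

* Grey levels are indexed 1..N in the moment-type features
  (Autocorrelation, Sum Average, cluster statistics, …).
* All logarithms are base 2, with 0·log 0 ≡ 0.
* *Sum Variance* is the second moment of the level-sum distribution about
  **Sum Average** (the standard erratum-corrected reading of the original
  definition, which misprints Sum Entropy as the centre); the literal
  variant is available via `GLCMConfig(sum_variance_about="sum_entropy")`.
* *Difference Variance* is the variance of the level-difference
  distribution `p_{x−y}`.
* Features with a degenerate denominator on constant blocks (Correlation,
  IMC1, IMC2) are defined as 0, so NaNs never propagate into quadrant
  means.
* **Quantization** is linear equal-width binning with the maximum mapping
  to the top level. Two ranges are supported: each image's own valid
  min–max (`per_image`, the default — appropriate for real scans, where it
  removes global brightness offsets between eyes) and a fixed 0–255 range
  (`fixed`). Note that a per-image range is a *global* statistic of the
  image: any localized change of texture amplitude shifts the range and
  thereby every quadrant's features. The synthetic validation studies use
  `fixed` for exactly this reason (§3).

The GLCM builder and all 21 formulas are verified in the test suite
against independent brute-force implementations (pair enumeration and
naive double-loop formula evaluation) and against scikit-image's
`graycomatrix` on mask-free tiles.

### 1.3 Flip invariance

Mirroring a block horizontally leaves the pooled 0° and 90° GLCMs
unchanged and swaps 45° with 135°, so the per-feature orientation maximum
is exactly invariant. Hence flipping left-eye images (§1.1) changes no
block feature value, only the assignment of blocks to quadrants — which is
the intended effect.

### 1.4 Interocular statistics

Per sex group:

1. **Decorrelation.** Every feature is Pearson-correlated with every other
   feature across the group's participants, separately per eye. Pairs with
   |r| ≥ 0.5 in *both* eyes are "correlated". Features in no correlated
   pair are kept outright. The remaining features are ranked by decreasing
   number *n* of correlated partners, ties broken by decreasing explained
   variance Σᵢ(r²_OD,i + r²_OS,i), then by canonical feature order; the
   ranked list is traversed once, keeping each not-yet-discarded feature
   and discarding its remaining correlated partners. The kept set is
   pairwise |r| < 0.5 in both eyes (asserted). An alternative reading that
   re-ranks after every discard is available
   (`StatsConfig(recompute_after_discard=True)`); on random structures both
   yield valid (occasionally different) uncorrelated sets.
   Features that are constant in either eye have undefined r; they are
   flagged and treated as uncorrelated.
2. **Normality gate.** Shapiro–Wilk on each eye's sample at the 10% level
   (deliberately conservative: borderline samples go to the
   non-parametric branch). The gate is applied to the raw per-eye samples;
   gating on the paired differences is available as
   `StatsConfig(normality_on="differences")`.
3. **Paired tests.** Paired t-test if both eyes pass the gate, otherwise a
   Wilcoxon signed-rank test with a fixed dialect: zero differences
   dropped, tied ranks averaged, exact null distribution for ≤ 25
   tie-free non-zero differences, continuity-corrected normal
   approximation otherwise. Identical samples are flagged degenerate with
   p = 1.
4. **Corrections**, each with family size m = number of kept features:
   * Bonferroni: significant iff p < α/m.
   * Benjamini–Hochberg: largest k with p̃_k < kα/m (strict inequality, as
     the step-up rule is usually stated); adjusted values via the monotone
     step-up transform.
   * Storey: π0̂ = #{p > λ}/(m(1−λ)) capped at 1 (λ = 0.5 by default),
     FDR̂(t) = min(1, π0̂·m·t / #{p ≤ t}) at t = 0.05, q-values
     q(p̃ᵢ) = min_{j≥i} π0̂·m·p̃ⱼ/j; significant iff q < α. With λ = 0 the
     q-values coincide with BH-adjusted p-values (tested to 1e−12).

The per-group output is a feature × (layer, quadrant) state grid
(`correlated-out`, `non-significant`, `significant-uncorrected`,
`significant-corrected:<methods>`) plus a count summary (kept features,
non-parametric tests, uncorrected significant, per-method significant,
π0̂, FDR̂).

## 2. The synthetic cohort generator

The real acquisitions behind this kind of study are not publicly
available, so all statistical structure of the generator is invented but
configurable; the analysis logic, not the biology, is the deliverable.
Defaults emulate a sex-balanced cohort of 49 + 49 healthy adults (ages
truncated-normal 42.5 ± 16.3 years on [19, 74]), both eyes each.

Each eye volume is built as follows (all intensities in arbitrary 0–255
reflectivity units; every quantity below is configurable via
`VolumeConfig`):

* **Interfaces.** Per-layer thickness = mean thickness + a smooth Gaussian
  random field (correlation length `interface_smoothness`, amplitude
  `interface_noise_sd`), floored at 1 voxel; a radial Gaussian foveal dip
  (`foveal_dip_depth`, `foveal_dip_radius`) then shrinks the four inner
  layers proportionally to their local thickness, down to zero at a deep
  dip. Surfaces are the cumulative sums — ordered by construction.
* **Reflectivity.** Voxels of layer L take
  `intensity_base[L] + texture_sd[L] · F_L + noise`, where `F_L` is
  depth-constant Gaussian-smoothed white noise standardised to unit
  variance (isotropic correlation length `texture_corr_length[L]`, in
  128-grid pixels) and the noise is i.i.d. `noise_sd`. Values are clipped
  to [0, 255]. The defaults (base reflectivities 160/110/120/90/130/70,
  texture sd 10, correlation length 2, noise sd 5) are placeholders for
  the undocumented intensity statistics of real scans and are labelled as
  such.
* **Effects.** An `EffectSpec` re-derives the target layer's field *from
  the same white noise* with perturbed (correlation length, sd) and
  substitutes it only inside the target quadrant's en-face footprint of
  the matching sex/eye. Consequences, all tested: a zero-delta effect is a
  bit-exact no-op; voxels outside the target region are bit-identical to
  the no-effect dataset; quadrant footprints are mirrored for left eyes so
  a "Q4" effect lands nasal-inferior in the post-flip frame for both eyes.
* **Reproducibility.** Every (participant, eye) uses an RNG substream
  keyed by (seed, participant id, eye), so adding participants never
  perturbs existing ones; identical configuration ⇒ bit-identical
  datasets.
* **Optional heterogeneity.** `VolumeConfig` can draw per-participant
  texture parameters (log-normal multipliers on sd and correlation
  length, additive jitter on mean level) shared by a participant's two
  eyes. The default cohort is homogeneous: participant-level latents are
  shared across the whole en-face plane, which induces long-range
  correlations among features of different quadrants and layers and makes
  localized effect injection unidentifiable after decorrelation (the
  cluster representative ends up in another quadrant). Heterogeneity is
  therefore opt-in, for experiments that need it.

What the generator does **not** model: OCT speckle physics, vascular
shadows, motion artefacts, segmentation errors, axial point-spread, or any
real anatomical sex difference. Passing validation studies therefore
demonstrate correctness and calibration of the *analysis*, not any claim
about real retinas.

## 3. Validation studies

Both studies (in `oculotex.studies`, shared by the test suite and
`scripts/acceptance.py`) run the full pipeline — volume synthesis,
projection, extraction, statistics — at a desk scale chosen to keep a run
in the seconds range: the full 512 × 128 en-face grid (the block geometry
requires it), a 32-voxel depth with proportionally thinner layers, and a
three-layer analysis (RNFL, IPL, ONL), i.e. 252 features per eye. Both
use fixed-range quantization (§1.2): synthetic volumes have no between-eye
brightness offsets to normalise away, and a per-image range couples all
quadrants of an image, which defeats locality checks.

* **Null study** (type-I calibration): 50 seeded cohorts of 20 + 20
  participants, no injected effect. Reported: the mean fraction of kept
  features declared significant per correction method; expected at or
  below α = 0.05.
* **Recovery study** (power / locality): 20 seeded cohorts at the full
  cohort size (49 + 49), with the IPL texture sd doubled (10 → 20) in Q4
  of female left eyes — an unambiguously strong effect. Reported: how
  often Entropy/Energy at IPL/Q4 are corrected-significant in the female
  group, how often *any* IPL/Q4 feature is, and how often anything is
  (falsely) detected in the male group.

### 3.1 Known limitation: named-feature recovery after decorrelation

The injected effect is essentially always detected *at the injected cell*
in the female group only. However, which feature name carries the
detection is not stable. Across participants of a homogeneous synthetic
cohort, all disorder-type features of one (layer, quadrant) cell (Entropy,
Energy, Sum Entropy, Difference Entropy, SSV, Maximum Probability, …) are
driven by the same realization-noise latent and are therefore mutually
|r| ≥ 0.5-correlated in both eyes; the decorrelation step keeps exactly
one representative of that cluster, and the ranking among its near-tied
members (by correlation count) is decided by sampling noise. Entropy or
Energy is the kept representative in roughly three quarters of runs; in
the remainder a close relative (Sum Entropy, SSV, Difference Variance)
carries the detection instead. This is a structural property of applying
a correlation filter to features that are functionals of the same matrix,
not a defect of any single stage; the recovery study therefore reports
both the strict named-feature rate and the cell-level detection rate.

## 4. Numerical and degenerate-input choices

* Empty GLCMs (no valid pixel pair) are flagged degenerate and excluded
  from the orientation maximum; a block with all four orientations
  degenerate is excluded from its quadrant mean; a quadrant with no valid
  block is NaN.
* A constant image quantizes to all-zero levels; a constant feature
  (zero variance across participants) has undefined correlations and is
  treated as uncorrelated; constant samples fail the normality gate (a
  point mass is not plausibly normal) and route to Wilcoxon, where an
  all-zero difference vector yields the degenerate p = 1.
* float32 volumes use a float32 depth-cumsum accumulator in the
  projection (sums of 0–255 values over ≤ 2⁶ depths are exact).
* Interface perturbation fields are synthesised on the coarse isotropic
  grid and replicated along the A-scan axis when the aspect ratio is
  integral; at the default smoothness (12 px) the replication step is far
  below the correlation length.
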