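# Methods

`olfparc` implements a connectivity-based parcellation analysis for a small
cortical seed region — modelled on primary olfactory cortex, whose four
subdivisions (anterior olfactory nucleus, olfactory tubercle, frontal and
temporal piriform cortex) receive direct olfactory-bulb input — together
with whole-brain network characterization of the resulting clusters.  This
note records the models, the defaults and why, the numerical choices, and
what the synthetic validation does and does not establish.

## Signal cleaning

The pipeline assumes volumes already on a common grid (registration is out
of scope).  Per subject, the cleaning chain is:

1. **Grand-mean intensity normalization** — the 4D global mean is scaled to
   10,000 (the FSL convention; the target is arbitrary because every
   downstream statistic is correlation-based).  This runs *first*: the
   detrending step that follows removes the temporal mean, after which a
   global-mean rescaling would be ill-defined.  Correlations are invariant
   to the ordering.
2. **Polynomial detrending** (default order 2, i.e. linear + quadratic):
   per-voxel least-squares projection onto an orthonormal polynomial basis
   in the time index; the residual has exactly zero sample correlation with
   each basis vector.
3. **Nuisance regression**: per-voxel OLS residual against confound columns
   (typically six motion parameters plus white-matter and CSF means), with
   an explicit intercept in the design.  A rank-deficient design is an
   error that names the collinear columns.
4. **Temporal band-pass** by hard FFT masking: bins with
   `low_hz <= f <= high_hz` are kept exactly, everything else zeroed.  The
   default passband is **0.008–0.1 Hz**, the field-standard resting-state
   band.  A much narrower band (0.008–0.01 Hz) can be configured, but at
   desk scale (T = 300, TR = 2 s) it retains almost no Fourier bins and is
   not the default.
5. **Spatial Gaussian smoothing**, sigma in **mm** (default 3 mm),
   converted to voxel units through the affine; reflect boundary handling
   preserves each frame's total sum.  Sheared/oblique affines are rejected.

Initial-frame removal (scanner equilibration) is a config integer, default
0: the generator simulates no T1 transient.

## Connectivity and stability

For each ROI voxel, the connectivity profile is the Pearson correlation
with every brain-mask voxel *outside* the ROI (self- and within-ROI
correlations would otherwise inflate cluster compactness).  Voxel ordering
is ascending linear index, x fastest — stored explicitly in the matrix
index maps so layouts are reproducible.  Gray-matter restriction of the
brain mask is the caller's responsibility.

Group matrices are Fisher-z averaged: `tanh(mean(atanh(r)))`, computed per
entry and returned on the r scale.  Inter-subject consistency is
quantified by leave-one-out stability: for each held-out subject, the
correlation (across target voxels, r-scale rows) between that subject's
row and the remaining subjects' average row, averaged over hold-outs.  The
significance threshold for a stability value is re-derived from the actual
target count via the exact t-transform of r (one-sided, Bonferroni over
ROI voxels) rather than hard-coded, because it depends on the dataset's
dimensions.

## Parcellation

Seed voxels are clustered by k-means under the correlation distance
`d(x, c) = 1 − r(x, c)`.  Rows are standardized (centered, unit norm
across targets), which makes `1 − r` equal to half the squared Euclidean
distance, so Lloyd updates are valid; centroids are member means
re-centered and re-normalized.  Initialization is k-means++ under the same
distance, `n_init = 10` restarts, best by total within-cluster distance,
deterministic given the seed; an empty cluster is re-seeded from the row
farthest from its centroid.  Max iterations: 300.  `k = 4` by default (one
cluster per anatomical subdivision); a k-sweep (3–6) reproduces the
multi-resolution analysis.  Automatic selection of k is a non-goal.

Cluster-vs-atlas agreement: the proportion of each cluster's voxels inside
each anatomical region, tested by shuffling the anatomical labels across
ROI voxels (10,000 permutations).  The null mean and SD per cell come from
a Gaussian fit (sample mean, unbiased SD — the `normfit` convention);
`z = (obs − mean)/sd`, one-sided normal-tail p, Benjamini–Hochberg FDR
across all k × C cells jointly.  An empirical tail p is reported alongside
for robustness; cells with a degenerate (zero-SD) null are flagged, never
silently ±inf.  Note the normal-fit p is anti-conservative for small
clusters: at an 80-voxel ROI the exact hypergeometric tail shows the
nominal-0.05 test truly rejects at ≈ 0.07; at the default study's 108
voxels the measured rate is ≈ 0.06.  Cluster naming uses an optimal
one-to-one assignment on the count matrix (ties to the lowest region
index).

## Group maps and TFCE inference

Per subject and seed, the seed's mean time series is correlated with every
brain voxel outside the seed and Fisher-z transformed (|r| clipped at
1 − 10⁻⁶ with a warning, so degenerate synthetic voxels stay finite).
Group inference is a one-sample sign-flipping permutation test: under the
symmetric null each subject's map may be multiplied by ±1.  The statistic
is the TFCE-enhanced t-map,

    TFCE(p) = Σ_h e(h, p)^E · h^H · dh,   h = dh, 2dh, …, h_max,

with `E = 0.5`, `H = 2`, 100 threshold steps and 26-connectivity by
default (the standard settings of the method); `dh = h_max / n_steps` with
`h_max` the map maximum by default.  With the adaptive `h_max`, TFCE is
monotone in the input only up to discretization; a fixed `h_max` restores
exact pointwise monotonicity, and scaling a map by c scales TFCE exactly
by `c^(H+1)`.  Negative values contribute nothing: inference is one-sided
positive for connectivity maps (negative connectivity is a non-goal);
difference maps (the lateralization index) use a two-sided variant that
enhances |t|.

Family-wise error is controlled by the max-TFCE null: the n_perm flip
patterns always include the identity, all 2^N patterns are enumerated when
2^N ≤ n_perm, and `fwe_p(v) = #{null_max ≥ tfce_obs(v)} / n_perm` — so the
smallest attainable p is 1/n_perm and the single-voxel N = 3 case
enumerates 8 flips to p = 1/8 exactly.  Default α = 0.001; 10,000
permutations in the `paper` profile, 1,000 in the `desk` profile.
Zero-variance voxels get t = 0 and are excluded from enhancement with a
warning.

Significance masks of several seeds are decomposed into **unique** masks
(significant for exactly one seed) and a **common** mask (significant for
all); every significant voxel belongs to exactly one of unique,
shared-but-not-all, or common.  Volume tables per atlas label report voxel
count × voxel volume, with entries under 80 mm³ marked suppressed.

The lateralization index is `LI = (Z_left − Z_right)/(Z_left + Z_right)`,
valid where `|Z_left + Z_right| > 10⁻⁶`, then smoothed (3 mm sigma, mm
units assumed as elsewhere) and tested two-sided with the same sign-flip
machinery.

## Synthetic data

The generator emulates the *statistical* structure the analysis assumes,
not realistic physiology.  Per subject, each of four parcels has a latent
unit-variance series `s_c`; a voxel in parcel c or in its target block is
`sqrt(ρ)·s_c + sqrt(1−ρ)·ε`, shared-target voxels mix all latents equally,
and remaining brain voxels are pure noise — so the expected correlation
between voxels sharing a latent is exactly ρ (default 0.5).  All series
(latents *and* noise) are Gaussian processes band-limited to the analysis
passband: if the noise were white, the band-pass filter would remove
out-of-band noise power and push within-parcel correlations above the
planted ρ.  A constant baseline (1000) gives intensity normalization a
nonzero mean.  Each subject draws from an own RNG stream derived
deterministically from the master seed, so generation is reproducible and
order-independent.

Default study conditions: 10 subjects, 24 × 24 × 16 grid of 2 mm voxels,
T = 300 at TR = 2 s, four 27-voxel parcels, ρ = 0.5, noise SD 1 — sized so
the full pipeline runs in a few minutes on one CPU.  Not simulated: head
motion, hemodynamic response shape, physiological noise spectra, scanner
drift beyond low-order trends, inter-subject anatomical variability.
Passing tests therefore demonstrate correctness of the *computations* and
calibration of the *inference* under the stated model, not robustness to
real-data artifacts.

`mirror_hemispheres` plants a mirror-image seed whose voxels carry the
*same* latent series as their source voxels with fresh independent noise.
This makes left and right seed connectivity maps exchangeable voxel by
voxel — the correct null for the lateralization test.  Mirroring geometry
alone would make the maps mirror images of each other, which is not
exchangeability at a fixed voxel.

## Validation design choices

- **Temporal-chain invariance**: the preprocessing chain without smoothing
  preserves within-parcel correlation to within 0.05 of ρ (checked at
  T = 1000).  Smoothing is excluded from this check by design: averaging
  neighbouring voxels that share a latent *raises* local correlation
  (≈ 0.88 at desk scale), which is its purpose, not a defect.
- **Network recovery scoring** runs on unsmoothed preprocessed data.  The
  generator plants voxel-exact structure with no inter-subject
  misalignment for smoothing to compensate; with smoothing on, planted
  signal spreads over the kernel support while independent noise is
  suppressed, so voxels several steps outside a planted block genuinely
  carry detectable signal (t ≈ 6) and "specificity against voxel-exact
  truth" stops being a meaningful quantity.  Without smoothing the
  planted-vs-not comparison is exact.
- **Permutation calibrations** use desk-scale nulls: 500 replicates of
  random labels at the default ROI size for the voxel-label z-test, and
  200 replicates of N = 6 Gaussian null maps on 6³ grids (full 64-flip
  enumeration) for the sign-flip FWE.  The hemispheric null uses 20
  replicates of mirrored 16 × 16 × 12 datasets with all 1024 flips
  enumerated, so the α = 0.001 threshold is attainable (min p ≈ 0.00098).

## Known limitations

- The normal-fit permutation p is anti-conservative for very small
  clusters (see above); the empirical tail p is reported alongside.
- Hard FFT masking has an ideal-filter frequency response but rings on
  non-bin-aligned components (Gibbs); the contracts are stated on FFT
  bins.
- Only shear-free affines are supported for smoothing; anisotropic voxel
  sizes are fine.
- Sign-flip inference assumes subject maps symmetric about zero under the
  null; lateralization maps at near-zero denominators are heavy-tailed,
  which the validity mask and smoothing mitigate but do not remove.
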