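# Methods

This note documents the models and numerical choices behind `twdfc_parcel`,
what the synthetic phantom does and does not emulate, and the known limits
of the inference.

## Track-weighted dynamic functional connectivity

For a bundle tractogram aligned to a BOLD grid, each streamline contributes
the windowed Pearson correlation of its two endpoint voxel series (nearest
voxel, no interpolation). A voxel's tw-dFC series is the mean over valid
traversing streamlines per window. Conventions:

- **Windows** are rectangular, stride 1 TR by default. The window length in
  time points is `round(target_s / TR)` for a ~40 s target (29 points at
  TR = 1.4 s, 55 at TR = 0.72 s, 20 at the phantom's TR = 2 s). ~40 s is the
  conventional operating point at which sliding-window FC is stable.
- **FC metric** is Pearson correlation; windows where either series has zero
  variance are flagged missing (NaN) rather than propagated.
- **Streamline validity**: a streamline whose endpoint falls outside the
  grid (or a supplied brain mask) is excluded from all voxels it traverses.
- **Voxel traversal** is exact: a segment traverses a voxel whenever it
  enters the cube of points nearest that voxel's center (all boundary-plane
  crossings are enumerated; this equals the limit of dense resampling
  followed by nearest-voxel mapping, and tests verify agreement with a
  0.2 µm-step sampling oracle). Fixed-step resampling at half a voxel edge —
  an obvious alternative — misses corner-clipped voxels at any finite step.
- The **static benchmark** paints the mean of the two endpoint BOLD series
  along each streamline (per time point), a simplified stand-in for
  approaches that map raw BOLD onto white-matter priors; it shares geometry
  and averaging with tw-dFC and differs only in carrying raw signal rather
  than windowed correlation.

## Group ICA

Per subject, every in-mask voxel series is standardised and a temporal PCA
keeps 50 components (or the data maximum if smaller). Subject reductions are
row-concatenated; a second (uncentered) PCA extracts the group directions;
**extended Infomax** unmixes k independent spatial maps. Sub- vs
super-Gaussian source behaviour is switched per component by the sign of the
usual stability statistic, EMA-smoothed so it cannot chatter near zero
kurtosis. Full-batch natural-gradient updates with learning rate 0.2, at
most 1024 iterations and up to 3 restarts; the rate halves on overshoot;
convergence is a relative weight change below 1e-6, and a persistent plateau
within three orders of that tolerance (typical when k exceeds the true
structure and components are interchangeable) is accepted with a warning.
Extended (rather than logistic-only) Infomax is necessary here: component
maps over a bundle take a few discrete levels and are therefore
sub-Gaussian, which the logistic nonlinearity cannot separate.

Back-reconstruction defaults to dual regression. A group-information-guided
variant refines each subject map by one-unit fixed-point negentropy ascent
in the subject's whitened spatial subspace, constrained to keep correlation
with the group map above a floor (default 0.7) by blending toward the
dual-regression initializer, which is kept outright when refinement does not
increase non-Gaussianity. Group z-maps are the across-subject mean maps,
z-scored over mask voxels. Components are sign-oriented to positive map
skewness, with an explicit `flip_sign` utility for manual overrides.

## Model order and parcellation

Five measures are computed for k = 2..5: split-half, test–retest,
cross-cohort and static-benchmark similarities (each the mean matched |r|
between group z-maps of two runs, matched one-to-one by the Hungarian
algorithm on absolute correlations — ICA signs and orders are arbitrary),
plus the mean pairwise |r| of back-reconstructed component time courses
(lower = more independent). The consensus k is the majority argbest, ties to
the smaller k. Parcellation clusters the (V × k) z-map matrix with k-means
(Euclidean, k-means++, 50 restarts); the mean silhouette over c = 2..6
selects c; labels are renumbered ventral → dorsal by centroid z-coordinate.
Cluster centroids are means of member-voxel centers in world mm.

## Decoding

Cluster proximity maps are `1/(1+d_mm)` from each centroid — bounded, exact
at the centroid, and any strictly decreasing transform would give identical
rank-based screening. Terms are screened per cluster by GM-masked Pearson
correlation (top 20, deduplicated, anatomy stoplist shipped as editable
text), then track-weighted (streamline mean of the term map painted over
traversed voxels) and correlated with the proximity maps over the bundle
mask. Significance uses surrogate maps that preserve spatial
autocorrelation: permutations of the cluster map smoothed over a bank of
Gaussian kernels — isotropic spatial scales plus kernels over a spectral
embedding of streamline co-traversal, since bundle-restricted maps
decorrelate along the tract topology rather than Euclidean distance — mixed
with non-negative weights fitted once per ensemble to the count-weighted
binned variogram (kernel columns computed analytically from K·Kᵀ), plus a
white nugget and a random large-scale trend component, and finally
rank-remapped onto the original value multiset. p-values are two-sided
permutation probabilities `(#{|r_s| ≥ |r|} + 1)/(n + 1)`; Benjamini–Hochberg
(statsmodels) corrects across all (cluster, term) pairs; effect size is R².
Surrogates are generated for the cluster maps (3 ensembles) rather than per
term, keeping 1000-permutation inference tractable.

## The phantom

Each subject's data are arc-shaped sub-bundles stacked ventral → dorsal on a
20×20×12 grid of 2 mm voxels (200 streamlines per sub-bundle; quadratic
arcs between 3×3×3-voxel endpoint patches). Endpoint-pair signals are built
by shared-latent mixing,

```
x(t) = sign(ρ)·√|ρ(t)|·c(t) + √(1−|ρ(t)|)·e(t),    ρ_i(t) = ρ0 + A·Σ_m L[i,m]·mode_m(t)
```

with a shared standard-normal latent `c` per sub-bundle, idiosyncratic white
noise per voxel, baseline ρ0 = 0.45 and amplitude A = 0.4 (the operating
point of the recovery guarantees), so the pairwise correlation equals ρ by
construction. Latent modes are random walks low-pass-filtered at the ~40 s
window scale (so windowed FC can track them), mutually orthogonalised, zero
mean, peak-normalised. A small multiple (0.5) of the mode drive is added to
the endpoint mean signal so the static benchmark shares the component
structure, and white observation noise (sd 0.3) covers every voxel,
attenuating realised correlations by 1/(1+sd²). Geometry and modes derive
from the spec seed and are shared across subjects; subject index and session
index drive independent noise; subjects' bundles are rigidly jittered by
0.5 mm.

Two deliberate asymmetries make the planted structure identifiable by
spatial ICA, and are fixed design choices, not tuning knobs: sub-bundle
calibres differ (middle arc widest — real sub-bundles differ in calibre
too), and the third, anti-loaded sub-bundle weights the two modes unequally
(−0.5, −0.15). With symmetric calibres the two-mode source distribution has
rotationally equivalent optima that ICA resolves arbitrarily, and with an
equal anti-loading the third bundle's time course is a 45° mode mixture that
no decomposition could attribute to either mode.

Ground-truth voxel labels are assigned by majority bundle membership among
traversing template streamlines (ties to the lowest bundle index). The term
library contains signal terms (affine in a cluster's proximity map, plus
smoothed noise) and null terms (Gaussian random fields smoothed to the same
FWHM, default 6 mm); the GM mask is the dilated union of endpoint patches.

**What the phantom does not emulate:** hemodynamics, realistic brain
geometry, bundle crossings, scanner noise, physiological confounds, and any
cohort heterogeneity beyond rigid jitter and independent noise. Passing
recovery tests therefore demonstrates correctness of the computations and
internal consistency of the pipeline, not performance on real MRI.

## Problem sizes

Default analyses use 12 subjects, 300 time points (TR 2 s, window 20
points), ~600–900 bundle voxels, and 500 surrogate maps per cluster in the
calibration experiment; the full pipeline completes in a few minutes on one
CPU. These scales were chosen as the smallest at which the recovery
guarantees hold with comfortable margins.

## Known limitations

- With only three sub-bundles the bundle mask supports roughly five
  effective spatial degrees of freedom. The binned variogram then cannot
  fully distinguish isotropically smooth structure from bundle-level block
  structure, so the surrogate null is imperfectly calibrated: its null
  false-positive rate is close to, but not reliably within a few percent
  of, the nominal 5%. Related, the track-weighting operator caps the
  correlation between any term map's track-weighted image and a proximity
  map near 0.6, while an honest autocorrelation-preserving null reaches
  similar values — so on this geometry surrogate-based inference has very
  limited power regardless of implementation, and decoding conclusions on
  the phantom rest on effect ranking rather than corrected significance.
  Real bundles, with richer within-tract structure, give the surrogate fit
  more to work with.
- GIG-ICA hyperparameters are not standardised anywhere; the implementation
  here is a constrained refinement around dual regression and is the
  documented fallback, not a reference implementation.
- The static benchmark simplifies published whole-brain prior-based
  mappings to endpoint-mean painting over the same tractogram.
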