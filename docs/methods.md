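# Methods

This note documents the models, parameter choices and numerical
decisions behind `topomap`, and what the phantom-based tests do and do
not demonstrate about real microscopy data.

## Coordinate and unit conventions

Voxel indices are 0-based `(z, y, x)`; the physical position of a voxel
center is `index × spacing` in nanometres, with the first voxel center
at the origin.  All distances everywhere in the package are Euclidean
distances between such physical positions with the anisotropic spacing
applied per axis — index-space distances are never used.  The default
spacing (125, 39.5, 39.5) nm reproduces the geometry of a reconstructed
3D-SIM stack: 125 nm axial steps and a 79 nm camera pixel halved
laterally by the reconstruction.  Stacks are assumed to be non-negative
scalar fields; any offset/16-bit conversion of raw reconstructions is
treated as already done upstream.

## Nuclear mask

Gaussian smoothing at a physical scale (default 200 nm, ≈5 lateral
voxels), Otsu's threshold on a 256-bin histogram of the smoothed
intensities, retention of the largest 26-connected component, and
per-z-plane hole filling.  The hole filling ensures the mask includes
the intranuclear interchromatin space, so that class 1 of the
classification reflects IC channels rather than extranuclear
background.  The 256-bin histogram makes the mask invariant under
positive rescaling of the intensities.  Masks whose grid fraction falls
below `min_mask_fraction` are returned flagged rather than rejected.

The 200 nm default suppresses sub-resolution texture in raw
acquisitions.  For synthetic phantoms, which are generated already
convolved with the microscope PSF, tests use `sigma_nm = 0`: smoothing
the phantom again would double-count the blur and systematically erode
the mask by about one voxel, which is exactly what the Dice comparison
against the true ellipsoid shows.

## Chromatin compaction classification

### Model

In-mask DAPI intensities follow a K = 7 Gaussian mixture with one
shared variance σ² ("equal intensity variance") and weights π; voxel
labels carry a Potts prior with interaction β over the 6-connected
lattice.  The per-voxel energy is

    E(c) = (x − μ_c)²/(2σ²) + log σ − log π_c + β · #{in-mask 6-neighbors with label ≠ c}

The −log π term can be disabled (`use_pi=False`).  The 6-connected
neighborhood deliberately ignores z-anisotropy in the Potts term; an
anisotropy-weighted interaction would be a straightforward variant but
is not implemented.  β defaults to 0.5 and is a user parameter, not
estimated from data.

### Fitting: two stages

1. **Mixture fit.** Shared-variance soft EM is run from three
   deterministic initializations — seeded k-means centers, evenly
   spaced intensities between the 0.5th and 99.5th percentile, and
   smoothed-histogram peaks gap-filled up to K — and the solution with
   the highest incomplete-data log-likelihood is selected.

   Why multi-start: nuclear DAPI data typically contain one dominant
   class (the interchromatin background).  SSE-based initializers such
   as k-means split that heavy mode across several components and merge
   sparse high-compaction classes; EM then stays in that basin.  A
   sparse class riding on the tail of a heavy one appears only as a
   histogram *shoulder*, not a local maximum, which is why detected
   peaks are augmented by bisecting the widest inter-peak gaps.

   Why selection uses the *soft-EM* likelihood: hard (classification)
   assignments truncate the tails of overlapping components and
   understate the fit of the correct solution, making model selection
   across restarts unreliable; the converged EM likelihood is the
   well-defined criterion.  The Potts energy is deliberately excluded
   from selection: a spatial prior rewards labelings with fewer
   boundary pairs and would therefore prefer merging thin layered
   classes — it regularizes the labeling *within* the chosen basin, it
   must not choose the basin.

2. **Labeling.** Starting from the MAP assignment under the selected
   parameters, checkerboard ICM sweeps (the two parities of `z + y + x`
   are independent sets under 6-connectivity, so the vectorized update
   is exact ICM and the total energy is non-increasing within a sweep)
   alternate with re-estimation of μ (class means), σ² (pooled
   within-class variance, floored at 1e-10 of the squared intensity
   range to survive noise-free inputs), and π (class frequencies).
   Iteration stops when fewer than `tol = 1e-3` of the labels change in
   a sweep, or after `max_iter = 50` sweeps (the result is then flagged
   as non-converged but still returned).  Energy ties break toward the
   lower class index; empty classes keep their previous mean and get a
   floor weight so they can repopulate.

Components are relabeled ascending in μ after fitting, so class 1 is
always the lowest-intensity (IC) class and class 7 the most compact.
`classify_gmm` is the β = 0 path of the same code, which makes the
"Potts-free HMRF equals the plain mixture MAP" equivalence exact by
construction; an independent soft-EM implementation (scikit-learn's
tied-covariance `GaussianMixture`) serves as the cross-check oracle in
the test suite.

## FISH spot segmentation and pairing filter

Threshold `T = max(mean + k_sd·SD, relative_floor·max)` over in-mask
channel intensities (defaults `k_sd = 4`, `relative_floor = 0.25`),
26-connected components, minimum size `min_voxels = 4`.  Centroids are
geometric gravity centers (unweighted voxel-position means) in nm;
volume is voxel count × voxel volume.  These preset values are declared
defaults, not measurements: single-copy FISH signals sit at the
volumetric resolution limit (~0.005 µm³), so no size or intensity
criterion can separate them from isolated background fluorophores.

That is the role of the pairing filter: a spot in either channel is
kept only if its centroid lies within `pairing_max_dist_nm = 500` of
the nearest centroid of the differently labeled channel, applied
symmetrically to both channels.  The 0.5 µm value is anchored by the
extended-fiber argument (10 kb of 10-nm fiber at a 200 bp nucleosomal
repeat spans ~500 nm), implemented in `extended_fiber_length`.

## Signal-to-class mapping and statistics

DAPI class fractions are voxel-count based; signal distributions are
intensity-weighted by default (`weighting="count"` available), per the
asymmetric definition of the workflow.  Both are normalized to 1 per
nucleus; enrichment is `e_k = 100·(s_k − d_k)` percentage points and
sums to zero.  Spot voxels that fall outside the mask are excluded and
logged.

The neighbor-class matrix defaults to the 6-connected adjacency tally
(`mode="adjacent"`); the nearest-different-voxel variant
(`mode="nearest"`, anisotropy-aware EDT per class) is provided because
the underlying notion of "nearest-neighbor voxel" admits both readings.
Minimal class-to-class distances use `scipy.ndimage`'s anisotropic
Euclidean distance transform per target class, averaged over source
voxels; absent target classes report NaN, never zero.

Group comparisons: Wilcoxon rank-sum with exact enumeration when both
groups have n ≤ 8 and no ties, otherwise the normal approximation with
continuity correction; two-tailed Student's t; pairwise t tests across
G groups use the Bonferroni level α/m with m = G(G−1)/2 and adjusted
p = min(1, m·p).  Stars: * ≤ 0.05, ** ≤ 0.01, *** ≤ 0.001.  Per-class
comparisons across channels are reported class by class without
cross-class adjustment; Bonferroni is reserved for distance-analysis
families.  Trend fits are least-squares parabolas over the ordinal
class index k = 1..K.  Replicate (sister-chromatid) pairing uses
mutual-nearest-neighbor matching with a 500 nm cutoff so each spot
contributes at most one pair.

## The phantom generator

The generator emulates the statistical structure the analysis assumes:

- **Geometry.** An ellipsoidal nucleus (default semi-axes 2000 × 1100 ×
  1100 nm — a flat nucleus of ~4 µm axial diameter — in a 64³ grid at
  (125, 39.5, 39.5) nm spacing).  Inside it, `n_cdcs = 20` CDC spheres
  with radii 500–700 nm (overlap allowed; CDCs are clusters of touching
  domains), plus a 200 nm chromatin layer lining the envelope
  (lamina-associated heterochromatin).  Chromatin voxels get class
  2..7 by the anisotropy-aware depth below the chromatin surface in
  80 nm shells (first shell → class 2, deeper than five shells →
  class 7); non-chromatin nuclear voxels are class 1.  These values
  were chosen so the resulting DAPI class fractions are roughly
  balanced across the seven classes, as measured nuclei show.
- **Intensities.** Class means 40, 55, …, 130 (arbitrary units,
  15 apart) with shared Gaussian noise SD 4.5 (= 0.3 × the class gap),
  then an anisotropic Gaussian PSF blur (σ 125 nm axial / 50 nm
  lateral, matching ~300/120 nm FWHM resolution).  The means are free
  parameters of the generator — no absolute intensity levels exist to
  copy — and are set well above the zero background because even the
  interchromatin compartment carries clear DAPI signal in real images.
- **Spots.** Channel-1 spot centers are drawn from a configurable class
  preference (default 60/30/10% on classes 2/3/4; `None` = uniform over
  the mask, i.e. proportional to the DAPI fractions); channel-2 centers
  are placed 100–300 nm from their channel-1 partner, emulating two
  contiguous differently labeled probes.  Spots are anisotropic
  Gaussians (σ 110/55 nm, ~130 nm lateral FWHM, amplitude 150).
  Unpaired background speckles (Poisson mean 2 per channel, same size
  and brightness as true spots — deliberately indistinguishable except
  by pairing) are planted at least 800 nm from every other-channel
  position, so the 500 nm filter must remove them all.
- **Determinism.** One RNG stream per phantom, draws in a fixed order
  (CDCs, ch1 spot classes/voxels, ch2 offsets, ch1 speckles, ch2
  speckles, DAPI noise, channel noise); identical config + seed gives
  bit-identical stacks and truth.

### What the phantoms do not emulate

No chromatin polymer structure below the shell scale, no nucleoli, no
camera noise model beyond additive Gaussian, no chromatic aberration or
reconstruction artifacts, no variation in staining efficiency.  Passing
the phantom suites therefore demonstrates correctness of the
*computational* pipeline under its own model assumptions — not that
seven intensity classes, or any particular β, are the right description
of a given real data set.

### Resolvable sampling in recovery tests

With 125 nm axial steps and ~80 nm shells, a single axial voxel step
crosses more than one class boundary: the layered truth is aliased and
no voxel classifier can recover it (the MAP solution provably prefers
merging adjacent thin layers).  Ground-truth recovery and
layered-structure tests therefore generate phantoms at 50 nm axial
sampling, where one step never spans more than one shell; the
acquisition-geometry default is retained everywhere else.  At that
resolvable sampling the HMRF recovers ~97% of voxels at noise 0.3 × the
class gap.

## Problem sizes

Tests and the acceptance script use 64³ phantom nuclei (≈50 000 in-mask
voxels) in batches of 10 for enrichment/null recovery, 3 for
classification recovery, and sub-32³ phantoms for oracle-equivalence
checks; brute-force distance oracles run on ≤16³ random maps.  These
sizes keep a full run in the low minutes on one CPU while leaving every
statistical margin (binomial SEs, sign patterns) comfortably resolved.

## Known limitations

- β is fixed, not estimated; no Gibbs/graph-cut posterior exploration.
- Whether DAPI should be rescaled per nucleus before classification is
  exposed as a config flag (`rescale_dapi`, default off) with no claim
  about the original workflow.
- Spot centroids are voxel-resolution gravity centers; no sub-voxel
  Gaussian fitting.
- One nucleus per stack; no multi-nucleus fields of view.
- The two readings of "nearest-neighbor voxel" (adjacency vs nearest
  different voxel) are both implemented; adjacency is the default
  without a faithfulness claim.
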