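# Methods

`wskreg` registers two LiDAR point clouds of the same forest plot taken from
incompatible viewpoints — typically an under-canopy handheld scan (HLS, the
*source*) and a UAV scan (ULS, the *target*) — by anchoring the alignment on
woody structure, the only part of a tree that looks the same from above and
below and does not move in wind.

## Pipeline

1. **Voxel preprocessing.** Both clouds are reduced to one centroid per
   occupied 0.15 m cubic cell. The grid is anchored at the per-cloud minimum
   corner (`floor(min/cell)`), which makes the result order-independent and
   reproducible without a shared datum. The centroid (rather than a surviving
   original point) was chosen as the representative: it is deterministic and
   averages range noise.

2. **Eigen-features and ROI.** Each point's neighborhood (radius R = 0.5 m,
   query point included) yields a covariance whose sorted eigenvalues
   l1 >= l2 >= l3 give linearity L = (l1-l2)/l1, first-component share
   PCA1 = l1/(l1+l2+l3), surface variation Sv = l3/(l1+l2+l3), planarity
   P = (l2-l3)/l1 and scatter S. The structural significance score
   SSS = L + PCA1 - Sv separates line-like woody returns (SSS -> 2) from
   isotropic foliage (SSS -> 0 for a perfect ball); points with SSS > tau
   (default 0.8) form the region of interest. **Scatter convention:** S is
   implemented as the bounded sphericity l3/l1. The unbounded alternative
   l1/l3 diverges on perfect lines and would invert the saliency ordering
   of the WSS score below, which is defined so that *lower* values mark
   locally unique structure such as branch bifurcations.

3. **Keypoints.** Within the ROI, the wood-structure significance
   WSS = (L + (1 - Sv)) / (1 + ln(1 + P + S)) is sorted ascending (ties to
   the lower index) and the top Nr = 0.8 fraction (ceiling, so a non-empty
   ROI always yields candidates) enters a single greedy non-maximum
   suppression sweep with radius R_N = 0.3 m: each kept point suppresses all
   not-yet-visited candidates within R_N. Kept keypoints are therefore
   pairwise >= R_N apart and each is the saliency minimum of its
   neighborhood at its turn. Nr is a fraction *of the ROI* (the scores are
   only computed there). Note the sweep order depends on WSS comparisons:
   two candidates whose scores differ only at round-off (~1e-11 happens on
   voxelized synthetic scenes) may swap under a rigid motion, so detector
   commutation with rotation is exact only when scores are distinct beyond
   noise.

4. **Description.** Surface normals are smallest-eigenvector estimates at
   the feature radius (no separate normal scale is introduced), with sign
   fixed by the summed projection of neighbor displacements — a
   rigid-invariant rule. Each keypoint gets a 352-D SHOT descriptor:
   a local reference frame from the (R_f - d)-weighted covariance of
   support displacements (R_f = 2.0 m), axes sign-disambiguated the same
   way; 2 radial shells x 2 elevation bands x 8 azimuth sectors, each with
   an 11-bin histogram of the cosine between support normal and keypoint
   normal; quadrilinear soft-binning (each support point contributes exactly
   unit mass) and final L2 normalization. The keypoint's reference normal is
   sign-aligned with the frame's z-axis: the frame's weighted disambiguation
   is much more stable than the per-point normal's, and a flipped reference
   would invert every cosine in the signature.

5. **Matching and filtering.** Exact nearest neighbors in descriptor space
   (Euclidean on unit vectors, monotone in cosine distance) in both
   directions; pairs must be mutual and satisfy |WSS(p) - WSS(q)| < delta
   (default 0.3, applied to raw scores — WSS is built from scale-free
   eigenvalue ratios, so magnitudes are comparable across platforms). A
   seeded tuple test then samples up to 1000 triplets of pairs and keeps
   every pair belonging to a triplet whose three cross-cloud distance
   ratios all lie in [alpha, 1/alpha], alpha = 0.9. Triplets with
   coincident points are discarded rather than failed.

6. **Transform estimation.** The rigid motion minimizes the scaled
   Geman-McClure cost sum_i mu r_i^2 / (mu + r_i^2) by graduated
   non-convexity: mu starts at the squared diameter of the correspondence
   span and is divided by 1.4 every 4 Gauss-Newton iterations on the
   linearized motion (omega, u), with the rotation re-projected onto SO(3)
   by SVD each step and a step-halving safeguard that keeps the objective
   non-increasing within each fixed-mu block. The solver runs at least 64
   iterations and keeps annealing until mu reaches a floor (cap 400
   iterations): on plot-scale scenes mu_0 is ~3600 m^2 and 64 iterations
   would leave the kernel far above the inlier scale. The standalone solver
   floors mu at 1e-4 m^2 (1 cm, for clean correspondences); the pipeline
   floors it at the squared voxel size (0.0225 m^2), because keypoint
   correspondences across independently sampled platform views carry
   voxel-scale noise and a deeper anneal overfits whichever tight subset
   the kernel lands on. Point-to-point ICP
   refinement is available but off by default; the pipeline's headline
   accuracy is reached without it.

## Evaluation metrics

Per-axis rotational error is measured as the angles between rank-paired
principal (PCA) axes of the reference and the aligned cloud, computed with
the atan2 form (stable near zero) and folded through |dot| to [0, 90]
degrees since PCA axis signs are arbitrary. Translational error is the
centroid distance. RMSE uses index pairing when point identity is known
(synthetic fixtures) and nearest-neighbor pairing with a 0.45 m cutoff
(3x the voxel size) otherwise. Keypoint repeatability is the fraction of
*source* keypoints with a target keypoint within a threshold after
ground-truth alignment (defaults 0.15/0.3/0.45/0.6 m); ANND is the mean
distance of each keypoint to its nearest fellow keypoint.

## Synthetic plantation generator

The simulator states a world and the tests live in it; its defaults are a
mature leaf-off plot: 30 m x 30 m, 433 trees/ha (39 trees), 22 m mean tree
height, trunks as tapered vertical cylinders on a 5 m x 4 m jittered
planting grid, five branches per tree leaving the upper trunk at 30-65
degrees from vertical, foliage ellipsoids at branch ends (250 points each
at leaf-on; x0.05 in the incomplete leaf-off state), and a ground plane
with 0.05 m roughness. Platform views are *statistical*, not ray-traced:
each point survives with a label- and height-dependent probability (ULS
retains canopy and upper structure and, under leaf-on, loses lower trunk
and ground; HLS retains trunk and ground with retention decaying upward),
then isotropic Gaussian noise of sigma = 0.03 m is added — inside the
<= 5 cm accuracy class of the instruments being emulated. Misalignments
are uniform random axes with angle <= 15 degrees and translation
components <= 5 m: beyond the voxel and NMS scales, yet a plausible field
initialization.

What a green test does **not** establish: real scans have beam-divergence
footprints, intensity-dependent noise, wind-driven foliage motion,
co-registration drift inside each scan, and occlusion that is spatially
correlated rather than i.i.d. — none of which the generator emulates. The
synthetic results validate the pipeline's logic and its stated tolerances,
not field-survey accuracy.

## Numerical choices and degenerate inputs

- Feature records need >= 5 neighbors and l1 > 1e-12 m^2; invalid records
  carry SSS = -inf (never in the ROI) and WSS = +inf (never salient).
- Eigenvalues come from symmetric eigendecomposition (identical to SVD for
  PSD matrices); round-off negatives are clamped to zero.
- Local reference frames are invalid on rank-deficient (collinear) support;
  such keypoints yield zero descriptors and are excluded from matching.
- The NMS comparison uses <= with index tie-break; a strict < would
  deadlock on exact ties from symmetric synthetic geometry.
- Transform files are plain-text 4x4 row-major homogeneous matrices; the
  bottom row is validated to (0,0,0,1) within 1e-9.
- LAS I/O uses a fixed 1 mm scale (quantization bound for round-trips);
  LAZ is rejected explicitly since no decompressor is assumed.

## Known limitations

- The detector's exact output can change under rigid motion when WSS values
  tie at round-off (see above); the keypoint *positions* remain stable.
- Plots whose ROI is empty (no woody structure, tau too high) abort with a
  stage-named error rather than degrading to foliage keypoints.
- The tuple test is sampling-based; with very large correspondence sets and
  few inliers, 1000 samples may miss rare inlier triplets — the cap is a
  parameter.
- Descriptor matching is O(|K_src| x |K_tgt|) exact search; adequate for
  plot-scale keypoint counts (thousands), not for whole-forest mosaics.
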