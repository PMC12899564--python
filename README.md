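# wskreg

Marker-free registration of cross-platform forest LiDAR point clouds.

UAV laser scanning (ULS) sees a plantation from above — mostly canopy —
while handheld scanning (HLS) sees trunks and ground from below. Fusing the
two into one coordinate system is what makes single-tree phenotyping
(height, stem, crown) possible, but the overlap between the views is weak
and foliage is unstable across time and viewpoint. `wskreg` aligns the two
clouds by detecting **woody salient keypoints** (WSK): points on trunks and
branch bifurcations, found by eigenvalue geometry, that look the same from
either side of the canopy.

Given sorted local covariance eigenvalues λ1 ≥ λ2 ≥ λ3 with
L = (λ1−λ2)/λ1, PCA1 = λ1/Σλ, Sv = λ3/Σλ, P = (λ2−λ3)/λ1, S = λ3/λ1:

- **ROI segmentation** keeps points with SSS = L + PCA1 − Sv > τ
  (woody returns are line-like, SSS → 2; foliage is isotropic, SSS → 0);
- **saliency ranking** sorts the ROI by
  WSS = (L + (1 − Sv)) / (1 + ln(1 + P + S)), lower = more locally unique
  (branch bifurcations), keeps the top Nr fraction, and enforces a 0.3 m
  non-maximum-suppression spacing;
- keypoints get 352-D **SHOT** descriptors; matches must be mutual nearest
  neighbors with |ΔWSS| < δ and survive a distance-ratio **tuple test**;
- the rigid transform is estimated with a **graduated non-convexity**
  (fast-global-registration style) Geman–McClure solver, optionally refined
  by ICP.

A seeded synthetic plantation simulator (row-planted tapered trunks,
branches, phenology-dependent foliage, platform-specific visibility, range
noise, known ground-truth misalignment) makes the whole pipeline testable
without any field data.

## Worked example

```python
import wskreg as w

# a 30 m x 30 m leaf-off plantation fixture with known ground truth
fx = w.make_registration_fixture(w.SceneConfig(seed=1))
res = w.register(fx.source, fx.target)          # HLS -> ULS
aligned = fx.source.transformed(res.transform)
err, n = w.rmse(fx.source_aligned, aligned, pairing="index")
theta = w.principal_axis_angles(fx.source_aligned, aligned)
print(res.counts)
print(f"RMSE {err:.3f} m over {n} points, axis errors "
      f"{[round(float(t), 3) for t in theta]} deg")
```

prints

```
{'source_points': 59701, 'target_points': 57022, 'source_keypoints': 8890,
 'target_keypoints': 7424, 'initial_matches': 8890, 'reciprocal_matches': 1471,
 'tuple_matches': 152}
RMSE 0.016 m over 147724 points, axis errors [0.022, 0.059, 0.063] deg
```

i.e. starting from a random misalignment of up to 15° / 5 m, the recovered
transform puts every point of the handheld scan within ~2 cm RMS of its
true position — below the 0.15 m voxel size — with sub-degree residual
rotation about every principal axis.

The same flow from the shell:

```sh
wskreg simulate --seed 1 --out-source src.ply --out-target tgt.ply \
       --out-transform T_gt.txt
wskreg register --source src.ply --target tgt.ply --out-transform T_est.txt \
       --report report.json
wskreg evaluate --reference tgt.ply --aligned aligned.ply
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default synthetic fixture from the given seed, runs the full
registration pipeline at default parameters, and reports the recovered
alignment quality on stderr; the JSON output file records the (empty) set of
benchmark quantities.
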