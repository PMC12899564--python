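"""Seeded synthetic plantation scenes and platform-specific LiDAR samplings.

The generator emulates square row-planted plantation plots: tapered vertical
trunk cylinders on a jittered planting grid, oblique branch cylinders
emanating from the upper trunk (their attachment points are the
bifurcation-like structures the keypoint detector favors), foliage as random
points in ellipsoids around branch ends whose density follows the phenology
(leaf-on vs sparse incomplete leaf-off), and a roughened ground plane.

Platform views model the aerial/under-canopy visibility asymmetry
statistically rather than by ray tracing: each point survives with a
label- and height-dependent retention probability (the aerial ULS view keeps
canopy and upper structure, losing lower trunk and ground under leaf-on
occlusion; the handheld HLS view keeps trunks and ground, decaying with
height), then isotropic Gaussian range noise is added. A seeded random
rigid misalignment with known inverse completes a registration fixture with
full point identity for index-matched error measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, floor, pi
from typing import Optional

import numpy as np

from .pointcloud import Label, PointCloud
from .transforms import RigidTransform, invert

__all__ = ["SceneConfig", "PlatformSamplingConfig", "RegistrationFixture",
           "generate_scene", "sample_platform_view", "uls_sampling", "hls_sampling",
           "random_rigid_misalignment", "make_registration_fixture"]


@dataclass
class SceneConfig:
    """Parameters of one synthetic plantation plot.

    Defaults follow a mature leaf-off plantation plot: a 30 m x 30 m plot
    with 433 trees/ha and 22 m mean tree height; the juvenile end of the
    observed range (1755 trees/ha, 15 m) is reachable through the same
    fields.
    """

    plot_size: tuple = (30.0, 30.0)       # meters
    row_spacing: float = 5.0              # meters between planting rows (x)
    tree_spacing: float = 4.0             # meters between trees in a row (y)
    trees_per_hectare: float = 433.0
    tree_height: float = 22.0             # mean total tree height, meters
    trunk_diameter: float = 0.35          # at breast height, meters
    branches_per_tree: int = 5
    branch_angle_range: tuple = (30.0, 65.0)  # degrees from vertical
    phenology: str = "leaf_off"           # "leaf_on" | "leaf_off"
    leaf_multiplier: Optional[float] = None   # default 1.0 leaf-on, 0.05 leaf-off
    leaf_points_per_cluster: int = 250    # at multiplier 1.0
    ground_roughness: float = 0.05        # meters (std of plane perturbation)
    point_spacing: float = 0.07           # surface sampling spacing, meters
    seed: int = 0

    def __post_init__(self) -> None:
        if self.row_spacing <= 0 or self.tree_spacing <= 0:
            raise ValueError("spacings must be positive")
        if self.trees_per_hectare < 0 or self.leaf_points_per_cluster < 0:
            raise ValueError("densities must be non-negative")
        if self.phenology not in ("leaf_on", "leaf_off"):
            raise ValueError("phenology must be 'leaf_on' or 'leaf_off'")

    @property
    def n_trees(self) -> int:
        area_ha = self.plot_size[0] * self.plot_size[1] / 1e4
        return ceil(area_ha * self.trees_per_hectare)

    @property
    def effective_leaf_multiplier(self) -> float:
        if self.leaf_multiplier is not None:
            return self.leaf_multiplier
        return 1.0 if self.phenology == "leaf_on" else 0.05


@dataclass
class PlatformSamplingConfig:
    """Visibility and noise model of one scanning platform.

    ``retention`` maps each semantic label to ``(p_bottom, p_top)``: the
    survival probability at the bottom and top of the scene, linearly
    interpolated in normalized height.
    """

    platform: str                         # "ULS" | "HLS"
    retention: dict = field(default_factory=dict)
    noise_sigma: float = 0.03             # meters, within the <= 5 cm class
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        for lbl, (a, b) in self.retention.items():
            if not (0 <= a <= 1 and 0 <= b <= 1):
                raise ValueError(f"retention probabilities for {lbl} must be in [0, 1]")


def uls_sampling(phenology: str = "leaf_off", noise_sigma: float = 0.03,
                 seed: int = 0) -> PlatformSamplingConfig:
    """Aerial view: canopy-dominated; lower trunk/ground suppressed when leaf-on."""
    if phenology == "leaf_on":
        retention = {Label.TRUNK: (0.08, 0.85), Label.BRANCH: (0.55, 0.95),
                     Label.LEAF: (0.85, 0.95), Label.GROUND: (0.08, 0.08)}
    else:
        retention = {Label.TRUNK: (0.5, 0.95), Label.BRANCH: (0.8, 0.95),
                     Label.LEAF: (0.85, 0.95), Label.GROUND: (0.55, 0.55)}
    return PlatformSamplingConfig("ULS", retention, noise_sigma, seed)


def hls_sampling(phenology: str = "leaf_off", noise_sigma: float = 0.03,
                 seed: int = 0) -> PlatformSamplingConfig:
    """Under-canopy view: trunks and ground captured; retention decays with height."""
    if phenology == "leaf_on":
        retention = {Label.TRUNK: (0.97, 0.6), Label.BRANCH: (0.75, 0.3),
                     Label.LEAF: (0.5, 0.12), Label.GROUND: (0.95, 0.95)}
    else:
        retention = {Label.TRUNK: (0.97, 0.75), Label.BRANCH: (0.85, 0.55),
                     Label.LEAF: (0.6, 0.35), Label.GROUND: (0.95, 0.95)}
    return PlatformSamplingConfig("HLS", retention, noise_sigma, seed)


def _cylinder_points(base: np.ndarray, axis: np.ndarray, length: float,
                     r0: float, r1: float, spacing: float, rng) -> np.ndarray:
    """Surface samples of a tapered cylinder from ``base`` along unit ``axis``."""
    n_rings = max(2, ceil(length / spacing))
    ts = np.linspace(0.0, length, n_rings)
    radii = r0 + (r1 - r0) * ts / length
    # orthonormal frame around the axis
    ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    pts = []
    for t, r in zip(ts, radii):
        m = max(3, ceil(2 * pi * r / spacing))
        ang = rng.uniform(0, 2 * pi) + np.arange(m) * (2 * pi / m)
        ring = (base + t * axis
                + r * np.cos(ang)[:, None] * u + r * np.sin(ang)[:, None] * v)
        pts.append(ring)
    return np.vstack(pts)


def generate_scene(config: SceneConfig) -> PointCloud:
    """Deterministic (per seed) labeled plantation scene."""
    rng = np.random.default_rng(config.seed)
    px, py = config.plot_size
    n_trees = config.n_trees
    n_rows = floor(px / config.row_spacing)
    per_row = floor(py / config.tree_spacing)
    if n_rows * per_row < n_trees:
        raise ValueError(
            f"density {config.trees_per_hectare}/ha needs {n_trees} trees but the "
            f"{config.row_spacing} m x {config.tree_spacing} m grid only fits "
            f"{n_rows * per_row} on the plot")
    x0 = (px - n_rows * config.row_spacing) / 2 + config.row_spacing / 2
    y0 = (py - per_row * config.tree_spacing) / 2 + config.tree_spacing / 2
    grid = [(x0 + i * config.row_spacing, y0 + j * config.tree_spacing)
            for i in range(n_rows) for j in range(per_row)][:n_trees]
    chunks: list[np.ndarray] = []
    labels: list[np.ndarray] = []

    def _add(pts, lbl):
        if len(pts):
            chunks.append(pts)
            labels.append(np.full(len(pts), lbl, dtype=np.int8))

    sp = config.point_spacing
    leaf_mult = config.effective_leaf_multiplier
    n_leaf = int(round(config.leaf_points_per_cluster * leaf_mult))
    for gx, gy in grid:
        cx = gx + rng.uniform(-0.3, 0.3)
        cy = gy + rng.uniform(-0.3, 0.3)
        h = max(3.0, config.tree_height + rng.normal(0.0, 1.0))
        trunk_top = 0.75 * h
        r0 = config.trunk_diameter / 2
        trunk = _cylinder_points(np.array([cx, cy, 0.0]), np.array([0.0, 0.0, 1.0]),
                                 trunk_top, r0, 0.35 * r0, sp, rng)
        _add(trunk, Label.TRUNK)
        for _ in range(config.branches_per_tree):
            z_attach = rng.uniform(0.5, 0.72) * h
            azim = rng.uniform(0, 2 * pi)
            tilt = np.radians(rng.uniform(*config.branch_angle_range))
            axis = np.array([np.sin(tilt) * np.cos(azim),
                             np.sin(tilt) * np.sin(azim), np.cos(tilt)])
            length = 0.3 * h * rng.uniform(0.8, 1.2)
            base = np.array([cx, cy, z_attach])
            branch = _cylinder_points(base, axis, length, 0.06, 0.025, 1.1 * sp, rng)
            _add(branch, Label.BRANCH)
            if n_leaf > 0:
                center = base + axis * length
                axes = np.array([1.6, 1.6, 1.1])
                g = rng.normal(size=(n_leaf, 3))
                g /= np.linalg.norm(g, axis=1)[:, None]
                rad = rng.uniform(0, 1, n_leaf) ** (1 / 3)
                _add(center + g * rad[:, None] * axes, Label.LEAF)
    gx = np.arange(0.15, px, 0.3)
    gy = np.arange(0.15, py, 0.3)
    gxx, gyy = np.meshgrid(gx, gy)
    ground = np.column_stack([
        gxx.ravel() + rng.uniform(-0.1, 0.1, gxx.size),
        gyy.ravel() + rng.uniform(-0.1, 0.1, gxx.size),
        rng.normal(0.0, config.ground_roughness, gxx.size),
    ])
    _add(ground, Label.GROUND)
    pts = np.vstack(chunks)
    lab = np.concatenate(labels)
    return PointCloud(pts, lab, source="synthetic", ids=np.arange(len(pts)))


def sample_platform_view(scene: PointCloud, config: PlatformSamplingConfig) -> PointCloud:
    """Stochastic platform view: height/label retention + Gaussian range noise."""
    rng = np.random.default_rng(config.seed)
    z = scene.points[:, 2]
    zmin, zmax = z.min(), z.max()
    zn = (z - zmin) / max(zmax - zmin, 1e-12)
    prob = np.ones(len(scene))
    if scene.labels is None:
        raise ValueError("platform sampling requires a labeled scene")
    for lbl, (p_bot, p_top) in config.retention.items():
        mask = scene.labels == int(lbl)
        prob[mask] = p_bot + (p_top - p_bot) * zn[mask]
    keep = rng.random(len(scene)) < prob
    view = scene.select(keep)
    if config.noise_sigma > 0:
        view.points = view.points + rng.normal(0.0, config.noise_sigma,
                                               view.points.shape)
    view.source = config.platform
    return view


def random_rigid_misalignment(max_rotation_deg: float, max_translation: float,
                              seed: int = 0) -> RigidTransform:
    """Uniform random axis, angle <= bound, translation components <= bound."""
    if max_rotation_deg < 0 or max_translation < 0:
        raise ValueError("bounds must be non-negative")
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0, max_rotation_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    t = rng.uniform(-max_translation, max_translation, 3)
    return RigidTransform(R, t)


@dataclass
class RegistrationFixture:
    """A matched source/target pair with known ground truth.

    ``transform_gt`` re-aligns ``source`` (the displaced handheld view) onto
    the scene frame shared with ``target``; ``source_aligned`` is exactly
    ``transform_gt`` applied to ``source`` (the noisy handheld view in scene
    coordinates) and ``source_clean`` its noise-free twin, index-matched
    point for point.
    """

    source: PointCloud          # HLS view, displaced by the inverse ground truth
    target: PointCloud          # ULS view, scene frame
    transform_gt: RigidTransform
    source_aligned: PointCloud  # = transform_gt(source), scene frame
    source_clean: PointCloud    # noise-free twin of source_aligned
    scene: PointCloud


def make_registration_fixture(scene_config: SceneConfig,
                              uls_config: Optional[PlatformSamplingConfig] = None,
                              hls_config: Optional[PlatformSamplingConfig] = None,
                              misalignment: Optional[RigidTransform] = None,
                              max_rotation_deg: float = 15.0,
                              max_translation: float = 5.0) -> RegistrationFixture:
    """Build a seeded HLS-source / ULS-target pair from one scene.

    Platform configs default to the phenology-matched visibility models with
    seeds derived from the scene seed; the misalignment defaults to a random
    rigid motion within (15 degrees, 5 m).
    """
    seed = scene_config.seed
    scene = generate_scene(scene_config)
    if uls_config is None:
        uls_config = uls_sampling(scene_config.phenology, seed=seed * 3 + 1)
    if hls_config is None:
        hls_config = hls_sampling(scene_config.phenology, seed=seed * 3 + 2)
    uls = sample_platform_view(scene, uls_config)
    hls = sample_platform_view(scene, hls_config)
    if misalignment is None:
        misalignment = random_rigid_misalignment(max_rotation_deg, max_translation,
                                                 seed=seed * 3 + 3)
    # noise-free twin: same retention draw, no noise
    clean_cfg = PlatformSamplingConfig(hls_config.platform, hls_config.retention,
                                       0.0, hls_config.seed)
    hls_clean = sample_platform_view(scene, clean_cfg)
    source = hls.transformed(invert(misalignment))
    return RegistrationFixture(source, uls, misalignment, hls, hls_clean, scene)
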