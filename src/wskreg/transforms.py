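"""Rigid-motion algebra: proper rotations + translations in meters.

A :class:`RigidTransform` maps a point ``p`` to ``R @ p + t``. Rotations are
validated to be proper (orthonormal, det = +1) on construction so that every
transform flowing through the pipeline is a genuine SE(3) element.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RigidTransform", "compose", "invert", "read_transform", "write_transform"]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``p -> rotation @ p + translation``."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {R.shape}")
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("transform contains non-finite entries")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-6:
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation is not proper (det != +1); reflections rejected")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "RigidTransform":
        M = np.asarray(M, dtype=float)
        if M.shape != (4, 4):
            raise ValueError(f"homogeneous matrix must be 4x4, got {M.shape}")
        if np.abs(M[3] - np.array([0.0, 0.0, 0.0, 1.0])).max() > _ORTHO_TOL:
            raise ValueError("bottom row of homogeneous matrix must be (0, 0, 0, 1)")
        return cls(M[:3, :3], M[:3, 3])

    def as_matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of points through the transform."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation


def compose(T1: RigidTransform, T2: RigidTransform) -> RigidTransform:
    """Return the transform applying ``T2`` first, then ``T1``."""
    return RigidTransform(T1.rotation @ T2.rotation,
                          T1.rotation @ T2.translation + T1.translation)


def invert(T: RigidTransform) -> RigidTransform:
    """Inverse motion: ``compose(T, invert(T))`` is the identity."""
    Rinv = T.rotation.T
    return RigidTransform(Rinv, -Rinv @ T.translation)


def read_transform(path) -> RigidTransform:
    """Read a 4x4 row-major whitespace-separated homogeneous matrix."""
    text = Path(path).read_text()
    values = text.split()
    if len(values) != 16:
        raise ValueError(f"{path}: expected 16 numbers for a 4x4 transform, got {len(values)}")
    try:
        M = np.array([float(v) for v in values]).reshape(4, 4)
    except ValueError as exc:
        raise ValueError(f"{path}: malformed transform matrix: {exc}") from None
    return RigidTransform.from_matrix(M)


def write_transform(T: RigidTransform, path) -> None:
    M = T.as_matrix()
    lines = [" ".join(f"{v:.17g}" for v in row) for row in M]
    Path(path).write_text("\n".join(lines) + "\n")
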