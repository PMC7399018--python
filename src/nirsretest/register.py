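"""Rigid landmark registration (Kabsch/SVD).

Aligns physical-head anatomical landmarks with their image-space
counterparts by the least-squares rotation + translation (no scaling),
as used to calibrate a neuronavigation session.  The residual RMS
distance over the landmark pairs is the fiducial registration error
(FRE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LandmarkSet", "RigidTransform", "fit_rigid", "apply_transform",
           "DEFAULT_LANDMARKS", "GUIDANCE_RADIUS_MM", "on_position"]

DEFAULT_LANDMARKS = (
    "inion", "right_eye_outer_corner", "nasion", "preauricular_left",
    "preauricular_right", "glabella", "left_alar", "right_alar",
)

# Guidance spheres: an optode counts as correctly repositioned when it is
# within this distance of its saved location.
GUIDANCE_RADIUS_MM = 6.0


@dataclass
class LandmarkSet:
    """Ordered, named 3-D points in mm."""

    points: np.ndarray                      # (n, 3)
    names: tuple[str, ...] = ()

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not self.names:
            self.names = tuple(f"p{i}" for i in range(len(self.points)))
        if len(self.names) != len(self.points):
            raise ValueError("one name per point required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("landmark names must be unique")


@dataclass
class RigidTransform:
    """p' = R p + t, with R a proper rotation."""

    rotation: np.ndarray     # (3, 3)
    translation: np.ndarray  # (3,)
    fre: float = 0.0         # mm, RMS over the fitted pairs

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


def fit_rigid(src: LandmarkSet, dst: LandmarkSet) -> RigidTransform:
    """Least-squares rigid transform mapping src points onto dst.

    SVD solution with determinant correction so reflections are
    excluded; requires at least 3 non-collinear matched pairs.
    """
    if src.names != dst.names:
        raise ValueError("landmark names do not match between the two sets")
    a, b = src.points, dst.points
    if len(a) < 3:
        raise ValueError("need at least 3 landmark pairs")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    # collinearity check: centred points must span a plane
    if np.linalg.matrix_rank(a0, tol=1e-9 * max(1.0, np.abs(a0).max())) < 2:
        raise ValueError("landmarks are collinear; rotation is ill-posed")
    h = a0.T @ b0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cb - r @ ca
    resid = (a @ r.T + t) - b
    fre = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return RigidTransform(rotation=r, translation=t, fre=fre)


def apply_transform(transform: RigidTransform, points: np.ndarray
                    ) -> np.ndarray:
    """Apply p' = R p + t to an (n, 3) point array."""
    pts = np.asarray(points, dtype=float)
    return pts @ transform.rotation.T + transform.translation


def on_position(saved: np.ndarray, measured: np.ndarray,
                radius_mm: float = GUIDANCE_RADIUS_MM) -> np.ndarray:
    """Which optodes lie within the guidance sphere of their saved spot."""
    saved = np.atleast_2d(saved)
    measured = np.atleast_2d(measured)
    return np.linalg.norm(measured - saved, axis=1) <= radius_mm
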