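"""Rigid-body geometry of implant migration.

A follow-up RSA examination yields the pose of the implant relative to the
bone-marker rigid body.  Migration between baseline and follow-up is the
relative rigid transform, conventionally reported as six degrees of freedom
(6 DOF): translations of the implant reference point along x/y/z in mm and
Euler rotations about the same axes in degrees.  This module converts between
poses and 6-DOF summaries, computes the scalar surrogate metrics (total
translation, total rotation, maximum total point motion) and provides the
rotation-offset operator used by the Monte Carlo power study.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .config import AXES, EULER_SEQ

__all__ = [
    "Dof6",
    "RigidTransform",
    "MarkerSet",
    "dof6_from_transforms",
    "dof6_to_transform",
    "total_translation",
    "total_rotation",
    "mtpm",
    "rotate_dof6",
    "random_xz_unit",
    "default_stem_points",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class Dof6:
    """Six-degrees-of-freedom migration: translations (mm), rotations (deg)."""

    tx: float
    ty: float
    tz: float
    rx: float
    ry: float
    rz: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("all six migration components must be finite")
        if np.any(np.abs(vals[3:]) >= 90.0):
            raise ValueError(
                "rotations must be below 90 deg (small-rotation regime)"
            )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.tx, self.ty, self.tz, self.rx, self.ry, self.rz], float
        )

    @classmethod
    def from_array(cls, a: Iterable[float]) -> "Dof6":
        a = np.asarray(list(a), float)
        if a.shape != (6,):
            raise ValueError("expected 6 components")
        return cls(*a)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(AXES, self.as_array()))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R @ x + t (R orthonormal, det +1; t in mm)."""

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, float)
        t = np.asarray(self.t, float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("R must be 3x3 and t a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("R is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("R must be a proper rotation (det +1)")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.R.T + self.t

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.R.T, -self.R.T @ self.t)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(self.R @ other.R, self.R @ other.t + self.t)


class MarkerSet:
    """Labelled 3D marker points (mm), e.g. tantalum beads in bone.

    Parameters
    ----------
    points
        (n, 3) array of coordinates in mm, n >= 3.
    labels
        Optional marker labels; defaults to ``m1..mn``.
    """

    def __init__(self, points: np.ndarray, labels: Iterable[str] | None = None):
        pts = np.atleast_2d(np.asarray(points, float))
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
            raise ValueError("need an (n, 3) array with n >= 3")
        if not np.all(np.isfinite(pts)):
            raise ValueError("marker coordinates must be finite")
        self.points = pts
        if labels is None:
            labels = [f"m{i + 1}" for i in range(len(pts))]
        self.labels = tuple(str(l) for l in labels)
        if len(self.labels) != len(pts):
            raise ValueError("labels and points disagree in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("marker labels must be unique")

    def __len__(self) -> int:
        return len(self.points)

    def is_collinear(self, tol: float = 1e-8) -> bool:
        c = self.points - self.points.mean(axis=0)
        s = np.linalg.svd(c, compute_uv=False)
        return bool(s[1] <= tol * max(s[0], 1.0))

    def reorder(self, labels: Iterable[str]) -> "MarkerSet":
        idx = {l: i for i, l in enumerate(self.labels)}
        order = [idx[l] for l in labels]
        return MarkerSet(self.points[order], labels)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.points, columns=["x", "y", "z"]).assign(
            label=self.labels
        )[["label", "x", "y", "z"]].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MarkerSet":
        df = pd.read_csv(path)
        return cls(df[["x", "y", "z"]].to_numpy(float), df["label"].astype(str))


def dof6_from_transforms(
    baseline: RigidTransform, followup: RigidTransform
) -> Dof6:
    """Decompose the migration between two poses into 6 DOF.

    The relative motion is ``followup o baseline^-1`` (how a point fixed in
    the implant moves between examinations, in the global frame).  Rotations
    are intrinsic x->y->z Euler angles in degrees; translations in mm.
    """
    rel = followup.compose(baseline.inverse())
    ang = Rotation.from_matrix(rel.R).as_euler(EULER_SEQ, degrees=True)
    return Dof6(*rel.t, *ang)


def dof6_to_transform(d: Dof6) -> RigidTransform:
    """Inverse of :func:`dof6_from_transforms` (relative to identity baseline)."""
    R = Rotation.from_euler(
        EULER_SEQ, [d.rx, d.ry, d.rz], degrees=True
    ).as_matrix()
    return RigidTransform(R, np.array([d.tx, d.ty, d.tz]))


def total_translation(d: Dof6) -> float:
    """Euclidean norm of the translation triple (mm)."""
    return float(np.linalg.norm([d.tx, d.ty, d.tz]))


def total_rotation(d: Dof6) -> float:
    """Euclidean norm of the Euler rotation triple (degrees).

    For small rotations (a few degrees per axis) this agrees with the true
    rotation angle of the composed matrix to well within 1%.
    """
    return float(np.linalg.norm([d.rx, d.ry, d.rz]))


def mtpm(motion: RigidTransform, model_points: MarkerSet | np.ndarray) -> float:
    """Maximum total point motion: the largest displacement over model points.

    MTPM = max_p || R p + t - p || over the implant surface-model points.
    Equals ||t|| exactly for a pure translation.
    """
    pts = (
        model_points.points
        if isinstance(model_points, MarkerSet)
        else np.atleast_2d(np.asarray(model_points, float))
    )
    if pts.size == 0:
        raise ValueError("model point set is empty")
    disp = motion.apply(pts) - pts
    return float(np.max(np.linalg.norm(disp, axis=1)))


def _check_xz_axis(axis_u: np.ndarray) -> np.ndarray:
    u = np.asarray(axis_u, float)
    if u.shape != (3,):
        raise ValueError("axis must be a 3-vector")
    if not np.isclose(np.linalg.norm(u), 1.0, atol=1e-9):
        raise ValueError("axis must be a unit vector")
    if not np.isclose(u[1], 0.0, atol=1e-9):
        raise ValueError("axis must lie in the x-z plane (zero y-component)")
    return u


def rotation_about(axis_u: np.ndarray, theta_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix for angle ``theta_deg`` about a unit axis."""
    u = np.asarray(axis_u, float)
    th = np.deg2rad(theta_deg)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1.0 - np.cos(th)) * (K @ K)


def rotate_dof6(d: Dof6, axis_u: np.ndarray, theta_deg: float) -> Dof6:
    """Rotate a 6-DOF migration vector about an x-z-plane axis.

    Applies the same Rodrigues rotation (angle ``theta_deg`` about
    ``axis_u``) to the translation triple and, treating small Euler angles as
    a rotation vector, to the rotation triple.  This block-diagonal action
    models a misaligned RSA coordinate frame; it preserves total translation
    and total rotation.
    """
    u = _check_xz_axis(axis_u)
    R = rotation_about(u, theta_deg)
    v = d.as_array()
    return Dof6.from_array(np.concatenate([R @ v[:3], R @ v[3:]]))


def random_xz_unit(rng: np.random.Generator) -> np.ndarray:
    """Uniform random unit vector in the x-z plane: (cos phi, 0, sin phi)."""
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return np.array([np.cos(phi), 0.0, np.sin(phi)])


def default_stem_points(
    length_mm: float = 160.0, n_per_side: int = 20
) -> np.ndarray:
    """Synthetic point cloud spanning a tapered femoral-stem silhouette.

    A stand-in for a proprietary implant CAD surface model: points along the
    two tapering lateral edges and the shoulder/tip of a stem of the given
    length, wedge-shaped in the frontal plane.  Adequate for MTPM, which only
    needs a representative envelope of the implant surface.
    """
    y = np.linspace(0.0, -length_mm, n_per_side)
    # taper from a 30 mm wide shoulder to an 8 mm tip
    half_w = np.linspace(15.0, 4.0, n_per_side)
    medial = np.column_stack([half_w, y, np.zeros(n_per_side)])
    lateral = np.column_stack([-half_w, y, np.zeros(n_per_side)])
    shoulder = np.array([[0.0, 5.0, 0.0], [0.0, 0.0, 5.0], [0.0, 0.0, -5.0]])
    tip = np.array([[0.0, -length_mm - 2.0, 0.0]])
    return np.vstack([medial, lateral, shoulder, tip])
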