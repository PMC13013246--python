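"""Coordinate spaces, homogeneous transforms and tracked-pose interpolation.

Every spatial quantity in the package is expressed in millimetres and moves
between named coordinate systems (ultrasound voxel grid, ultrasound image
space, probe, optical tracking, CT) through 4x4 homogeneous transforms.
Points are column vectors under left-multiplication; transforms carry space
tags so that chains such as

    ct  <-  tracking  <-  probe  <-  us  <-  us_vox

can only be composed when the tags line up.  Probe poses delivered by the
optical tracking system are time-stamped rigid transforms; poses at
arbitrary times are obtained by spherical linear interpolation (SLERP) of
the rotation and linear interpolation of the translation between the two
bracketing samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

__all__ = [
    "HomogeneousTransform",
    "VolumeGeometry",
    "PointCloud",
    "TrackingStream",
    "compose",
    "invert",
    "voxel_to_physical",
    "physical_to_voxel",
    "interpolate_pose",
    "rigid_from_parts",
    "average_rigid",
]

_LAST_ROW = np.array([0.0, 0.0, 0.0, 1.0])


class SpaceTagError(ValueError):
    """Raised when transforms are chained across mismatched coordinate spaces."""


@dataclass(frozen=True)
class HomogeneousTransform:
    """A 4x4 affine map ``to_space <- from_space`` in millimetres.

    Parameters
    ----------
    matrix
        4x4 real matrix whose last row is exactly ``(0, 0, 0, 1)``.
    from_space, to_space
        Free-form space tags (e.g. ``"us"``, ``"probe"``, ``"tracking"``,
        ``"ct"``).  Composition is only permitted when tags chain.
    """

    matrix: np.ndarray
    from_space: str
    to_space: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"expected 4x4 matrix, got shape {m.shape}")
        if not np.allclose(m[3], _LAST_ROW, atol=1e-12):
            raise ValueError("last row of a homogeneous transform must be (0,0,0,1)")
        object.__setattr__(self, "matrix", m)

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls, space: str) -> "HomogeneousTransform":
        return cls(np.eye(4), from_space=space, to_space=space)

    @classmethod
    def from_rotation_translation(
        cls,
        rotation: np.ndarray,
        translation: Sequence[float],
        from_space: str,
        to_space: str,
    ) -> "HomogeneousTransform":
        m = np.eye(4)
        m[:3, :3] = np.asarray(rotation, dtype=float)
        m[:3, 3] = np.asarray(translation, dtype=float)
        return cls(m, from_space=from_space, to_space=to_space)

    # -- predicates --------------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def is_rigid(self, tol: float = 1e-6) -> bool:
        r = self.rotation
        return (
            np.allclose(r @ r.T, np.eye(3), atol=tol)
            and abs(np.linalg.det(r) - 1.0) < tol
        )

    # -- application -------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an ``(N, 3)`` array of points (mm)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[-1] != 3:
            raise ValueError("points must be (N, 3)")
        return pts @ self.rotation.T + self.translation

    def __matmul__(self, other: "HomogeneousTransform") -> "HomogeneousTransform":
        return compose(self, other)


def rigid_from_parts(
    rotation: Rotation, translation: Sequence[float], from_space: str, to_space: str
) -> HomogeneousTransform:
    """Build a rigid transform from a scipy ``Rotation`` and translation (mm)."""
    return HomogeneousTransform.from_rotation_translation(
        rotation.as_matrix(), translation, from_space, to_space
    )


def compose(a: HomogeneousTransform, b: HomogeneousTransform) -> HomogeneousTransform:
    """Return ``a . b``, the map applying ``b`` first and then ``a``.

    Space tags must chain: ``a.from_space == b.to_space``.
    """
    if a.from_space != b.to_space:
        raise SpaceTagError(
            f"cannot compose {a.to_space}<-{a.from_space} with "
            f"{b.to_space}<-{b.from_space}: tags do not chain"
        )
    return HomogeneousTransform(
        a.matrix @ b.matrix, from_space=b.from_space, to_space=a.to_space
    )


def invert(t: HomogeneousTransform) -> HomogeneousTransform:
    """Inverse transform with swapped space tags."""
    if abs(np.linalg.det(t.matrix[:3, :3])) < 1e-12:
        raise ValueError("transform is singular and cannot be inverted")
    # invert the affine part analytically to keep the last row exact
    r_inv = np.linalg.inv(t.matrix[:3, :3])
    m = np.eye(4)
    m[:3, :3] = r_inv
    m[:3, 3] = -r_inv @ t.matrix[:3, 3]
    return HomogeneousTransform(m, from_space=t.to_space, to_space=t.from_space)


@dataclass(frozen=True)
class VolumeGeometry:
    """Voxel-grid geometry: spacing (mm/voxel), origin (mm), direction cosines.

    Voxel indices are 0-based; the physical position of index ``i`` is
    ``origin + direction @ (spacing * i)`` (LPS-style header semantics of
    MetaImage/NRRD, applied identically to US and CT volumes).
    """

    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray
    size: tuple[int, int, int]

    def __post_init__(self) -> None:
        sp = np.asarray(self.spacing, dtype=float)
        org = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if sp.shape != (3,) or org.shape != (3,):
            raise ValueError("spacing and origin must be length-3")
        if np.any(sp <= 0):
            raise ValueError("spacing must be positive")
        if not np.allclose(d @ d.T, np.eye(3), atol=1e-6):
            raise ValueError("direction cosines must be orthonormal")
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", org)
        object.__setattr__(self, "direction", d)
        object.__setattr__(self, "size", tuple(int(s) for s in self.size))

    @classmethod
    def unit(cls, size: tuple[int, int, int]) -> "VolumeGeometry":
        return cls(np.ones(3), np.zeros(3), np.eye(3), size)

    def to_transform(self, from_space: str = "us_vox", to_space: str = "us") -> HomogeneousTransform:
        """The voxel-to-mm map as a homogeneous transform (A in the chain)."""
        m = np.eye(4)
        m[:3, :3] = self.direction @ np.diag(self.spacing)
        m[:3, 3] = self.origin
        return HomogeneousTransform(m, from_space=from_space, to_space=to_space)


@dataclass
class PointCloud:
    """An ``(N, 3)`` set of coordinates (mm or voxel indices) in a tagged space."""

    points: np.ndarray
    space: str
    label: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if pts.size and not np.all(np.isfinite(pts)):
            raise ValueError("point cloud contains non-finite coordinates")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    def transformed(self, t: HomogeneousTransform) -> "PointCloud":
        if t.from_space != self.space:
            raise SpaceTagError(
                f"transform expects points in {t.from_space!r}, cloud is in {self.space!r}"
            )
        return PointCloud(t.apply(self.points), space=t.to_space, label=self.label)


def voxel_to_physical(geom: VolumeGeometry, voxels: PointCloud) -> PointCloud:
    """Map 0-based voxel indices to physical mm coordinates.

    Indices outside ``[0, size)`` produce a warning but are still mapped:
    downstream cone masking is responsible for discarding them.
    """
    idx = voxels.points
    if idx.size:
        size = np.asarray(geom.size, dtype=float)
        if np.any(idx < 0) or np.any(idx >= size):
            warnings.warn("voxel indices outside volume extent", stacklevel=2)
    mm = geom.origin + (geom.spacing * idx) @ geom.direction.T
    return PointCloud(mm, space="us", label=voxels.label)


def physical_to_voxel(geom: VolumeGeometry, cloud: PointCloud) -> np.ndarray:
    """Continuous 0-based voxel indices for physical mm points."""
    return ((cloud.points - geom.origin) @ geom.direction) / geom.spacing


@dataclass
class TrackingStream:
    """Time-stamped rigid probe poses ``tracking <- probe``.

    Timestamps are float seconds and strictly increasing; poses between
    samples are interpolated with quaternion SLERP (rotation) and linear
    interpolation (translation).
    """

    timestamps: np.ndarray
    poses: list[HomogeneousTransform] = field(repr=False)

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        if ts.ndim != 1 or len(ts) != len(self.poses):
            raise ValueError("timestamps and poses must have equal length")
        if len(ts) and np.any(np.diff(ts) <= 0):
            raise ValueError("tracking timestamps must be strictly increasing")
        for p in self.poses:
            if not p.is_rigid():
                raise ValueError("tracking poses must be rigid")
        self.timestamps = ts

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def t_start(self) -> float:
        return float(self.timestamps[0])

    @property
    def t_end(self) -> float:
        return float(self.timestamps[-1])


def interpolate_pose(stream: TrackingStream, t: float) -> HomogeneousTransform:
    """Probe pose at time ``t`` by SLERP / linear interpolation.

    ``t`` must lie within the stream's time range; the tracked poses give no
    basis for extrapolation, so out-of-range queries raise.
    """
    ts = stream.timestamps
    if len(ts) == 0:
        raise ValueError("empty tracking stream")
    if t < ts[0] or t > ts[-1]:
        raise ValueError(
            f"time {t:.6f} s outside tracking range [{ts[0]:.6f}, {ts[-1]:.6f}] s"
        )
    j = int(np.searchsorted(ts, t))
    if j < len(ts) and ts[j] == t:
        return stream.poses[j]
    lo, hi = j - 1, j
    p0, p1 = stream.poses[lo], stream.poses[hi]
    alpha = (t - ts[lo]) / (ts[hi] - ts[lo])
    # scipy's Slerp already resolves the quaternion double cover (shortest path)
    rots = Rotation.from_matrix(np.stack([p0.rotation, p1.rotation]))
    rot = Slerp([0.0, 1.0], rots)(alpha)
    trans = (1.0 - alpha) * p0.translation + alpha * p1.translation
    return rigid_from_parts(rot, trans, from_space=p0.from_space, to_space=p0.to_space)


def average_rigid(transforms: Sequence[HomogeneousTransform]) -> HomogeneousTransform:
    """Average of rigid transforms: quaternion mean rotation, mean translation.

    Used to pool the calibration matrices retained by the consistency filter
    into a single probe calibration.
    """
    if not transforms:
        raise ValueError("no transforms to average")
    f, to = transforms[0].from_space, transforms[0].to_space
    quats = []
    ref = None
    for t in transforms:
        if (t.from_space, t.to_space) != (f, to):
            raise SpaceTagError("cannot average transforms across different spaces")
        q = Rotation.from_matrix(t.rotation).as_quat()
        if ref is None:
            ref = q
        elif np.dot(q, ref) < 0:
            q = -q
        quats.append(q)
    q_mean = np.mean(quats, axis=0)
    q_mean /= np.linalg.norm(q_mean)
    trans = np.mean([t.translation for t in transforms], axis=0)
    return rigid_from_parts(Rotation.from_quat(q_mean), trans, from_space=f, to_space=to)
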