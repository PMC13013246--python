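"""Spatial probe calibration from US recordings of a calibration phantom.

The fixed transform ``T_pr_US`` (US image space -> probe-marker space) is
estimated from frames of a rigid calibration phantom of known geometry:

1. edge voxels are segmented slice-wise with the Canny detector,
2. edges are restricted to the interior of the US cone,
3. DBSCAN clustering isolates the phantom's inner structures from noise,
4. a principal-axes pre-alignment and point-to-point ICP register the
   clustered cloud onto the phantom's CT-space structure model, yielding
   ``T_CT_US``,
5. the result is composed per frame as

       T_pr_US = T_pr_tr . T_tr_CT . T_CT_US

   with ``T_pr_tr`` the inverted tracked probe pose and ``T_tr_CT`` the
   marker-based phantom-CT-to-tracking transform.

Because contact force and probe positioning degrade single frames, the
calibration is repeated over many frames and filtered for consistency:
the attempts with the lowest residual unidirectional Hausdorff distance
of the aligned structures are kept and pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage.feature import canny
from sklearn.cluster import DBSCAN

from .geometry import (
    HomogeneousTransform,
    PointCloud,
    TrackingStream,
    VolumeGeometry,
    average_rigid,
    compose,
    interpolate_pose,
    invert,
    voxel_to_physical,
)

__all__ = [
    "ConeParams",
    "CalibrationParams",
    "PhantomModel",
    "CalibrationResult",
    "ConsistencyReport",
    "segment_edges",
    "mask_cone",
    "cluster_structures",
    "prealign_phantom",
    "icp_refine",
    "marker_registration",
    "fit_rigid",
    "calibrate_frame",
    "calibrate_recording",
    "select_consistent",
    "consistency_stats",
    "combined_sigma",
]


# ---------------------------------------------------------------------------
# parameters and domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConeParams:
    """US scan cone in image-space mm: apex, axis, half-angle and depth range."""

    apex: tuple[float, float, float]
    axis: tuple[float, float, float]
    half_angle_deg: float
    r_min: float
    r_max: float

    def __post_init__(self) -> None:
        if not 0.0 < self.half_angle_deg < 90.0:
            raise ValueError("cone half-angle must be in (0, 90) degrees")
        if not 0.0 <= self.r_min < self.r_max:
            raise ValueError("need 0 <= r_min < r_max")


@dataclass(frozen=True)
class CalibrationParams:
    """Tunables of the per-frame calibration chain (all lengths in mm)."""

    canny_sigma: float = 2.0
    canny_low_frac: float = 0.1
    canny_high_frac: float = 0.2
    cone: ConeParams | None = None
    cone_margin: float = 2.0
    dbscan_eps: float = 3.0
    dbscan_min_pts: int = 10
    cluster_size_floor: int = 50
    max_points: int = 4000
    icp_max_iter: int = 100
    icp_tol: float = 1e-6


@dataclass
class PhantomModel:
    """Geometry of the calibration phantom in its CT space.

    ``structure_cloud`` samples the surfaces of the phantom's inner
    structures; ``markers_ct`` (and, when measured, ``markers_tr``) are the
    optical-marker positions used for ``T_tr_CT``.  For a static phantom
    ``t_tr_ct`` may be supplied once per recording instead.
    """

    structure_cloud: PointCloud
    markers_ct: dict[str, np.ndarray]
    markers_tr: dict[str, np.ndarray] = field(default_factory=dict)
    t_tr_ct: HomogeneousTransform | None = None

    def __post_init__(self) -> None:
        pts = self.structure_cloud.points
        if len(pts) < 4 or np.linalg.matrix_rank(pts - pts.mean(0), tol=1e-6) < 3:
            raise ValueError("phantom structure cloud must have rank-3 spread")
        if len(self.markers_ct) < 3:
            raise ValueError("need at least 3 phantom markers")

    def tracking_transform(self) -> HomogeneousTransform:
        """``T_tr_CT`` from the stored transform or the paired markers."""
        if self.t_tr_ct is not None:
            return self.t_tr_ct
        names = sorted(set(self.markers_ct) & set(self.markers_tr))
        if len(names) < 3:
            raise ValueError("phantom model has neither t_tr_ct nor >=3 paired markers")
        a = np.stack([np.asarray(self.markers_ct[n], float) for n in names])
        b = np.stack([np.asarray(self.markers_tr[n], float) for n in names])
        t, _ = marker_registration(a, b)
        return t


@dataclass
class CalibrationResult:
    """One frame's probe calibration with its composition factors."""

    t_pr_us: HomogeneousTransform
    t_pr_tr: HomogeneousTransform
    t_tr_ct: HomogeneousTransform
    t_ct_us: HomogeneousTransform
    residual_hd: float
    frame_index: int
    failed_stage: str | None = None

    @property
    def failed(self) -> bool:
        return self.failed_stage is not None


@dataclass
class ConsistencyReport:
    """Per-test-point spread of repeated calibrations (mm)."""

    sigma: np.ndarray        # (n_points, 3) per-axis sample std
    combined: np.ndarray     # (n_points,) root-sum-of-squares

    def as_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "point": np.arange(1, len(self.combined) + 1),
                "sigma_x": self.sigma[:, 0],
                "sigma_y": self.sigma[:, 1],
                "sigma_z": self.sigma[:, 2],
                "combined": self.combined,
            }
        )


def combined_sigma(sigma: np.ndarray) -> np.ndarray:
    """Root-sum-of-squares of per-axis standard deviations, per point."""
    s = np.atleast_2d(np.asarray(sigma, dtype=float))
    return np.sqrt(np.sum(s**2, axis=-1))


# ---------------------------------------------------------------------------
# segmentation and clustering
# ---------------------------------------------------------------------------

def segment_edges(
    volume: np.ndarray,
    sigma: float = 2.0,
    low_frac: float = 0.1,
    high_frac: float = 0.2,
) -> PointCloud:
    """Edge voxels of a 3D US volume by slice-wise 2D Canny detection.

    The detector runs on each axial (k) slice with hysteresis thresholds
    expressed as fractions of that slice's intensity range.  Returns the
    edge voxels as 0-based indices; a uniform volume yields an empty cloud.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("segment_edges expects a 3D scalar volume")
    idx = []
    for k in range(vol.shape[2]):
        sl = vol[:, :, k]
        rng = float(sl.max() - sl.min())
        if rng <= 0:
            continue
        edges = canny(
            sl, sigma=sigma, low_threshold=low_frac * rng, high_threshold=high_frac * rng
        )
        ij = np.argwhere(edges)
        if len(ij):
            idx.append(np.column_stack([ij, np.full(len(ij), k)]))
    pts = np.concatenate(idx, axis=0) if idx else np.empty((0, 3))
    return PointCloud(pts.astype(float), space="us_vox", label="edges")


def mask_cone(cloud: PointCloud, cone: ConeParams, margin: float = 2.0) -> PointCloud:
    """Keep points inside the US cone, shrunk by a boundary margin (mm).

    The margin removes the bright cone-boundary artefacts that the edge
    detector produces at the transition to the zeroed outside region.
    """
    apex = np.asarray(cone.apex, dtype=float)
    axis = np.asarray(cone.axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    v = cloud.points - apex
    r = np.linalg.norm(v, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(r > 0, v @ axis / np.where(r > 0, r, 1.0), 1.0)
    ang = np.arccos(np.clip(cosang, -1.0, 1.0))
    half = np.deg2rad(cone.half_angle_deg)
    keep = (
        (r >= cone.r_min + margin)
        & (r <= cone.r_max - margin)
        & (ang <= half)
        & (r * np.sin(np.maximum(half - ang, 0.0)) >= margin)
    )
    return PointCloud(cloud.points[keep], space=cloud.space, label=cloud.label)


def cluster_structures(
    cloud: PointCloud,
    eps: float = 3.0,
    min_pts: int = 10,
    size_floor: int = 50,
) -> list[PointCloud]:
    """DBSCAN clusters of an edge cloud (mm); small clusters become noise."""
    if len(cloud) < min_pts:
        warnings.warn("too few points to cluster; returning no clusters", stacklevel=2)
        return []
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(cloud.points)
    clusters = []
    for lab in sorted(set(labels) - {-1}):
        pts = cloud.points[labels == lab]
        if len(pts) >= size_floor:
            clusters.append(
                PointCloud(pts, space=cloud.space, label=f"cluster_{lab}")
            )
    if not clusters:
        warnings.warn("all points classified as noise", stacklevel=2)
    return clusters


# ---------------------------------------------------------------------------
# rigid fitting, pre-alignment, ICP
# ---------------------------------------------------------------------------

def fit_rigid(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid fit (Kabsch) mapping paired ``source`` -> ``target``.

    Always returns a proper rotation (det +1); reflections are rejected by
    the sign correction of the smallest singular direction.
    """
    a = np.asarray(source, dtype=float)
    b = np.asarray(target, dtype=float)
    ca, cb = a.mean(0), b.mean(0)
    h = (a - ca).T @ (b - cb)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cb - r @ ca
    return r, t


def _directed_hd(source: np.ndarray, target: np.ndarray) -> float:
    tree = cKDTree(target)
    d, _ = tree.query(source, workers=-1)
    return float(np.max(d))


def _principal_axes(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(0)
    cov = c.T @ c / len(points)
    w, v = np.linalg.eigh(cov)
    v = v[:, ::-1]  # descending eigenvalue order
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return v


def prealign_phantom(
    clusters: list[PointCloud], model: PhantomModel
) -> HomogeneousTransform:
    """Initial rigid guess CT <- US from centroids and principal axes.

    All four proper sign combinations of the principal axes are tried and
    the one with the lowest unidirectional Hausdorff distance of the merged
    cluster cloud against the model structures is kept.
    """
    if not clusters:
        raise ValueError("pre-alignment needs at least one cluster")
    src = np.concatenate([c.points for c in clusters])
    if np.linalg.matrix_rank(src - src.mean(0), tol=1e-6) < 2:
        raise ValueError("cluster cloud is degenerate (rank < 2)")
    tgt = model.structure_cloud.points
    vs, vt = _principal_axes(src), _principal_axes(tgt)
    cs, ct = src.mean(0), tgt.mean(0)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for signs in ([1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]):
        r = vt @ np.diag(signs).astype(float) @ vs.T
        t = ct - r @ cs
        hd = _directed_hd(src @ r.T + t, tgt)
        if best is None or hd < best[0]:
            best = (hd, r, t)
    assert best is not None
    space = clusters[0].space
    return HomogeneousTransform.from_rotation_translation(
        best[1], best[2], from_space=space, to_space=model.structure_cloud.space
    )


def icp_refine(
    source: PointCloud,
    target: PointCloud,
    init: HomogeneousTransform,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[HomogeneousTransform, float, bool]:
    """Point-to-point ICP refinement of ``init``.

    Iterates nearest-neighbour correspondences against ``target`` and
    closed-form rigid updates until the mean residual changes by less than
    ``tol`` mm.  Returns ``(transform, residual_hd, converged)`` where
    ``residual_hd`` is the unidirectional Hausdorff distance of the aligned
    source toward the target — the quality score used by the consistency
    filter.
    """
    if len(source) == 0 or len(target) == 0:
        raise ValueError("ICP requires non-empty source and target clouds")
    src = source.points
    tree = cKDTree(target.points)
    r, t = init.rotation.copy(), init.translation.copy()
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        moved = src @ r.T + t
        d, j = tree.query(moved, workers=-1)
        r, t = fit_rigid(src, target.points[j])
        mean_res = float(np.mean(d))
        if abs(prev - mean_res) < tol:
            converged = True
            break
        prev = mean_res
    aligned = src @ r.T + t
    residual_hd = _directed_hd(aligned, target.points)
    if not converged:
        warnings.warn("ICP did not converge; returning best iterate", stacklevel=2)
    out = HomogeneousTransform.from_rotation_translation(
        r, t, from_space=init.from_space, to_space=init.to_space
    )
    return out, residual_hd, converged


def marker_registration(
    markers_ct: np.ndarray, markers_tr: np.ndarray
) -> tuple[HomogeneousTransform, float]:
    """Rigid ``T_tr_CT`` from >=3 paired optical-marker positions.

    Returns the transform and the RMS fiducial registration error (mm).
    """
    a = np.asarray(markers_ct, dtype=float)
    b = np.asarray(markers_tr, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need >=3 paired markers of equal count")
    if np.linalg.matrix_rank(a - a.mean(0), tol=1e-9) < 2:
        raise ValueError("markers are collinear; the rotation is not determined")
    r, t = fit_rigid(a, b)
    rms = float(np.sqrt(np.mean(np.sum((a @ r.T + t - b) ** 2, axis=1))))
    return (
        HomogeneousTransform.from_rotation_translation(
            r, t, from_space="phantom_ct", to_space="tracking"
        ),
        rms,
    )


# ---------------------------------------------------------------------------
# per-frame calibration and consistency assessment
# ---------------------------------------------------------------------------

def _subsample(points: np.ndarray, max_points: int) -> np.ndarray:
    if len(points) <= max_points:
        return points
    stride = int(np.ceil(len(points) / max_points))
    return points[::stride]


def calibrate_frame(
    volume: np.ndarray,
    geometry: VolumeGeometry,
    pose_tr_pr: HomogeneousTransform,
    model: PhantomModel,
    params: CalibrationParams,
    frame_index: int = 0,
) -> CalibrationResult:
    """Single-frame probe calibration via the full segmentation chain.

    Any stage failure (no edges, no clusters, degenerate cloud) marks the
    result as failed with the stage name and an infinite residual; such
    frames are dropped by the consistency filter rather than raising.
    """
    identity = HomogeneousTransform.identity("us")

    def _failed(stage: str) -> CalibrationResult:
        return CalibrationResult(
            t_pr_us=identity,
            t_pr_tr=identity,
            t_tr_ct=identity,
            t_ct_us=identity,
            residual_hd=np.inf,
            frame_index=frame_index,
            failed_stage=stage,
        )

    edges_vox = segment_edges(
        volume, params.canny_sigma, params.canny_low_frac, params.canny_high_frac
    )
    if len(edges_vox) == 0:
        return _failed("segment_edges")
    cloud_mm = voxel_to_physical(geometry, edges_vox)
    if params.cone is not None:
        cloud_mm = mask_cone(cloud_mm, params.cone, params.cone_margin)
        if len(cloud_mm) == 0:
            return _failed("mask_cone")
    cloud_mm = PointCloud(
        _subsample(cloud_mm.points, params.max_points), space="us", label="edges"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clusters = cluster_structures(
            cloud_mm, params.dbscan_eps, params.dbscan_min_pts, params.cluster_size_floor
        )
    if not clusters:
        return _failed("cluster_structures")
    try:
        init = prealign_phantom(clusters, model)
    except ValueError:
        return _failed("prealign_phantom")
    merged = PointCloud(
        np.concatenate([c.points for c in clusters]), space="us", label="structures"
    )
    t_ct_us, residual_hd, _ = icp_refine(
        merged, model.structure_cloud, init, params.icp_max_iter, params.icp_tol
    )
    t_tr_ct = model.tracking_transform()
    t_pr_tr = invert(pose_tr_pr)
    t_pr_us = compose(compose(t_pr_tr, t_tr_ct), t_ct_us)
    return CalibrationResult(
        t_pr_us=t_pr_us,
        t_pr_tr=t_pr_tr,
        t_tr_ct=t_tr_ct,
        t_ct_us=t_ct_us,
        residual_hd=residual_hd,
        frame_index=frame_index,
    )


def select_consistent(
    results: list[CalibrationResult], k: int = 30
) -> list[CalibrationResult]:
    """The ``k`` calibrations with the lowest residual HD (ties: lower frame)."""
    if k > len(results):
        raise ValueError(f"cannot keep k={k} of {len(results)} results")
    return sorted(results, key=lambda r: (r.residual_hd, r.frame_index))[:k]


def consistency_stats(
    results: list[CalibrationResult], test_points: PointCloud
) -> ConsistencyReport:
    """Spread of repeated calibrations over a set of US-space test points.

    Each test point is mapped into probe space by every calibration; the
    per-axis sample standard deviations and their root-sum-of-squares
    (the "combined" value) quantify calibration consistency.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 calibration results")
    mapped = np.stack([r.t_pr_us.apply(test_points.points) for r in results])
    sigma = np.std(mapped, axis=0, ddof=1)
    return ConsistencyReport(sigma=sigma, combined=combined_sigma(sigma))


def calibrate_recording(
    frames: list[np.ndarray],
    frame_times: np.ndarray,
    geometry: VolumeGeometry,
    tracking: TrackingStream,
    model: PhantomModel,
    params: CalibrationParams,
    n_attempts: int | None = None,
    keep: int = 30,
) -> tuple[HomogeneousTransform, list[CalibrationResult], list[CalibrationResult]]:
    """Calibrate over many frames and pool the consistent subset.

    Runs :func:`calibrate_frame` on up to ``n_attempts`` frames, keeps the
    ``keep`` attempts with the lowest residual HD and returns the averaged
    probe calibration together with all and the kept per-frame results.
    """
    n = len(frames) if n_attempts is None else min(n_attempts, len(frames))
    results = []
    for i in range(n):
        pose = interpolate_pose(tracking, float(frame_times[i]))
        results.append(
            calibrate_frame(frames[i], geometry, pose, model, params, frame_index=i)
        )
    usable = [r for r in results if not r.failed]
    if len(usable) < keep:
        keep = len(usable)
    if keep == 0:
        raise RuntimeError("every calibration frame failed")
    kept = select_consistent(usable, keep)
    pooled = average_rigid([r.t_pr_us for r in kept])
    return pooled, results, kept
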