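"""US-to-CT myocardium registration for the ECG-matched baseline frame.

The left-ventricular myocardium segmented in the matched US frame is
registered onto the CT segmentation in three steps:

1. a rigid pre-alignment from the three anatomical landmarks (apex,
   mitral-valve centre, aortic-valve centre),
2. independent normalization of both clouds to zero centroid and unit RMS
   radius, and
3. an affine coherent-point-drift (CPD) fit on the normalized clouds.

CPD treats the moving (US) cloud as the centroids of a Gaussian mixture
with an added uniform outlier component of weight ``w`` and maximizes the
likelihood of the fixed (CT) cloud under an affine map ``y -> B y + t``
by expectation-maximization.  The outlier term absorbs the partial
overlap caused by the US cone cropping parts of the myocardium.

The composed result maps mm points of the baseline US frame into CT
space and, stored with the inverted probe pose at the baseline time,
provides the deformation factor of the voxel-to-CT transfer chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import HomogeneousTransform, PointCloud, TrackingStream, interpolate_pose, invert
from .stream_io import LandmarkSet
from .calibration import fit_rigid

__all__ = [
    "NormParams",
    "RegistrationResult",
    "landmark_prealign",
    "normalize",
    "cpd_affine",
    "build_registration",
]


@dataclass(frozen=True)
class NormParams:
    """Centroid (mm) and RMS-radius scale (mm) of a normalized cloud."""

    centroid: np.ndarray
    scale: float

    def forward(self, points: np.ndarray) -> np.ndarray:
        return (points - self.centroid) / self.scale

    def inverse(self, points: np.ndarray) -> np.ndarray:
        return points * self.scale + self.centroid


@dataclass
class RegistrationResult:
    """Affine US->CT registration with all factors kept for reproduction.

    ``transform_points`` applies, in order: the rigid landmark
    pre-alignment, source-side normalization, the CPD affine, and
    target-side denormalization.  ``t_ust_tr`` is the inverted tracked
    probe pose at the baseline time (probe <- tracking); combined with the
    inverted probe calibration it carries tracked points back into the
    baseline frame's image space, completing the deformation factor of the
    transfer chain.
    """

    prealign: HomogeneousTransform
    affine_b: np.ndarray
    affine_t: np.ndarray
    norm_source: NormParams
    norm_target: NormParams
    sigma2: float
    baseline_time: float
    t_ust_tr: HomogeneousTransform | None
    landmark_residuals: np.ndarray

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        """Map mm points of the baseline US frame into CT mm."""
        y = self.prealign.apply(points)
        yn = self.norm_source.forward(y)
        zn = yn @ self.affine_b.T + self.affine_t
        return self.norm_target.inverse(zn)

    def transform_cloud(self, cloud: PointCloud) -> PointCloud:
        return PointCloud(self.transform_points(cloud.points), space="ct", label=cloud.label)


def landmark_prealign(
    lm_us: LandmarkSet, lm_ct: LandmarkSet
) -> tuple[HomogeneousTransform, np.ndarray]:
    """Rigid fit of the three US landmarks onto their CT counterparts.

    Returns the transform and the per-landmark residuals (mm).  A
    near-collinear landmark triplet (smallest triangle height < 1 mm)
    leaves the rotation about the landmark axis undetermined and raises.
    """
    a = lm_us.as_array()
    b = lm_ct.as_array()
    # smallest triangle height = 2*area / longest side
    e = np.linalg.norm(np.roll(a, -1, axis=0) - a, axis=1)
    area = 0.5 * np.linalg.norm(np.cross(a[1] - a[0], a[2] - a[0]))
    if 2.0 * area / np.max(e) < 1.0:
        raise ValueError("landmark triplet is near-collinear; pre-alignment is ill-posed")
    r, t = fit_rigid(a, b)
    residuals = np.linalg.norm(a @ r.T + t - b, axis=1)
    transform = HomogeneousTransform.from_rotation_translation(
        r, t, from_space=lm_us.space, to_space=lm_ct.space
    )
    return transform, residuals


def normalize(cloud: PointCloud) -> tuple[PointCloud, NormParams]:
    """Shift to zero centroid and scale to unit RMS radius."""
    pts = cloud.points
    if len(pts) < 2:
        raise ValueError("normalization needs at least 2 points")
    centroid = pts.mean(0)
    scale = float(np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1))))
    if scale <= 0:
        raise ValueError("cannot normalize a degenerate (single-location) cloud")
    params = NormParams(centroid=centroid, scale=scale)
    return PointCloud(params.forward(pts), space=cloud.space, label=cloud.label), params


def cpd_affine(
    source: np.ndarray,
    target: np.ndarray,
    w: float = 0.1,
    max_iter: int = 150,
    tol: float = 1e-8,
    history: list | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Affine coherent point drift on (normalized) clouds.

    Fits ``B, t`` such that ``source @ B.T + t`` explains ``target`` as a
    Gaussian mixture with uniform-outlier weight ``w``; EM stops when the
    objective (negative log-likelihood) changes by less than ``tol`` or the
    mixture variance collapses.  Returns ``(B, t, sigma2)``; when a list is
    passed as ``history`` the per-iteration objective values are appended
    to it.
    """
    y = np.asarray(source, dtype=float)
    x = np.asarray(target, dtype=float)
    if len(y) < 4 or len(x) < 4:
        raise ValueError("CPD needs at least 4 points per cloud")
    n, m, d = len(x), len(y), 3
    b = np.eye(d)
    t = np.zeros(d)
    ty = y @ b.T + t
    sigma2 = float(np.sum((x[:, None, :] - ty[None, :, :]) ** 2) / (d * m * n))
    prev_obj = np.inf
    for _ in range(max_iter):
        # E-step: posterior P[m_, n_] of point correspondences
        diff2 = np.sum((x[None, :, :] - ty[:, None, :]) ** 2, axis=2)  # (m, n)
        g = np.exp(-diff2 / (2.0 * sigma2))
        c = (2.0 * np.pi * sigma2) ** (d / 2.0) * (w / (1.0 - w)) * (m / n)
        denom = g.sum(axis=0) + c
        p = g / denom[None, :]
        # objective: negative log-likelihood of the mixture
        obj = -float(np.sum(np.log(denom))) + n * d / 2.0 * np.log(sigma2)
        if history is not None:
            history.append(obj)
        np_ = float(p.sum())
        if np_ < 1e-12:
            break
        p1 = p.sum(axis=1)          # (m,)
        pt1 = p.sum(axis=0)         # (n,)
        mu_x = pt1 @ x / np_
        mu_y = p1 @ y / np_
        xh = x - mu_x
        yh = y - mu_y
        a_mat = (p @ xh).T @ yh     # sum_{m,n} p_mn x_n y_m^T  -> (d, d)
        yy = (yh * p1[:, None]).T @ yh
        try:
            b = a_mat @ np.linalg.inv(yy)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular update matrix in affine CPD") from exc
        t = mu_x - b @ mu_y
        ty = y @ b.T + t
        tr_xpx = float(np.sum(pt1 * np.sum(xh**2, axis=1)))
        tr_ab = float(np.trace(a_mat @ b.T))
        sigma2 = (tr_xpx - tr_ab) / (np_ * d)
        if sigma2 < 1e-12:
            sigma2 = 1e-12
            break
        if abs(prev_obj - obj) < tol:
            break
        prev_obj = obj
    return b, t, float(sigma2)


def build_registration(
    seg_us_t: PointCloud,
    seg_ct: PointCloud,
    lm_us: LandmarkSet,
    lm_ct: LandmarkSet,
    tracking: TrackingStream | None = None,
    baseline_time: float = 0.0,
    w: float = 0.1,
    max_iter: int = 150,
    tol: float = 1e-8,
    max_points: int = 1500,
) -> RegistrationResult:
    """Full registration of the baseline-frame myocardium onto the CT one.

    ``seg_us_t`` is in the baseline frame's image space (mm); ``seg_ct``
    in CT mm.  Normalization parameters come from the full clouds; the
    quadratic-cost CPD stage runs on an even subsample of at most
    ``max_points`` per side.  When a tracking stream is given, the
    inverted probe pose at ``baseline_time`` is stored so the result can
    serve as the deformation factor of the transfer chain.
    """
    prealign, residuals = landmark_prealign(lm_us, lm_ct)
    moved = PointCloud(prealign.apply(seg_us_t.points), space="ct", label=seg_us_t.label)
    src_n, norm_src = normalize(moved)
    tgt_n, norm_tgt = normalize(seg_ct)

    def _thin(pts: np.ndarray) -> np.ndarray:
        if len(pts) <= max_points:
            return pts
        stride = int(np.ceil(len(pts) / max_points))
        return pts[::stride]

    b, t, sigma2 = cpd_affine(
        _thin(src_n.points), _thin(tgt_n.points), w=w, max_iter=max_iter, tol=tol
    )
    if abs(np.linalg.det(b)) < 1e-9:
        raise ValueError("affine CPD produced a singular matrix")
    t_ust_tr = None
    if tracking is not None:
        t_ust_tr = invert(interpolate_pose(tracking, baseline_time))
    return RegistrationResult(
        prealign=prealign,
        affine_b=b,
        affine_t=t,
        norm_source=norm_src,
        norm_target=norm_tgt,
        sigma2=sigma2,
        baseline_time=baseline_time,
        t_ust_tr=t_ust_tr,
        landmark_residuals=residuals,
    )
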