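"""Deterministic synthetic recordings with known ground-truth transforms.

The generator emulates the study conditions of a static torso phantom
imaged by a moving, optically tracked 3D US probe:

* a rigid calibration phantom — an asymmetric arrangement of spheres of
  distinct radii with four non-coplanar optical markers — with a CT label
  volume at 0.5 mm spacing,
* a static left-ventricular myocardium shell (truncated ellipsoid with a
  mitral and an aortic basal opening) with apex/valve landmarks and a CT
  label volume,
* a smooth probe trajectory around an apical viewpoint sampled as a
  tracking stream (60 Hz) and US frame clock (20 Hz), with optional
  Gaussian pose noise on the *measured* tracking only,
* a periodic ECG (600 Hz) with one sharp R-peak per cycle, and
* rendered US volumes: geometric voxelization of the structures inside
  the scan cone, bright against a darker background, with optional
  multiplicative speckle — sufficient because every downstream stage
  consumes edges or segmentations, not raw echo physics.

Every output is a pure function of ``(config, seed)``; the ground-truth
probe calibration and phantom poses are kept so that recovery tests can
compare against them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .calibration import ConeParams, PhantomModel
from .geometry import (
    HomogeneousTransform,
    PointCloud,
    TrackingStream,
    VolumeGeometry,
    compose,
    invert,
    rigid_from_parts,
)
from .stream_io import (
    EcgTrace,
    LandmarkSet,
    RecordingBundle,
    UsFrameSequence,
    write_landmarks,
    write_label_volume,
    write_recording,
)

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "make_calibration_phantom",
    "make_lv_phantom",
    "simulate_trajectory",
    "render_us_volume",
    "synth_ecg",
    "make_world",
    "write_world",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WorldConfig:
    """Study conditions of the synthetic recording (lengths mm, times s)."""

    # US grid and scan cone (image space)
    us_size: tuple[int, int, int] = (80, 80, 80)
    us_spacing: float = 1.0
    cone_apex: tuple[float, float, float] = (40.0, 40.0, -5.0)
    cone_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    cone_half_angle_deg: float = 40.0
    cone_r_min: float = 8.0
    cone_r_max: float = 92.0

    # timing
    heart_rate_hz: float = 1.0
    duration_s: float = 10.0          # ten cardiac cycles at 1 Hz
    frame_rate_hz: float = 20.0
    tracking_rate_hz: float = 60.0
    ecg_fs: float = 600.0
    ecg_phase_s: float = 0.5
    rr_jitter_s: float = 0.0

    # probe motion (per-component sinusoid amplitudes)
    trans_amplitude_mm: float = 4.0
    rot_amplitude_deg: float = 4.0
    extreme: bool = False             # large motions per the study's stress mode

    # noise
    sigma_tracking_mm: float = 0.0
    sigma_tracking_deg: float = 0.0
    sigma_us: float = 0.0

    # calibration phantom: sphere centres/radii (phantom-CT mm), markers
    sphere_centres: tuple = ((-20.0, -10.0, -5.0), (15.0, -15.0, 5.0),
                             (5.0, 20.0, 12.0), (-8.0, 6.0, 22.0))
    sphere_radii: tuple = (5.0, 7.0, 9.0, 4.0)
    marker_positions: tuple = ((-40.0, -40.0, -30.0), (45.0, -35.0, -25.0),
                               (40.0, 40.0, 35.0), (-35.0, 45.0, 20.0))
    symmetric_phantom: bool = False   # reproduces the pre-alignment failure mode
    model_cloud_points: int = 4000

    # LV shell (patient-CT mm): outer semi-axes, wall, basal truncation
    lv_outer: tuple[float, float, float] = (22.0, 22.0, 35.0)
    lv_wall: float = 7.0
    lv_trunc_z: float = 29.0
    mitral_dir: tuple[float, float, float] = (0.30, 0.0, 1.0)
    aortic_dir: tuple[float, float, float] = (-0.45, 0.25, 1.0)
    opening_half_angle_deg: float = 14.0
    shell_points: int = 5000

    # CT rendering
    ct_spacing: float = 0.5

    # calibration recording
    n_cal_frames: int = 100
    cal_duration_s: float = 5.0

    @property
    def cone(self) -> ConeParams:
        return ConeParams(
            apex=self.cone_apex,
            axis=self.cone_axis,
            half_angle_deg=self.cone_half_angle_deg,
            r_min=self.cone_r_min,
            r_max=self.cone_r_max,
        )

    @property
    def motion_amplitudes(self) -> tuple[float, float]:
        if self.extreme:
            return 15.0, 20.0
        return self.trans_amplitude_mm, self.rot_amplitude_deg


# ---------------------------------------------------------------------------
# small geometric helpers
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform unit-sphere directions."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _random_rigid(
    rng: np.random.Generator,
    max_angle_deg: float,
    max_trans: float,
    from_space: str,
    to_space: str,
) -> HomogeneousTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(-max_angle_deg, max_angle_deg))
    trans = rng.uniform(-max_trans, max_trans, size=3)
    return rigid_from_parts(Rotation.from_rotvec(angle * axis), trans, from_space, to_space)


def _voxel_grid_mm(geom: VolumeGeometry) -> np.ndarray:
    """Physical centres of all voxels, shape ``(*size, 3)``."""
    idx = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in geom.size], indexing="ij"),
        axis=-1,
    )
    return geom.origin + (geom.spacing * idx) @ geom.direction.T


def _cone_mask_mm(points: np.ndarray, cone: ConeParams) -> np.ndarray:
    apex = np.asarray(cone.apex)
    axis = np.asarray(cone.axis, dtype=float)
    axis /= np.linalg.norm(axis)
    v = points - apex
    r = np.linalg.norm(v, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(r > 0, v @ axis / np.where(r > 0, r, 1.0), 1.0)
    ang = np.arccos(np.clip(cosang, -1.0, 1.0))
    return (r >= cone.r_min) & (r <= cone.r_max) & (ang <= np.deg2rad(cone.half_angle_deg))


# ---------------------------------------------------------------------------
# calibration phantom
# ---------------------------------------------------------------------------

def make_calibration_phantom(
    config: WorldConfig, seed: int = 0
) -> tuple[PhantomModel, np.ndarray, VolumeGeometry]:
    """Sphere-cluster phantom: model, CT label volume and its geometry.

    The default arrangement of spheres with distinct radii and pairwise
    distances breaks every rotational symmetry so that the principal-axes
    pre-alignment is well-posed; ``symmetric_phantom`` replaces it with a
    symmetric square of equal spheres to reproduce the failure mode of a
    flipped pre-alignment.
    """
    if config.symmetric_phantom:
        import warnings

        warnings.warn(
            "symmetric phantom requested: pre-alignment is ambiguous", stacklevel=2
        )
        centres = np.array(
            [(-20.0, -20.0, 0.0), (20.0, -20.0, 0.0), (20.0, 20.0, 0.0), (-20.0, 20.0, 0.0)]
        )
        radii = np.full(4, 6.0)
    else:
        centres = np.asarray(config.sphere_centres, dtype=float)
        radii = np.asarray(config.sphere_radii, dtype=float)

    # model cloud: surface samples proportional to area
    weights = radii**2 / np.sum(radii**2)
    clouds = []
    for c, r, w in zip(centres, radii, weights):
        n = max(50, int(round(config.model_cloud_points * w)))
        clouds.append(c + r * _fibonacci_sphere(n))
    structure = PointCloud(np.concatenate(clouds), space="phantom_ct", label="structures")

    markers = {
        f"m{i}": np.asarray(p, dtype=float) for i, p in enumerate(config.marker_positions)
    }
    model = PhantomModel(structure_cloud=structure, markers_ct=markers)

    # CT label volume
    lo = centres.min(0) - radii.max() - 5.0
    hi = centres.max(0) + radii.max() + 5.0
    size = tuple(int(np.ceil((hi[i] - lo[i]) / config.ct_spacing)) for i in range(3))
    geom = VolumeGeometry(np.full(3, config.ct_spacing), lo, np.eye(3), size)
    grid = _voxel_grid_mm(geom)
    labels = np.zeros(size, dtype=np.uint8)
    for c, r in zip(centres, radii):
        labels |= (np.sum((grid - c) ** 2, axis=-1) <= r**2).astype(np.uint8)
    return model, labels, geom


# ---------------------------------------------------------------------------
# LV phantom
# ---------------------------------------------------------------------------

def _mid_surface_point(direction: np.ndarray, mid_axes: np.ndarray) -> np.ndarray:
    u = direction / np.linalg.norm(direction)
    s = 1.0 / np.sqrt(np.sum((u / mid_axes) ** 2))
    return s * u


def _lv_membership(points: np.ndarray, config: WorldConfig) -> np.ndarray:
    outer = np.asarray(config.lv_outer)
    inner = outer - config.lv_wall
    q_out = np.sum((points / outer) ** 2, axis=-1)
    q_in = np.sum((points / inner) ** 2, axis=-1)
    member = (q_out <= 1.0) & (q_in >= 1.0) & (points[..., 2] <= config.lv_trunc_z)
    mid_axes = outer - config.lv_wall / 2.0
    cos_open = np.cos(np.deg2rad(config.opening_half_angle_deg))
    r = np.linalg.norm(points, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        for d in (config.mitral_dir, config.aortic_dir):
            u = np.asarray(d, dtype=float)
            u /= np.linalg.norm(u)
            cosang = np.where(r > 0, points @ u / np.where(r > 0, r, 1.0), 1.0)
            member &= cosang < cos_open
    return member


def make_lv_phantom(
    config: WorldConfig, seed: int = 0
) -> tuple[PointCloud, LandmarkSet, np.ndarray, VolumeGeometry]:
    """Truncated-ellipsoid myocardium shell with two basal openings.

    Returns a point sample of the wall (``shell_points`` points spread
    through the wall thickness), the landmark set (apex and opening
    centres), and the CT label volume with its geometry.  All coordinates
    are in the patient-CT space, centred on the ellipsoid.
    """
    rng = np.random.default_rng(seed)
    outer = np.asarray(config.lv_outer)
    inner = outer - config.lv_wall
    mid_axes = outer - config.lv_wall / 2.0

    # rejection-sample directions on the mid ellipsoid, area-weighted via
    # oversampling, then jitter radially through the wall
    pts = []
    need = config.shell_points
    while sum(len(p) for p in pts) < need:
        u = _fibonacci_sphere(4 * need)
        # deterministic rotation offset from rng to decorrelate batches
        u = u @ Rotation.random(random_state=np.random.RandomState(rng.integers(2**31 - 1))).as_matrix().T
        surf = u * mid_axes
        frac = rng.uniform(-0.45, 0.45, size=len(surf))
        cand = surf * (1.0 + frac[:, None] * config.lv_wall / np.linalg.norm(surf, axis=1)[:, None])
        keep = _lv_membership(cand, config)
        pts.append(cand[keep])
    shell = np.concatenate(pts)[:need]
    cloud = PointCloud(shell, space="ct", label="lv_shell")

    apex = np.array([0.0, 0.0, -outer[2]])
    mitral = _mid_surface_point(np.asarray(config.mitral_dir), mid_axes)
    aortic = _mid_surface_point(np.asarray(config.aortic_dir), mid_axes)
    landmarks = LandmarkSet(apex, mitral, aortic, space="ct")

    lo = -outer - 3.0
    hi = np.array([outer[0], outer[1], config.lv_trunc_z]) + 3.0
    size = tuple(int(np.ceil((hi[i] - lo[i]) / config.ct_spacing)) for i in range(3))
    geom = VolumeGeometry(np.full(3, config.ct_spacing), lo, np.eye(3), size)
    grid = _voxel_grid_mm(geom)
    labels = _lv_membership(grid, config).astype(np.uint8)
    return cloud, landmarks, labels, geom


# ---------------------------------------------------------------------------
# trajectory and ECG
# ---------------------------------------------------------------------------

def _sinusoid_path(rng: np.random.Generator, n_components: int = 2):
    freqs = rng.uniform(0.08, 0.35, size=(n_components, 6))
    phases = rng.uniform(0, 2 * np.pi, size=(n_components, 6))
    weights = rng.dirichlet(np.ones(n_components), size=6).T

    def path(t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros((len(t), 6))
        for k in range(n_components):
            out += weights[k] * np.sin(2 * np.pi * freqs[k] * t[:, None] + phases[k])
        return out

    return path


def simulate_trajectory(
    config: WorldConfig,
    seed: int,
    t_tr_obj: HomogeneousTransform,
    t_pr_us: HomogeneousTransform,
    object_centre_ct: np.ndarray,
    duration: float | None = None,
    frame_count: int | None = None,
):
    """Smooth probe path keeping a static object centred in the scan cone.

    The probe pose is constructed so that the object's centroid stays near
    the cone's mid-depth point while sinusoidal translations ``d(t)`` and
    rotations about the object centroid (amplitudes per config; large in
    ``extreme`` mode) vary the viewpoint.  Returns the *measured* tracking
    stream (pose noise applied when configured), the US frame timestamps,
    and the exact pose function used for rendering.
    """
    rng = np.random.default_rng(seed)
    dur = config.duration_s if duration is None else duration
    amp_t, amp_r = config.motion_amplitudes
    path = _sinusoid_path(rng)
    cone = config.cone
    apex = np.asarray(cone.apex, dtype=float)
    axis = np.asarray(cone.axis, dtype=float)
    axis /= np.linalg.norm(axis)
    c_mid = apex + axis * 0.5 * (cone.r_min + cone.r_max)
    c_obj = np.asarray(object_centre_ct, dtype=float)

    def pose_fn(t: float) -> HomogeneousTransform:
        x = path(np.asarray([t]))[0]
        d = amp_t * x[:3]
        ang = np.deg2rad(amp_r) * x[3:]
        rot = Rotation.from_euler("xyz", ang)
        # us -> object-CT map: centre object at cone mid-depth, then perturb
        v = np.eye(4)
        v[:3, :3] = rot.as_matrix()
        v[:3, 3] = c_obj + d - v[:3, :3] @ c_mid
        v_t = HomogeneousTransform(v, from_space="us", to_space=t_tr_obj.from_space)
        return compose(compose(t_tr_obj, v_t), invert(t_pr_us))

    n_track = max(2, int(round(dur * config.tracking_rate_hz)) + 1)
    track_times = np.linspace(0.0, dur, n_track)
    poses = []
    for t in track_times:
        p = pose_fn(float(t))
        if config.sigma_tracking_mm > 0 or config.sigma_tracking_deg > 0:
            d_rot = Rotation.from_rotvec(
                np.deg2rad(config.sigma_tracking_deg) * rng.normal(size=3)
            )
            noisy_r = d_rot.as_matrix() @ p.rotation
            noisy_t = p.translation + config.sigma_tracking_mm * rng.normal(size=3)
            p = HomogeneousTransform.from_rotation_translation(
                noisy_r, noisy_t, p.from_space, p.to_space
            )
        poses.append(p)
    stream = TrackingStream(track_times, poses)

    if frame_count is None:
        frame_count = int(round(dur * config.frame_rate_hz))
    frame_times = np.arange(frame_count) / config.frame_rate_hz
    frame_times = frame_times[frame_times <= dur]
    return stream, frame_times, pose_fn


def synth_ecg(
    heart_rate_hz: float = 1.0,
    duration: float = 10.0,
    fs: float = 600.0,
    seed: int = 0,
    phase: float = 0.5,
    rr_jitter: float = 0.0,
    noise: float = 0.01,
) -> tuple[EcgTrace, np.ndarray]:
    """Periodic ECG-like trace with one sharp R-peak per cycle.

    Each cycle carries a narrow Gaussian R-wave (sigma 10 ms, amplitude 1)
    and a broader T-wave bump (amplitude 0.25, below any half-range
    detection threshold).  Returns the trace and the ground-truth R-peak
    times.
    """
    if not 0.5 <= heart_rate_hz <= 3.0:
        raise ValueError("heart rate must be within 0.5-3 Hz")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration * fs))) / fs
    rr = 1.0 / heart_rate_hz
    peaks = []
    tk = phase
    while tk < duration:
        peaks.append(tk)
        tk += rr + (rng.normal(0.0, rr_jitter) if rr_jitter > 0 else 0.0)
    peaks_arr = np.asarray(peaks)
    # snap ground-truth peaks onto the sample grid so the local-maximum
    # search can recover them exactly
    peaks_arr = np.round(peaks_arr * fs) / fs
    x = np.zeros_like(t)
    for pk in peaks_arr:
        x += np.exp(-0.5 * ((t - pk) / 0.010) ** 2)
        x += 0.25 * np.exp(-0.5 * ((t - pk - 0.25 * rr) / 0.060) ** 2)
    if noise > 0:
        x += noise * rng.normal(size=len(t))
    return EcgTrace(t, x, fs), peaks_arr


# ---------------------------------------------------------------------------
# US rendering
# ---------------------------------------------------------------------------

def render_us_volume(
    membership,
    geom: VolumeGeometry,
    cone: ConeParams,
    pose_tr_pr: HomogeneousTransform,
    t_pr_us: HomogeneousTransform,
    t_tr_obj: HomogeneousTransform,
    sigma_us: float = 0.0,
    seed: int = 0,
    background: float = 20.0,
    foreground: float = 220.0,
) -> np.ndarray:
    """Geometric US frame: structures voxelized through the true chain.

    ``membership(points_ct) -> bool`` decides which object-CT positions are
    inside a structure.  Voxel centres are carried into object-CT space via
    ``inv(T_tr_obj) . T_tr_pr . T_pr_US . A``; voxels outside the scan cone
    are zeroed; multiplicative speckle of strength ``sigma_us`` is applied
    when requested.  Returns a float32 volume in [0, 255].
    """
    grid_mm = _voxel_grid_mm(geom)                    # US image mm
    chain = compose(invert(t_tr_obj), compose(pose_tr_pr, t_pr_us))
    flat = grid_mm.reshape(-1, 3)
    obj_pts = chain.apply(flat).reshape(grid_mm.shape)
    vol = np.where(membership(obj_pts), foreground, background).astype(np.float32)
    if sigma_us > 0:
        rng = np.random.default_rng(seed)
        vol *= (1.0 + sigma_us * rng.standard_normal(vol.shape)).astype(np.float32)
    vol[~_cone_mask_mm(grid_mm, cone)] = 0.0
    if not np.any(vol > background):
        import warnings

        warnings.warn("structure outside scan cone: background-only frame", stacklevel=2)
    return np.clip(vol, 0.0, 255.0)


# ---------------------------------------------------------------------------
# the complete world
# ---------------------------------------------------------------------------

@dataclass
class SyntheticWorld:
    """A complete synthetic study: phantoms, trajectories, ECG, truth."""

    config: WorldConfig
    seed: int
    # calibration phantom
    phantom: PhantomModel
    phantom_labels: np.ndarray = field(repr=False)
    phantom_geom: VolumeGeometry = None
    t_tr_phantom: HomogeneousTransform = None
    cal_tracking: TrackingStream = None
    cal_frame_times: np.ndarray = None
    cal_pose_fn: object = None
    # LV phantom
    lv_cloud: PointCloud = None
    lv_landmarks: LandmarkSet = None
    lv_labels: np.ndarray = field(default=None, repr=False)
    lv_geom: VolumeGeometry = None
    t_tr_ct: HomogeneousTransform = None
    tracking: TrackingStream = None
    frame_times: np.ndarray = None
    pose_fn: object = None
    # shared truth
    true_t_pr_us: HomogeneousTransform = None
    us_geom: VolumeGeometry = None
    ecg: EcgTrace = None
    ecg_peaks: np.ndarray = None

    # -- ground-truth mappings --------------------------------------------
    def ct_to_frame_us(self, t: float) -> HomogeneousTransform:
        """Exact map patient-CT mm -> image mm of the frame at time ``t``."""
        pose = self.pose_fn(float(t))
        return compose(invert(self.true_t_pr_us), compose(invert(pose), self.t_tr_ct))

    def lv_frame_voxels(self, t: float) -> PointCloud:
        """The LV shell sample as continuous voxel indices of frame ``t``."""
        mm = self.ct_to_frame_us(t).apply(self.lv_cloud.points)
        a_inv = invert(self.us_geom.to_transform())
        return PointCloud(a_inv.apply(mm), space="us_vox", label="lv_shell")

    def lv_frame_landmarks(self, t: float) -> LandmarkSet:
        m = self.ct_to_frame_us(t)
        return LandmarkSet(
            m.apply(self.lv_landmarks.apex)[0],
            m.apply(self.lv_landmarks.mitral_centre)[0],
            m.apply(self.lv_landmarks.aortic_centre)[0],
            space="us",
        )

    def lv_frame_segmentation(self, t: float) -> PointCloud:
        """The LV shell sample in frame-``t`` image mm (a manual segmentation stand-in)."""
        mm = self.ct_to_frame_us(t).apply(self.lv_cloud.points)
        return PointCloud(mm, space="us", label="lv_shell")

    def render_frame(self, t: float, kind: str = "lv") -> np.ndarray:
        if kind == "lv":
            pose, t_obj = self.pose_fn(float(t)), self.t_tr_ct
            member = lambda p: _lv_membership(p, self.config)  # noqa: E731
        else:
            pose, t_obj = self.cal_pose_fn(float(t)), self.t_tr_phantom
            centres = np.asarray(self.config.sphere_centres)
            radii = np.asarray(self.config.sphere_radii)
            if self.config.symmetric_phantom:
                centres = np.array([(-20.0, -20.0, 0.0), (20.0, -20.0, 0.0),
                                    (20.0, 20.0, 0.0), (-20.0, 20.0, 0.0)])
                radii = np.full(4, 6.0)

            def member(p, centres=centres, radii=radii):
                hit = np.zeros(p.shape[:-1], dtype=bool)
                for c, r in zip(centres, radii):
                    hit |= np.sum((p - c) ** 2, axis=-1) <= r**2
                return hit

        frame_seed = int(
            np.random.SeedSequence([self.seed, int(round(t * 1e6)) % (2**31)]).generate_state(1)[0]
            % (2**31)
        )
        return render_us_volume(
            member, self.us_geom, self.config.cone, pose, self.true_t_pr_us,
            t_obj, sigma_us=self.config.sigma_us, seed=frame_seed,
        )

    def make_recording(self, kind: str = "lv") -> RecordingBundle:
        times = self.frame_times if kind == "lv" else self.cal_frame_times
        tracking = self.tracking if kind == "lv" else self.cal_tracking
        vols = [self.render_frame(float(t), kind).astype(np.uint8) for t in times]
        seq = UsFrameSequence(times, vols, self.us_geom)
        return RecordingBundle(
            us=seq,
            ecg=self.ecg,
            tracking=tracking,
            metadata={"kind": kind, "seed": self.seed},
        )


def make_world(config: WorldConfig | None = None, seed: int = 0) -> SyntheticWorld:
    """Build the full synthetic study deterministically from (config, seed)."""
    config = config or WorldConfig()
    root = np.random.SeedSequence(seed)
    s_truth, s_traj, s_cal_traj, s_ecg, s_lv = [
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(5)
    ]
    rng = np.random.default_rng(s_truth)

    true_t_pr_us = _random_rigid(rng, 15.0, 15.0, from_space="us", to_space="probe")
    t_tr_phantom = _random_rigid(rng, 180.0, 50.0, from_space="phantom_ct", to_space="tracking")
    t_tr_phantom = HomogeneousTransform.from_rotation_translation(
        t_tr_phantom.rotation,
        t_tr_phantom.translation + np.array([300.0, 120.0, 900.0]),
        "phantom_ct", "tracking",
    )
    t_tr_ct = _random_rigid(rng, 180.0, 50.0, from_space="ct", to_space="tracking")
    t_tr_ct = HomogeneousTransform.from_rotation_translation(
        t_tr_ct.rotation,
        t_tr_ct.translation + np.array([280.0, 150.0, 950.0]),
        "ct", "tracking",
    )

    phantom, ph_labels, ph_geom = make_calibration_phantom(config, seed)
    phantom.markers_tr = {
        k: t_tr_phantom.apply(v)[0] for k, v in phantom.markers_ct.items()
    }
    phantom.t_tr_ct = t_tr_phantom

    lv_cloud, lv_lm, lv_labels, lv_geom = make_lv_phantom(config, s_lv)

    us_geom = VolumeGeometry(
        np.full(3, config.us_spacing), np.zeros(3), np.eye(3), config.us_size
    )

    tracking, frame_times, pose_fn = simulate_trajectory(
        config, s_traj, t_tr_ct, true_t_pr_us, lv_cloud.points.mean(0)
    )
    n_cal = config.n_cal_frames
    cal_dur = config.cal_duration_s
    cal_tracking, cal_frame_times, cal_pose_fn = simulate_trajectory(
        config, s_cal_traj, t_tr_phantom, true_t_pr_us,
        np.asarray(config.sphere_centres).mean(0),
        duration=cal_dur,
        frame_count=n_cal,
    )
    ecg, peaks = synth_ecg(
        config.heart_rate_hz, config.duration_s, config.ecg_fs, s_ecg,
        phase=config.ecg_phase_s, rr_jitter=config.rr_jitter_s,
    )

    world = SyntheticWorld(
        config=config,
        seed=seed,
        phantom=phantom,
        phantom_labels=ph_labels,
        phantom_geom=ph_geom,
        t_tr_phantom=t_tr_phantom,
        cal_tracking=cal_tracking,
        cal_frame_times=cal_frame_times,
        cal_pose_fn=cal_pose_fn,
        lv_cloud=lv_cloud,
        lv_landmarks=lv_lm,
        lv_labels=lv_labels,
        lv_geom=lv_geom,
        t_tr_ct=t_tr_ct,
        tracking=tracking,
        frame_times=frame_times,
        pose_fn=pose_fn,
        true_t_pr_us=true_t_pr_us,
        us_geom=us_geom,
        ecg=ecg,
        ecg_peaks=peaks,
    )

    # the LV must stay visible inside the scan cone in every frame
    bad = []
    for t in frame_times:
        mm = world.ct_to_frame_us(float(t)).apply(lv_cloud.points)
        if not np.all(_cone_mask_mm(mm, config.cone)):
            bad.append(float(t))
    if bad:
        raise ValueError(f"LV leaves the scan cone in frames at t={bad}")
    return world


def write_world(world: SyntheticWorld, out_dir: str | Path) -> dict:
    """Render and write the full on-disk bundle plus a ground-truth manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["lv_recording"] = write_recording(out_dir / "lv_recording", world.make_recording("lv"))
    paths["cal_recording"] = write_recording(
        out_dir / "cal_recording", world.make_recording("cal")
    )
    write_label_volume(out_dir / "ct_lv_labels.nrrd", world.lv_labels, world.lv_geom)
    write_label_volume(out_dir / "ct_phantom_labels.nrrd", world.phantom_labels, world.phantom_geom)
    write_landmarks(out_dir / "ct_landmarks.fcsv", world.lv_landmarks)
    manifest = {
        "seed": world.seed,
        "true_t_pr_us": world.true_t_pr_us.matrix.tolist(),
        "t_tr_phantom": world.t_tr_phantom.matrix.tolist(),
        "t_tr_ct": world.t_tr_ct.matrix.tolist(),
        "frame_times": world.frame_times.tolist(),
        "cal_frame_times": world.cal_frame_times.tolist(),
        "ecg_peaks": world.ecg_peaks.tolist(),
        "phantom_markers_tr": {k: v.tolist() for k, v in world.phantom.markers_tr.items()},
    }
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    paths["manifest"] = out_dir / "ground_truth.json"
    return paths
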