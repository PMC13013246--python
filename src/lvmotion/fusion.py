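"""Forward transfer of US voxels into CT coordinates.

Any voxel of any US frame reaches CT space through the chain

    p_CT = D( T_USt_tr . T_tr_pr(t) . T_pr_US . A . p_UsVox )

where ``A`` maps voxel indices to image mm, ``T_pr_US`` is the probe
calibration, ``T_tr_pr(t)`` the interpolated probe pose at the frame
time, ``T_USt_tr`` carries tracked points back into the image space of
the ECG-matched baseline frame, and ``D`` is the affine registration of
the baseline frame onto the CT segmentation.  Because the calibration and
registration are fixed per recording, transferring the same static
structure from different probe poses should yield coinciding clouds in
CT; any residual displacement measures the accumulated error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationResult
from .geometry import (
    HomogeneousTransform,
    PointCloud,
    TrackingStream,
    VolumeGeometry,
    compose,
    interpolate_pose,
    invert,
)
from .registration import RegistrationResult
from .stream_io import label_volume_to_cloud

__all__ = ["TransferChain", "transfer_points", "transfer_segmentation", "superimpose"]


@dataclass
class TransferChain:
    """All factors needed to move voxels of one recording into CT space."""

    geom: VolumeGeometry
    calibration: CalibrationResult | HomogeneousTransform
    tracking: TrackingStream
    registration: RegistrationResult

    @property
    def t_pr_us(self) -> HomogeneousTransform:
        cal = self.calibration
        return cal if isinstance(cal, HomogeneousTransform) else cal.t_pr_us

    def tracking_to_baseline_us(self) -> HomogeneousTransform:
        """``T_USt_tr``: tracking space into the baseline frame's image mm."""
        t_pr_tr = self.registration.t_ust_tr
        if t_pr_tr is None:
            raise ValueError(
                "transfer chain is missing the baseline pose factor (t_ust_tr)"
            )
        return compose(invert(self.t_pr_us), t_pr_tr)


def transfer_points(
    chain: TransferChain, frame_time: float, voxels: PointCloud
) -> PointCloud:
    """Transfer voxel indices of the frame at ``frame_time`` into CT mm."""
    if voxels.space != "us_vox":
        raise ValueError("transfer_points expects a cloud of US voxel indices")
    a = chain.geom.to_transform()                      # us <- us_vox
    pose = interpolate_pose(chain.tracking, frame_time)  # tracking <- probe
    to_tracking = compose(pose, compose(chain.t_pr_us, a))
    to_baseline = compose(chain.tracking_to_baseline_us(), to_tracking)
    baseline_mm = to_baseline.apply(voxels.points)
    ct_mm = chain.registration.transform_points(baseline_mm)
    return PointCloud(ct_mm, space="ct", label=voxels.label)


def transfer_segmentation(
    chain: TransferChain, frame_time: float, label_volume: np.ndarray
) -> PointCloud:
    """Transfer the labelled voxel centres of a segmentation mask.

    The mask must live on the chain's US grid; the physical centre of
    every non-zero voxel is pushed through :func:`transfer_points`.
    """
    if tuple(label_volume.shape) != chain.geom.size:
        raise ValueError("label volume shape does not match the chain's US geometry")
    idx = np.argwhere(np.asarray(label_volume) > 0).astype(float)
    cloud = PointCloud(idx, space="us_vox", label="segmentation")
    if len(cloud) == 0:
        import warnings

        warnings.warn("empty segmentation; returning empty cloud", stacklevel=2)
        return PointCloud(np.empty((0, 3)), space="ct", label="segmentation")
    return transfer_points(chain, frame_time, cloud)


def superimpose(
    transfers: list[tuple[TransferChain, float, np.ndarray]]
) -> tuple[PointCloud, np.ndarray]:
    """Union of transferred segmentations with per-point frame provenance.

    ``transfers`` is a list of ``(chain, frame_time, label_volume)``.
    Returns the merged CT cloud and an integer array tagging each point
    with the index of its source entry.
    """
    if not transfers:
        raise ValueError("superimpose needs at least one frame")
    clouds, tags = [], []
    for i, (chain, t, seg) in enumerate(transfers):
        c = transfer_segmentation(chain, t, seg)
        clouds.append(c.points)
        tags.append(np.full(len(c), i, dtype=int))
    merged = np.concatenate(clouds) if clouds else np.empty((0, 3))
    return (
        PointCloud(merged, space="ct", label="superimposed"),
        np.concatenate(tags) if tags else np.empty(0, dtype=int),
    )
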