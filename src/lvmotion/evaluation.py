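"""Quantitative evaluation of transferred structures against CT ground truth.

Because the US cone crops parts of the myocardium, distances are measured
unidirectionally from the (possibly partial) US-derived cloud toward the
complete CT segmentation: the directed Hausdorff distance, its outlier-
robust 95th percentile (HD95), the volumetric DICE overlap, per-point
displacements, and a 17-segment (AHA) bullseye of the maximum
displacement per left-ventricular wall segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import PointCloud
from .stream_io import LandmarkSet

__all__ = [
    "SegmentModel",
    "SegmentDisplacementMap",
    "directed_hausdorff",
    "hd95",
    "dice",
    "point_displacements",
    "assign_segments",
    "bullseye",
    "cross_transfer_matrix",
]


# ---------------------------------------------------------------------------
# point-cloud metrics
# ---------------------------------------------------------------------------

def _nn_distances(a: PointCloud | np.ndarray, b: PointCloud | np.ndarray) -> np.ndarray:
    pa = a.points if isinstance(a, PointCloud) else np.asarray(a, dtype=float)
    pb = b.points if isinstance(b, PointCloud) else np.asarray(b, dtype=float)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("point-cloud metrics require non-empty clouds")
    d, _ = cKDTree(pb).query(pa, workers=-1)
    return d


def directed_hausdorff(a: PointCloud | np.ndarray, b: PointCloud | np.ndarray) -> float:
    """max over ``a`` of the Euclidean distance to the nearest point of ``b``."""
    return float(np.max(_nn_distances(a, b)))


def hd95(a: PointCloud | np.ndarray, b: PointCloud | np.ndarray) -> float:
    """95th percentile (linear interpolation) of directed NN distances a -> b."""
    return float(np.percentile(_nn_distances(a, b), 95, method="linear"))


def point_displacements(
    transferred: PointCloud | np.ndarray, ct_seg: PointCloud | np.ndarray
) -> np.ndarray:
    """Closest distance to a segmented CT voxel for every transferred point."""
    return _nn_distances(transferred, ct_seg)


def dice(
    a: PointCloud | np.ndarray,
    b: PointCloud | np.ndarray,
    grid_spacing: float = 1.0,
    origin: np.ndarray | None = None,
) -> float:
    """Volumetric overlap ``2|A n B| / (|A| + |B|)`` on a shared voxel grid.

    Both clouds are quantized to an isotropic grid (default 1 mm) whose
    origin defaults to the joint minimum corner, snapped to a multiple of
    the spacing so that a common rigid shift of both clouds leaves the
    score unchanged up to voxel quantization.
    """
    pa = a.points if isinstance(a, PointCloud) else np.asarray(a, dtype=float)
    pb = b.points if isinstance(b, PointCloud) else np.asarray(b, dtype=float)
    if len(pa) == 0 and len(pb) == 0:
        raise ValueError("DICE of two empty clouds is undefined")
    if len(pa) == 0 or len(pb) == 0:
        return 0.0
    if origin is None:
        lo = np.minimum(pa.min(0), pb.min(0))
        origin = np.floor(lo / grid_spacing) * grid_spacing
    va = {tuple(v) for v in np.floor((pa - origin) / grid_spacing).astype(int)}
    vb = {tuple(v) for v in np.floor((pb - origin) / grid_spacing).astype(int)}
    inter = len(va & vb)
    return 2.0 * inter / (len(va) + len(vb))


# ---------------------------------------------------------------------------
# 17-segment model
# ---------------------------------------------------------------------------

@dataclass
class SegmentModel:
    """Geometry of the AHA 17-segment partition of the left ventricle.

    The long axis runs from the apex toward the mitral-valve centre; the
    aortic-valve direction, projected perpendicular to the long axis,
    fixes the circumferential reference so that the aortic valve sits at
    the centre of (basal) segment 2.  The axial extent is split into an
    apical cap (nearest ``cap_fraction`` of the axis) and three equal
    thirds carrying 4, 6 and 6 circumferential sectors.
    """

    apex: np.ndarray
    mitral_centre: np.ndarray
    aortic_centre: np.ndarray
    cap_fraction: float = 0.15

    def __post_init__(self) -> None:
        self.apex = np.asarray(self.apex, dtype=float)
        self.mitral_centre = np.asarray(self.mitral_centre, dtype=float)
        self.aortic_centre = np.asarray(self.aortic_centre, dtype=float)
        axis = self.mitral_centre - self.apex
        n = np.linalg.norm(axis)
        if n < 1e-9:
            raise ValueError("apex and mitral centre coincide")
        self.long_axis = axis / n
        self.axis_length = float(n)
        ref = self.aortic_centre - self.apex
        ref = ref - (ref @ self.long_axis) * self.long_axis
        rn = np.linalg.norm(ref)
        if rn < 1e-9:
            raise ValueError("aortic centre lies on the long axis; no angular reference")
        self.angular_reference = ref / rn
        # right-handed in-plane basis (reference, ortho, long_axis)
        self.ortho = np.cross(self.long_axis, self.angular_reference)

    @classmethod
    def from_landmarks(cls, lm: LandmarkSet, cap_fraction: float = 0.15) -> "SegmentModel":
        return cls(lm.apex, lm.mitral_centre, lm.aortic_centre, cap_fraction)


@dataclass
class SegmentDisplacementMap:
    """Maximum displacement (mm) and point count per AHA segment 1..17.

    Segments without members carry NaN and are listed in ``missing``
    rather than reported as zero displacement.
    """

    values: np.ndarray
    counts: np.ndarray

    @property
    def missing(self) -> list[int]:
        return [i + 1 for i in range(17) if self.counts[i] == 0]

    def as_table(self):
        import pandas as pd

        return pd.DataFrame(
            {"segment": np.arange(1, 18), "max_mm": self.values, "count": self.counts}
        )


# basal/mid rings: 60-degree sectors, aortic direction at the centre of the
# second segment of the ring; apical ring: 90-degree sectors, aortic
# direction at the centre of the second sector (segment 14)
def _ring_ids(theta: np.ndarray, n_sectors: int, base: int) -> np.ndarray:
    """Segment ids of one ring: sector 0 is centred on the aortic reference
    and carries id ``base + 1``; a point exactly on an angular boundary is
    assigned the lower of the two adjacent segment ids."""
    width = 2.0 * np.pi / n_sectors
    x = (theta + width / 2.0) / width
    sec = np.floor(x).astype(int) % n_sectors
    ids = base + (sec + 1) % n_sectors
    on_boundary = x == np.round(x)
    if np.any(on_boundary):
        sec_lo = (np.floor(x[on_boundary]).astype(int) - 1) % n_sectors
        ids_lo = base + (sec_lo + 1) % n_sectors
        ids[on_boundary] = np.minimum(ids[on_boundary], ids_lo)
    return ids


def assign_segments(points: PointCloud | np.ndarray, model: SegmentModel) -> np.ndarray:
    """AHA segment id (1..17) for every point.

    Axial position along the apex->mitral axis splits the cap (segment 17)
    from the apical, mid and basal thirds; the circumferential angle from
    the aortic reference assigns the sector.  Points beyond the valve
    plane are clamped into the basal ring, points behind the apex into the
    cap.  Boundary ties resolve toward the lower segment id by the
    half-open interval convention.
    """
    pts = points.points if isinstance(points, PointCloud) else np.asarray(points, dtype=float)
    rel = pts - model.apex
    s = (rel @ model.long_axis) / model.axis_length
    u = rel @ model.angular_reference
    v = rel @ model.ortho
    theta = np.arctan2(v, u)
    seg = np.empty(len(pts), dtype=int)

    cap = s < model.cap_fraction
    seg[cap] = 17
    third = (1.0 - model.cap_fraction) / 3.0
    apical = ~cap & (s < model.cap_fraction + third)
    mid = ~cap & ~apical & (s < model.cap_fraction + 2.0 * third)
    basal = ~cap & ~apical & ~mid

    # apical ring (segments 13-16): aortic direction at centre of segment 14
    seg[apical] = _ring_ids(theta[apical], 4, 13)
    # mid ring (7-12): aortic direction at centre of segment 8
    seg[mid] = _ring_ids(theta[mid], 6, 7)
    # basal ring (1-6): aortic direction at centre of segment 2
    seg[basal] = _ring_ids(theta[basal], 6, 1)
    return seg


def bullseye(
    points: PointCloud | np.ndarray,
    displacements: np.ndarray,
    model: SegmentModel,
) -> SegmentDisplacementMap:
    """Maximum displacement per AHA segment for the bullseye view."""
    disp = np.asarray(displacements, dtype=float)
    pts = points.points if isinstance(points, PointCloud) else np.asarray(points, dtype=float)
    if len(pts) != len(disp):
        raise ValueError("points and displacements must have equal length")
    seg = assign_segments(pts, model)
    values = np.full(17, np.nan)
    counts = np.zeros(17, dtype=int)
    for i in range(1, 18):
        mask = seg == i
        counts[i - 1] = int(mask.sum())
        if counts[i - 1]:
            values[i - 1] = float(disp[mask].max())
    return SegmentDisplacementMap(values=values, counts=counts)


def plot_bullseye(seg_map: SegmentDisplacementMap, ax=None, cmap: str = "viridis"):
    """Render the 17-segment map as the standard bullseye polar plot."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    vals = seg_map.values
    vmax = np.nanmax(vals) if np.any(np.isfinite(vals)) else 1.0
    cm = plt.get_cmap(cmap)
    rings = [(range(0, 6), 3, 4, 6), (range(6, 12), 2, 3, 6), (range(12, 16), 1, 2, 4)]
    for idxs, r0, r1, n in rings:
        width = 2 * np.pi / n
        for j, i in enumerate(idxs):
            # sector j of the ring; segment-2-style offset already baked
            theta0 = (j - 1) * width - width / 2.0
            color = cm(vals[i] / vmax) if np.isfinite(vals[i]) else (0.8, 0.8, 0.8)
            ax.bar(theta0 + width / 2.0, r1 - r0, width=width, bottom=r0,
                   color=color, edgecolor="k", linewidth=0.5)
    c17 = cm(vals[16] / vmax) if np.isfinite(vals[16]) else (0.8, 0.8, 0.8)
    ax.bar(0, 1, width=2 * np.pi, bottom=0, color=c17, edgecolor="k", linewidth=0.5)
    ax.set_xticks([])
    ax.set_yticks([])
    return ax


# ---------------------------------------------------------------------------
# cross-transfer matrix
# ---------------------------------------------------------------------------

def cross_transfer_matrix(
    frame_times: np.ndarray,
    segmentations: list[np.ndarray],
    chains: list,
    ct_cloud: PointCloud,
) -> np.ndarray:
    """HD95 of every frame transferred through every registration baseline.

    Entry ``(i, j)`` is the unidirectional HD95 (mm) of frame ``j``'s
    segmentation, transferred to CT through the chain whose registration
    baseline is frame ``i``, against the CT ground-truth cloud.  Rows are
    baseline frames, columns transferred frames; a failed transfer leaves
    NaN.  Segmentations may be label volumes on the US grid or
    ``PointCloud`` objects of (continuous) voxel indices.
    """
    from .fusion import transfer_points, transfer_segmentation

    n = len(frame_times)
    if not (len(segmentations) == len(chains) == n):
        raise ValueError("frame_times, segmentations and chains must align")
    out = np.full((n, n), np.nan)
    for i, chain in enumerate(chains):
        for j in range(n):
            seg = segmentations[j]
            try:
                if isinstance(seg, PointCloud):
                    cloud = transfer_points(chain, float(frame_times[j]), seg)
                else:
                    cloud = transfer_segmentation(chain, float(frame_times[j]), seg)
                out[i, j] = hd95(cloud, ct_cloud)
            except (ValueError, RuntimeError):
                continue
    return out
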