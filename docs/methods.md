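# Methods

## Problem and model

`lvmotion` transfers structures segmented in optically tracked 3D
echocardiography (US) into the coordinate system of a cardiac CT, so that
left-ventricular (LV) motion observed in US can be expressed where
radiotherapy planning happens. A voxel `p_UsVox` of the US frame acquired
at time `t` reaches CT space through the chain

```
p_CT = D( T_USt_tr · T_tr_pr(t) · T_pr_US · A · p_UsVox )
```

with

- `A` — the voxel-to-mm map of the US grid (spacing, origin, direction
  cosines, MetaImage/NRRD header semantics, 0-based indices);
- `T_pr_US` — the fixed *spatial probe calibration* from US image space
  to the coordinate system of the optical markers on the probe;
- `T_tr_pr(t)` — the tracked probe pose at the frame time, interpolated
  from the tracking stream by quaternion SLERP (rotation, shortest path
  via sign-flipped quaternions) and linear interpolation (translation);
- `T_USt_tr` — the inverse pose chain of the ECG-matched *baseline*
  frame, carrying tracked points back into that frame's image space;
- `D` — the affine registration of the baseline-frame myocardium onto
  the CT segmentation.

All lengths are mm, timestamps float seconds, points are columns under
left-multiplication by 4×4 homogeneous matrices, and every transform
carries `from_space`/`to_space` tags so mis-chained compositions fail
loudly rather than silently.

## Pipeline stages

**ECG-gated frame matching.** The cardiac CT is triggered at a fixed
fraction of the R-R interval (default 0.78 per the study protocol).
R-peaks are found by a local-maximum search: maxima above
`median + 0.5·(max − median)` separated by a 0.3 s refractory period
(a 200 bpm physiological ceiling; the threshold convention is ours, the
source method states only a local-maximum search). Peak time is the
sample timestamp — at 600 Hz the 1.7 ms granularity is far below the
25 ms matching bound. One trigger is placed per complete R-R interval and
the US frame with the smallest |Δt| is matched (ties to the earlier
frame); the best of the recorded cycles becomes the registration
baseline. At a 20 Hz frame floor the worst possible trigger-to-frame
offset is half the 50 ms interval, 25 ms.

**Probe calibration.** Frames of a rigid calibration phantom are pushed
through: slice-wise 2D Canny edge detection (sigma 2 voxels, hysteresis
0.1/0.2 of the slice intensity range; 2D because the axial slices carry
the native image resolution), a scan-cone mask with a 2 mm boundary
margin against cone-edge artefacts, DBSCAN clustering (eps 3 mm,
min_samples 10, 50-point cluster floor) to isolate the phantom's inner
structures, a principal-axes pre-alignment trying all four proper sign
combinations and keeping the lowest directed Hausdorff distance, and
point-to-point ICP with closed-form Kabsch updates (proper rotations
only; mean-residual tolerance 1e-6 mm, 100 iterations). This yields
`T_CT_US`; together with the marker-based phantom pose `T_tr_CT` and the
inverted probe pose the calibration composes as
`T_pr_US = T_pr_tr · T_tr_CT · T_CT_US`. Because probe contact and
positioning degrade single frames, the calibration runs over many frames
(default 100) and the 30 with the lowest residual directed Hausdorff
distance are kept and pooled (quaternion-mean rotation, mean
translation). Consistency is reported as per-axis standard deviations of
test points mapped through all retained calibrations, combined by
root-sum-of-squares.

**US→CT registration.** The three anatomical landmarks (apex, mitral and
aortic valve centres) give a closed-form rigid pre-alignment; both
myocardium clouds are then normalized to zero centroid and unit RMS
radius, and an affine coherent point drift (CPD) fit runs on the
normalized clouds. CPD treats the moving cloud as Gaussian-mixture
centroids with a uniform outlier component (weight `w = 0.1`, our
default; the outlier term absorbs the cone-cropped partial overlap
instead of any trimming heuristic) and maximizes the likelihood by EM;
the objective is monitored and non-increasing. The normalization
parameters are estimated on the full clouds; the quadratic-cost EM runs
on an even subsample of at most 1500 points per side. The registration
direction is US→CT, matching the forward chain. A non-rigid extension is
deliberately out of scope.

**Transfer and evaluation.** Points — not resampled volumes — are the
transfer currency; voxelization happens only inside the DICE metric
(shared 1 mm isotropic grid snapped to a common origin). Because the US
cone crops the myocardium, distances are *unidirectional* from the
US-derived cloud toward the CT segmentation: directed Hausdorff, its
95th percentile (HD95, linearly interpolated percentile), and per-point
nearest-voxel displacements. The cross-transfer matrix transfers every
frame's segmentation through every baseline registration (rows =
baseline, columns = transferred frame). Displacements are summarized on
the AHA 17-segment bullseye: the long axis runs apex→mitral centre, the
aortic direction projected perpendicular to it fixes the angular
reference so the aortic valve sits at the centre of segment 2 (mid and
apical rings use the analogous convention: segments 8 and 14); the
apical cap occupies the nearest 15 % of the axis and the remainder is
split into equal thirds (the exact fractions are not standardized at
this granularity, so they are configuration values). Points exactly on a
boundary take the lower segment id; each segment reports the *maximum*
member displacement, and empty segments are flagged missing rather than
reported as zero.

## Synthetic study

The generator emulates the study's conditions — a *static* torso phantom
imaged by a moving tracked probe — so that every displacement after
transfer is, by construction, error:

- calibration phantom: four spheres of distinct radii (4–9 mm) in an
  asymmetric arrangement (all pairwise distances distinct, rank-3
  spread) plus four non-coplanar optical markers; a symmetric mode
  reproduces the flipped-pre-alignment failure case;
- LV: a truncated-ellipsoid shell (outer semi-axes 22/22/35 mm, 7 mm
  wall) with mitral and aortic basal openings and landmarks at the apex
  and opening centres;
- trajectory: smooth sinusoidal probe motion about an apical viewpoint
  (default ±4 mm / ±4°; an "extreme" mode uses ±15 mm / ±20°), tracking
  sampled at 60 Hz, frames at 20 Hz, with optional Gaussian pose noise
  applied to the *measured* tracking only — the rendered images always
  use the exact pose;
- ECG: 600 Hz, one sharp Gaussian R-wave per cycle (amplitude 1,
  sigma 10 ms) plus a sub-threshold T-wave, default 1 Hz over 10 s (ten
  cycles, mirroring the recorded datasets);
- US rendering: geometric voxelization of the structures through the
  inverse truth chain into an 80³ grid at 1 mm, bright against a darker
  background, zeroed outside the scan cone (half-angle 40°), with
  optional multiplicative speckle. This is deliberately not a wave
  simulation: every downstream stage consumes edges or segmentations,
  so geometric contrast is the operative content. Consequently, passing
  tests demonstrate the correctness of the *transform chain and
  algorithms*, not robustness to real speckle statistics, shadowing,
  or manual-segmentation variability.

All outputs are pure functions of `(config, seed)`; the ground-truth
probe calibration, phantom poses and R-peak times are retained for
recovery tests.

## Numerical choices and degenerate inputs

- Rigid fits (markers, landmarks, ICP updates) use Kabsch SVD with the
  determinant sign correction: reflections are never returned.
- Collinear marker or landmark triplets (smallest triangle height
  < 1 mm) are rejected as ill-posed.
- Pose interpolation refuses to extrapolate beyond the tracking stream;
  translation between samples is linear (a screw-motion interpolant
  would also be defensible; linear is the simpler convention and the
  differences are negligible at 60 Hz).
- CPD stops on an objective change below 1e-8 or a variance collapse
  below 1e-12; a singular affine update raises.
- Uniform volumes yield empty edge clouds; all-noise DBSCAN results and
  empty segmentations warn and propagate as flagged failures rather
  than exceptions inside the per-frame calibration loop, so the
  consistency filter can discard them.

## Problem sizes used in the checks

The bundled end-to-end checks run a 10 s, 200-frame study with a
5000-point LV shell, a 12-frame noiseless calibration recording pooled
to the best 6, and a 100-frame calibration recording with 0.5 mm
tracking noise filtered to the best 30 — sizes chosen so the whole suite
runs in minutes on one CPU while keeping every stage's statistics
meaningful. On the noiseless study the recovered probe calibration
agrees with the generator's truth to below 0.1 mm / 0.1° and the
cross-transfer HD95 matrix stays below 0.05 mm; these numbers are
recomputed, not stored, by `scripts/acceptance.py` and the test suite.

## Known limitations

- The affine CPD cannot express the scaling/shearing *calibration*
  refinements or non-rigid US/CT discrepancies of real tissue; both are
  explicit non-goals here.
- The commercial calibration phantom's true inner geometry is not
  modelled; the sphere-cluster stand-in is clearly labelled synthetic
  and real phantom meshes must be supplied for real data.
- Arrhythmia-robust QRS detection (Pan–Tompkins-class) is out of scope;
  the local-maximum search assumes reasonably regular rhythm.
- FCSV landmark files are read and written in the package's single
  LPS-style mm convention; no RAS↔LPS conversion is attempted.
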