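# lvmotion

Transfer of left-ventricular (LV) structures from optically tracked 3D
echocardiography (US) into cardiac-CT coordinates, with quantitative
error evaluation. The intended users are researchers building US-based
cardiorespiratory motion management for stereotactic arrhythmia
radioablation (STAR), where motion seen live in US must be expressed in
the CT frame used for radiation planning.

Any US voxel `p_UsVox` of the frame at time `t` is mapped to CT by

```
p_CT = D( T_USt_tr · T_tr_pr(t) · T_pr_US · A · p_UsVox )
```

where `A` is the voxel-to-mm map of the US grid, `T_pr_US` the spatial
probe calibration estimated from a calibration phantom
(`T_pr_US = T_pr_tr · T_tr_CT · T_CT_US`, via Canny edge segmentation,
DBSCAN clustering, principal-axes pre-alignment and ICP), `T_tr_pr(t)`
the SLERP-interpolated tracked probe pose, and `D` the affine
coherent-point-drift registration of the ECG-matched baseline frame's
myocardium onto the CT segmentation (landmark rigid pre-alignment +
normalization + CPD). Accuracy is quantified with unidirectional
(US→CT) Hausdorff metrics, HD95, DICE, and an AHA 17-segment bullseye
of maximum per-segment displacement. A deterministic synthetic-phantom
generator supplies complete recordings (US volumes, 600 Hz ECG, 60 Hz
tracking) with known ground-truth transforms.

## Worked example

```python
import numpy as np
from lvmotion import (
    CalibrationParams, TransferChain, WorldConfig, make_world,
)
from lvmotion.calibration import calibrate_recording
from lvmotion.frame_match import match_recording
from lvmotion.registration import build_registration
from lvmotion.evaluation import cross_transfer_matrix

# a noiseless synthetic study: static LV phantom, moving tracked probe
cfg = WorldConfig(n_cal_frames=12, cal_duration_s=2.0, duration_s=10.0)
world = make_world(cfg, seed=11)

# probe calibration from the phantom recording, pooled over the best frames
params = CalibrationParams(cone=cfg.cone)
frames = [world.render_frame(float(t), "cal") for t in world.cal_frame_times]
t_pr_us, results, kept = calibrate_recording(
    frames, world.cal_frame_times, world.us_geom,
    world.cal_tracking, world.phantom, params, keep=6)

# ECG gating: trigger at 78 % R-R, closest US frame per cycle
matches, best = match_recording(world.ecg, world.frame_times)
print(f"best cycle offset: {best.offset_ms:.1f} ms")

# register the baseline frame, then transfer another frame through the chain
t0 = float(world.frame_times[best.matched_frame_index])
reg = build_registration(
    world.lv_frame_segmentation(t0), world.lv_cloud,
    world.lv_frame_landmarks(t0), world.lv_landmarks,
    tracking=world.tracking, baseline_time=t0)
chain = TransferChain(geom=world.us_geom, calibration=t_pr_us,
                      tracking=world.tracking, registration=reg)

times = np.array([t0, float(world.frame_times[120])])
segs = [world.lv_frame_voxels(float(t)) for t in times]
mat = cross_transfer_matrix(times, segs, [chain, chain], world.lv_cloud)
print(f"cross-transfer HD95 (mm): {np.round(mat, 3)}")
```

Output:

```
best cycle offset: 18.7 ms
cross-transfer HD95 (mm): [[0.    0.007]
 [0.    0.007]]
```

The 18.7 ms offset is the residual between the CT trigger phase and the
closest 20 Hz US frame (the worst case at that frame rate is 25 ms). The
near-zero HD95 values confirm the evaluation premise of the static
phantom: the same structure transferred from different probe poses
coincides in CT, so on real data any residual displacement measures the
accumulated calibration/tracking/registration error.

A CLI mirrors the library:
`lvmotion simulate|validate|match|calibrate|register|transfer|evaluate`.

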