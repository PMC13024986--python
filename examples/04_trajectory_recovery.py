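"""End-to-end healing-trajectory recovery on synthetic scans.

Prescribes an exponential wound-area decay A(t) = A0 exp(-k (t - 1)),
generates one labeled, noise-jittered scan per follow-up day, runs the
segmentation + planimetry pipeline on each, and recovers k by
log-linear regression on the extracted areas.
"""
import numpy as np

from woundmetry import (
    SyntheticScene,
    TrajectorySpec,
    generate_series,
    roi_from_labels,
)

K_TRUE = 0.1  # per day

scene = SyntheticScene("sphere_torso", {"radius": 100.0}, {"theta": 1.0},
                       resolution=2.0, seed=7)
traj = TrajectorySpec("exponential", a0_cm2=500.0, rate=K_TRUE,
                      scan_days=(1, 4, 8, 15), noise_sigma_mm=0.1)

frames = generate_series(scene, traj)
print("day   true area   extracted   rel. error")
areas = []
for f in frames:
    a = roi_from_labels(f.mesh).area_cm2
    areas.append(a)
    print(f"{f.day:3d}  {f.true_area_cm2:9.2f}  {a:10.2f}   {a / f.true_area_cm2 - 1:+.2e}")

days = np.array([f.day for f in frames], dtype=float)
k = -np.polyfit(days - days[0], np.log(areas), 1)[0]
print(f"\nprescribed decay rate k : {K_TRUE:.4f} /day")
print(f"recovered decay rate k  : {k:.4f} /day  "
      f"({abs(k - K_TRUE) / K_TRUE * 100:.2f}% off)")

# Each frame's wound patch is re-solved in closed form to match A(t)
# exactly, so the residual error is pure mesh discretization + noise.
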