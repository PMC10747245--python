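"""Generate one synthetic gait trial and write it in all external formats.

The generator produces bilateral sagittal joint-angle waveforms, the 12
lower-limb feature points realizing them through a planar linkage, and
per-limb vertical ground-reaction forces, then writes OpenPose-style
per-frame JSON, reference joint-centre CSV, GRF CSVs and a manifest.
"""

from pathlib import Path

from gaitval import GaitProfile, make_trial
from gaitval.io import write_trial

profile = GaitProfile(seed=42, n_cycles=5, noise_sd=2.0, dropout_prob_crossing=0.5)
trial = make_trial(profile)
out = write_trial(trial, Path("scratch") / "example_trial")

print(f"frames: {trial.pose.n_frames} at {trial.pose.rate:.0f} Hz")
print(f"force samples per limb: {len(trial.grf_right.fz)} at {trial.grf_right.rate:.0f} Hz")
print(f"declared right initial contacts (force samples): {trial.true_events['right'].tolist()}")
dropped = int((trial.pose.confidence == 0).any(axis=1).sum())
print(f"frames with occluded left-limb keypoints: {dropped}")
print(f"written to {out}")
# The dropout count shows the far-limb occlusion model at work: those
# frames carry confidence 0 for the left knee/ankle/foot points.
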