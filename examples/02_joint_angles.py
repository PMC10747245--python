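"""Compute sagittal joint angles from landmarks and check them against truth.

On a noiseless trial the angles recomputed from the emitted feature
points match the generator's waveforms to float precision — the core
round-trip guarantee behind every downstream test.
"""

import numpy as np

from gaitval import GaitProfile, JOINTS, SIDES, joint_angles, make_trial

trial = make_trial(GaitProfile(seed=7, n_cycles=3))
angles = joint_angles(trial.pose)

for side in SIDES:
    for joint in JOINTS:
        wf = angles[(side, joint)]
        err = np.nanmax(np.abs(wf.values - trial.true_angles[(side, joint)]))
        print(f"{side:5s} {joint:5s}: peak {np.nanmax(wf.values):6.1f} deg, "
              f"min {np.nanmin(wf.values):6.1f} deg, round-trip error {err:.1e} deg")
# Peaks reflect the profile amplitudes (hip ~30 flex, knee ~60 swing
# flexion, ankle ~14 dorsiflexion); errors are at machine precision.
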