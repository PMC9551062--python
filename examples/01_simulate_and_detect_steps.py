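"""Simulate a wrist-worn walk and detect its steps.

Generates two minutes of synthetic 100 Hz wrist acceleration for a walk at
110 steps/min, derives the filtered norm channels, and runs the
extremum-pruning step detector.  The detected count and mean step time
should match the generator's ground truth to within a couple of percent.
"""

import numpy as np

from watchwalk import preprocess, steps
from watchwalk.simulate import simulate_walk

rec, truth = simulate_walk(cadence_spm=110, duration_s=120, noise_sd_g=0.03, seed=1)
ps = preprocess.compute_channels(rec)

bout = steps.detect_steps(
    steps.WalkingBout(0.0, rec.duration_s, [], "walk_armswing"), ps
)

true_step_time = np.mean(np.diff(truth.step_times))
est_step_time = np.mean(np.diff(bout.step_times))

print(f"ground-truth steps : {len(truth.step_times)}")
print(f"detected steps     : {bout.steps}")
print(f"true mean step time: {true_step_time:.3f} s")
print(f"est. mean step time: {est_step_time:.3f} s")
print(f"step-time error    : {100 * abs(est_step_time - true_step_time) / true_step_time:.2f} %")
print()
print("The detector finds one band-channel maximum per step; a per-cent-level")
print("step-time error means the wrist signal timing tracks the true gait cycle.")
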