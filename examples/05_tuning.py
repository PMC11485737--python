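"""Auditory receptive fields: tone schedule -> trial averaging -> best frequency.

Simulates a tuned cell through a full 8-frequency x 3-level x 10-repeat
tone session and recovers its best frequency from the trial-averaged
receptive field.
"""

import numpy as np

from castream import synthetic, tuning

cfg = synthetic.SyntheticConfig(
    n_cells=1, duration_s=970.0, tuning_enabled=True, tuned_cells=(0,),
    tone_n_repeats=10, group_event_rate_hz=0.0,
    height=64, width=64, min_center_spacing_px=1.0,
)
gt = synthetic.generate_ground_truth(cfg, seed=8)
dff = synthetic.ground_truth_traces(gt)[:, 0]
dff = dff + np.random.default_rng(8).normal(0, 0.05, dff.size)

rf = tuning.ReceptiveField(0, list(gt.schedule.frequencies_hz), list(gt.schedule.levels_db))
for event, frames in tuning.assign_trials(gt.schedule, cfg.frame_rate, cfg.n_frames):
    tuning.update_receptive_field(rf, dff, event, frames)

print("frequency grid (kHz):",
      [round(float(f) / 1000, 1) for f in rf.frequencies_hz])
print("trials per grid cell:", int(rf.n_trials.min()), "-", int(rf.n_trials.max()))
print(rf.to_dataframe().round(3))
print(f"true BF  = {gt.best_frequency_hz[0] / 1000:.1f} kHz")
print(f"found BF = {tuning.best_frequency(rf) / 1000:.1f} kHz")
# The receptive field is the mean dF/F0 during each tone, averaged over
# repeats; the best frequency is the grid frequency of its maximal entry.
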