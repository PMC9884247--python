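"""Simulate a pursuit session and screen out saccade-contaminated trials.

Generates one synthetic participant (3 directions x 2 contrasts x 2 cue
blocks), injects occasional saccade-like transients, then applies the speed
thresholds (5 deg/s during fixation, 20 deg/s during pursuit).
"""

import numpy as np

from pursuitmvpa import SimulationConfig, generate_eye_traces, screen_saccades

config = SimulationConfig(n_trials_per_cell=20, saccade_rate=0.1, seed=0)
traces = generate_eye_traces(config)
report = screen_saccades(traces)

print(f"simulated trials : {len(traces)}")
print(f"kept after screen: {len(report.kept_trial_ids)}")
reasons = {}
for _, reason in report.rejected:
    reasons[reason] = reasons.get(reason, 0) + 1
print(f"rejections       : {reasons}")

tr = report.kept_traces(traces)[0]
print(f"\nexample trial {tr.trial_id}: target {tr.target_direction} deg, "
      f"cue {tr.cue_direction} deg, contrast {tr.contrast:.0%}, "
      f"true latency {tr.latency_true:.1f} ms")
print(f"peak eye speed: {tr.speed().max():.1f} deg/s "
      f"(approaches steady-state gain x 16 deg/s target speed)")
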