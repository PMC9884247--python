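"""Quantify cue attraction with rotated-trace distances (delta-delta-y).

Rotating every velocity trace by -30 deg maps the central direction onto
the horizontal axis; the vertical separation between the mean traces of the
0 and -60 deg groups (delta-y) then measures behavioral direction
discrimination. The cue pulls invalid-block traces together, so the
valid-minus-invalid difference (delta-delta-y) is positive — and larger at
12% contrast, where the target is less reliable relative to the cue.
"""

import numpy as np

from pursuitmvpa import SimulationConfig, generate_eye_traces, rotate_and_distance

config = SimulationConfig(n_trials_per_cell=100, seed=1)
traces = generate_eye_traces(config)

for contrast in (1.0, 0.12):
    sel = [t for t in traces if np.isclose(t.contrast, contrast)]
    res = rotate_and_distance(sel, rotation=-30.0, upper_dir=0.0, lower_dir=-60.0)
    print(f"contrast {contrast:>5.0%}: delta-delta-y at +100 ms post latency = "
          f"{res.value_at_100ms:.2f} deg/s "
          f"(mean latency {res.mean_latency['valid']:.0f} ms valid)")

print("\nA larger value at 12% contrast is the reliability-weighting "
      "signature: weak sensory evidence yields stronger cue attraction.")
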