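"""Cluster-based sign-flip permutation test on a group of time courses.

Fourteen simulated participants carry a 1-SD effect between 40 and 90 ms;
the test thresholds the pointwise one-sample t, sums t within contiguous
supra-threshold runs, and compares each cluster mass against the
permutation distribution of the maximum |mass| under participant-level
sign flips — controlling the family-wise error rate across time.
"""

import numpy as np

from pursuitmvpa import cluster_test

rng = np.random.default_rng(4)
traces = rng.normal(size=(14, 150))
traces[:, 40:91] += 1.0  # injected effect

res = cluster_test(traces, time=np.arange(150.0), threshold_p=0.05,
                   n_perm=5000, seed=0)
print(f"{len(res.clusters)} candidate cluster(s) at defining threshold "
      f"p < {res.threshold_p}")
for c in res.clusters:
    flag = "SIGNIFICANT" if c.p < 0.05 else "n.s."
    print(f"  {c.start_ms:>5.0f}-{c.end_ms:<5.0f} ms  sign {c.sign:+d}  "
          f"mass {c.mass:8.1f}  p = {c.p:.4f}  [{flag}]")
print("\nThe significant cluster should overlap the injected 40-90 ms window;"
      "\nisolated noise excursions stay non-significant.")
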