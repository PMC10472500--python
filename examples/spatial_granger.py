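"""Snapshot-based (spatial) Granger causality on coupled spatial series.

Generates two spatial autoregressive snapshot series with one-directional
coupling a -> b and shows that spatial GC recovers the direction, with an
F-test per snapshot.
"""

import numpy as np

from engramfield.spatial_gc import SnapshotSeries, gc_over_time
from engramfield.synthetic import make_coupled_spatial_pair

a, b = make_coupled_spatial_pair(
    n_points=32, direction="a_to_b", coupling=0.8,
    innovation_sd=1.0, n_snapshots=100, seed=3,
)
src = SnapshotSeries(a, label="a")
tgt = SnapshotSeries(b, label="b")
a2b, b2a = gc_over_time(src, tgt, p=1, alpha=0.05)

for res in (a2b, b2a):
    s = res.summary()
    print(f"{s['direction']:<6} mean strength {s['mean_strength']:.3f}  "
          f"CV {s['cv_percent']:5.1f}%  significant in "
          f"{100*s['fraction_significant']:.0f}% of snapshots")
print("directionality correct in",
      np.mean(a2b.strengths > b2a.strengths).round(2) * 100, "% of snapshots")
# The true (a -> b) direction has the larger strength in nearly every
# snapshot; the reverse direction sits at the 5% false-positive floor.
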