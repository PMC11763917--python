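"""Temporal concentration of saliency (EMD spikiness) and submodular pick.

Keeps the top 5% most salient entries of each map, collapses them onto the
time axis, and scores the distance of that profile from uniform: 0 means
saliency is spread evenly over time; (T-1)/2 means a single spike at an
endpoint. Then picks the most representative subjects by greedy coverage.
"""

import numpy as np

from arrowtime import (
    SaliencyMap,
    emd_spikiness,
    submodular_pick,
)

rng = np.random.default_rng(0)
T, N = 40, 6

flat = SaliencyMap("flat", rng.normal(size=(T, N)))          # scattered saliency
spiky_attr = 0.01 * rng.normal(size=(T, N))
spiky_attr[8] += 12.0                                         # one dominant time point
spiky = SaliencyMap("spiky", spiky_attr)

for s in (flat, spiky):
    print(f"{s.subject_id:>5}: EMD spikiness = {emd_spikiness(s, fraction=0.05):.2f} "
          f"(max possible {(T - 1) / 2:.1f})")

maps = [flat, spiky] + [
    SaliencyMap(f"s{i}", rng.normal(size=(T, N)) * (rng.random((T, N)) > 0.6))
    for i in range(4)
]
picks = submodular_pick(maps, budget=3)
print("submodular pick order:", [maps[i].subject_id for i in picks],
      "(subjects that together cover the most attribution-weighted features)")
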