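"""Microstate-locked parcel activity against a segment-preserving null.

Simulates parcel-level source magnitudes where one parcel is activated
whenever one microstate is present, then tests every (parcel, state) cell
with 1000 segment-preserving label shuffles at the |z| >= 3.6 criterion
(Bonferroni 0.05/204).
"""

import numpy as np

from megms import stats_rest, synth
from megms.containers import Segmentation

layout = synth.make_layout(32, seed=1)
maps = synth.make_topographies(6, layout, "meg", seed=2)
_, truth = synth.simulate_resting(layout, maps, 240.0, 250.0, seed=3)
labels = truth.label_sequence
seg = Segmentation(labels, np.ones(labels.size), np.ones(labels.size),
                   250.0, 6)

parcels = synth.simulate_parcels(
    labels, n_parcels=34,
    effect_table=[(10, 3, 1.0)],  # parcel 10 activates with state 3
    noise_sd=0.2, parcel_names=synth.schaefer_parcel_names(), seed=4,
)
res = stats_rest.parcel_permutation_test(parcels, seg, n_perm=1000,
                                         z_crit=3.6, seed=5)

hits = np.argwhere(res.mask)
print(f"cells tested: {res.z.size}, significant at |z|>=3.6: {len(hits)}")
for p, m in hits:
    print(f"  parcel {res.parcel_names[p]}  state {m + 1}  "
          f"z = {res.z[p, m]:.1f}")
# The injected (parcel 10, state 3) cell is strongly positive.  The same
# parcel's other states go mildly negative: the permutation null mixes the
# activated frames into every state, so states that never see the boost sit
# below their null mean.  Parcels without an effect stay well inside the
# 3.6-sigma band.
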