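"""Event-locked microstate statistics in an auditory oddball paradigm.

Simulates 612 standard and 55 deviant stimuli where deviance detection
boosts one microstate 150-300 ms after onset, builds detection-rate curves,
and computes the microstate mismatch statistic (deviant minus standard
detection rate in the window).
"""

import numpy as np

from megms import stats_evoked, synth
from megms.containers import MicrostateSet, Segmentation
from megms import fit

layout = synth.make_layout(32, seed=1)
maps = synth.make_topographies(6, layout, "meg", seed=2)
rec, events, truth = synth.simulate_evoked(
    layout, maps, n_std=612, n_dev=55, deviant_state=6, boost=0.8,
    fs=250.0, snr=10.0, seed=3,
)

templates = MicrostateSet(maps, "meg")
seg = fit.backfit(rec, templates)
seg = fit.smooth_labels(seg, rec, templates)

std = events.subset(events.std_preceding_deviant)
dev = events.subset(np.asarray(events.types) == "deviant")
curve_std = stats_evoked.detection_rate_curve(seg, std, "standard")
curve_dev = stats_evoked.detection_rate_curve(seg, dev, "deviant")
stat = stats_evoked.mms_mmn(curve_std, curve_dev, window_ms=(150, 300))

print(f"events: {events.n_events} total, {curve_dev.n_events} deviants")
print(f"peak in-window deviant detections of state 6: "
      f"{curve_dev.counts[6].max()} of {curve_dev.n_events}")
print("mismatch statistic per state (index 0 = unlabeled):")
print(np.round(stat, 3))
# The boosted state carries a clearly positive mismatch statistic; the
# remaining states compensate with negative values because exactly one
# label (or none) occupies each frame.
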