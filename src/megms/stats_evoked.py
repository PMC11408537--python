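"""Event-locked statistics: microstate detection-rate curves, the
microstate mismatch-negativity statistic (difference in detection rates
between deviant and standard stimuli), MMN peak amplitudes from
baseline-normalized parcel epochs, and the right-minus-left lateralization
score.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import DetectionRateCurve, EventSet, ParcelSeries, Segmentation
from .errors import InvalidArgumentError

__all__ = [
    "detection_rate_curve",
    "mms_mmn",
    "epoch_parcels",
    "mmn_peak",
    "lateralization_score",
]


def _epoch_frames(epoch_ms, fs: float):
    lo = int(round(epoch_ms[0] * fs / 1000.0))
    hi = int(round(epoch_ms[1] * fs / 1000.0))
    if hi <= lo:
        raise InvalidArgumentError("empty epoch window")
    return lo, hi


def detection_rate_curve(
    seg: Segmentation,
    events: EventSet,
    event_type: str,
    epoch_ms=(-200.0, 500.0),
) -> DetectionRateCurve:
    """Per-state counts of events labeled by each state at each epoch frame.

    Row 0 of ``counts`` holds the unlabeled class, so each column sums to
    ``n_events`` exactly.  Events whose epoch would run off the recording
    are dropped with a warning and excluded from ``n_events``.
    """
    lo, hi = _epoch_frames(epoch_ms, seg.fs)
    rel = np.arange(lo, hi)
    onsets = events.onsets[np.asarray(events.types) == event_type]
    ok = (onsets + lo >= 0) & (onsets + hi <= seg.n_frames)
    if not ok.all():
        warnings.warn(
            f"dropped {int((~ok).sum())} {event_type} events too close to the edge",
            stacklevel=2,
        )
    onsets = onsets[ok]
    K = seg.n_states
    counts = np.zeros((K + 1, rel.size), dtype=int)
    frame_idx = onsets[:, None] + rel[None, :]  # (n_events, n_rel)
    labs = seg.labels[frame_idx]
    for m in range(K + 1):
        counts[m] = (labs == m).sum(axis=0)
    times_ms = rel / seg.fs * 1000.0
    return DetectionRateCurve(counts, times_ms, len(onsets), seg.fs)


def _window_cols(curve: DetectionRateCurve, window_ms) -> np.ndarray:
    lo_f = int(np.ceil(window_ms[0] * curve.fs / 1000.0))
    hi_f = int(np.floor(window_ms[1] * curve.fs / 1000.0))
    rel = np.round(curve.times_ms * curve.fs / 1000.0).astype(int)
    cols = np.flatnonzero((rel >= lo_f) & (rel <= hi_f))
    if cols.size == 0:
        raise InvalidArgumentError("window empty after frame rounding")
    return cols


def mms_mmn(
    curve_std: DetectionRateCurve,
    curve_dev: DetectionRateCurve,
    window_ms=(150.0, 300.0),
) -> np.ndarray:
    """Deviant-minus-standard mean in-window detection rate per state.

    Counts are normalized per event so unequal event counts compare fairly.
    Index 0 is the unlabeled class; when event counts match, the statistic
    summed over all classes is zero (label conservation).
    """
    if curve_std.counts.shape[0] != curve_dev.counts.shape[0]:
        raise InvalidArgumentError("curves have different state sets")
    if curve_std.counts.shape[1] != curve_dev.counts.shape[1]:
        raise InvalidArgumentError("curves have different epoch grids")
    cols = _window_cols(curve_std, window_ms)
    mean_std = curve_std.counts[:, cols].mean(axis=1) / max(curve_std.n_events, 1)
    mean_dev = curve_dev.counts[:, cols].mean(axis=1) / max(curve_dev.n_events, 1)
    return mean_dev - mean_std


def epoch_parcels(
    ps: ParcelSeries, events: EventSet, epoch_ms=(-200.0, 500.0)
):
    """Cut a parcel series into event-locked epochs.

    Returns ``(epochs, kept_mask)`` with epochs of shape
    ``(n_parcels, n_events_kept, n_frames)``; events running off the
    recording are dropped (reflected in ``kept_mask``).
    """
    lo, hi = _epoch_frames(epoch_ms, ps.fs)
    rel = np.arange(lo, hi)
    ok = (events.onsets + lo >= 0) & (events.onsets + hi <= ps.n_frames)
    onsets = events.onsets[ok]
    idx = onsets[:, None] + rel[None, :]
    return ps.values[:, idx], ok


def mmn_peak(
    parcel_epochs: np.ndarray,
    types: np.ndarray,
    std_preceding: np.ndarray,
    fs: float,
    baseline_ms: float = 200.0,
    search_ms=(150.0, 300.0),
    direction: str = "standard_minus_deviant",
):
    """Per-region MMN peak amplitude from baseline-normalized epochs.

    ``parcel_epochs`` is (regions, epochs, frames) spanning
    (-baseline_ms, ...) around onset.  Each epoch/region is z-scored by its
    baseline mean/SD and rectified; deviants and the standards immediately
    preceding a deviant are averaged per type; the peak is the most
    prominent negative local minimum of the averaged-type difference inside
    the search window.  ``direction`` selects standard - deviant (default)
    or deviant - standard.  Zero-baseline-SD epochs are dropped with a
    warning.

    Returns ``(peaks, defined, n_dropped)`` with one entry per region;
    ``peaks`` is 0 where no negative excursion exists (``defined`` False).
    """
    x = np.asarray(parcel_epochs, dtype=float)
    if x.ndim != 3:
        raise InvalidArgumentError("parcel_epochs must be (regions, epochs, frames)")
    types = np.asarray(types)
    std_preceding = np.asarray(std_preceding, dtype=bool)
    R, E, F = x.shape
    if E != types.size:
        raise InvalidArgumentError("epoch/type length mismatch")
    if direction not in ("standard_minus_deviant", "deviant_minus_standard"):
        raise InvalidArgumentError("unknown direction")
    nb = int(round(baseline_ms * fs / 1000.0))
    mu = x[:, :, :nb].mean(axis=2, keepdims=True)
    sd = x[:, :, :nb].std(axis=2, keepdims=True)
    bad = (sd[:, :, 0] == 0).any(axis=0)  # any region with flat baseline
    n_dropped = int(bad.sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} epochs with zero baseline SD", stacklevel=2)
    sd[sd == 0] = 1.0
    z = np.abs((x - mu) / sd)
    keep = ~bad
    is_dev = (types == "deviant") & keep
    is_std = std_preceding & keep
    if not is_dev.any() or not is_std.any():
        raise InvalidArgumentError("both stimulus types must be present")
    avg_dev = z[:, is_dev].mean(axis=1)
    avg_std = z[:, is_std].mean(axis=1)
    diff = avg_std - avg_dev if direction == "standard_minus_deviant" else avg_dev - avg_std

    onset = nb  # epoch starts baseline_ms before onset
    lo = onset + int(np.ceil(search_ms[0] * fs / 1000.0))
    hi = onset + int(np.floor(search_ms[1] * fs / 1000.0))
    peaks = np.zeros(R)
    defined = np.zeros(R, dtype=bool)
    for r in range(R):
        best = 0.0
        for i in range(max(lo, 1), min(hi + 1, F - 1)):
            v = diff[r, i]
            if v < 0 and v <= diff[r, i - 1] and v <= diff[r, i + 1] and v < best:
                best = float(v)
        peaks[r] = best
        defined[r] = best < 0
    return peaks, defined, n_dropped


def lateralization_score(peak_right: float, peak_left: float) -> float:
    """Right-minus-left MMN peak difference.

    With negative-valued peaks, a more negative right peak yields a negative
    score (right-lateralized); positive scores indicate left lateralization.
    """
    if not (np.isfinite(peak_right) and np.isfinite(peak_left)):
        return float("nan")
    return float(peak_right - peak_left)
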