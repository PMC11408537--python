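"""Sensor-space preprocessing: planar combination, GFP, spatial filtering,
band filtering/resampling, and epoch-wise artifact rejection.

The canonical order for MEG is: filter/resample the signed gradiometer data,
then combine gradiometer pairs (`combine_planar`) to obtain nonnegative
field magnitudes.  Artifact rejection here is a documented, parameter-
transparent simplification of toolbox z-value routines: per-channel z-scores
over the whole recording, epoch score = max over frames of the channel-summed
|z|, epochs above threshold dropped.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import GfpSeries, Recording, SensorLayout
from .errors import EmptyResultError, InvalidArgumentError

__all__ = [
    "combine_planar",
    "gfp",
    "spatial_filter",
    "standard_filter_resample",
    "epoch_and_reject",
]


def combine_planar(grad_x: np.ndarray, grad_y: np.ndarray) -> np.ndarray:
    """Per-site planar-gradient magnitude: sqrt(gx^2 + gy^2), elementwise.

    Output is nonnegative and invariant to sign flips of either input.
    """
    grad_x = np.asarray(grad_x, dtype=float)
    grad_y = np.asarray(grad_y, dtype=float)
    if grad_x.shape != grad_y.shape:
        raise InvalidArgumentError("gradiometer matrices must share shape")
    return np.hypot(grad_x, grad_y)


def gfp(rec: Recording) -> GfpSeries:
    """Global field power per frame.

    EEG: spatial standard deviation across channels after removing the
    per-frame channel mean (the classic average-referenced GFP).  MEG
    (combined gradiometers): root-mean-square across channels with no mean
    subtraction — magnitudes have no reference to remove.
    """
    if rec.n_channels < 2:
        raise InvalidArgumentError("GFP needs at least 2 channels")
    if rec.modality == "eeg":
        return GfpSeries(rec.data.std(axis=0), "signed")
    return GfpSeries(np.sqrt(np.mean(rec.data**2, axis=0)), "positive")


def spatial_filter(rec: Recording, layout: SensorLayout) -> Recording:
    """Trimmed-mean spatial smoothing over each channel's 6-nearest patch.

    For every channel and frame, the 7-value set {channel, 6 neighbors} is
    sorted, one maximum and one minimum are dropped, and the mean of the
    remaining 5 replaces the channel value.  Removes isolated spatial
    outliers without widening the per-frame value range.
    """
    if layout.n_channels != rec.n_channels:
        raise InvalidArgumentError("layout does not cover the recording's channels")
    idx = np.column_stack([np.arange(rec.n_channels), layout.neighbor_table])
    patch = rec.data[idx]  # (C, 7, T)
    patch = np.sort(patch, axis=1)
    out = patch[:, 1:6, :].mean(axis=1)
    return Recording(out, rec.fs, rec.modality, rec.condition, rec.channel_names)


def standard_filter_resample(
    rec: Recording,
    notch_hz: float = 50.0,
    hp_hz: float = 1.0,
    lp_hz: float = 30.0,
    target_fs: float = 250.0,
    order: int = 4,
    notch_q: float = 30.0,
) -> Recording:
    """Zero-phase notch + band-pass filtering followed by resampling.

    Filters are IIR applied forward-backward (no phase distortion): a notch
    at ``notch_hz`` (power-grid hum) and a Butterworth band-pass
    [``hp_hz``, ``lp_hz``].  Resampling to ``target_fs`` uses polyphase
    filtering.  Meant for signed data (EEG or uncombined gradiometers);
    a band-passed signal is zero-mean, so combined-magnitude recordings
    should be filtered before combination.
    """
    if target_fs > rec.fs:
        raise InvalidArgumentError("target_fs must not exceed the recording fs")
    data = rec.data
    nyq = rec.fs / 2
    if notch_hz is not None and 0 < notch_hz < nyq:
        b, a = signal.iirnotch(notch_hz, notch_q, fs=rec.fs)
        data = signal.filtfilt(b, a, data, axis=1)
    sos = signal.butter(
        order, [hp_hz, lp_hz], btype="bandpass", fs=rec.fs, output="sos"
    )
    data = signal.sosfiltfilt(sos, data, axis=1)
    if target_fs != rec.fs:
        from fractions import Fraction

        frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=1)
    out = Recording.__new__(Recording)
    out.data = np.asarray(data, dtype=float)
    out.fs = float(target_fs)
    out.modality = rec.modality
    out.condition = rec.condition
    out.channel_names = list(rec.channel_names)
    return out


def epoch_and_reject(
    rec: Recording, epoch_s: float = 2.0, z_thresh: float = 20.0
):
    """Split into fixed epochs, drop artifact epochs, concatenate survivors.

    Per-channel z-scores are computed over the whole recording; an epoch's
    score is the maximum over its frames of the channel-summed |z|.  Epochs
    whose score exceeds ``z_thresh`` are rejected; the survivors are
    concatenated in temporal order.  Returns ``(Recording, report)`` where
    ``report`` is a list of dicts (epoch, score, kept).
    """
    n_ep_frames = int(round(epoch_s * rec.fs))
    n_epochs = rec.n_frames // n_ep_frames
    if n_epochs < 1:
        raise InvalidArgumentError("recording shorter than one epoch")
    mu = rec.data.mean(axis=1, keepdims=True)
    sd = rec.data.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = np.abs((rec.data - mu) / sd).sum(axis=0)  # channel-summed |z| per frame
    report = []
    kept = []
    for e in range(n_epochs):
        sl = slice(e * n_ep_frames, (e + 1) * n_ep_frames)
        score = float(z[sl].max())
        keep = score <= z_thresh
        report.append({"epoch": e, "score": score, "kept": bool(keep)})
        if keep:
            kept.append(rec.data[:, sl])
    if not kept:
        raise EmptyResultError("all epochs rejected")
    clean = np.concatenate(kept, axis=1)
    out = Recording(clean, rec.fs, rec.modality, rec.condition, rec.channel_names)
    return out, report
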