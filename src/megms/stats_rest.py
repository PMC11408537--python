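"""Resting-state statistics: segment-preserving permutation nulls for
parcel-level activity, paired condition contrasts with Bonferroni control,
the occipital alpha-change index, and Kendall rank correlations.

The permutation null randomizes *when* each microstate occurs while
preserving exactly how often and for how long it occurs: the label sequence
is run-length encoded (unlabeled stretches included) and the order of runs
is uniformly permuted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

from .containers import ParcelSeries, Recording, Segmentation
from .errors import InvalidArgumentError
from .preprocess import gfp as _gfp  # noqa: F401  (re-export convenience)

__all__ = [
    "segment_shuffle",
    "parcel_permutation_test",
    "ParcelPermutationGrid",
    "coverage_contrast",
    "alpha_change_index",
    "kendall_tau_b",
]


def _rle(labels: np.ndarray):
    labels = np.asarray(labels, dtype=int)
    edges = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [labels.size]])
    return labels[starts], ends - starts


def segment_shuffle(
    labels: np.ndarray, rng: np.random.Generator, return_runs: bool = False
):
    """Uniformly permute the order of label runs (unlabeled runs included).

    The per-label multisets of run counts and run durations are preserved
    exactly by construction; only the temporal order changes.  With
    ``return_runs`` the permuted ``(states, lengths)`` run list is returned
    alongside the concatenated sequence (same-label runs that land adjacent
    merge in the concatenated view but not in the run list).
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise InvalidArgumentError("empty label sequence")
    states, lengths = _rle(labels)
    perm = rng.permutation(states.size)
    out = np.repeat(states[perm], lengths[perm])
    if return_runs:
        return out, states[perm], lengths[perm]
    return out


@dataclass
class ParcelPermutationGrid:
    """Parcel x state permutation results (z-scores and significance mask)."""

    observed: np.ndarray  # (P, K)
    null_mean: np.ndarray
    null_sd: np.ndarray
    z: np.ndarray  # NaN where undefined
    mask: np.ndarray  # |z| >= z_crit (False where undefined)
    n_perm: int
    z_crit: float
    seed: int
    parcel_names: list[str]


def _state_means(values: np.ndarray, labels: np.ndarray, K: int) -> np.ndarray:
    """(P, K) mean parcel amplitude over frames labeled by each state."""
    onehot = np.zeros((labels.size, K))
    idx = labels > 0
    onehot[idx, labels[idx] - 1] = 1.0
    counts = onehot.sum(axis=0)
    sums = values @ onehot
    with np.errstate(invalid="ignore", divide="ignore"):
        return sums / counts


def parcel_permutation_test(
    ps: ParcelSeries,
    seg: Segmentation,
    n_perm: int = 1000,
    z_crit: float = 3.6,
    seed: int = 0,
) -> ParcelPermutationGrid:
    """Microstate-locked parcel activity against a segment-preserving null.

    The observed statistic for (parcel p, state m) is the mean of p's series
    over frames labeled m.  The null distribution comes from ``n_perm``
    segment shuffles of the labels; z = (observed - null mean) / null SD.
    Cells with zero null SD or states without labeled frames are flagged
    undefined (NaN z, excluded from the mask).
    """
    if ps.n_frames != seg.n_frames:
        raise InvalidArgumentError("parcel series and segmentation misaligned")
    K = seg.n_states
    rng = np.random.default_rng(seed)
    observed = _state_means(ps.values, seg.labels, K)
    null = np.empty((n_perm, ps.n_parcels, K))
    for i in range(n_perm):
        null[i] = _state_means(ps.values, segment_shuffle(seg.labels, rng), K)
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (observed - null_mean) / null_sd
    z[~np.isfinite(z)] = np.nan
    mask = np.where(np.isnan(z), False, np.abs(z) >= z_crit)
    return ParcelPermutationGrid(
        observed, null_mean, null_sd, z, mask, n_perm, z_crit, seed, ps.parcel_names
    )


@dataclass
class ContrastResult:
    """Per-state paired t-tests between two conditions."""

    t: np.ndarray
    p: np.ndarray
    cohen_d: np.ndarray
    significant: np.ndarray
    alpha_per_test: float  # exact Bonferroni fraction, e.g. 0.05/6


def coverage_contrast(
    cov_a: np.ndarray, cov_b: np.ndarray, alpha: float = 0.05
) -> ContrastResult:
    """Paired, microstate-specific t-tests of per-subject coverage vectors.

    The per-test alpha is Bonferroni-adjusted by the number of states tested
    and kept as the exact fraction (0.05/6 for six states).  Cohen's d is
    mean(diff)/SD(diff).  Zero-variance differences yield NaN (flagged, not
    significant).
    """
    cov_a = np.asarray(cov_a, dtype=float)
    cov_b = np.asarray(cov_b, dtype=float)
    if cov_a.shape != cov_b.shape or cov_a.ndim != 2:
        raise InvalidArgumentError("coverage matrices must be matching (n, K)")
    n, K = cov_a.shape
    if n < 3:
        raise InvalidArgumentError("need at least 3 paired subjects")
    alpha_per_test = alpha / K
    t = np.full(K, np.nan)
    p = np.full(K, np.nan)
    d = np.full(K, np.nan)
    for m in range(K):
        diff = cov_a[:, m] - cov_b[:, m]
        sd = diff.std(ddof=1)
        if sd == 0:
            if np.allclose(diff, 0):
                t[m], p[m], d[m] = 0.0, 1.0, 0.0
            continue
        res = stats.ttest_rel(cov_a[:, m], cov_b[:, m])
        t[m], p[m] = float(res.statistic), float(res.pvalue)
        d[m] = float(diff.mean() / sd)
    significant = np.where(np.isnan(p), False, p < alpha_per_test)
    return ContrastResult(t, p, d, significant, alpha_per_test)


@dataclass
class AlphaChangeResult:
    """Most prominent negative spectral-difference peak in the alpha band."""

    index: float
    freq_hz: float
    defined: bool


def _mean_occipital_spectrum(rec: Recording, channels: list, window_s: float):
    names = list(rec.channel_names)
    try:
        rows = [names.index(c) if isinstance(c, str) else int(c) for c in channels]
    except ValueError as err:
        raise InvalidArgumentError(f"unknown occipital channel: {err}") from err
    nper = int(round(window_s * rec.fs))
    f, pxx = sps.welch(
        rec.data[rows], fs=rec.fs, window="hann", nperseg=nper, noverlap=0,
        axis=-1, average="mean",
    )
    return f, pxx.mean(axis=0)


def alpha_change_index(
    roe: Recording,
    rce: Recording,
    occipital_channels: list,
    band=(8.0, 12.0),
    window_s: float = 2.0,
) -> AlphaChangeResult:
    """Occipital alpha-power change between eyes-open and eyes-closed rest.

    Power spectra are averaged periodograms over non-overlapping Hann
    windows (``window_s`` -> 0.5 Hz resolution at 2 s), averaged over the
    occipital channels.  The index is the value of the most prominent
    negative local minimum of ROE - RCE within the alpha band: eyes-closed
    alpha enhancement makes it negative.  With no negative excursion the
    index is 0 and ``defined`` is False.
    """
    if not occipital_channels:
        raise InvalidArgumentError("occipital channel list is empty")
    if roe.fs != rce.fs or roe.n_channels != rce.n_channels:
        raise InvalidArgumentError("recordings must share channels and fs")
    f, p_roe = _mean_occipital_spectrum(roe, occipital_channels, window_s)
    _, p_rce = _mean_occipital_spectrum(rce, occipital_channels, window_s)
    diff = p_roe - p_rce
    in_band = (f >= band[0]) & (f <= band[1])
    idx = np.flatnonzero(in_band)
    best_val, best_f = 0.0, np.nan
    for i in idx:
        left = diff[i - 1] if i > 0 else np.inf
        right = diff[i + 1] if i < diff.size - 1 else np.inf
        if diff[i] < 0 and diff[i] <= left and diff[i] <= right:
            if diff[i] < best_val:
                best_val, best_f = float(diff[i]), float(f[i])
    if best_val == 0.0:
        return AlphaChangeResult(0.0, np.nan, False)
    return AlphaChangeResult(best_val, best_f, True)


def kendall_tau_b(x, y):
    """Kendall's tau-b with tie correction; p from the normal approximation.

    Returns ``(tau_b, p)``; fully tied input yields ``(nan, nan)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be equal-length 1-D")
    if x.size < 3:
        raise InvalidArgumentError("need at least 3 observations")
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
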