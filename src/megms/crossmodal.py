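"""EEG-MEG cross-modal analyses: microstate label co-occurrence against a
segment-preserving permutation null, group-level association by mean
z-score, and cross-subject correlation of per-microstate global explained
variance with FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CooccurrenceGrid, Segmentation
from .errors import InvalidArgumentError
from .stats_rest import segment_shuffle

__all__ = [
    "cooccurrence_counts",
    "cooccurrence_permutation",
    "group_association",
    "gev_correlation",
    "GevCorrelationResult",
]


def _counts(labels_meg: np.ndarray, labels_eeg: np.ndarray, km: int, ke: int):
    combined = labels_meg * (ke + 1) + labels_eeg
    return np.bincount(combined, minlength=(km + 1) * (ke + 1)).reshape(km + 1, ke + 1)


def cooccurrence_counts(
    seg_meg: Segmentation, seg_eeg: Segmentation
) -> CooccurrenceGrid:
    """Joint MEG x EEG label counts over shared frames.

    ``counts[m, e]`` is the number of frames with MEG label m and EEG label
    e; index 0 is the unlabeled class on each axis.  The grid sums to the
    shared frame count.
    """
    if seg_meg.n_frames != seg_eeg.n_frames:
        raise InvalidArgumentError("segmentations must share frame count")
    grid = _counts(seg_meg.labels, seg_eeg.labels, seg_meg.n_states, seg_eeg.n_states)
    return CooccurrenceGrid(grid)


def cooccurrence_permutation(
    seg_meg: Segmentation,
    seg_eeg: Segmentation,
    n_perm: int = 10_000,
    seed: int = 0,
) -> CooccurrenceGrid:
    """Co-occurrence z-scores against a segment-preserving MEG null.

    The MEG label sequence is segment-shuffled (EEG held fixed); each
    shuffle preserves the MEG per-label run-count and run-duration
    multisets exactly.  Cells with zero null SD get NaN z.
    """
    if seg_meg.n_frames != seg_eeg.n_frames:
        raise InvalidArgumentError("segmentations must share frame count")
    km, ke = seg_meg.n_states, seg_eeg.n_states
    rng = np.random.default_rng(seed)
    observed = _counts(seg_meg.labels, seg_eeg.labels, km, ke).astype(float)
    null = np.empty((n_perm, km + 1, ke + 1))
    for i in range(n_perm):
        null[i] = _counts(segment_shuffle(seg_meg.labels, rng), seg_eeg.labels, km, ke)
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (observed - null_mean) / null_sd
    z[~np.isfinite(z)] = np.nan
    return CooccurrenceGrid(
        observed.astype(int), z, null_mean, null_sd, n_perm, seed
    )


def group_association(
    grids: list[CooccurrenceGrid], mean_z_crit: float = 3.0
):
    """Average per-subject co-occurrence z over subjects and apply the
    mean-z association rule.

    Returns ``(mean_z, mask)``; the unlabeled row/column (index 0) is kept
    in ``mean_z`` for reporting but always excluded from the association
    mask.
    """
    if not grids:
        raise InvalidArgumentError("need at least one subject grid")
    zs = np.stack([g.z for g in grids])
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells stay NaN
        mean_z = np.nanmean(zs, axis=0)
    mask = np.where(np.isnan(mean_z), False, mean_z > mean_z_crit)
    mask[0, :] = False
    mask[:, 0] = False
    return mean_z, mask


@dataclass
class GevCorrelationResult:
    """Cross-subject GEV correlations between MEG and EEG microstates."""

    r: np.ndarray  # (K_meg, K_eeg)
    p: np.ndarray
    q: np.ndarray  # Benjamini-Hochberg adjusted
    mask: np.ndarray  # positive and FDR-significant


def gev_correlation(
    gev_meg: np.ndarray, gev_eeg: np.ndarray, alpha: float = 0.05
) -> GevCorrelationResult:
    """Pearson correlations of per-subject GEV across modality state pairs.

    Benjamini-Hochberg FDR is applied across all K_meg x K_eeg cells; the
    mask flags cells that are both positive and FDR-significant.
    Zero-variance columns yield NaN cells excluded from correction.
    """
    gev_meg = np.asarray(gev_meg, dtype=float)
    gev_eeg = np.asarray(gev_eeg, dtype=float)
    if gev_meg.ndim != 2 or gev_eeg.ndim != 2 or gev_meg.shape[0] != gev_eeg.shape[0]:
        raise InvalidArgumentError("GEV matrices must be (n_subjects, K) with equal n")
    n = gev_meg.shape[0]
    if n < 4:
        raise InvalidArgumentError("need at least 4 subjects")
    km, ke = gev_meg.shape[1], gev_eeg.shape[1]
    r = np.full((km, ke), np.nan)
    p = np.full((km, ke), np.nan)
    for i in range(km):
        for j in range(ke):
            x, y = gev_meg[:, i], gev_eeg[:, j]
            if x.std() == 0 or y.std() == 0:
                continue
            res = stats.pearsonr(x, y)
            r[i, j], p[i, j] = float(res.statistic), float(res.pvalue)
    q = np.full_like(p, np.nan)
    finite = np.isfinite(p)
    if finite.any():
        _, q_flat, _, _ = multipletests(p[finite], alpha=alpha, method="fdr_bh")
        q[finite] = q_flat
    mask = np.where(np.isnan(q), False, (r > 0) & (q < alpha))
    return GevCorrelationResult(r, p, q, mask)
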