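"""Back-fitting microstate templates to recordings and temporal metrics.

Competitive fitting assigns each frame the template with the highest
mode-specific spatial similarity, provided it clears the similarity floor
(default 0.50); frames below the floor stay unlabeled (label 0).  Temporal
smoothing is the classic Besag-style relaxation: each labeled frame pays a
data cost 1 - sim^2 and earns a contiguity bonus proportional to how many
frames in its window already carry the candidate label.
"""

from __future__ import annotations

import numpy as np

from .containers import MicrostateSet, Recording, Segmentation, TemporalMetrics
from .errors import InvalidArgumentError, UndefinedGevError
from .cluster import similarity_matrix
from .preprocess import gfp as _gfp

__all__ = ["backfit", "smooth_labels", "extract_segments", "temporal_metrics"]


def _frame_similarities(rec: Recording, ms: MicrostateSet) -> np.ndarray:
    """(T, K) similarity of every frame to every template; zero-power frames
    get similarity 0 to everything (they cannot clear the floor)."""
    X = rec.data.T.copy()
    if ms.mode == "eeg":
        Xc = X - X.mean(axis=1, keepdims=True)
    else:
        Xc = X
    norms = np.linalg.norm(Xc, axis=1)
    ok = norms > 0
    S = np.zeros((X.shape[0], ms.k))
    if ok.any():
        S[ok] = similarity_matrix(X[ok], ms.maps, ms.mode)
    return S


def backfit(rec: Recording, ms: MicrostateSet, threshold: float = 0.50) -> Segmentation:
    """Competitive per-frame template assignment with a similarity floor.

    Label = argmax over templates of the spatial similarity (ties -> lowest
    template index); frames whose best similarity is below ``threshold``
    are left unlabeled (0).
    """
    if rec.n_channels != ms.n_channels:
        raise InvalidArgumentError("recording/template channel mismatch")
    S = _frame_similarities(rec, ms)
    best = np.argmax(S, axis=1)
    best_sim = S[np.arange(S.shape[0]), best]
    labels = np.where(best_sim >= threshold, best + 1, 0)
    sims = np.where(labels > 0, best_sim, 0.0)
    g = _gfp(rec).values
    return Segmentation(labels, sims, g, rec.fs, ms.k)


def smooth_labels(
    seg: Segmentation,
    rec: Recording,
    ms: MicrostateSet,
    half_window: int = 3,
    besag_lambda: float = 10.0,
    max_iter: int = 100,
) -> Segmentation:
    """Besag-style temporal smoothing of a labeled segmentation.

    For each labeled frame t the candidate cost is

        cost(t, m) = (1 - sim(t, m)^2) - (lambda / (2 b)) * N_m(t)

    where N_m(t) counts frames in [t-b, t+b] \\ {t} currently labeled m.
    Frames are relabeled synchronously to the argmin until a fixed point or
    ``max_iter`` sweeps.  Sub-threshold (unlabeled) frames are frozen: they
    neither change nor attract labels.  ``lambda = 0`` is the identity.
    """
    if half_window < 0 or besag_lambda < 0:
        raise InvalidArgumentError("half_window and besag_lambda must be >= 0")
    labels = seg.labels.copy()
    if besag_lambda == 0 or half_window == 0 or not (labels > 0).any():
        return Segmentation(labels, seg.sims.copy(), seg.gfp.copy(), seg.fs, seg.n_states)
    S = _frame_similarities(rec, ms)
    T, K = S.shape
    data_cost = 1.0 - S**2
    b = half_window
    lam = besag_lambda / (2.0 * b)
    labeled = labels > 0
    for _ in range(max_iter):
        onehot = np.zeros((T, K))
        idx = labels > 0
        onehot[idx, labels[idx] - 1] = 1.0
        # windowed counts via cumulative sums, excluding the frame itself
        cs = np.vstack([np.zeros((1, K)), np.cumsum(onehot, axis=0)])
        lo = np.clip(np.arange(T) - b, 0, T)
        hi = np.clip(np.arange(T) + b + 1, 0, T)
        counts = cs[hi] - cs[lo] - onehot
        cost = data_cost - lam * counts
        new = np.argmin(cost, axis=1) + 1
        new = np.where(labeled, new, 0)
        if np.array_equal(new, labels):
            break
        labels = new
    sims = np.where(labels > 0, S[np.arange(T), np.maximum(labels - 1, 0)], 0.0)
    return Segmentation(labels, sims, seg.gfp.copy(), seg.fs, seg.n_states)


def extract_segments(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs as ``(label, start_frame, length)`` with half-open spans;
    concatenating the runs reconstructs the input exactly."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        return []
    edges = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [labels.size]])
    return [(int(labels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def temporal_metrics(seg: Segmentation) -> TemporalMetrics:
    """Coverage, mean duration, occurrence rate and GEV per microstate.

    coverage_m  = fraction of frames labeled m (unlabeled completes to 1);
    duration_m  = mean run length of m, in ms;
    occurrence  = runs of m per second;
    GEV_m       = sum over frames labeled m of (gfp * sim)^2, over the
                  total sum of gfp^2; total GEV is the sum over states.
    """
    if seg.n_frames == 0:
        raise InvalidArgumentError("empty segmentation")
    T = seg.n_frames
    K = seg.n_states
    denom = float(np.sum(seg.gfp**2))
    if denom == 0:
        raise UndefinedGevError("zero total field power")
    coverage = np.zeros(K)
    mean_dur = np.zeros(K)
    occurrence = np.zeros(K)
    gev = np.zeros(K)
    runs = extract_segments(seg.labels)
    total_s = T / seg.fs
    for m in range(1, K + 1):
        sel = seg.labels == m
        coverage[m - 1] = sel.sum() / T
        lengths = [ln for lab, _, ln in runs if lab == m]
        if lengths:
            mean_dur[m - 1] = np.mean(lengths) / seg.fs * 1000.0
            occurrence[m - 1] = len(lengths) / total_s
        gev[m - 1] = float(np.sum((seg.gfp[sel] * seg.sims[sel]) ** 2)) / denom
    return TemporalMetrics(
        coverage=coverage,
        mean_duration_ms=mean_dur,
        occurrence_per_s=occurrence,
        gev=gev,
        gev_total=float(gev.sum()),
        unlabeled_fraction=float((seg.labels == 0).sum() / T),
    )
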