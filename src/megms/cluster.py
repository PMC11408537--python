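"""Microstate identification: GFP-peak extraction, polarity-aware modified
k-means, cluster-validity criteria and the meta-criterion, at individual and
group level.

Two similarity semantics drive everything here.  In EEG mode a topography's
polarity is meaningless, so similarity is the absolute Pearson correlation
after average-reference centering, and templates are updated as the first
principal eigenvector of the assigned maps (the classic modified k-means).
In MEG mode combined-gradiometer maps are nonnegative magnitudes without a
reference, so similarity is the plain uncentered cosine and templates are
normalized nonnegative means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import CriterionCurves, GfpSeries, MicrostateSet, Recording
from .errors import (
    InvalidArgumentError,
    SelectionError,
    UndefinedSimilarityError,
)
from .preprocess import gfp as _gfp

__all__ = [
    "find_gfp_peaks",
    "spatial_similarity",
    "similarity_matrix",
    "modified_kmeans",
    "compute_criteria",
    "meta_criterion",
    "two_level_clustering",
    "extract_peak_maps",
]


# ---------------------------------------------------------------------------
# peaks and similarity


def find_gfp_peaks(g: GfpSeries, min_separation_frames: int = 0) -> np.ndarray:
    """Indices of strict local maxima of the GFP series.

    Among maxima closer than ``min_separation_frames`` the larger one wins
    (greedy, descending value; ties resolved toward the earlier frame).
    """
    v = g.values
    if v.size < 3:
        raise InvalidArgumentError("series too short for peak detection")
    core = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
    peaks = np.flatnonzero(core) + 1
    if min_separation_frames > 1 and peaks.size:
        order = peaks[np.argsort(-v[peaks], kind="stable")]
        accepted: list[int] = []
        for p in order:
            if all(abs(p - q) >= min_separation_frames for q in accepted):
                accepted.append(int(p))
        peaks = np.sort(accepted)
    return np.asarray(peaks, dtype=int)


def _normalize_points(X: np.ndarray, mode: str) -> np.ndarray:
    """Center (EEG) and unit-normalize topographies row-wise."""
    X = np.asarray(X, dtype=float)
    if mode == "eeg":
        X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise UndefinedSimilarityError("zero-norm topography")
    return X / norms


def spatial_similarity(a: np.ndarray, b: np.ndarray, mode: str) -> float:
    """Mode-specific similarity between two topographies.

    EEG: |Pearson correlation| after centering (polarity ignored).
    MEG: uncentered cosine (data nonnegative; no absolute value needed).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise InvalidArgumentError("topographies must share length")
    A = _normalize_points(a[None, :], mode)
    B = _normalize_points(b[None, :], mode)
    s = float((A @ B.T).item())
    return abs(s) if mode == "eeg" else s


def similarity_matrix(X: np.ndarray, templates: np.ndarray, mode: str) -> np.ndarray:
    """(N, K) similarity of each row of X to each template, mode semantics."""
    Xn = _normalize_points(X, mode)
    Tn = _normalize_points(templates, mode)
    S = Xn @ Tn.T
    return np.abs(S) if mode == "eeg" else S


# ---------------------------------------------------------------------------
# modified k-means


def _update_template(cluster: np.ndarray, mode: str) -> np.ndarray:
    if mode == "eeg":
        # first principal eigenvector of the scatter: polarity-invariant mean
        scatter = cluster.T @ cluster
        vals, vecs = np.linalg.eigh(scatter)
        v = vecs[:, -1]
        v = v - v.mean()
        n = np.linalg.norm(v)
        if n == 0:
            return None
        return v / n
    m = cluster.mean(axis=0)
    m = np.clip(m, 0.0, None)
    n = np.linalg.norm(m)
    if n == 0:
        return None
    return m / n


def _init_plusplus(
    X: np.ndarray, k: int, mode: str, rng: np.random.Generator
) -> np.ndarray:
    """k-means++-style seeding in the mode-specific similarity geometry.

    The next seed is drawn with probability proportional to the squared
    distance (1 - sim^2 for EEG, 1 - sim for MEG) to the nearest seed so
    far, which makes restarts on tightly clustered data start from distinct
    clusters almost surely.
    """
    N = X.shape[0]
    chosen = [int(rng.integers(N))]
    d_min = None
    for _ in range(k - 1):
        s = (X @ X[chosen[-1]]).ravel()
        d = 1.0 - s**2 if mode == "eeg" else 1.0 - np.abs(s)
        d = np.clip(d, 0.0, None)
        d_min = d if d_min is None else np.minimum(d_min, d)
        w = d_min**2
        total = w.sum()
        if total <= 0:
            remaining = np.setdiff1d(np.arange(N), chosen)
            chosen.append(int(rng.choice(remaining)))
            continue
        chosen.append(int(rng.choice(N, p=w / total)))
    return np.array(chosen)


def modified_kmeans(
    peak_maps: np.ndarray,
    k: int,
    mode: str,
    n_restarts: int = 100,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int = 0,
):
    """Polarity-aware k-means on GFP-peak topographies.

    Points are unit-normalized (EEG: centered first).  Each iteration assigns
    every map to the template with the highest mode-specific similarity
    (ties -> lowest template index) and re-estimates templates (EEG: leading
    eigenvector; MEG: clamped normalized mean).  The objective is the mean
    squared similarity of maps to their assigned template ("explained
    variance" of unit-norm maps); iteration stops when its relative change
    falls below ``tol``.  The best of ``n_restarts`` seeded restarts wins.

    Returns ``(MicrostateSet, assignments, explained_variance)``.
    """
    X = _normalize_points(peak_maps, mode)
    N, C = X.shape
    if k > N:
        raise InvalidArgumentError("k cannot exceed the number of maps")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        templates = X[_init_plusplus(X, k, mode, rng)].copy()
        prev_ev = -np.inf
        for _ in range(max_iter):
            S = similarity_matrix(X, templates, mode)
            assign = np.argmax(S, axis=1)
            best_sim = S[np.arange(N), assign]
            ev = float(np.mean(best_sim**2))
            for j in range(k):
                members = X[assign == j]
                t = _update_template(members, mode) if len(members) else None
                if t is None:
                    # empty/degenerate cluster: reseed from the worst-fit map
                    t = X[int(np.argmin(best_sim))].copy()
                templates[j] = t
            if abs(ev - prev_ev) < tol * max(abs(prev_ev), 1e-12):
                break
            prev_ev = ev
        S = similarity_matrix(X, templates, mode)
        assign = np.argmax(S, axis=1)
        ev = float(np.mean(S[np.arange(N), assign] ** 2))
        if best is None or ev > best[2]:
            best = (templates.copy(), assign.copy(), ev)
    templates, assign, ev = best
    ms = MicrostateSet(templates, mode)
    return ms, assign, ev


# ---------------------------------------------------------------------------
# cluster-validity criteria


def _distance_matrix(X: np.ndarray, mode: str) -> np.ndarray:
    """Pairwise mode-specific distances: 1 - sim^2 (EEG), 1 - sim (MEG)."""
    S = similarity_matrix(X, X, mode)
    D = 1.0 - S**2 if mode == "eeg" else 1.0 - S
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, None)


def _pair_sample(N: int, max_pairs: int, rng: np.random.Generator):
    """All index pairs i<j, subsampled (seeded) beyond ``max_pairs``."""
    n_pairs = N * (N - 1) // 2
    iu = np.triu_indices(N, 1)
    if n_pairs <= max_pairs:
        return iu
    sel = rng.choice(n_pairs, size=max_pairs, replace=False)
    return iu[0][sel], iu[1][sel]


def _gamma(dist, same, rng):
    """Goodman-Kruskal Gamma over (within, between) distance pairs."""
    w = np.sort(dist[same])
    b = np.sort(dist[~same])
    if w.size == 0 or b.size == 0:
        return np.nan
    # s+ = #{(w_i, b_j): w_i < b_j}, s- = #{w_i > b_j}; ties count in neither
    less = b.size - np.searchsorted(b, w, side="right")
    greater = np.searchsorted(b, w, side="left")
    s_plus = float(less.sum())
    s_minus = float(greater.sum())
    denom = s_plus + s_minus
    return (s_plus - s_minus) / denom if denom > 0 else np.nan


def _silhouette(D, assign, k):
    N = D.shape[0]
    s = np.zeros(N)
    sizes = np.bincount(assign, minlength=k)
    sums = np.zeros((N, k))
    for j in range(k):
        sums[:, j] = D[:, assign == j].sum(axis=1)
    for i in range(N):
        own = assign[i]
        if sizes[own] <= 1:
            s[i] = 0.0
            continue
        a = sums[i, own] / (sizes[own] - 1)
        others = [sums[i, j] / sizes[j] for j in range(k) if j != own and sizes[j] > 0]
        if not others:
            s[i] = 0.0
            continue
        b = min(others)
        m = max(a, b)
        s[i] = (b - a) / m if m > 0 else 0.0
    return float(np.mean(s))


def _davies_bouldin(D, assign, k):
    """Medoid-based Davies-Bouldin on a precomputed distance matrix."""
    medoids, scatters = [], []
    for j in range(k):
        idx = np.flatnonzero(assign == j)
        if idx.size == 0:
            return np.nan
        sub = D[np.ix_(idx, idx)]
        m_local = int(np.argmin(sub.sum(axis=1)))
        medoids.append(idx[m_local])
        scatters.append(float(sub[m_local].mean()))
    db_terms = []
    for i in range(k):
        ratios = []
        for j in range(k):
            if i == j:
                continue
            m = D[medoids[i], medoids[j]]
            if m == 0:
                return np.nan
            ratios.append((scatters[i] + scatters[j]) / m)
        db_terms.append(max(ratios))
    return float(np.mean(db_terms))


def _point_biserial(dist, same):
    y = (~same).astype(float)  # 1 = different cluster
    if y.std() == 0 or dist.std() == 0:
        return np.nan
    return float(np.corrcoef(dist, y)[0, 1])


def _dunn(D, assign, k):
    between = np.inf
    diameter = 0.0
    for i in range(k):
        mi = assign == i
        if not mi.any():
            return np.nan
        diameter = max(diameter, float(D[np.ix_(mi, mi)].max()))
        for j in range(i + 1, k):
            mj = assign == j
            if mj.any():
                between = min(between, float(D[np.ix_(mi, mj)].min()))
    if diameter == 0:
        return np.nan
    return between / diameter


def _within_dispersion(D, assign, k):
    """W(k): sum over clusters of mean pairwise distance x cluster size / 2."""
    W = 0.0
    for j in range(k):
        idx = assign == j
        n = int(idx.sum())
        if n > 1:
            W += D[np.ix_(idx, idx)].sum() / (2 * n)
    return W


def compute_criteria(
    peak_maps: np.ndarray,
    assignments_by_k: dict,
    mode: str,
    max_pairs: int = 50_000,
    seed: int = 0,
) -> CriterionCurves:
    """Six cluster-validity curves over the evaluated k grid.

    All curves are oriented maximize-is-better (Davies-Bouldin negated).
    Gamma and Point-Biserial are computed on at most ``max_pairs`` seeded
    pairs; the others use the full distance matrix.  Krzanowski-Lai needs
    both grid neighbors and is NaN at the grid ends.  Degenerate geometry
    (zero Dunn denominator, zero-distance medoids, ...) yields NaN with a
    flag in ``degenerate``.
    """
    k_grid = np.array(sorted(assignments_by_k), dtype=int)
    X = _normalize_points(peak_maps, mode)
    N, C = X.shape
    D = _distance_matrix(X, mode)
    rng = np.random.default_rng(seed)
    ii, jj = _pair_sample(N, max_pairs, rng)
    dist = D[ii, jj]

    curves = {name: np.full(k_grid.size, np.nan) for name in CriterionCurves.CRITERIA}
    W = {}
    for pos, k in enumerate(k_grid):
        assign = np.asarray(assignments_by_k[k], dtype=int)
        if assign.shape != (N,):
            raise InvalidArgumentError(f"assignment for k={k} misaligned")
        same = assign[ii] == assign[jj]
        curves["gamma"][pos] = _gamma(dist, same, rng)
        curves["silhouette"][pos] = _silhouette(D, assign, k)
        db = _davies_bouldin(D, assign, k)
        curves["davies_bouldin"][pos] = -db if np.isfinite(db) else np.nan
        curves["point_biserial"][pos] = _point_biserial(dist, same)
        curves["dunn"][pos] = _dunn(D, assign, k)
        W[k] = _within_dispersion(D, assign, k)

    # Krzanowski-Lai: DIFF(k) = (k-1)^(2/C) W(k-1) - k^(2/C) W(k)
    diff = {}
    for k in k_grid:
        if k - 1 in W:
            diff[k] = (k - 1) ** (2 / C) * W[k - 1] - k ** (2 / C) * W[k]
    for pos, k in enumerate(k_grid):
        if k in diff and k + 1 in diff and diff[k + 1] != 0:
            curves["krzanowski_lai"][pos] = abs(diff[k]) / abs(diff[k + 1])

    degenerate = {name: ~np.isfinite(c) for name, c in curves.items()}
    return CriterionCurves(k_grid, curves, degenerate)


def meta_criterion(curves: CriterionCurves) -> int:
    """Consensus cluster count: the median over per-criterion optima.

    Each curve is min-max normalized to [0, 1]; the median curve is the
    elementwise median of the normalized curves.  The candidate set is the
    argmax k of each valid criterion plus the argmax of the median curve;
    the result is the median of these candidates, rounded half-down, snapped
    to the nearest grid value (lower on ties).
    """
    k_grid = curves.k_grid
    normalized = []
    candidates = []
    for name in CriterionCurves.CRITERIA:
        c = curves.curves.get(name)
        if c is None:
            continue
        finite = np.isfinite(c)
        if finite.sum() < 2:
            continue
        lo, hi = np.nanmin(c), np.nanmax(c)
        if hi == lo:
            continue  # flat curve carries no preference
        norm = (c - lo) / (hi - lo)
        normalized.append(norm)
        candidates.append(int(k_grid[np.nanargmax(norm)]))
    if len(candidates) < 2:
        raise SelectionError("fewer than 2 valid criterion curves")
    median_curve = np.nanmedian(np.vstack(normalized), axis=0)
    candidates.append(int(k_grid[np.nanargmax(median_curve)]))
    cand = np.sort(candidates)
    n = cand.size
    if n % 2:
        k_star = float(cand[n // 2])
    else:
        k_star = (cand[n // 2 - 1] + cand[n // 2]) / 2.0
    k_int = int(np.ceil(k_star - 0.5))  # round half-down
    # snap to grid, preferring the lower value on ties
    pos = int(np.argmin(np.abs(k_grid - k_int)))
    return int(k_grid[pos])


# ---------------------------------------------------------------------------
# end-to-end identification


def extract_peak_maps(
    rec: Recording,
    min_separation_frames: int = 0,
    max_maps: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Topographies at GFP peaks, optionally subsampled (seeded) to
    ``max_maps`` for tractability of the pairwise validity criteria."""
    peaks = find_gfp_peaks(_gfp(rec), min_separation_frames)
    maps = rec.data[:, peaks].T
    if max_maps is not None and maps.shape[0] > max_maps:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(maps.shape[0], size=max_maps, replace=False))
        maps = maps[keep]
    return maps


@dataclass
class IdentificationResult:
    microstates: MicrostateSet
    k: int
    curves: CriterionCurves
    explained_variance: float


def identify_microstates(
    peak_maps: np.ndarray,
    mode: str,
    k_grid=range(2, 13),
    n_restarts: int = 20,
    tol: float = 1e-6,
    seed: int = 0,
) -> IdentificationResult:
    """Cluster peak maps over ``k_grid`` and pick k by the meta-criterion."""
    k_grid = [int(k) for k in k_grid]
    results = {}
    assignments = {}
    for k in k_grid:
        ms, assign, ev = modified_kmeans(
            peak_maps, k, mode, n_restarts=n_restarts, tol=tol, seed=seed + k
        )
        results[k] = (ms, ev)
        assignments[k] = assign
    curves = compute_criteria(peak_maps, assignments, mode, seed=seed)
    k_opt = meta_criterion(curves)
    ms, ev = results[k_opt]
    return IdentificationResult(ms, k_opt, curves, ev)


def two_level_clustering(
    recordings: list[Recording],
    mode: str,
    k_grid=range(2, 13),
    n_restarts: int = 20,
    tol: float = 1e-6,
    min_separation_frames: int = 0,
    max_maps: int | None = 3000,
    seed: int = 0,
):
    """Individual-then-group microstate identification.

    Per subject: GFP-peak maps -> modified k-means with the subject-level
    meta-criterion k.  The pooled individual templates then feed a
    group-level k-means with its own meta-criterion.  With a single subject
    the group set is that subject's individual set.  Returns
    ``(group_set, subject_results)``.
    """
    if not recordings:
        raise InvalidArgumentError("need at least one recording")
    subject_results = []
    for s, rec in enumerate(recordings):
        try:
            peak_maps = extract_peak_maps(
                rec, min_separation_frames, max_maps, seed=seed + 1000 + s
            )
            res = identify_microstates(
                peak_maps, mode, k_grid, n_restarts, tol, seed=seed + s
            )
        except Exception as err:  # annotate with the subject index
            raise type(err)(f"subject {s}: {err}") from err
        subject_results.append(res)
    if len(subject_results) == 1:
        only = subject_results[0]
        group = MicrostateSet(only.microstates.maps.copy(), mode, provenance="group")
        return group, subject_results
    pooled = np.vstack([r.microstates.maps for r in subject_results])
    grid = [k for k in k_grid if k <= pooled.shape[0] - 1]
    group_res = identify_microstates(
        pooled, mode, grid, n_restarts, tol, seed=seed + 777
    )
    group = MicrostateSet(group_res.microstates.maps, mode, provenance="group")
    return group, subject_results
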