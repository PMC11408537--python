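"""Synthetic MEG/EEG data with known microstate structure.

The generator emulates the statistical structure the microstate model
assumes: a sequence of quasi-stable topographic states with dwell times in a
configurable range (default 50-150 ms), an amplitude envelope (default a
rectified 10 Hz sinusoid, mimicking alpha-band waxing and waning), and
modality-specific noise — signed, average-referenced noise for EEG versus a
nonnegative noise floor for combined-gradiometer MEG.  Event-locked variants
add deviant-stimulus perturbations in a post-onset window, and a parcel
simulator produces source-magnitude series with state-locked activations.

All randomness flows through one `numpy.random.Generator` seeded explicitly,
so every output is reproducible from its seed.
"""

from __future__ import annotations

import numpy as np

from .containers import EventSet, GroundTruth, ParcelSeries, Recording, SensorLayout
from .errors import GenerationError, InvalidArgumentError

__all__ = [
    "make_layout",
    "make_topographies",
    "simulate_resting",
    "simulate_evoked",
    "simulate_parcels",
    "simulate_paired_modalities",
]


# ---------------------------------------------------------------------------
# layout and template topographies


def make_layout(n_channels: int, seed: int = 0) -> SensorLayout:
    """Quasi-uniform sensor positions on the upper hemisphere of a unit sphere.

    Points follow a Fibonacci spiral restricted to z >= 0 with a small seeded
    angular jitter; each channel's six nearest neighbors (Euclidean) form the
    neighbor table used by the spatial filter.
    """
    if n_channels < 8:
        raise InvalidArgumentError("need at least 8 channels")
    rng = np.random.default_rng(seed)
    i = np.arange(n_channels)
    golden = (1 + 5**0.5) / 2
    # z in (0, 1]: upper hemisphere only
    z = 1.0 - i / n_channels
    theta = 2 * np.pi * i / golden + rng.uniform(0, 0.02, n_channels)
    r = np.sqrt(np.clip(1 - z**2, 0, None))
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    neighbors = np.argsort(d, axis=1, kind="stable")[:, :6]
    names = [f"ch{j:03d}" for j in range(n_channels)]
    return SensorLayout(names, pos, neighbors)


def _smooth_map(layout: SensorLayout, rng: np.random.Generator, mode: str) -> np.ndarray:
    """One smooth topography: a sum of Gaussian bumps over sensor positions."""
    pos = layout.positions
    n_bumps = rng.integers(2, 4)
    centers = pos[rng.choice(len(pos), size=n_bumps, replace=False)]
    widths = rng.uniform(0.35, 0.7, n_bumps)
    if mode == "meg":
        amps = rng.uniform(0.5, 1.5, n_bumps)
    else:
        amps = rng.uniform(0.5, 1.5, n_bumps) * rng.choice([-1.0, 1.0], n_bumps)
    d2 = ((pos[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    m = (amps * np.exp(-d2 / (2 * widths**2))).sum(axis=1)
    if mode == "eeg":
        m = m - m.mean()
    norm = np.linalg.norm(m)
    if norm == 0:
        raise GenerationError("degenerate zero map")
    return m / norm


def make_topographies(
    K: int,
    layout: SensorLayout,
    mode: str = "meg",
    seed: int = 0,
    max_abs_cosine: float = 0.7,
    max_retries: int = 500,
) -> np.ndarray:
    """K unit-norm template maps with pairwise |cosine| <= ``max_abs_cosine``.

    EEG maps are average-referenced (zero channel mean); MEG maps are
    elementwise nonnegative.  Maps violating the separation constraint are
    redrawn; after ``max_retries`` failed draws a :class:`GenerationError`
    is raised.
    """
    if K < 2:
        raise InvalidArgumentError("K must be >= 2")
    rng = np.random.default_rng(seed)
    maps: list[np.ndarray] = []
    tries = 0
    while len(maps) < K:
        cand = _smooth_map(layout, rng, mode)
        if all(abs(float(cand @ m)) <= max_abs_cosine for m in maps):
            maps.append(cand)
        else:
            tries += 1
            if tries > max_retries:
                raise GenerationError(
                    f"could not draw {K} maps with |cos| <= {max_abs_cosine}"
                )
    return np.array(maps)


# ---------------------------------------------------------------------------
# state-sequence machinery


def _coverage_to_pick_weights(w: np.ndarray) -> np.ndarray:
    """Invert the no-self-transition bias so run-state sampling weights v
    yield stationary coverage w.

    With next-state probabilities proportional to v (excluding the current
    state) and i.i.d. run durations, the stationary coverage of state i is
    proportional to v_i (1 - v_i).  Solving v_i (1 - v_i) = c * w_i by fixed
    point gives the sampling weights.  Coverages above 0.5 are unreachable
    without self-transitions; such targets saturate near 0.5.
    """
    if len(w) == 2:
        return np.array([0.5, 0.5])  # forced alternation
    v = w.copy()
    for _ in range(500):
        v_new = w / np.clip(1.0 - v, 1e-6, None)
        v_new = np.clip(v_new / v_new.sum(), 1e-9, 0.975)
        if np.max(np.abs(v_new - v)) < 1e-12:
            v = v_new
            break
        v = v_new
    return v / v.sum()


def _draw_runs(
    n_frames: int,
    lo_f: int,
    hi_f: int,
    weights: np.ndarray,
    rng: np.random.Generator,
):
    """Run states/lengths summing exactly to ``n_frames``.

    Durations are uniform on [lo_f, hi_f] frames; successive states are drawn
    from ``weights`` with no immediate self-transition.  The tail is closed by
    merging the remainder into the final run when that stays <= hi_f, or by
    splitting the final stretch into two in-range runs, so every run respects
    the bounds exactly.
    """
    K = len(weights)
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0 or np.any(w < 0):
        raise InvalidArgumentError("coverage weights must be nonnegative, not all zero")
    w = _coverage_to_pick_weights(w / w.sum())
    states: list[int] = []
    lengths: list[int] = []
    total = 0
    prev = -1
    while total < n_frames:
        remaining = n_frames - total
        if remaining <= hi_f:
            if remaining >= lo_f:
                length = remaining
            elif lengths and lengths[-1] + remaining <= hi_f:
                lengths[-1] += remaining
                break
            elif not lengths:
                # recording shorter than one minimal dwell: single short run
                states.append(_pick_state(w, prev, K, rng))
                lengths.append(remaining)
                break
            else:
                # split previous run + remainder into two in-range runs
                pool = (lengths.pop() if lengths else 0) + remaining
                if lengths:
                    prev_state = states.pop()
                else:
                    prev_state = _pick_state(w, prev, K, rng)
                half = pool // 2
                half = int(np.clip(half, lo_f, hi_f))
                other = pool - half
                other = int(np.clip(other, lo_f, hi_f))
                half = pool - other
                states.append(prev_state)
                lengths.append(half)
                nxt = _pick_state(w, prev_state, K, rng)
                states.append(nxt)
                lengths.append(other)
                break
        else:
            length = int(rng.integers(lo_f, hi_f + 1))
        s = _pick_state(w, prev, K, rng)
        states.append(s)
        lengths.append(length)
        total += length
        prev = s
    return np.array(states, dtype=int), np.array(lengths, dtype=int)


def _pick_state(w: np.ndarray, prev: int, K: int, rng: np.random.Generator) -> int:
    p = w.copy()
    if 0 <= prev < K and p.sum() - p[prev] > 0:
        p[prev] = 0.0
    p = p / p.sum()
    return int(rng.choice(K, p=p))


def _label_sequence(
    n_frames: int,
    fs: float,
    dwell_ms_range,
    weights,
    rng: np.random.Generator,
) -> np.ndarray:
    lo, hi = dwell_ms_range
    if not lo < hi:
        raise InvalidArgumentError("dwell range must satisfy lo < hi")
    lo_f = max(1, int(round(lo * fs / 1000)))
    hi_f = max(lo_f + 1, int(round(hi * fs / 1000)))
    states, lengths = _draw_runs(n_frames, lo_f, hi_f, np.asarray(weights), rng)
    return np.repeat(states + 1, lengths)  # labels are 1-based


def _envelope(n_frames: int, fs: float, envelope_hz: float, rng) -> np.ndarray:
    t = np.arange(n_frames) / fs
    phase = rng.uniform(0, 2 * np.pi)
    return np.abs(np.sin(2 * np.pi * envelope_hz * t + phase))


def _synthesize(
    maps: np.ndarray,
    labels: np.ndarray,
    envelope: np.ndarray,
    mode: str,
    snr: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Frame t = envelope(t) * map_{L(t)} + modality-specific noise."""
    K, C = maps.shape
    T = labels.size
    clean = envelope[None, :] * maps[labels - 1].T  # labels are 1..K here
    if mode == "eeg":
        # random polarity per run: microstate analysis ignores polarity
        run_edges = np.flatnonzero(np.diff(labels)) + 1
        signs = np.empty(T)
        start = 0
        for edge in list(run_edges) + [T]:
            signs[start:edge] = rng.choice([-1.0, 1.0])
            start = edge
        clean = clean * signs[None, :]
    if np.isinf(snr):
        noise = np.zeros_like(clean)
    else:
        if not snr > 0:
            raise InvalidArgumentError("snr must be positive")
        signal_rms = np.sqrt(np.mean(clean**2))
        sd = signal_rms / snr if signal_rms > 0 else 1.0 / snr
        noise = rng.normal(0.0, sd, size=clean.shape)
        if mode == "meg":
            noise = np.abs(noise)  # nonnegative noise floor
    data = clean + noise
    if mode == "eeg":
        data = data - data.mean(axis=0, keepdims=True)  # average reference
    return data


# ---------------------------------------------------------------------------
# public simulators


def simulate_resting(
    layout: SensorLayout,
    maps: np.ndarray,
    duration_s: float = 240.0,
    fs: float = 250.0,
    dwell_ms_range=(50.0, 150.0),
    snr: float = 10.0,
    envelope_hz: float = 10.0,
    coverage_weights=None,
    mode: str = "meg",
    seed: int = 0,
    condition: str = "ROE",
):
    """Resting-state recording driven by a hidden microstate sequence.

    Returns ``(Recording, GroundTruth)``.  Dwell times are uniform on
    ``dwell_ms_range`` (ms); the amplitude envelope is a rectified sinusoid
    at ``envelope_hz``; ``snr`` is the clean-signal RMS over the noise SD.
    """
    if not fs > 0:
        raise InvalidArgumentError("fs must be positive")
    rng = np.random.default_rng(seed)
    K = maps.shape[0]
    if coverage_weights is None:
        coverage_weights = np.full(K, 1.0 / K)
    coverage_weights = np.asarray(coverage_weights, dtype=float)
    n_frames = int(round(duration_s * fs))
    labels = _label_sequence(n_frames, fs, dwell_ms_range, coverage_weights, rng)
    env = _envelope(n_frames, fs, envelope_hz, rng)
    data = _synthesize(maps, labels, env, mode, snr, rng)
    rec = Recording(data, fs, mode, condition, list(layout.channel_names))
    gt = GroundTruth(maps, labels, env, coverage_weights / coverage_weights.sum(), seed)
    return rec, gt


def make_event_schedule(
    n_std: int, n_dev: int, rng: np.random.Generator
) -> np.ndarray:
    """Pseudorandom standard/deviant order: starts with a standard and never
    places two deviants back to back (so every deviant has a preceding
    standard, as the peak-amplitude analysis requires)."""
    if n_dev >= n_std:
        raise InvalidArgumentError("need more standards than deviants")
    n = n_std + n_dev
    # choose deviant slots among positions 1..n-1 with no two adjacent
    while True:
        slots = np.sort(rng.choice(np.arange(1, n), size=n_dev, replace=False))
        if n_dev < 2 or np.all(np.diff(slots) > 1):
            break
    types = np.array(["standard"] * n, dtype=object)
    types[slots] = "deviant"
    return types


def simulate_evoked(
    layout: SensorLayout,
    maps: np.ndarray,
    n_std: int = 612,
    n_dev: int = 55,
    isi_ms: float = 500.0,
    deviant_state: int = 1,
    boost_window_ms=(150.0, 300.0),
    boost: float = 1.0,
    fs: float = 250.0,
    snr: float = 10.0,
    dwell_ms_range=(50.0, 150.0),
    envelope_hz: float = 10.0,
    mode: str = "meg",
    seed: int = 0,
    lead_s: float = 1.0,
    tail_s: float = 1.0,
):
    """Oddball-paradigm recording with a stimulus-locked state perturbation.

    After each deviant onset, with probability ``boost`` per event, frames in
    ``boost_window_ms`` are relabeled to ``deviant_state`` before the signal
    is synthesized — emulating deviance detection raising one microstate's
    prevalence in the 150-300 ms window.  Standards keep baseline dynamics.

    Returns ``(Recording, EventSet, GroundTruth)``.
    """
    K = maps.shape[0]
    if not 1 <= deviant_state <= K:
        raise InvalidArgumentError("deviant_state must be a valid 1-based state index")
    if not 0.0 <= boost <= 1.0:
        raise InvalidArgumentError("boost must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_events = n_std + n_dev
    soa_f = int(round(isi_ms * fs / 1000))
    n_frames = int(round(lead_s * fs)) + n_events * soa_f + int(round(tail_s * fs))
    onsets = int(round(lead_s * fs)) + np.arange(n_events) * soa_f
    types = make_event_schedule(n_std, n_dev, rng)
    if onsets[-1] + int(round(boost_window_ms[1] * fs / 1000)) >= n_frames:
        raise InvalidArgumentError("events overlap recording end")

    labels = _label_sequence(n_frames, fs, dwell_ms_range, np.full(K, 1 / K), rng)
    w_lo = int(np.ceil(boost_window_ms[0] * fs / 1000))
    w_hi = int(np.floor(boost_window_ms[1] * fs / 1000))
    for onset, typ in zip(onsets, types):
        if typ == "deviant" and rng.random() < boost:
            labels[onset + w_lo : onset + w_hi + 1] = deviant_state

    env = _envelope(n_frames, fs, envelope_hz, rng)
    data = _synthesize(maps, labels, env, mode, snr, rng)
    rec = Recording(data, fs, mode, "MMN", list(layout.channel_names))

    preceding = np.zeros(n_events, dtype=bool)
    is_std = types == "standard"
    preceding[:-1] = is_std[:-1] & (types[1:] == "deviant")
    events = EventSet(onsets, types, preceding)
    gt = GroundTruth(maps, labels, env, np.full(K, 1.0 / K), seed)
    return rec, events, gt


def simulate_parcels(
    labels: np.ndarray,
    n_parcels: int,
    effect_table=(),
    noise_sd: float = 0.2,
    baseline: float = 1.0,
    fs: float = 250.0,
    parcel_names=None,
    seed: int = 0,
) -> ParcelSeries:
    """Parcel-level source-magnitude series locked to a label sequence.

    ``values[p, t] = baseline + delta(p, L(t)) + noise``, clipped at zero.
    ``effect_table`` is an iterable of ``(parcel_index, state, delta)``
    triples (state is 1-based); an unknown state raises.
    """
    if n_parcels < 1:
        raise InvalidArgumentError("n_parcels must be >= 1")
    labels = np.asarray(labels, dtype=int)
    K = int(labels.max(initial=0))
    rng = np.random.default_rng(seed)
    T = labels.size
    values = np.full((n_parcels, T), float(baseline))
    for parcel, state, delta in effect_table:
        if not np.isfinite(delta):
            raise InvalidArgumentError("delta must be finite")
        if not 1 <= state <= K:
            raise InvalidArgumentError(f"unknown state {state} in effect_table")
        if not 0 <= parcel < n_parcels:
            raise InvalidArgumentError(f"parcel {parcel} out of range")
        values[parcel, labels == state] += delta
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, size=values.shape)
    values = np.clip(values, 0.0, None)
    if parcel_names is None:
        parcel_names = [f"parcel{p:02d}" for p in range(n_parcels)]
    return ParcelSeries(values, list(parcel_names), fs)


def schaefer_parcel_names() -> list[str]:
    """The 34 parcel names of a 17-network x 2-hemisphere parcellation."""
    networks = [
        "VisCent", "VisPeri", "SomMotA", "SomMotB", "DorsAttnA", "DorsAttnB",
        "SalVentAttnA", "SalVentAttnB", "LimbicA", "LimbicB", "ContA", "ContB",
        "ContC", "DefaultA", "DefaultB", "DefaultC", "TempPar",
    ]
    return [f"{h}_{n}" for h in ("LH", "RH") for n in networks]


def simulate_paired_modalities(
    layout_meg: SensorLayout,
    layout_eeg: SensorLayout,
    maps_meg: np.ndarray,
    maps_eeg: np.ndarray,
    duration_s: float = 300.0,
    fs: float = 250.0,
    dwell_ms_range=(50.0, 150.0),
    snr: float = 10.0,
    envelope_hz: float = 10.0,
    coupling: float = 0.0,
    seed: int = 0,
):
    """Simultaneous MEG + EEG recordings with a controllable label coupling.

    ``coupling=1`` drives both modalities from one label sequence (distinct
    map sets, index-paired); ``coupling=0`` uses independent sequences.
    Intermediate values copy the MEG labels over each EEG run with that
    probability.  Returns ``(rec_meg, rec_eeg, (gt_meg, gt_eeg))``.
    """
    if not 0.0 <= coupling <= 1.0:
        raise InvalidArgumentError("coupling must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    K_meg, K_eeg = maps_meg.shape[0], maps_eeg.shape[0]
    n_frames = int(round(duration_s * fs))
    labels_meg = _label_sequence(
        n_frames, fs, dwell_ms_range, np.full(K_meg, 1 / K_meg), rng
    )
    labels_eeg = _label_sequence(
        n_frames, fs, dwell_ms_range, np.full(K_eeg, 1 / K_eeg), rng
    )
    if coupling > 0:
        if K_eeg < K_meg:
            raise InvalidArgumentError("coupling requires K_eeg >= K_meg")
        edges = np.flatnonzero(np.diff(labels_eeg)) + 1
        bounds = np.concatenate([[0], edges, [n_frames]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            if rng.random() < coupling:
                labels_eeg[a:b] = labels_meg[a:b]
    env = _envelope(n_frames, fs, envelope_hz, rng)
    data_meg = _synthesize(maps_meg, labels_meg, env, "meg", snr, rng)
    data_eeg = _synthesize(maps_eeg, labels_eeg, env, "eeg", snr, rng)
    rec_meg = Recording(data_meg, fs, "meg", "ROE", list(layout_meg.channel_names))
    rec_eeg = Recording(data_eeg, fs, "eeg", "ROE", list(layout_eeg.channel_names))
    gt_meg = GroundTruth(maps_meg, labels_meg, env, np.full(K_meg, 1 / K_meg), seed)
    gt_eeg = GroundTruth(maps_eeg, labels_eeg, env, np.full(K_eeg, 1 / K_eeg), seed)
    return rec_meg, rec_eeg, (gt_meg, gt_eeg)
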