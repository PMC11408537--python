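"""Core in-memory containers shared across the pipeline.

The analysis treats two sensor modalities:

``"meg"``
    Combined planar gradiometers — nonnegative field magnitudes, no
    reference, polarity meaningless by construction.
``"eeg"``
    Average-referenced electric potentials — signed, polarity ignored
    during clustering and fitting.
``"grad"``
    Signed planar-gradiometer data *before* pairwise combination; only the
    preprocessing stage consumes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

MODALITIES = ("meg", "eeg", "grad")


def _as_2d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise InvalidArgumentError(f"{name} must be 2-D, got shape {arr.shape}")
    return arr


@dataclass
class SensorLayout:
    """Sensor positions on a unit-sphere scalp plus a 6-nearest-neighbor table."""

    channel_names: list[str]
    positions: np.ndarray  # (C, 3)
    neighbor_table: np.ndarray  # (C, 6) int indices

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.neighbor_table = np.asarray(self.neighbor_table, dtype=int)
        n = len(self.channel_names)
        if len(set(self.channel_names)) != n:
            raise InvalidArgumentError("channel names must be unique")
        if self.positions.shape != (n, 3):
            raise InvalidArgumentError("positions must be (n_channels, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise InvalidArgumentError("positions must be finite")
        if self.neighbor_table.shape != (n, 6):
            raise InvalidArgumentError("neighbor_table must be (n_channels, 6)")
        if any(c in row for c, row in enumerate(self.neighbor_table)):
            raise InvalidArgumentError("neighbor_table must not be self-referential")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


@dataclass
class Recording:
    """Continuous multichannel sensor data (channels x frames)."""

    data: np.ndarray
    fs: float
    modality: str
    condition: str = ""
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = _as_2d_float(self.data, "data")
        if self.modality not in MODALITIES:
            raise InvalidArgumentError(f"modality must be one of {MODALITIES}")
        if not self.fs > 0:
            raise InvalidArgumentError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise InvalidArgumentError("data contains NaN or Inf")
        if self.modality == "meg" and self.data.size and self.data.min() < -1e-12:
            raise InvalidArgumentError(
                "combined-gradiometer (meg) data must be nonnegative"
            )
        if self.channel_names is None:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        elif len(self.channel_names) != self.data.shape[0]:
            raise InvalidArgumentError("channel_names length mismatch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fs


@dataclass
class GfpSeries:
    """Per-frame global field power; ``mode`` records how it was computed."""

    values: np.ndarray
    mode: str  # "signed" (EEG spatial SD) | "positive" (MEG RMS)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InvalidArgumentError("GFP values must be 1-D")
        if self.values.size and self.values.min() < 0:
            raise InvalidArgumentError("GFP values must be nonnegative")


@dataclass
class GroundTruth:
    """What the synthetic generator actually embedded in a recording."""

    true_maps: np.ndarray  # (K, C)
    label_sequence: np.ndarray  # (T,) ints in 0..K
    envelope: np.ndarray  # (T,) nonnegative
    coverage_targets: np.ndarray  # (K,)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.true_maps = _as_2d_float(self.true_maps, "true_maps")
        self.label_sequence = np.asarray(self.label_sequence, dtype=int)
        self.envelope = np.asarray(self.envelope, dtype=float)
        self.coverage_targets = np.asarray(self.coverage_targets, dtype=float)


@dataclass
class MicrostateSet:
    """K unit-norm template topographies plus the clustering mode behind them."""

    maps: np.ndarray  # (K, C)
    mode: str  # "meg" | "eeg"
    provenance: str = "individual"  # "individual" | "group"

    def __post_init__(self) -> None:
        self.maps = _as_2d_float(self.maps, "maps")
        if self.mode not in ("meg", "eeg"):
            raise InvalidArgumentError("mode must be 'meg' or 'eeg'")
        norms = np.linalg.norm(self.maps, axis=1)
        if self.maps.size and not np.allclose(norms, 1.0, atol=1e-6):
            raise InvalidArgumentError("maps must have unit Euclidean norm")
        if self.mode == "meg" and self.maps.size and self.maps.min() < -1e-12:
            raise InvalidArgumentError("meg-mode maps must be nonnegative")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass
class Segmentation:
    """Per-frame microstate labeling: 0 = unlabeled, 1..K = template index."""

    labels: np.ndarray
    sims: np.ndarray
    gfp: np.ndarray
    fs: float
    n_states: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.sims = np.asarray(self.sims, dtype=float)
        self.gfp = np.asarray(self.gfp, dtype=float)
        if not (self.labels.shape == self.sims.shape == self.gfp.shape):
            raise InvalidArgumentError("labels, sims, gfp must share shape")
        if self.labels.size:
            if self.labels.min() < 0 or self.labels.max() > self.n_states:
                raise InvalidArgumentError("labels must lie in [0, n_states]")

    @property
    def n_frames(self) -> int:
        return self.labels.size


@dataclass
class TemporalMetrics:
    """Coverage, mean duration, occurrence rate and GEV per microstate."""

    coverage: np.ndarray  # (K,)
    mean_duration_ms: np.ndarray  # (K,)
    occurrence_per_s: np.ndarray  # (K,)
    gev: np.ndarray  # (K,)
    gev_total: float
    unlabeled_fraction: float


@dataclass
class ParcelSeries:
    """Nonnegative parcel x time source-magnitude series."""

    values: np.ndarray
    parcel_names: list[str]
    fs: float

    def __post_init__(self) -> None:
        self.values = _as_2d_float(self.values, "values")
        if self.values.size and self.values.min() < 0:
            raise InvalidArgumentError("parcel magnitudes must be nonnegative")
        if len(self.parcel_names) != self.values.shape[0]:
            raise InvalidArgumentError("parcel_names length mismatch")

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class EventSet:
    """Stimulus onsets (frame indices) with per-event types and selection flags."""

    onsets: np.ndarray
    types: np.ndarray  # array of "standard" / "deviant"
    std_preceding_deviant: np.ndarray  # bool, true for standards right before a deviant

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=int)
        self.types = np.asarray(self.types, dtype=object)
        self.std_preceding_deviant = np.asarray(self.std_preceding_deviant, dtype=bool)
        if not (len(self.onsets) == len(self.types) == len(self.std_preceding_deviant)):
            raise InvalidArgumentError("event fields must share length")
        if self.onsets.size > 1 and np.any(np.diff(self.onsets) <= 0):
            raise InvalidArgumentError("onsets must be strictly increasing")

    @property
    def n_events(self) -> int:
        return len(self.onsets)

    def subset(self, mask: np.ndarray) -> "EventSet":
        mask = np.asarray(mask, dtype=bool)
        return EventSet(
            self.onsets[mask], self.types[mask], self.std_preceding_deviant[mask]
        )


@dataclass
class PermutationResult:
    """Observed statistic against a permutation null summarised as a z-score."""

    observed: float
    null_mean: float
    null_sd: float
    z: float
    n_perm: int
    seed: int | None = None

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.z))


@dataclass
class CriterionCurves:
    """Cluster-validity scores over a grid of candidate cluster counts.

    All curves are stored maximize-is-better (Davies-Bouldin is negated).
    """

    k_grid: np.ndarray
    curves: dict  # criterion name -> np.ndarray aligned with k_grid
    degenerate: dict = field(default_factory=dict)  # name -> bool mask of NaN flags

    CRITERIA = (
        "gamma",
        "silhouette",
        "davies_bouldin",
        "point_biserial",
        "dunn",
        "krzanowski_lai",
    )

    def __post_init__(self) -> None:
        self.k_grid = np.asarray(self.k_grid, dtype=int)
        for name, c in self.curves.items():
            c = np.asarray(c, dtype=float)
            if c.shape != self.k_grid.shape:
                raise InvalidArgumentError(f"curve {name} misaligned with k_grid")
            self.curves[name] = c


@dataclass
class DetectionRateCurve:
    """Counts of events labeled by each state at each epoch-relative frame.

    Row 0 counts unlabeled frames; row m counts state m.
    """

    counts: np.ndarray  # (K+1, n_rel_frames)
    times_ms: np.ndarray  # (n_rel_frames,)
    n_events: int
    fs: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.counts.shape[1] != self.times_ms.size:
            raise InvalidArgumentError("counts/times_ms misaligned")
        if self.counts.size and (
            self.counts.min() < 0 or self.counts.max() > self.n_events
        ):
            raise InvalidArgumentError("counts must lie in [0, n_events]")


@dataclass
class CooccurrenceGrid:
    """MEG x EEG label co-occurrence counts with permutation z-scores.

    Index 0 on each axis is the unlabeled class.
    """

    counts: np.ndarray  # (K_meg+1, K_eeg+1)
    z: np.ndarray | None = None
    null_mean: np.ndarray | None = None
    null_sd: np.ndarray | None = None
    n_perm: int = 0
    seed: int | None = None
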