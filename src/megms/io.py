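"""File formats and configuration.

Recordings round-trip through BrainVision triplets (``.vhdr``/``.vmrk``/
``.eeg``; binary multiplexed IEEE float 32 or vectorized ASCII — both read
back through MNE) or through CSV matrices with a sampling-rate header line.
Templates, segmentations, events and metrics use CSV/TSV/JSON.  All numeric
text output is full double precision with '.' decimals, locale-independent.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .containers import EventSet, MicrostateSet, Recording, Segmentation, SensorLayout
from .containers import TemporalMetrics
from .errors import InvalidArgumentError

__all__ = [
    "PipelineConfig",
    "write_recording",
    "read_recording",
    "write_events",
    "read_events",
    "write_layout",
    "read_layout",
    "write_microstates",
    "read_microstates",
    "write_segmentation",
    "read_segmentation",
    "metrics_to_json",
]


@dataclass
class PipelineConfig:
    """All pipeline parameters; the defaults are the published protocol.

    Sampling/filtering: 250 Hz target rate, 50 Hz notch, 1-30 Hz band,
    2-s epochs.  Fitting: similarity floor 0.50, smoothing half window 3,
    Besag factor 10.  Statistics: 1000 parcel permutations at |z| >= 3.6
    (Bonferroni 0.05/204), 10000 co-occurrence permutations with the
    mean-z > 3 rule, coverage contrasts at 0.05/6.
    """

    target_fs: float = 250.0
    notch_hz: float = 50.0
    hp_hz: float = 1.0
    lp_hz: float = 30.0
    epoch_s: float = 2.0
    reject_z: float = 20.0
    k_grid: list = field(default_factory=lambda: list(range(2, 13)))
    n_restarts: int = 100
    tol: float = 1e-6
    mode: str = "meg"
    threshold: float = 0.50
    half_window: int = 3
    besag_lambda: float = 10.0
    n_perm_parcel: int = 1000
    n_perm_cooc: int = 10_000
    z_crit: float = 3.6
    mean_z_crit: float = 3.0
    alpha: float = 0.05
    n_states_tested: int = 6
    n_parcels: int = 34
    mmn_window_ms: tuple = (150.0, 300.0)
    baseline_ms: float = 200.0
    epoch_ms: tuple = (-200.0, 500.0)
    alpha_band: tuple = (8.0, 12.0)
    occipital_channels: list = field(default_factory=list)
    seed: int = 0

    @property
    def bonferroni_alpha_coverage(self) -> float:
        """Exact per-test alpha for the microstate-specific contrasts."""
        return self.alpha / self.n_states_tested

    @property
    def bonferroni_alpha_parcel(self) -> float:
        """Exact per-test alpha for the parcel x state comparisons."""
        return self.alpha / (self.n_parcels * self.n_states_tested)

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d["mmn_window_ms"] = list(d["mmn_window_ms"])
        d["epoch_ms"] = list(d["epoch_ms"])
        d["alpha_band"] = list(d["alpha_band"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("mmn_window_ms", "epoch_ms", "alpha_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# recordings


def _write_brainvision(rec: Recording, base: str, ascii_format: bool) -> str:
    vhdr = base + ".vhdr"
    vmrk = base + ".vmrk"
    dat = base + ".eeg"
    name = os.path.basename(base)
    fmt = "ASCII" if ascii_format else "BINARY"
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={name}.eeg",
        f"MarkerFile={name}.vmrk",
        f"DataFormat={fmt}",
        "DataOrientation=" + ("VECTORIZED" if ascii_format else "MULTIPLEXED"),
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={1e6 / rec.fs:.10g}",
    ]
    if ascii_format:
        lines += ["[ASCII Infos]", "DecimalSymbol=.", "SkipLines=0", "SkipColumns=0"]
    else:
        lines += ["[Binary Infos]", "BinaryFormat=IEEE_FLOAT_32"]
    lines.append("[Channel Infos]")
    for i, ch in enumerate(rec.channel_names, start=1):
        lines.append(f"Ch{i}={ch},,1,V")
    lines += ["[Comment]", f"modality={rec.modality}", f"condition={rec.condition}"]
    with open(vhdr, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    with open(vmrk, "w") as fh:
        fh.write(
            "Brain Vision Data Exchange Marker File, Version 1.0\n"
            "[Common Infos]\nCodepage=UTF-8\n"
            f"DataFile={name}.eeg\n[Marker Infos]\n"
            "Mk1=New Segment,,1,1,0,0\n"
        )
    if ascii_format:
        with open(dat, "w") as fh:
            for row in rec.data:
                fh.write(" ".join(f"{float(v):.17g}" for v in row) + "\n")
    else:
        rec.data.astype("<f4").T.tofile(dat)  # multiplexed: frame-major
    return vhdr


def write_recording(
    rec: Recording, path: str, fmt: str = "brainvision", ascii_format: bool = False
) -> str:
    """Write a recording; returns the path to read back from.

    ``fmt='brainvision'`` writes a vhdr/vmrk/eeg triplet (``path`` without
    extension); ``fmt='csv'`` writes a channel x time matrix preceded by a
    ``# fs=...`` header line.
    """
    if fmt == "brainvision":
        base = path[:-5] if path.endswith(".vhdr") else path
        return _write_brainvision(rec, base, ascii_format)
    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write(f"# fs={rec.fs!r} modality={rec.modality} condition={rec.condition}\n")
            df = pd.DataFrame(rec.data, index=rec.channel_names)
            df.to_csv(fh, float_format="%.17g")
        return path
    raise InvalidArgumentError("fmt must be 'brainvision' or 'csv'")


def _read_brainvision(path: str) -> Recording:
    import mne

    # guard against silently truncated binary payloads
    with open(path) as fh:
        header = fh.read()
    n_ch = None
    binary = "DataFormat=BINARY" in header
    for line in header.splitlines():
        if line.startswith("NumberOfChannels="):
            n_ch = int(line.split("=", 1)[1])
    if n_ch is None:
        raise InvalidArgumentError(f"malformed header (no NumberOfChannels): {path}")
    if binary:
        dat = path[:-5] + ".eeg"
        size = os.path.getsize(dat)
        if size % (4 * n_ch) != 0:
            raise InvalidArgumentError(
                f"truncated binary data file {dat}: {size} bytes not a multiple "
                f"of {4 * n_ch}"
            )
    modality, condition = "eeg", ""
    for line in header.splitlines():
        if line.startswith("modality="):
            modality = line.split("=", 1)[1].strip()
        elif line.startswith("condition="):
            condition = line.split("=", 1)[1].strip()
    if not binary and "DataOrientation=VECTORIZED" in header:
        # vectorized ASCII (channels in rows): plain numeric payload
        fs = None
        names = []
        for line in header.splitlines():
            if line.startswith("SamplingInterval="):
                fs = 1e6 / float(line.split("=", 1)[1])
            elif line.startswith("Ch") and "=" in line and line[2].isdigit():
                names.append(line.split("=", 1)[1].split(",")[0])
        if fs is None:
            raise InvalidArgumentError(f"malformed header (no SamplingInterval): {path}")
        data = np.loadtxt(path[:-5] + ".eeg", ndmin=2)
        return Recording(data, fs, modality, condition, names)
    raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    data = raw.get_data()
    return Recording(data, raw.info["sfreq"], modality, condition, raw.ch_names)


def read_recording(path: str, fmt: str | None = None) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    if fmt is None:
        fmt = "brainvision" if path.endswith(".vhdr") else "csv"
    if fmt == "brainvision":
        return _read_brainvision(path if path.endswith(".vhdr") else path + ".vhdr")
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# fs="):
            raise InvalidArgumentError(f"{path}:1: missing '# fs=' header line")
        fields = dict(tok.split("=", 1) for tok in first[2:].split())
        df = pd.read_csv(fh, index_col=0)
    return Recording(
        df.to_numpy(float),
        float(fields["fs"]),
        fields.get("modality", "eeg"),
        fields.get("condition", ""),
        [str(c) for c in df.index],
    )


# ---------------------------------------------------------------------------
# events, layouts, templates, segmentations


def write_events(events: EventSet, path: str) -> None:
    df = pd.DataFrame(
        {
            "sample": events.onsets,
            "type": events.types,
            "std_preceding_deviant": events.std_preceding_deviant.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_events(path: str) -> EventSet:
    df = pd.read_csv(path, sep="\t")
    return EventSet(
        df["sample"].to_numpy(int),
        df["type"].to_numpy(object),
        df["std_preceding_deviant"].to_numpy(bool),
    )


def write_layout(layout: SensorLayout, path: str) -> None:
    df = pd.DataFrame(layout.positions, columns=["x", "y", "z"])
    df.insert(0, "channel", layout.channel_names)
    for j in range(6):
        df[f"nb{j}"] = layout.neighbor_table[:, j]
    df.to_csv(path, index=False, float_format="%.17g")


def read_layout(path: str) -> SensorLayout:
    df = pd.read_csv(path)
    return SensorLayout(
        [str(c) for c in df["channel"]],
        df[["x", "y", "z"]].to_numpy(float),
        df[[f"nb{j}" for j in range(6)]].to_numpy(int),
    )


def write_microstates(ms: MicrostateSet, base: str) -> None:
    """Templates as channels x K CSV plus a JSON sidecar (mode, k)."""
    pd.DataFrame(
        ms.maps.T, columns=[f"state{m + 1}" for m in range(ms.k)]
    ).to_csv(base + ".csv", index=False, float_format="%.17g")
    with open(base + ".json", "w") as fh:
        json.dump({"mode": ms.mode, "k": ms.k, "provenance": ms.provenance}, fh)


def read_microstates(base: str) -> MicrostateSet:
    maps = pd.read_csv(base + ".csv").to_numpy(float).T
    with open(base + ".json") as fh:
        meta = json.load(fh)
    return MicrostateSet(maps, meta["mode"], meta.get("provenance", "individual"))


def write_segmentation(seg: Segmentation, base: str) -> None:
    pd.DataFrame(
        {"frame": np.arange(seg.n_frames), "label": seg.labels,
         "sim": seg.sims, "gfp": seg.gfp}
    ).to_csv(base + ".tsv", sep="\t", index=False, float_format="%.17g")
    with open(base + ".json", "w") as fh:
        json.dump({"fs": seg.fs, "n_states": seg.n_states}, fh)


def read_segmentation(base: str) -> Segmentation:
    df = pd.read_csv(base + ".tsv", sep="\t")
    with open(base + ".json") as fh:
        meta = json.load(fh)
    return Segmentation(
        df["label"].to_numpy(int), df["sim"].to_numpy(float),
        df["gfp"].to_numpy(float), meta["fs"], meta["n_states"],
    )


def metrics_to_json(metrics: TemporalMetrics, path: str | None = None) -> dict:
    d = {
        "coverage": metrics.coverage.tolist(),
        "mean_duration_ms": metrics.mean_duration_ms.tolist(),
        "occurrence_per_s": metrics.occurrence_per_s.tolist(),
        "gev": metrics.gev.tolist(),
        "gev_total": metrics.gev_total,
        "unlabeled_fraction": metrics.unlabeled_fraction,
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)
    return d
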