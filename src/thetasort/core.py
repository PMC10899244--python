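"""Canonical data types and file formats.

A recording lives on disk as a flat binary sample matrix (``<name>.bin``)
plus a JSON sidecar (``<name>.json``) declaring rate, channel layout and
the µV scale.  Events and spike tables are UTF-8 tab-separated text with a
single header line, so fixtures diff cleanly.  Time is in seconds,
zero-based at recording start; sample index ``s`` corresponds to time
``s / rate``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "EventTable",
    "SpikeTrain",
    "SnippetArray",
    "SessionManifest",
    "FormatError",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "read_spike_table",
    "write_spike_table",
]

#: JSON sidecar keys required for every recording.
_HEADER_KEYS = ("rate_hz", "n_channels", "dtype", "order", "scale_uV")


class FormatError(ValueError):
    """Malformed on-disk recording, event table or spike table."""


@dataclass
class Recording:
    """Multichannel extracellular voltage matrix in µV.

    Parameters
    ----------
    samples
        ``(n_channels, n_samples)`` float array, microvolts.
    rate
        Sampling rate in Hz.
    channel_ids
        Unique label per channel (e.g. ``"ch01"``).
    regions
        Per-channel anatomical tag (e.g. ``"HIP-RH"``); optional.
    t0
        Recording start time in seconds.
    """

    samples: np.ndarray
    rate: float
    channel_ids: list[str]
    regions: list[str] | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_ids)} channel_ids for "
                f"{self.samples.shape[0]} channel rows"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")
        if self.regions is not None and len(self.regions) != len(self.channel_ids):
            raise ValueError("regions must align with channel_ids")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds (n_samples / rate)."""
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        """Sample-centred time axis in seconds."""
        return np.arange(self.n_samples) / self.rate

    def channel(self, channel_id: str) -> np.ndarray:
        """Return the 1-D trace of one channel by label."""
        try:
            idx = self.channel_ids.index(channel_id)
        except ValueError:
            raise KeyError(f"unknown channel {channel_id!r}") from None
        return self.samples[idx]


@dataclass
class EventTable:
    """Behavioral epochs: rows of (label, t_start, t_end), half-open [start, end)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table, columns=["label", "t_start", "t_end"])
        df["t_start"] = df["t_start"].astype(float)
        df["t_end"] = df["t_end"].astype(float)
        bad = df.index[df["t_start"] >= df["t_end"]]
        if len(bad):
            raise FormatError(
                f"event row {bad[0]}: t_start >= t_end "
                f"({df.loc[bad[0], 't_start']} >= {df.loc[bad[0], 't_end']})"
            )
        # epochs sharing a label must not overlap
        for label, grp in df.groupby("label"):
            g = grp.sort_values("t_start")
            if (g["t_start"].values[1:] < g["t_end"].values[:-1]).any():
                raise FormatError(f"overlapping epochs with label {label!r}")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def epochs(self, label: str | None = None) -> list[tuple[str, float, float]]:
        df = self.table if label is None else self.table[self.table["label"] == label]
        return [tuple(r) for r in df.itertuples(index=False)]

    @property
    def labels(self) -> list[str]:
        return list(dict.fromkeys(self.table["label"]))


@dataclass
class SpikeTrain:
    """Detected spike times (s) on one channel, strictly increasing."""

    channel_id: str
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=np.float64)
        if self.spike_times.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if len(self.spike_times) > 1 and not np.all(np.diff(self.spike_times) > 0):
            raise ValueError("spike_times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.spike_times)


@dataclass
class SnippetArray:
    """Aligned spike waveform windows.

    ``waveforms`` is ``(n_spikes, n_samples)`` in µV with the trough at
    index ``pre_samples``; ``n_samples = pre_samples + post_samples + 1``.
    """

    waveforms: np.ndarray
    pre_samples: int
    post_samples: int
    rate: float
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        self.waveforms = np.atleast_2d(np.asarray(self.waveforms, dtype=np.float64))
        self.spike_times = np.asarray(self.spike_times, dtype=np.float64)
        expected = self.pre_samples + self.post_samples + 1
        if self.waveforms.size and self.waveforms.shape[1] != expected:
            raise ValueError(
                f"snippet length {self.waveforms.shape[1]} != "
                f"pre+post+1 = {expected}"
            )
        if len(self.spike_times) != self.waveforms.shape[0] and self.waveforms.size:
            raise ValueError("spike_times must align with waveform rows")

    def __len__(self) -> int:
        return 0 if self.waveforms.size == 0 else self.waveforms.shape[0]

    @property
    def n_samples(self) -> int:
        return self.pre_samples + self.post_samples + 1


@dataclass
class SessionManifest:
    """Ordered chronic-recording sessions: (week, recording path, events path)."""

    sessions: list[tuple[float, str, str | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        weeks = [s[0] for s in self.sessions]
        if any(b < a for a, b in zip(weeks, weeks[1:])):
            raise ValueError("session_time must be non-decreasing")

    def __len__(self) -> int:
        return len(self.sessions)

    @property
    def weeks(self) -> list[float]:
        return [s[0] for s in self.sessions]


# ---------------------------------------------------------------------------
# recording I/O


def write_recording(recording: Recording, path: str | Path) -> Path:
    """Write ``<path>.bin`` (flat binary, channel-major) + ``<path>.json``.

    Default encoding is float32 little-endian at unit µV scale, which
    round-trips bit-exactly for float32-representable data.
    """
    path = Path(path)
    base = path.with_suffix("") if path.suffix in {".bin", ".json"} else path
    header = {
        "rate_hz": recording.rate,
        "n_channels": recording.n_channels,
        "n_samples": recording.n_samples,
        "dtype": "float32",
        "order": "channel_major",
        "scale_uV": 1.0,
        "channel_ids": recording.channel_ids,
        "regions": recording.regions,
        "t0_s": recording.t0,
    }
    payload = recording.samples.astype("<f4")
    base.with_suffix(".bin").write_bytes(payload.tobytes(order="C"))
    base.with_suffix(".json").write_text(json.dumps(header, indent=1))
    return base.with_suffix(".bin")


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording` (µV scale applied)."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix in {".bin", ".json"} else path
    header_path = base.with_suffix(".json")
    if not header_path.exists():
        raise FormatError(f"missing header {header_path}")
    try:
        header = json.loads(header_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"corrupt header {header_path}: {exc}") from exc
    for key in _HEADER_KEYS:
        if key not in header:
            raise FormatError(f"header missing key {key!r}")
    dtype = np.dtype(header["dtype"]).newbyteorder("<")
    raw = np.frombuffer(base.with_suffix(".bin").read_bytes(), dtype=dtype)
    n_ch = int(header["n_channels"])
    if n_ch > 0 and raw.size % n_ch:
        raise FormatError(
            f"payload of {raw.size} samples not divisible by {n_ch} channels"
        )
    n_samples = raw.size // n_ch if n_ch else 0
    if header["order"] == "channel_major":
        samples = raw.reshape(n_ch, n_samples)
    elif header["order"] == "interleaved":
        samples = raw.reshape(n_samples, n_ch).T
    else:
        raise FormatError(f"unknown sample order {header['order']!r}")
    samples = samples.astype(np.float64) * float(header["scale_uV"])
    return Recording(
        samples=samples,
        rate=float(header["rate_hz"]),
        channel_ids=list(header.get("channel_ids") or [f"ch{i}" for i in range(n_ch)]),
        regions=header.get("regions"),
        t0=float(header.get("t0_s", 0.0)),
    )


# ---------------------------------------------------------------------------
# tabular I/O


def write_events(events: EventTable, path: str | Path) -> Path:
    path = Path(path)
    events.table.to_csv(path, sep="\t", index=False)
    return path


def read_events(path: str | Path) -> EventTable:
    df = pd.read_csv(path, sep="\t")
    missing = {"label", "t_start", "t_end"} - set(df.columns)
    if missing:
        raise FormatError(f"event table missing columns {sorted(missing)}")
    return EventTable(df)


def write_spike_table(
    spike_trains: Sequence[SpikeTrain],
    cluster_labels: Sequence[np.ndarray] | None,
    path: str | Path,
) -> Path:
    """Write (channel, spike_time_s, cluster) TSV, time-sorted within channel.

    ``cluster_labels`` aligns 1:1 with each train's spikes; pass ``None``
    for unsorted spikes (cluster written as 0).
    """
    rows = []
    for i, train in enumerate(spike_trains):
        labels = (
            np.zeros(len(train), dtype=int)
            if cluster_labels is None
            else np.asarray(cluster_labels[i], dtype=int)
        )
        if len(labels) != len(train):
            raise ValueError(
                f"channel {train.channel_id}: {len(labels)} labels "
                f"for {len(train)} spikes"
            )
        order = np.argsort(train.spike_times, kind="stable")
        for j in order:
            rows.append((train.channel_id, train.spike_times[j], labels[j]))
    df = pd.DataFrame(rows, columns=["channel", "spike_time_s", "cluster"])
    df.to_csv(Path(path), sep="\t", index=False, float_format="%.7f")
    return Path(path)


def read_spike_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"channel", "spike_time_s", "cluster"} - set(df.columns)
    if missing:
        raise FormatError(f"spike table missing columns {sorted(missing)}")
    return df
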