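"""Domain containers and on-disk formats for floor-vibration event records.

A monitored event is a short multi-channel burst of floor acceleration
captured by several structure-mounted accelerometers.  Each event is stored
as one :class:`AccelRecord`; a labelled collection of events forms an
:class:`EventDataset`, the unit the rest of the package operates on.

Acceleration is expressed in g throughout; time in seconds.  Two on-disk
containers are supported: a directory of per-event CSV files with JSON
metadata sidecars (human-inspectable) and a single HDF5 file (bit-exact
round trips).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import h5py
import numpy as np

#: Activity classes used across the package.  ``fall`` is the positive class.
ACTIVITY_LABELS = (
    "fall",
    "walk",
    "free_jump",
    "rhythmic_jump",
    "bag_drop",
    "ball_drop",
)

UNLABELED = "unlabeled"

#: Default sampling rate (Hz) of the laboratory acquisition design.
DEFAULT_FS = 1652.0

#: Default binary class map: fall is positive (+1), every other activity
#: negative (-1).
DEFAULT_CLASS_MAP: dict[str, int] = {
    label: (1 if label == "fall" else -1) for label in ACTIVITY_LABELS
}


class FormatError(ValueError):
    """Raised when an on-disk event file violates the container format."""


@dataclass
class AccelRecord:
    """One event: multi-channel floor acceleration plus provenance.

    Parameters
    ----------
    channels : ndarray of shape (n_samples, n_sensors)
        Acceleration samples in g.  At least 2 samples and 2 sensors
        (the correlation feature needs sensor pairs); all values finite.
    fs : float
        Sampling rate in Hz, strictly positive.
    label : str
        Activity class, one of :data:`ACTIVITY_LABELS` or ``"unlabeled"``.
    meta : dict
        Free-form provenance (excitation position, mass in kg, seed, ...).
    """

    channels: np.ndarray
    fs: float = DEFAULT_FS
    label: str = UNLABELED
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2:
            raise ValueError(
                f"channels must be 2-D (n_samples, n_sensors); got ndim={self.channels.ndim}"
            )
        n_samples, n_sensors = self.channels.shape
        if n_samples < 2:
            raise ValueError(f"need at least 2 samples per event; got {n_samples}")
        if n_sensors < 2:
            raise ValueError(
                f"need at least 2 sensors (correlation features use pairs); got {n_sensors}"
            )
        if not np.all(np.isfinite(self.channels)):
            bad = np.argwhere(~np.isfinite(self.channels))[0]
            raise ValueError(
                f"non-finite sample at row {bad[0]}, sensor {bad[1]}"
            )
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValueError(f"sampling rate must be positive and finite; got {self.fs}")
        if self.label != UNLABELED and self.label not in ACTIVITY_LABELS:
            raise ValueError(
                f"unknown label {self.label!r}; expected one of {ACTIVITY_LABELS} or {UNLABELED!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.channels.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.channels.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds (n_samples / fs)."""
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        """Time axis in seconds, starting at 0 with step 1/fs."""
        return np.arange(self.n_samples) / self.fs


@dataclass
class EventDataset:
    """Ordered collection of events sharing sensor count and sampling rate."""

    records: list[AccelRecord] = field(default_factory=list)
    class_map: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_MAP))

    def __post_init__(self) -> None:
        if self.records:
            ns = self.records[0].n_sensors
            fs = self.records[0].fs
            for i, rec in enumerate(self.records):
                if rec.n_sensors != ns:
                    raise ValueError(
                        f"record {i} has {rec.n_sensors} sensors, expected {ns}"
                    )
                if rec.fs != fs:
                    raise ValueError(f"record {i} has fs={rec.fs}, expected {fs}")
                if rec.label != UNLABELED and rec.label not in self.class_map:
                    raise ValueError(
                        f"record {i} label {rec.label!r} not in class map"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AccelRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> AccelRecord:
        return self.records[i]

    @property
    def n_sensors(self) -> int:
        if not self.records:
            raise ValueError("empty dataset has no sensor count")
        return self.records[0].n_sensors

    @property
    def fs(self) -> float:
        if not self.records:
            raise ValueError("empty dataset has no sampling rate")
        return self.records[0].fs

    def labels(self) -> list[str]:
        return [rec.label for rec in self.records]

    def binary_labels(self) -> np.ndarray:
        """Per-event class in {+1 fall, -1 non-fall, 0 unlabeled}."""
        return np.array(
            [0 if r.label == UNLABELED else self.class_map[r.label] for r in self.records],
            dtype=int,
        )

    def subset(self, indices: Sequence[int]) -> "EventDataset":
        return EventDataset(
            records=[self.records[i] for i in indices], class_map=dict(self.class_map)
        )


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------

_FORMATS = ("csv_dir", "hdf5")


def _event_ids(n: int) -> list[str]:
    width = max(5, len(str(max(n - 1, 0))))
    return [f"event_{i:0{width}d}" for i in range(n)]


def write_events(ds: EventDataset, path: str | Path, format: str = "hdf5") -> None:
    """Write a dataset to disk.

    ``csv_dir``: one ``<event_id>.csv`` (header ``time,s1..sN``) plus
    ``<event_id>.meta.json`` per event.  ``hdf5``: one file, one group per
    event with an ``accel`` dataset and ``fs_hz``/``label``/``meta``
    attributes.  HDF5 round trips are bit-identical; CSV is decimal text
    written with 17 significant digits (round trip to <=1e-9 relative).
    """
    path = Path(path)
    if format == "csv_dir":
        path.mkdir(parents=True, exist_ok=True)
        for eid, rec in zip(_event_ids(len(ds)), ds):
            header = "time," + ",".join(f"s{j + 1}" for j in range(rec.n_sensors))
            table = np.column_stack([rec.time, rec.channels])
            np.savetxt(path / f"{eid}.csv", table, delimiter=",",
                       header=header, comments="", fmt="%.17g")
            meta = {"label": rec.label, "fs_hz": rec.fs, **rec.meta}
            (path / f"{eid}.meta.json").write_text(json.dumps(meta, default=str))
    elif format == "hdf5":
        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "w") as f:
            for eid, rec in zip(_event_ids(len(ds)), ds):
                grp = f.create_group(eid)
                grp.create_dataset("accel", data=rec.channels.astype(np.float64))
                grp.attrs["fs_hz"] = rec.fs
                grp.attrs["label"] = rec.label
                grp.attrs["meta"] = json.dumps(rec.meta, default=str)
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")


def _read_csv_event(csv_path: Path) -> tuple[np.ndarray, dict]:
    meta_path = csv_path.with_suffix("").with_suffix(".meta.json")
    # csv_path like event_00000.csv -> sidecar event_00000.meta.json
    meta_path = csv_path.parent / (csv_path.stem + ".meta.json")
    if not meta_path.exists():
        raise FormatError(f"{csv_path}: missing metadata sidecar {meta_path.name}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{meta_path}: invalid JSON ({exc})") from exc
    lines = csv_path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{csv_path}: empty file")
    header = lines[0].split(",")
    if header[0].strip() != "time" or len(header) < 3:
        raise FormatError(
            f"{csv_path}: line 1: malformed header {lines[0]!r}; expected 'time,s1,...,sN'"
        )
    n_cols = len(header)
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) != n_cols:
            raise FormatError(
                f"{csv_path}: line {lineno}: expected {n_cols} columns, got {len(cells)}"
            )
        try:
            row = [float(c) for c in cells]
        except ValueError as exc:
            raise FormatError(f"{csv_path}: line {lineno}: non-numeric cell ({exc})") from exc
        if not all(np.isfinite(row)):
            raise FormatError(f"{csv_path}: line {lineno}: non-finite value")
        rows.append(row)
    data = np.asarray(rows, dtype=float)
    return data[:, 1:], meta


def read_events(path: str | Path, format: str = "hdf5") -> EventDataset:
    """Read a dataset written by :func:`write_events`.

    Record order is file order: lexicographic event ids for both formats.
    Malformed input raises :class:`FormatError` naming the file (and line,
    for CSV).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[AccelRecord] = []
    if format == "csv_dir":
        for csv_path in sorted(path.glob("*.csv")):
            channels, meta = _read_csv_event(csv_path)
            fs = meta.pop("fs_hz", None)
            label = meta.pop("label", UNLABELED)
            if fs is None or not (np.isfinite(fs) and fs > 0):
                raise FormatError(f"{csv_path}: non-positive or missing fs_hz in sidecar")
            try:
                records.append(AccelRecord(channels, fs=float(fs), label=label, meta=meta))
            except ValueError as exc:
                raise FormatError(f"{csv_path}: {exc}") from exc
    elif format == "hdf5":
        with h5py.File(path, "r") as f:
            for eid in sorted(f.keys()):
                grp = f[eid]
                fs = float(grp.attrs["fs_hz"])
                if fs <= 0:
                    raise FormatError(f"{path}:{eid}: non-positive fs_hz")
                label = str(grp.attrs["label"])
                meta = json.loads(str(grp.attrs.get("meta", "{}")))
                try:
                    records.append(
                        AccelRecord(grp["accel"][()], fs=fs, label=label, meta=meta)
                    )
                except ValueError as exc:
                    raise FormatError(f"{path}:{eid}: {exc}") from exc
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    return EventDataset(records=records)


# ---------------------------------------------------------------------------
# Continuous-stream segmentation
# ---------------------------------------------------------------------------


def segment_event(
    stream: np.ndarray,
    fs: float,
    trigger_threshold: float,
    window: float,
) -> list[AccelRecord]:
    """Cut a continuous multi-channel stream into per-event records.

    An event is triggered where any channel first exceeds ``trigger_threshold``
    (in g, absolute value) after a quiet gap of at least ``window`` seconds.
    Each record spans ``[t_trigger - 0.1*window, t_trigger + window]``,
    clipped to the stream bounds; events never overlap.  A quiet stream
    yields an empty list.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if trigger_threshold <= 0:
        raise ValueError("trigger_threshold must be positive")
    stream = np.asarray(stream, dtype=float)
    if stream.ndim != 2:
        raise ValueError("stream must be 2-D (n_samples, n_sensors)")
    above = np.any(np.abs(stream) > trigger_threshold, axis=1)
    n = stream.shape[0]
    w = int(round(window * fs))
    pre = int(round(0.1 * window * fs))
    records: list[AccelRecord] = []
    i = 0
    prev_end = 0
    while i < n:
        if above[i]:
            # require quiet gap of >= window before the trigger (stream start counts)
            gap_start = max(0, i - w)
            if i == 0 or not above[gap_start:i].any():
                # pre-trigger padding never reaches into the previous event
                start = max(0, i - pre, prev_end)
                end = min(n, i + w + 1)
                records.append(
                    AccelRecord(
                        stream[start:end],
                        fs=fs,
                        label=UNLABELED,
                        meta={"trigger_index": int(i), "start_index": int(start)},
                    )
                )
                i = end
                prev_end = end
                continue
        i += 1
    return records
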