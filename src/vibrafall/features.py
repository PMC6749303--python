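"""Per-event signal features: peak value, energy, sensor correlation.

Three feature views are extracted from every event, each feeding one base
classifier of the multi-view ensemble:

* **peak** — maximum absolute acceleration per sensor, ``A_max = max|a(t)|``
  (g); one column per sensor.
* **energy** — integral of the rectified signal, ``E = integral |a(t)| dt``
  (g*s), evaluated with the trapezoidal rule at the sampling step; one
  column per sensor.  (Despite the name, the statistic is the area under
  |a|, not the squared signal — this mirrors the definition the detector
  was designed with.)
* **corr** — Pearson correlation coefficient
  ``rho = Cov(a1, a2) / (D(a1) D(a2))`` for every unordered sensor pair in
  lexicographic order (1,2), (1,3), ..., (n-1,n); one column per pair.

For ``n`` sensors the view widths are therefore ``(n, n, n(n-1)/2)`` —
(4, 4, 6) for the four-sensor laboratory layout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .signal_core import EventDataset

VIEW_NAMES = ("peak", "energy", "corr")


@dataclass
class FeatureView:
    """A per-event feature matrix for one view.

    Attributes
    ----------
    view : str
        One of ``"peak"``, ``"energy"``, ``"corr"``.
    matrix : ndarray of shape (n_events, d)
    columns : list of str
        Column names, e.g. ``peak_s1`` or ``corr_s1s3``.
    """

    view: str
    matrix: np.ndarray
    columns: list[str]

    def __post_init__(self) -> None:
        if self.view not in VIEW_NAMES:
            raise ValueError(f"unknown view {self.view!r}")
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite values")
        if self.view == "corr" and self.matrix.size:
            if self.matrix.min() < -1 - 1e-12 or self.matrix.max() > 1 + 1e-12:
                raise ValueError("correlation features must lie in [-1, 1]")
        if self.view in ("peak", "energy") and self.matrix.size and self.matrix.min() < 0:
            raise ValueError(f"{self.view} features must be nonnegative")

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    def to_csv(self, path: str | Path, event_ids: list[str] | None = None) -> None:
        """Export as CSV with header ``event_id,<view>_<col>``."""
        import pandas as pd

        n = self.matrix.shape[0]
        ids = event_ids if event_ids is not None else [f"event_{i:05d}" for i in range(n)]
        df = pd.DataFrame(self.matrix, columns=self.columns)
        df.insert(0, "event_id", ids)
        df.to_csv(path, index=False)


def peak_value(a: np.ndarray) -> float:
    """Maximum absolute value of a single-channel series (g)."""
    a = np.asarray(a, dtype=float)
    if a.size == 0:
        raise ValueError("peak_value of an empty series is undefined")
    if not np.all(np.isfinite(a)):
        raise ValueError("series contains non-finite samples")
    return float(np.max(np.abs(a)))


def signal_energy(a: np.ndarray, fs: float) -> float:
    """Area under the rectified series, trapezoidal rule at step 1/fs (g*s)."""
    a = np.asarray(a, dtype=float)
    if a.size < 2:
        raise ValueError("signal_energy needs at least 2 samples")
    if fs <= 0:
        raise ValueError("fs must be positive")
    return float(np.trapezoid(np.abs(a), dx=1.0 / fs))


def sensor_correlation(a1: np.ndarray, a2: np.ndarray) -> float:
    """Pearson correlation coefficient between two equal-length channels.

    A zero-variance (constant) channel makes the coefficient undefined; the
    uninformative value 0 is returned with a warning so that degenerate
    channels cannot poison downstream training.
    """
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    if a1.shape != a2.shape:
        raise ValueError(f"channel length mismatch: {a1.shape} vs {a2.shape}")
    if a1.size < 2:
        raise ValueError("sensor_correlation needs at least 2 samples")
    s1 = a1.std()
    s2 = a2.std()
    if s1 == 0.0 or s2 == 0.0:
        warnings.warn(
            "constant channel in sensor_correlation; returning 0", RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    cov = np.mean((a1 - a1.mean()) * (a2 - a2.mean()))
    return float(np.clip(cov / (s1 * s2), -1.0, 1.0))


def sensor_pairs(n_sensors: int) -> list[tuple[int, int]]:
    """Unordered sensor pairs in lexicographic order, 0-based."""
    return [(i, j) for i in range(n_sensors) for j in range(i + 1, n_sensors)]


def extract_views(ds: EventDataset) -> tuple[FeatureView, FeatureView, FeatureView]:
    """Extract the (peak, energy, corr) views for every event of a dataset.

    Rows follow dataset order; peak/energy columns follow sensor order and
    corr columns the lexicographic pair order.  Per-event feature errors are
    re-raised with the event index attached.
    """
    if len(ds) == 0:
        raise ValueError("cannot extract features from an empty dataset")
    n = ds.n_sensors
    pairs = sensor_pairs(n)
    peak = np.empty((len(ds), n))
    energy = np.empty((len(ds), n))
    corr = np.empty((len(ds), len(pairs)))
    for i, rec in enumerate(ds):
        try:
            for j in range(n):
                peak[i, j] = peak_value(rec.channels[:, j])
                energy[i, j] = signal_energy(rec.channels[:, j], rec.fs)
            for k, (p, q) in enumerate(pairs):
                corr[i, k] = sensor_correlation(rec.channels[:, p], rec.channels[:, q])
        except ValueError as exc:
            raise ValueError(f"event {i}: {exc}") from exc
    return (
        FeatureView("peak", peak, [f"peak_s{j + 1}" for j in range(n)]),
        FeatureView("energy", energy, [f"energy_s{j + 1}" for j in range(n)]),
        FeatureView(
            "corr", corr, [f"corr_s{p + 1}s{q + 1}" for p, q in pairs]
        ),
    )


def view_widths(n_sensors: int) -> tuple[int, int, int]:
    """Widths of the (peak, energy, corr) views for ``n_sensors`` channels."""
    if n_sensors < 2:
        raise ValueError("need at least 2 sensors")
    return n_sensors, n_sensors, n_sensors * (n_sensors - 1) // 2


def stack_views(views: tuple[FeatureView, FeatureView, FeatureView]) -> np.ndarray:
    """Concatenate the three views into one design matrix (peak|energy|corr)."""
    order = {v.view: v for v in views}
    if set(order) != set(VIEW_NAMES):
        raise ValueError("expected exactly one view of each kind")
    return np.hstack([order[name].matrix for name in VIEW_NAMES])
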