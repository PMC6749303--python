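"""Confusion-based evaluation of event detectors, and a classical
autocorrelation-template baseline.

Falls are the positive class (+1).  Sensitivity is the percentage of true
falls detected, specificity the percentage of non-falls correctly
rejected; the miss rate and false-alarm rate are their complements
(``miss = 100 - Se``, ``false alarm = 100 - Sp``).  The false-alarm rate
is additionally broken down per non-fall activity, mirroring the usual
"which activity confuses the detector" diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .signal_core import EventDataset


@dataclass
class EvalReport:
    """Confusion counts and derived percentage metrics.

    ``sensitivity`` / ``miss_rate`` are ``None`` ("undefined") when the
    test set contains no positive events, and likewise ``specificity`` /
    ``false_alarm_rate`` with no negatives; they are never NaN.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    per_activity_false_alarm: dict[str, float] = field(default_factory=dict)

    @property
    def n_test(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n_test

    @property
    def sensitivity(self) -> float | None:
        pos = self.tp + self.fn
        return None if pos == 0 else 100.0 * self.tp / pos

    @property
    def specificity(self) -> float | None:
        neg = self.fp + self.tn
        return None if neg == 0 else 100.0 * self.tn / neg

    @property
    def miss_rate(self) -> float | None:
        se = self.sensitivity
        return None if se is None else 100.0 - se

    @property
    def false_alarm_rate(self) -> float | None:
        sp = self.specificity
        return None if sp is None else 100.0 - sp

    def as_dict(self) -> dict:
        """Reporting form: metrics rounded to 2 decimals, undefined marked."""
        def fmt(v):
            return "undefined" if v is None else round(v, 2)

        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "accuracy": fmt(self.accuracy),
            "sensitivity": fmt(self.sensitivity),
            "specificity": fmt(self.specificity),
            "miss_rate": fmt(self.miss_rate),
            "false_alarm_rate": fmt(self.false_alarm_rate),
            "per_activity_false_alarm": {
                k: round(v, 2) for k, v in self.per_activity_false_alarm.items()
            },
        }

    def summary(self) -> str:
        d = self.as_dict()
        lines = [
            f"n_test={self.n_test}  TP={self.tp} FP={self.fp} TN={self.tn} FN={self.fn}",
            f"accuracy={d['accuracy']}%  sensitivity={d['sensitivity']}%  "
            f"specificity={d['specificity']}%",
            f"miss_rate={d['miss_rate']}%  false_alarm_rate={d['false_alarm_rate']}%",
        ]
        for act, fa in sorted(self.per_activity_false_alarm.items()):
            lines.append(f"  false alarms among {act}: {fa:.2f}%")
        return "\n".join(lines)


def evaluate(
    pred: Sequence[int],
    truth: Sequence[int],
    activities: Sequence[str] | None = None,
) -> EvalReport:
    """Confusion metrics of predicted vs true binary labels (+1 fall).

    ``activities`` (optional per-event tags) enables the per-activity
    false-alarm breakdown over the non-fall activities.
    """
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be equal-length 1-D label arrays")
    if pred.size == 0:
        raise ValueError("cannot evaluate zero events")
    if not np.all(np.isin(pred, (-1, 1))) or not np.all(np.isin(truth, (-1, 1))):
        raise ValueError("labels must be +1 (fall) or -1 (non-fall)")
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == -1)))
    tn = int(np.sum((pred == -1) & (truth == -1)))
    fn = int(np.sum((pred == -1) & (truth == 1)))
    per_act: dict[str, float] = {}
    if activities is not None:
        acts = np.asarray(activities)
        if acts.shape != pred.shape:
            raise ValueError("activities must align with predictions")
        for act in sorted(set(acts[truth == -1])):
            m = (acts == act) & (truth == -1)
            per_act[str(act)] = 100.0 * float(np.sum(pred[m] == 1)) / float(np.sum(m))
    return EvalReport(tp=tp, fp=fp, tn=tn, fn=fn, per_activity_false_alarm=per_act)


def relative_change(new: float, old: float) -> float:
    """Percentage change ``100 (new - old) / old``, rounded to 2 decimals."""
    if old <= 0:
        raise ValueError("baseline value must be positive")
    return round(100.0 * (new - old) / old, 2)


# ---------------------------------------------------------------------------
# Autocorrelation-template baseline
# ---------------------------------------------------------------------------


def _autocorr_signature(rec_channels: np.ndarray, lag_window: int) -> np.ndarray:
    """Normalised autocorrelation of the strongest channel up to lag_window."""
    ch = int(np.argmax(np.max(np.abs(rec_channels), axis=0)))
    a = rec_channels[:, ch] - rec_channels[:, ch].mean()
    denom = float(np.dot(a, a))
    if denom == 0.0:
        return np.zeros(lag_window)
    return np.array(
        [np.dot(a[: a.size - k], a[k:]) / denom for k in range(lag_window)]
    )


def autocorr_baseline(
    train_ds: EventDataset, test_ds: EventDataset, lag_window: int = 200
) -> np.ndarray:
    """Nearest-template classifier on acceleration autocorrelations.

    For every event the normalised autocorrelation of its strongest channel
    is computed up to ``lag_window`` lags; per-class mean autocorrelations
    from the labelled training events serve as templates and each test
    event takes the label of the nearest template (Euclidean distance).

    This is a deliberately simple stand-in for autocorrelation-difference
    activity classifiers used as comparison baselines; it is not a
    re-implementation of any specific published detector.
    """
    if len(train_ds) == 0 or len(test_ds) == 0:
        raise ValueError("train and test datasets must be nonempty")
    min_len = min(rec.n_samples for rec in list(train_ds) + list(test_ds))
    if lag_window > min_len:
        raise ValueError(
            f"lag_window {lag_window} exceeds shortest record length {min_len}"
        )
    y_train = train_ds.binary_labels()
    if np.any(y_train == 0):
        raise ValueError("training events must be labelled")
    sigs = np.vstack(
        [_autocorr_signature(rec.channels, lag_window) for rec in train_ds]
    )
    templates = {}
    for c in np.unique(y_train):
        templates[int(c)] = sigs[y_train == c].mean(axis=0)
    classes = sorted(templates)
    preds = np.empty(len(test_ds), dtype=int)
    for i, rec in enumerate(test_ds):
        s = _autocorr_signature(rec.channels, lag_window)
        d = [np.linalg.norm(s - templates[c]) for c in classes]
        preds[i] = classes[int(np.argmin(d))]
    return preds
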