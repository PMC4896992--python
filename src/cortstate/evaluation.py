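"""Point-by-point accuracy scoring and method-comparison tables.

A segmentation is scored against reference labels window by window: each
window's label is compared with the reference state at the window's start
time. Three percentages are reported per experiment:

* ``percent_correct`` — correct labels among *classified* windows,
* ``percent_unclassified`` — windows the method declined to label,
* ``total_accuracy`` — correct labels among *all* windows, i.e.
  unclassified windows count as incorrect
  (``total = correct * fraction_classified``).

Methods that label every window (the coded-vector classifier, the RMS
threshold) have ``percent_unclassified = 0`` and
``total_accuracy = percent_correct``. Comparison tables aggregate with an
unweighted mean and SD across experiments; elapsed wall time is recorded
as information only.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import StateSegmentation

__all__ = ["AccuracyRow", "UNCLASSIFIED", "score", "compare_methods"]

#: Sentinel label for windows a method declined to classify.
UNCLASSIFIED = "unclassified"


@dataclass
class AccuracyRow:
    """Accuracy of one method on one experiment."""

    percent_correct: float
    percent_unclassified: float
    total_accuracy: float
    n_windows: int
    method: str = ""

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "% classified correctly": self.percent_correct,
            "% unable to classify": self.percent_unclassified,
            "% total accuracy": self.total_accuracy,
            "n windows": self.n_windows,
        }


def _reference_labels(reference, times: np.ndarray) -> np.ndarray:
    if hasattr(reference, "label_at"):
        return np.asarray(reference.label_at(times), dtype=object).astype(str)
    ref = np.asarray(reference, dtype=object).astype(str)
    if ref.shape[0] != times.shape[0]:
        raise ValueError("reference label array must match the window count")
    return ref


def score(seg: StateSegmentation, reference, method: str = "") -> AccuracyRow:
    """Point-by-point accuracy of a segmentation against reference labels.

    ``reference`` is either an object with ``label_at(times)`` (e.g. a
    simulation's ground truth) or an array of per-window labels. Windows
    labelled :data:`UNCLASSIFIED` (or ``None``) are excluded from
    ``percent_correct`` but count against ``total_accuracy``.

    Raises
    ------
    ValueError
        If the segmentation is empty or spans do not overlap.
    """
    if seg.n_windows == 0:
        raise ValueError("empty segmentation")
    if hasattr(reference, "duration_s"):
        if seg.window_times[0] >= reference.duration_s or seg.window_times[-1] < 0:
            raise ValueError("segmentation and reference spans do not overlap")
    ref = _reference_labels(reference, seg.window_times)
    pred = np.array(
        [UNCLASSIFIED if v is None else str(v) for v in seg.labels], dtype=object
    )
    classified = pred != UNCLASSIFIED
    n = pred.shape[0]
    n_classified = int(classified.sum())
    n_correct = int(np.sum(pred[classified] == ref[classified]))
    percent_correct = 100.0 * n_correct / n_classified if n_classified else 0.0
    percent_unclassified = 100.0 * (n - n_classified) / n
    total = 100.0 * n_correct / n
    return AccuracyRow(
        percent_correct=percent_correct,
        percent_unclassified=percent_unclassified,
        total_accuracy=total,
        n_windows=n,
        method=method,
    )


def compare_methods(
    recordings: Sequence[tuple],
    methods: Mapping[str, Callable],
) -> pd.DataFrame:
    """Score several methods over several experiments.

    Parameters
    ----------
    recordings
        Sequence of ``(recording, reference)`` pairs; ``reference`` as in
        :func:`score`.
    methods
        Mapping of method name to a callable ``recording ->``
        :class:`~cortstate.classifier.StateSegmentation`. A method failure
        on a recording is recorded in the table (NaN accuracies with the
        error message) rather than raised.

    Returns
    -------
    pandas.DataFrame
        One row per (method, experiment) plus ``mean`` / ``sd`` summary
        rows per method. The ``time_s`` column is informational.
    """
    if len(recordings) == 0:
        raise ValueError("at least one recording required")
    if len(methods) == 0:
        raise ValueError("at least one method required")
    rows = []
    for name, fn in methods.items():
        per_exp = []
        for i, (rec, reference) in enumerate(recordings):
            t0 = time.perf_counter()
            try:
                seg = fn(rec)
                row = score(seg, reference, method=name)
                elapsed = time.perf_counter() - t0
                d = row.as_dict()
                d.update({"experiment": i, "time_s": elapsed, "error": ""})
                per_exp.append(d)
            except Exception as exc:  # failure is recorded, not fatal
                per_exp.append({
                    "method": name, "experiment": i,
                    "% classified correctly": np.nan,
                    "% unable to classify": np.nan,
                    "% total accuracy": np.nan,
                    "n windows": 0, "time_s": np.nan, "error": str(exc),
                })
        df = pd.DataFrame(per_exp)
        cols = ["% classified correctly", "% unable to classify", "% total accuracy"]
        mean_row = {"method": name, "experiment": "mean",
                    **{c: df[c].mean() for c in cols},
                    "n windows": int(df["n windows"].sum()),
                    "time_s": df["time_s"].sum(), "error": ""}
        sd_row = {"method": name, "experiment": "sd",
                  **{c: df[c].std(ddof=1) if len(df) > 1 else 0.0 for c in cols},
                  "n windows": 0, "time_s": np.nan, "error": ""}
        rows.extend(per_exp + [mean_row, sd_row])
    return pd.DataFrame(rows)
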