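"""State-conditioned partitioning and averaging of haemodynamic series.

Given a per-window state segmentation of concurrent LFP, this module

* extracts the maximal stable periods of each state (longer than 30 s by
  default, so transition ramps and noise have limited influence),
* averages the concurrent oxy-, deoxy- and total haemoglobin (Hbo, Hbr,
  Hbt, micromolar) over those periods per state,
* averages stimulus-evoked trials time-locked to onset, sorted by each
  trial's classified state (baseline-subtracted, with a minimum-trials
  inclusion rule), and
* runs a label-permutation control: the true desynchronised-minus-
  synchronised difference is pooled with differences recomputed under
  random reassignments of the state labels, and flagged iff it falls
  outside the Tukey fences ``[Q1 - 1.5*IQR, Q3 + 1.5*IQR]`` of the pooled
  set (linear-interpolation quartiles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .classifier import DESYNCHRONISED, SYNCHRONISED, StateSegmentation

__all__ = [
    "HemoRecording",
    "StatePeriodSummary",
    "TrialAverage",
    "RandomisationReport",
    "stable_periods",
    "baseline_state_means",
    "state_sorted_trial_average",
    "randomisation_control",
]

SPECIES = ("hbo", "hbr", "hbt")


@dataclass
class HemoRecording:
    """Concurrent haemoglobin concentration series (micromolar).

    ``hbt`` is nominally ``hbo + hbr`` when all three are changes from a
    common baseline, but the three series are stored independently since
    measured estimates need not satisfy the identity exactly.
    """

    times: np.ndarray
    hbo: np.ndarray
    hbr: np.ndarray
    hbt: np.ndarray
    baseline_assumption: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for sp in SPECIES:
            arr = np.asarray(getattr(self, sp), dtype=float)
            if arr.shape != self.times.shape:
                raise ValueError(f"{sp} length does not match times")
            setattr(self, sp, arr)

    @property
    def sample_rate(self) -> float:
        if self.times.size < 2:
            return float("nan")
        return 1.0 / float(np.median(np.diff(self.times)))

    def series(self, sp: str) -> np.ndarray:
        if sp not in SPECIES:
            raise KeyError(f"unknown species {sp!r}")
        return getattr(self, sp)


def stable_periods(
    seg: StateSegmentation, min_duration_s: float = 30.0
) -> dict[str, list[tuple[float, float]]]:
    """Maximal single-state intervals strictly longer than ``min_duration_s``.

    A run of ``m`` consecutive identical window labels starting at window
    time ``t`` becomes the interval ``[t, t + m * step_s)``.
    """
    if seg.n_windows == 0:
        raise ValueError("empty segmentation")
    labels = seg.labels.astype(str)
    times = seg.window_times
    out: dict[str, list[tuple[float, float]]] = {}
    start = 0
    for i in range(1, seg.n_windows + 1):
        if i == seg.n_windows or labels[i] != labels[start]:
            t0 = float(times[start])
            t1 = float(times[i - 1]) + seg.step_s
            if t1 - t0 > min_duration_s:
                out.setdefault(labels[start], []).append((t0, t1))
            start = i
    return out


@dataclass
class StatePeriodSummary:
    """Per-state stable-period means of the three haemoglobin species.

    ``pooled[state][species]`` is the duration-weighted mean over all of a
    state's periods (equivalent to concatenating the samples);
    ``differences[species]`` is desynchronised minus synchronised.
    """

    periods: dict[str, list[tuple[float, float]]]
    period_means: dict[str, list[dict[str, float]]]
    period_durations: dict[str, list[float]]
    pooled: dict[str, dict[str, float]]
    differences: dict[str, float]
    min_duration_s: float = 30.0


def baseline_state_means(
    hemo: HemoRecording,
    periods: Mapping[str, Sequence[tuple[float, float]]],
    min_duration_s: float = 30.0,
) -> StatePeriodSummary:
    """Mean Hbo/Hbr/Hbt per stable period and per state.

    Periods must lie within the recording span. Pooling across a state's
    periods is duration-weighted, i.e. equivalent to a single mean over all
    labelled samples.
    """
    t = hemo.times
    period_means: dict[str, list[dict[str, float]]] = {}
    period_durations: dict[str, list[float]] = {}
    pooled: dict[str, dict[str, float]] = {}
    for state, ivals in periods.items():
        period_means[state] = []
        period_durations[state] = []
        sums = {sp: 0.0 for sp in SPECIES}
        counts = 0
        for (start, end) in ivals:
            if start < t[0] - 1e-9 or end > t[-1] + 1.0 / hemo.sample_rate + 1e-9:
                raise ValueError(
                    f"period ({start}, {end}) outside recording span "
                    f"({t[0]}, {t[-1]})"
                )
            mask = (t >= start) & (t < end)
            if not np.any(mask):
                raise ValueError(f"period ({start}, {end}) contains no samples")
            means = {sp: float(hemo.series(sp)[mask].mean()) for sp in SPECIES}
            period_means[state].append(means)
            period_durations[state].append(end - start)
            for sp in SPECIES:
                sums[sp] += float(hemo.series(sp)[mask].sum())
            counts += int(mask.sum())
        pooled[state] = {sp: sums[sp] / counts for sp in SPECIES} if counts else {}

    differences = {}
    if DESYNCHRONISED in pooled and SYNCHRONISED in pooled and \
            pooled[DESYNCHRONISED] and pooled[SYNCHRONISED]:
        differences = {
            sp: pooled[DESYNCHRONISED][sp] - pooled[SYNCHRONISED][sp]
            for sp in SPECIES
        }
    return StatePeriodSummary(
        periods={s: list(v) for s, v in periods.items()},
        period_means=period_means,
        period_durations=period_durations,
        pooled=pooled,
        differences=differences,
        min_duration_s=min_duration_s,
    )


@dataclass
class TrialAverage:
    """State-sorted, baseline-subtracted trial averages.

    ``traces[state][species]`` is the mean time-locked trace on
    ``rel_times``; ``summaries[state][species]`` the scalar mean over the
    post-onset summary window. ``included[state]`` is False when the state
    provided fewer than ``min_trials`` trials, in which case the state
    should be excluded from cross-experiment grand averages.
    """

    rel_times: np.ndarray
    traces: dict[str, dict[str, np.ndarray]]
    summaries: dict[str, dict[str, float]]
    n_trials: dict[str, int]
    included: dict[str, bool]
    per_trial_summaries: dict[str, dict[str, np.ndarray]]
    summary_window_s: tuple[float, float] = (0.0, 10.0)
    min_trials: int = 5


def state_sorted_trial_average(
    hemo: HemoRecording,
    trials,
    trial_states: Sequence[str],
    pre_s: float = 10.0,
    post_s: float = 54.0,
    summary_window_s: tuple[float, float] = (0.0, 10.0),
    min_trials: int = 5,
) -> TrialAverage:
    """Average evoked haemodynamic trials grouped by classified state.

    Each trial's traces are sampled on a common grid relative to onset
    (``-pre_s`` to ``+post_s``), the pre-stimulus mean subtracted per
    trial, and trials averaged within each state. The scalar summary is
    the mean of the averaged trace over ``summary_window_s`` after onset.
    States represented by fewer than ``min_trials`` trials are flagged as
    not included (a warning is emitted; a state with zero trials has empty
    traces).
    """
    onsets = np.asarray(trials.onsets, dtype=float)
    trial_states = np.asarray(trial_states, dtype=object)
    if trial_states.shape[0] != onsets.shape[0]:
        raise ValueError("one state per trial required")
    dt = 1.0 / hemo.sample_rate
    rel = np.arange(-pre_s, post_s + dt / 2, dt)

    per_trial: dict[str, dict[str, list]] = {}
    for onset, state in zip(onsets, trial_states):
        if onset - pre_s < hemo.times[0] - 1e-9 or onset + post_s > hemo.times[-1] + 1e-9:
            raise ValueError(f"trial at {onset} s extends beyond the recording")
        grid = onset + rel
        entry = per_trial.setdefault(str(state), {sp: [] for sp in SPECIES})
        for sp in SPECIES:
            trace = np.interp(grid, hemo.times, hemo.series(sp))
            baseline = trace[rel < 0].mean()
            entry[sp].append(trace - baseline)

    lo, hi = summary_window_s
    smask = (rel >= lo) & (rel <= hi)
    traces: dict[str, dict[str, np.ndarray]] = {}
    summaries: dict[str, dict[str, float]] = {}
    n_trials: dict[str, int] = {}
    included: dict[str, bool] = {}
    per_trial_summaries: dict[str, dict[str, np.ndarray]] = {}
    for state, entry in per_trial.items():
        n = len(entry["hbo"])
        n_trials[state] = n
        included[state] = n >= min_trials
        if not included[state]:
            warnings.warn(
                f"state {state!r} has only {n} trials (< {min_trials}); "
                "excluded from cross-experiment averaging",
                stacklevel=2,
            )
        traces[state] = {sp: np.mean(entry[sp], axis=0) for sp in SPECIES}
        summaries[state] = {
            sp: float(traces[state][sp][smask].mean()) for sp in SPECIES
        }
        per_trial_summaries[state] = {
            sp: np.array([tr[smask].mean() for tr in entry[sp]]) for sp in SPECIES
        }
    return TrialAverage(
        rel_times=rel,
        traces=traces,
        summaries=summaries,
        n_trials=n_trials,
        included=included,
        per_trial_summaries=per_trial_summaries,
        summary_window_s=summary_window_s,
        min_trials=min_trials,
    )


@dataclass
class RandomisationReport:
    """Outcome of the label-permutation control for one scalar quantity."""

    true_difference: float
    null_differences: np.ndarray
    q1: float
    q3: float
    lower_fence: float
    upper_fence: float
    true_is_outlier: bool
    n_null_outliers: int

    @property
    def true_is_unique_outlier(self) -> bool:
        return self.true_is_outlier and self.n_null_outliers == 0


def _weighted_state_diff(values, labels, weights) -> float:
    desync = labels == DESYNCHRONISED
    sync = labels == SYNCHRONISED
    if not desync.any() or not sync.any():
        raise ValueError("both states must be represented among the units")
    return float(
        np.average(values[desync], weights=weights[desync])
        - np.average(values[sync], weights=weights[sync])
    )


def randomisation_control(
    values: Sequence[float],
    labels: Sequence[str],
    n_repeats: int = 50,
    rng: np.random.Generator | int | None = None,
    weights: Sequence[float] | None = None,
) -> RandomisationReport:
    """Permutation control for a state-sorted difference.

    ``values`` are per-unit scalars (stable-period means or per-trial
    evoked summaries), ``labels`` the classified state of each unit, and
    ``weights`` optional pooling weights (period durations). The true
    desynchronised-minus-synchronised difference is recomputed under
    ``n_repeats`` random permutations of the labels (unit values, and any
    weights, stay attached to their units, so durations are preserved).
    The true difference is pooled with the null differences and flagged as
    an outlier iff it lies outside ``[Q1 - 1.5*IQR, Q3 + 1.5*IQR]`` of the
    pooled set, with linear-interpolation quartiles.

    Raises
    ------
    ValueError
        If fewer than two units, or either state is absent.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object).astype(str)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    if values.shape[0] < 2:
        raise ValueError("need at least two units to permute")
    if weights is None:
        weights = np.ones_like(values)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != values.shape:
            raise ValueError("weights must match values")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    true_diff = _weighted_state_diff(values, labels, weights)
    nulls = np.empty(n_repeats)
    for r in range(n_repeats):
        perm = rng.permutation(labels.shape[0])
        nulls[r] = _weighted_state_diff(values, labels[perm], weights)

    pooled = np.concatenate([[true_diff], nulls])
    q1, q3 = np.percentile(pooled, [25.0, 75.0], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    true_out = bool(true_diff < lo or true_diff > hi)
    n_null_out = int(np.sum((nulls < lo) | (nulls > hi)))
    return RandomisationReport(
        true_difference=true_diff,
        null_differences=nulls,
        q1=float(q1),
        q3=float(q3),
        lower_fence=float(lo),
        upper_fence=float(hi),
        true_is_outlier=true_out,
        n_null_outliers=n_null_out,
    )
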