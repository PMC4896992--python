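"""Coded-vector brain state classifier.

The classifier summarises each analysis window of LFP by a 10-element
integer code describing how every unordered pair of EEG band powers
relates, then labels the window with the state of the nearest stored
"model vector" (L1 distance).

Training (initialisation) proceeds on state-labelled data:

1. Form the 10 absolute pairwise band-power difference series
   (``Err``), one per unordered band pair in a fixed canonical order.
2. From the lower-variance state (the desynchronised state by default),
   set an upper bound ``UB = mean_k |mean_t Err_k|`` (rounded to one
   decimal place) and a lower bound ``LB = 0.5 * UB``. The bounds are set
   once and frozen so that codes stay comparable.
3. Code every window elementwise: ``Err < LB -> C1``,
   ``LB <= Err <= UB -> C2``, ``Err > UB -> C3`` (codes 2, 3, 4 by
   default; any integer-separated coding behaves identically).
4. Keep the ``l`` most frequent coded vectors of each state as that
   state's model vectors.

Classification codes each new window with the frozen bounds and assigns
the state of the globally nearest model vector, so every window receives
a label (there is no "unclassifiable" outcome).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .spectral import (
    BandPowerSeries,
    LFPRecording,
    WindowScheme,
    CLASSIFICATION_SCHEME,
    INITIALISATION_SCHEME,
    band_powers,
    default_channel_subset,
)

__all__ = [
    "SYNCHRONISED",
    "DESYNCHRONISED",
    "PAIR_ORDER",
    "PAIR_NAMES",
    "Bounds",
    "ModelVectorSet",
    "StateSegmentation",
    "pairwise_differences",
    "compute_bounds",
    "encode",
    "define_model_vectors",
    "label_coded_vectors",
    "classify",
    "classify_trials",
    "train_classifier",
    "classify_recording",
]

SYNCHRONISED = "synchronised"
DESYNCHRONISED = "desynchronised"

#: Canonical order of the C(5,2) unordered band pairs (indices into the
#: band axis). Fixed so that coded vectors and model files are portable.
PAIR_ORDER: tuple[tuple[int, int], ...] = tuple(itertools.combinations(range(5), 2))

_BANDS = ("delta", "theta", "alpha", "beta", "gamma")
PAIR_NAMES: tuple[str, ...] = tuple(f"{_BANDS[i]}-{_BANDS[j]}" for i, j in PAIR_ORDER)


def pairwise_differences(f: BandPowerSeries | np.ndarray) -> np.ndarray:
    """Absolute pairwise band-power differences, shape ``(n_windows, 10)``.

    Each unordered pair of the five band series is differenced exactly once
    (combinations, not permutations) and the absolute value taken, so the
    order of subtraction is immaterial. Columns follow :data:`PAIR_ORDER`.
    """
    powers = f.powers if isinstance(f, BandPowerSeries) else np.asarray(f, float)
    if powers.ndim != 2 or powers.shape[1] != 5:
        raise ValueError(f"expected (n_windows, 5) band powers, got {powers.shape}")
    err = np.empty((powers.shape[0], len(PAIR_ORDER)))
    for k, (i, j) in enumerate(PAIR_ORDER):
        err[:, k] = np.abs(powers[:, i] - powers[:, j])
    return err


@dataclass(frozen=True)
class Bounds:
    """Frozen coding bounds. ``lb`` is always exactly ``0.5 * ub``."""

    ub: float
    lb: float
    source_state: str = DESYNCHRONISED
    rounding_precision: int = 1


def compute_bounds(
    err: np.ndarray,
    rounding_precision: int = 1,
    source_state: str = DESYNCHRONISED,
) -> Bounds:
    """Automatic coding bounds from a training ``Err`` series.

    ``UB`` is the mean over the 10 pair series of the absolute time-mean of
    each series, rounded to ``rounding_precision`` decimal places;
    ``LB = 0.5 * UB`` (not independently rounded). The training series
    should come from the state with the smaller band-power variance so the
    bounds are tight.
    """
    err = np.asarray(err, dtype=float)
    if err.size == 0:
        raise ValueError("cannot compute bounds from an empty Err series")
    if err.ndim != 2:
        raise ValueError("Err series must be 2-D (windows x pairs)")
    ub = float(np.round(np.mean(np.abs(err.mean(axis=0))), rounding_precision))
    return Bounds(ub=ub, lb=0.5 * ub, source_state=source_state,
                  rounding_precision=rounding_precision)


DEFAULT_CODES = (2, 3, 4)


def encode(
    err: np.ndarray,
    bounds: Bounds,
    codes: tuple[int, int, int] = DEFAULT_CODES,
) -> np.ndarray:
    """Elementwise three-level coding of an ``Err`` series.

    ``err < LB -> codes[0]``; ``LB <= err <= UB -> codes[1]``;
    ``err > UB -> codes[2]``. Both boundaries belong to the middle code.
    """
    err = np.asarray(err, dtype=float)
    c1, c2, c3 = codes
    out = np.full(err.shape, c2, dtype=int)
    out[err < bounds.lb] = c1
    out[err > bounds.ub] = c3
    return out


@dataclass
class ModelVectorSet:
    """A trained model: per-state model vectors plus the frozen coding setup.

    Attributes
    ----------
    vectors
        Mapping state -> integer array of shape ``(l, 10)``, ordered by
        descending training occurrence count.
    counts
        Mapping state -> occurrence count of each model vector in training.
    bounds, codes
        The frozen coding configuration.
    variance_explained
        Mapping state -> fraction of that state's training windows whose
        coded vector is one of the state's model vectors (occurrence
        coverage; coded vectors are categorical so this is the natural
        analogue of explained variance).
    feature_config
        The band/window/normalisation configuration frozen at training;
        classification refuses features computed differently.
    """

    vectors: dict[str, np.ndarray]
    counts: dict[str, np.ndarray]
    bounds: Bounds
    codes: tuple[int, int, int] = DEFAULT_CODES
    variance_explained: dict[str, float] = field(default_factory=dict)
    feature_config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ls = {s: v.shape[0] for s, v in self.vectors.items()}
        if len(set(ls.values())) > 1:
            raise ValueError(f"states must share the same l, got {ls}")

    @property
    def states(self) -> list[str]:
        return list(self.vectors)

    @property
    def l(self) -> int:
        return next(iter(self.vectors.values())).shape[0]

    @property
    def n_vectors(self) -> int:
        return sum(v.shape[0] for v in self.vectors.values())


def _top_coded_vectors(coded: np.ndarray, l: int, state: str):
    vecs, counts = np.unique(coded, axis=0, return_counts=True)
    if vecs.shape[0] < l:
        raise ValueError(
            f"state {state!r} has only {vecs.shape[0]} distinct coded vectors; "
            f"cannot select l={l} model vectors (reduce l or add training data)"
        )
    order = np.argsort(-counts, kind="stable")[:l]
    top = vecs[order]
    top_counts = counts[order]
    coverage = float(top_counts.sum()) / float(coded.shape[0])
    return top, top_counts, coverage


def define_model_vectors(
    train: Mapping[str, BandPowerSeries],
    l: int = 5,
    bounds_state: str | None = None,
    rounding_precision: int = 1,
    codes: tuple[int, int, int] = DEFAULT_CODES,
) -> ModelVectorSet:
    """Train a model from state-labelled band-power series.

    Parameters
    ----------
    train
        Mapping of state name -> band powers of the training windows of
        that state. Both states must be present.
    l
        Number of model vectors kept per state (the ``l`` most frequent
        distinct coded vectors; default 5, giving 10 model vectors for two
        states).
    bounds_state
        State whose ``Err`` series sets the bounds. By default the state
        with the smaller mean per-pair ``Err`` variance is chosen
        automatically (the desynchronised state in practice, since its band
        powers are flatter).
    """
    if len(train) < 2:
        raise ValueError("training data must contain at least two states")
    errs = {s: pairwise_differences(bp) for s, bp in train.items()}
    for s, e in errs.items():
        if e.shape[0] == 0:
            raise ValueError(f"state {s!r} has no training windows")

    if bounds_state is None:
        bounds_state = min(errs, key=lambda s: float(errs[s].var(axis=0).mean()))
    elif bounds_state not in errs:
        raise KeyError(f"bounds_state {bounds_state!r} not in training data")
    bounds = compute_bounds(errs[bounds_state], rounding_precision, bounds_state)

    vectors: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    coverage: dict[str, float] = {}
    for s, e in errs.items():
        coded = encode(e, bounds, codes)
        vectors[s], counts[s], coverage[s] = _top_coded_vectors(coded, l, s)

    configs = {repr(sorted(bp.feature_config().items())) for bp in train.values()}
    if len(configs) > 1:
        raise ValueError("training series computed with differing feature configs")
    feature_config = next(iter(train.values())).feature_config()

    return ModelVectorSet(
        vectors=vectors,
        counts=counts,
        bounds=bounds,
        codes=codes,
        variance_explained=coverage,
        feature_config=feature_config,
    )


@dataclass
class StateSegmentation:
    """Per-window state labels with timing and match distances.

    ``distances[state][i]`` is the L1 distance from window ``i``'s coded
    vector to the nearest model vector of ``state`` (absent for
    classifiers, like the power threshold, that have no such notion).
    """

    window_times: np.ndarray
    labels: np.ndarray
    step_s: float
    window_s: float
    distances: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.window_times = np.asarray(self.window_times, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.window_times.shape != self.labels.shape:
            raise ValueError("one label per window required")

    @property
    def n_windows(self) -> int:
        return self.labels.shape[0]


def _nearest_per_state(coded: np.ndarray, model: ModelVectorSet) -> dict[str, np.ndarray]:
    out = {}
    for s, vecs in model.vectors.items():
        # (n_windows, l) L1 distances, minimised over the state's vectors
        d = np.abs(coded[:, None, :] - vecs[None, :, :]).sum(axis=2)
        out[s] = d.min(axis=1)
    return out


def label_coded_vectors(
    coded: np.ndarray, model: ModelVectorSet
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Assign a state to each coded vector by nearest model vector.

    Returns ``(labels, distances)`` where ``distances[state]`` holds the
    per-vector L1 distance to the nearest model vector of that state. The
    state of the globally minimal distance wins; a tie between states keeps
    the previous vector's label (synchronised for a tie on the first).
    """
    coded = np.asarray(coded, dtype=int)
    dists = _nearest_per_state(coded, model)
    states = model.states
    dmat = np.stack([dists[s] for s in states], axis=1)  # (n, n_states)
    best = dmat.argmin(axis=1)
    dmin = dmat.min(axis=1)
    tie = (dmat == dmin[:, None]).sum(axis=1) > 1

    labels = np.empty(coded.shape[0], dtype=object)
    prev = SYNCHRONISED if SYNCHRONISED in states else states[0]
    for i in range(coded.shape[0]):
        labels[i] = prev if tie[i] else states[best[i]]
        prev = labels[i]
    return labels, dists


def classify(
    data: BandPowerSeries,
    model: ModelVectorSet,
    check_features: bool = True,
) -> StateSegmentation:
    """Label every window with the state of its nearest model vector.

    Each window is coded with the model's frozen bounds; the L1 distance to
    every model vector is computed and the state of the globally minimal
    distance assigned. A tie between states at equal minimal distance keeps
    the previous window's label (temporal continuity); a tie on the very
    first window defaults to the synchronised state. Every window receives
    a label.

    ``check_features`` enforces that ``data`` was computed under the
    feature configuration frozen in the model, except for the window
    scheme: training conventionally uses a finer window than
    classification, so only bands and normalisation must match.
    """
    if check_features and model.feature_config:
        got = data.feature_config()
        for key in ("bands", "normalisation"):
            if got.get(key) != model.feature_config.get(key):
                raise ValueError(
                    f"feature config mismatch on {key!r}: model was trained with "
                    f"{model.feature_config.get(key)!r}, data has {got.get(key)!r}"
                )
    err = pairwise_differences(data)
    coded = encode(err, model.bounds, model.codes)
    labels, dists = label_coded_vectors(coded, model)
    return StateSegmentation(
        window_times=data.times,
        labels=labels,
        step_s=data.scheme.step_s,
        window_s=data.scheme.window_s,
        distances=dists,
    )


def classify_trials(
    seg: StateSegmentation,
    trials,
    prestim_window_s: float = 10.0,
    exclusion: tuple[float, float] = (0.001, 16.432),
) -> np.ndarray:
    """Per-trial state from the pre-stimulus windows of a segmentation.

    Windows whose time stamp falls inside any stimulation interval
    ``[onset - exclusion[0], onset + exclusion[1]]`` are excluded from
    classification use. Each trial is then labelled by the majority state
    over the remaining windows stamped in ``[onset - prestim_window_s,
    onset)``; a majority tie takes the state of the window nearest to
    stimulus onset.

    Raises
    ------
    ValueError
        If a trial's pre-stimulus period contains zero windows.
    """
    onsets = np.asarray(trials.onsets, dtype=float)
    t = seg.window_times
    excluded = np.zeros(t.shape, dtype=bool)
    for onset in onsets:
        excluded |= (t >= onset - exclusion[0]) & (t <= onset + exclusion[1])

    out = np.empty(onsets.shape[0], dtype=object)
    for i, onset in enumerate(onsets):
        sel = (~excluded) & (t >= onset - prestim_window_s) & (t < onset)
        if not np.any(sel):
            raise ValueError(
                f"trial at {onset} s: no usable windows in its "
                f"{prestim_window_s} s pre-stimulus period"
            )
        lab = seg.labels[sel]
        times = t[sel]
        vals, cnts = np.unique(lab.astype(str), return_counts=True)
        winners = vals[cnts == cnts.max()]
        if winners.shape[0] == 1:
            out[i] = str(winners[0])
        else:
            # tie: state of the window closest to onset
            out[i] = str(lab[np.argmax(times)])
    return out


def train_classifier(
    rec: LFPRecording,
    reference,
    scheme: WindowScheme = INITIALISATION_SCHEME,
    l: int = 5,
    channels: Sequence[int] | None = None,
    normalisation: str = "relative",
    bounds_state: str | None = None,
    rounding_precision: int = 1,
) -> ModelVectorSet:
    """Convenience: train a model from a recording plus reference labels.

    ``reference`` is anything with a ``label_at(times)`` method (for
    example the ground truth of a simulated recording). Band powers are
    computed at the initialisation scheme (4 s window, 0.4 s step by
    default), split by the reference label at each window's start time,
    and passed to :func:`define_model_vectors`.
    """
    if channels is None:
        channels = default_channel_subset(rec)
    bp = band_powers(rec, scheme=scheme, channels=channels,
                     normalisation=normalisation)
    labels = reference.label_at(bp.times)
    train: dict[str, BandPowerSeries] = {}
    for s in np.unique(labels.astype(str)):
        mask = labels.astype(str) == s
        train[str(s)] = BandPowerSeries(
            times=bp.times[mask],
            powers=bp.powers[mask],
            scheme=bp.scheme,
            channels_used=bp.channels_used,
            band_names=bp.band_names,
            normalisation=bp.normalisation,
        )
    return define_model_vectors(
        train, l=l, bounds_state=bounds_state,
        rounding_precision=rounding_precision,
    )


def classify_recording(
    rec: LFPRecording,
    model: ModelVectorSet,
    scheme: WindowScheme = CLASSIFICATION_SCHEME,
    channels: Sequence[int] | None = None,
) -> StateSegmentation:
    """Convenience: band powers at the classification scheme, then classify."""
    if channels is None:
        channels = default_channel_subset(rec)
    bp = band_powers(
        rec,
        scheme=scheme,
        channels=channels,
        normalisation=model.feature_config.get("normalisation", "relative"),
    )
    return classify(bp, model)
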