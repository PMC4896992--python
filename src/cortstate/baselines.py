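"""RMS power-threshold baseline classifier.

A widely used simple comparator: the broadband LFP is cut into the same
moving windows as the spectral classifier, each window's RMS amplitude is
computed per channel and averaged across the channel subset, and the mean
of all window RMS values for the experiment becomes the threshold. Windows
above the threshold are labelled synchronised (large-amplitude state),
windows below desynchronised. Because the threshold depends on absolute
power it must be recomputed for every experiment, and it is biased toward
the state the recording spends most time in — the property that motivates
the coded-vector classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .classifier import DESYNCHRONISED, SYNCHRONISED, StateSegmentation
from .spectral import (
    CLASSIFICATION_SCHEME,
    LFPRecording,
    WindowScheme,
    default_channel_subset,
    window_slices,
)

__all__ = ["RMSSeries", "PowerThresholdModel", "rms_windows", "power_threshold_classify"]


@dataclass
class RMSSeries:
    """Per-window RMS amplitude, averaged across a channel subset."""

    times: np.ndarray
    values: np.ndarray
    scheme: WindowScheme
    channels_used: list[int]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")


@dataclass
class PowerThresholdModel:
    """The per-experiment threshold (mean of all window RMS values)."""

    threshold: float
    scheme: WindowScheme
    channels_used: list[int]


def rms_windows(
    rec: LFPRecording,
    scheme: WindowScheme = CLASSIFICATION_SCHEME,
    channels: Sequence[int] | None = None,
) -> RMSSeries:
    """Moving-window RMS of the raw LFP.

    Per window and channel: square each sample, take the mean, take the
    square root; channel results are then averaged across the subset.
    """
    if channels is None:
        channels = default_channel_subset(rec)
    if len(channels) == 0:
        raise ValueError("empty channel subset")
    rows = rec.channel_rows(channels)
    win = scheme.window_samples(rec.sample_rate)
    step = scheme.step_samples(rec.sample_rate)
    slices = window_slices(rec.n_samples, rec.sample_rate, scheme)

    acc = np.zeros(len(slices))
    for r in rows:
        sq = rec.samples[r] ** 2
        view = np.lib.stride_tricks.sliding_window_view(sq, win)[::step]
        view = view[: len(slices)]
        acc += np.sqrt(view.mean(axis=1))
    acc /= len(rows)
    starts = np.arange(len(slices)) * step
    times = rec.t0 + starts / rec.sample_rate
    return RMSSeries(times=times, values=acc, scheme=scheme,
                     channels_used=list(channels))


def power_threshold_classify(
    rms: RMSSeries,
) -> tuple[StateSegmentation, PowerThresholdModel]:
    """Label each window by comparing its RMS to the experiment-mean RMS.

    Windows with RMS above the threshold are synchronised, below are
    desynchronised; a window exactly at the threshold is labelled
    synchronised (the published rule leaves equality open). A degenerate
    recording whose windows all equal the threshold triggers a warning.
    Every window receives a label.
    """
    if rms.values.size == 0:
        raise ValueError("empty RMS series")
    threshold = float(rms.values.mean())
    if np.all(rms.values == threshold):
        warnings.warn(
            "all window RMS values equal the threshold; labels are "
            "determined entirely by the equality tie rule",
            stacklevel=2,
        )
    labels = np.where(rms.values >= threshold, SYNCHRONISED, DESYNCHRONISED)
    seg = StateSegmentation(
        window_times=rms.times,
        labels=labels.astype(object),
        step_s=rms.scheme.step_s,
        window_s=rms.scheme.window_s,
    )
    model = PowerThresholdModel(threshold=threshold, scheme=rms.scheme,
                                channels_used=rms.channels_used)
    return seg, model
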