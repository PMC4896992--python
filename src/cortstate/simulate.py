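"""Synthetic two-state LFP and haemodynamics generator.

Emulates urethane-style spontaneous alternation between a synchronised
cortical state (large-amplitude, delta-dominated LFP) and a desynchronised
state (low-amplitude LFP with relatively elevated beta/gamma), together
with coupled haemodynamic baseline shifts (oxy- and total haemoglobin up,
deoxyhaemoglobin down during desynchronisation) and state-dependent
stimulus-evoked responses. Every simulated recording comes with exact
ground-truth state labels, so downstream classifiers can be scored without
human labelling.

The LFP model is a sum of band-limited noise components: for each EEG band
a white-noise trace is band-pass filtered and scaled so that the band's
share of total power matches the state's configured band profile and the
overall RMS matches the state's amplitude scale. A slow multiplicative
amplitude envelope (log-normal, ~minute timescale) is applied to all
channels jointly, reproducing the within-state amplitude nonstationarity
of real LFP; deeper channels receive a mildly larger low-frequency gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import signal

from .classifier import SYNCHRONISED, DESYNCHRONISED
from .spectral import BAND_ORDER, LFPRecording, default_bands
from .hemodynamics import HemoRecording

__all__ = [
    "StateParams",
    "StimSchedule",
    "SimConfig",
    "GroundTruth",
    "TrialSet",
    "simulate_states",
    "simulate_lfp",
    "simulate_hemodynamics",
    "simulate_stimulus_trials",
]

HEMO_SPECIES = ("hbo", "hbr", "hbt")


@dataclass(frozen=True)
class StateParams:
    """Per-state LFP synthesis parameters.

    ``band_weights`` is the relative power profile over (delta, theta,
    alpha, beta, gamma); it is normalised internally so only ratios matter.
    ``rms`` is the overall amplitude scale (arbitrary voltage units).
    """

    band_weights: tuple[float, float, float, float, float]
    rms: float

    def __post_init__(self) -> None:
        w = np.asarray(self.band_weights, dtype=float)
        if w.shape != (5,):
            raise ValueError("band_weights must have five entries")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("band_weights must be nonnegative and not all zero")
        if self.rms <= 0:
            raise ValueError("rms must be positive")

    @property
    def normalised_weights(self) -> np.ndarray:
        w = np.asarray(self.band_weights, dtype=float)
        return w / w.sum()


@dataclass(frozen=True)
class StimSchedule:
    """Periodic stimulation protocol: ``n_trials`` trials separated by
    ``iti_s``, stimulus applied ``onset_in_trial_s`` into each trial, as a
    pulse train of ``pulse_rate_hz`` lasting ``duration_s``."""

    n_trials: int = 30
    iti_s: float = 70.0
    onset_in_trial_s: float = 10.0
    duration_s: float = 16.0
    pulse_rate_hz: float = 5.0

    def __post_init__(self) -> None:
        if self.n_trials < 0:
            raise ValueError("n_trials must be nonnegative")
        if min(self.iti_s, self.duration_s, self.pulse_rate_hz) <= 0:
            raise ValueError("iti_s, duration_s and pulse_rate_hz must be positive")
        if self.onset_in_trial_s < 0:
            raise ValueError("onset_in_trial_s must be nonnegative")

    @property
    def onsets(self) -> np.ndarray:
        return self.onset_in_trial_s + self.iti_s * np.arange(self.n_trials)

    @property
    def total_span_s(self) -> float:
        return self.n_trials * self.iti_s

    @property
    def pulses_per_trial(self) -> int:
        return int(round(self.duration_s * self.pulse_rate_hz))


# Default evoked haemodynamic kernels: gamma-variate responses. In the
# synchronised state the response is robust with an early (~5 s) peak; in
# the desynchronised state it is attenuated and peaks late (~16 s).
_DEFAULT_EVOKED = {
    SYNCHRONISED: {
        "peak_s": 5.0,
        "shape": 2.5,
        "amplitude": {"hbo": 4.0, "hbr": -1.5, "hbt": 2.5},
    },
    DESYNCHRONISED: {
        "peak_s": 16.0,
        "shape": 2.5,
        "amplitude": {"hbo": 1.6, "hbr": -0.6, "hbt": 1.0},
    },
}

# Default evoked-LFP pulse adaptation: synchronised trials start with a
# large deflection that decays to a plateau; desynchronised trials start
# small and grow gradually, stabilising ~10-12 s after onset.
_DEFAULT_LFP_PULSE = {
    SYNCHRONISED: {"first": 2.0, "steady": 0.7, "tau_pulses": 15.0},
    DESYNCHRONISED: {"first": 0.25, "steady": 0.8, "tau_pulses": 25.0},
}


@dataclass
class SimConfig:
    """Full configuration of one simulated experiment.

    Defaults describe a spontaneous urethane-style recording: state dwell
    times exponential with mean 120 s (shifted so every visit exceeds
    35 s, guaranteeing that >30 s stable periods exist), a
    delta-dominated synchronised state with twice the desynchronised RMS
    (so absolute gamma-band power is nevertheless higher while
    desynchronised),
    and desynchronised haemodynamic baseline offsets of +8.56 uM Hbo,
    -5.56 uM Hbr and +2.00 uM Hbt reached through a first-order lag
    (tau = 5 s).
    """

    duration_s: float = 600.0
    sample_rate_lfp: float = 1529.4  # 24414 Hz acquisition / 16
    sample_rate_hemo: float = 8.0
    n_channels: int = 16
    dwell_distribution: str = "truncated_exponential"
    dwell_mean_s: Mapping[str, float] = field(
        default_factory=lambda: {SYNCHRONISED: 120.0, DESYNCHRONISED: 120.0}
    )
    dwell_floor_s: float = 35.0
    sync_params: StateParams = field(
        default_factory=lambda: StateParams((0.57, 0.16, 0.08, 0.13, 0.06), 1.0)
    )
    desync_params: StateParams = field(
        default_factory=lambda: StateParams((0.08, 0.10, 0.12, 0.30, 0.40), 0.5)
    )
    amplitude_drift_sigma: float = 0.2
    amplitude_drift_tau_s: float = 60.0
    depth_gain_range: tuple[float, float] = (0.9, 1.1)
    hemo_baseline_shift: Mapping[str, float] = field(
        default_factory=lambda: {"hbo": 8.56, "hbr": -5.56, "hbt": 2.00}
    )
    hemo_lag_tau_s: float = 5.0
    hemo_noise_sd: float = 0.5
    evoked_params: Mapping[str, dict] = field(
        default_factory=lambda: {s: dict(v) for s, v in _DEFAULT_EVOKED.items()}
    )
    lfp_pulse_params: Mapping[str, dict] = field(
        default_factory=lambda: {s: dict(v) for s, v in _DEFAULT_LFP_PULSE.items()}
    )
    stim_schedule: StimSchedule | None = None
    initial_state: str | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sample_rate_lfp <= 0 or self.sample_rate_hemo <= 0:
            raise ValueError("sample rates must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be at least 1")
        if self.dwell_distribution not in ("truncated_exponential", "fixed"):
            raise ValueError(
                f"unknown dwell_distribution {self.dwell_distribution!r} "
                "(use 'truncated_exponential' or 'fixed')"
            )
        for s in (SYNCHRONISED, DESYNCHRONISED):
            if s not in self.dwell_mean_s:
                raise ValueError(f"dwell_mean_s missing state {s!r}")
            if self.dwell_mean_s[s] <= 0:
                raise ValueError("dwell times must be positive")
        if self.dwell_distribution == "truncated_exponential":
            if self.dwell_floor_s < 0:
                raise ValueError("dwell_floor_s must be nonnegative")
            for s, m in self.dwell_mean_s.items():
                if m <= self.dwell_floor_s:
                    raise ValueError(
                        f"dwell mean for {s!r} ({m} s) must exceed the floor "
                        f"({self.dwell_floor_s} s)"
                    )
        if self.sync_params.rms < self.desync_params.rms:
            raise ValueError(
                "synchronised RMS scale must not be below the desynchronised "
                "scale (large-amplitude low-frequency vs low-amplitude "
                "high-frequency); equal scales are allowed for degenerate "
                "indistinguishable-state configurations"
            )
        if self.initial_state not in (None, SYNCHRONISED, DESYNCHRONISED):
            raise ValueError(f"invalid initial_state {self.initial_state!r}")
        if self.stim_schedule is not None:
            sched = self.stim_schedule
            last_end = sched.onsets[-1] + sched.duration_s if sched.n_trials else 0.0
            if last_end > self.duration_s:
                raise ValueError(
                    f"stimulus schedule extends to {last_end} s, beyond the "
                    f"configured duration of {self.duration_s} s"
                )


@dataclass
class GroundTruth:
    """True state intervals of a simulated recording.

    ``intervals`` is a list of ``(start_s, end_s, state)`` triples that are
    non-overlapping, contiguous, cover ``[0, duration_s]`` and alternate
    between the two states.
    """

    intervals: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("at least one interval required")
        prev_end = None
        prev_state = None
        for start, end, state in self.intervals:
            if end <= start:
                raise ValueError("intervals must have positive duration")
            if prev_end is not None and abs(start - prev_end) > 1e-9:
                raise ValueError("intervals must be contiguous")
            if state == prev_state:
                raise ValueError("states must alternate between intervals")
            prev_end, prev_state = end, state

    @property
    def duration_s(self) -> float:
        return self.intervals[-1][1]

    @property
    def states(self) -> list[str]:
        return [s for _, _, s in self.intervals]

    def label_at(self, times) -> np.ndarray:
        """State label at each time (times beyond the end clamp to the
        last interval)."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        starts = np.array([s for s, _, _ in self.intervals])
        idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, None)
        labels = np.array([st for _, _, st in self.intervals], dtype=object)
        return labels[idx]

    def label_track(self, rate: float, n_samples: int) -> np.ndarray:
        """Per-sample label array of length exactly ``n_samples``."""
        t = np.arange(n_samples) / rate
        return self.label_at(t)

    def occupancy(self) -> dict[str, float]:
        """Fraction of total time spent in each state."""
        total = self.duration_s
        out: dict[str, float] = {}
        for start, end, state in self.intervals:
            out[state] = out.get(state, 0.0) + (end - start) / total
        return out


@dataclass
class TrialSet:
    """Stimulus-trial structure: onsets plus the pulse-train description."""

    onsets: np.ndarray
    duration_s: float
    pulse_rate_hz: float

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)

    @property
    def n_trials(self) -> int:
        return self.onsets.shape[0]

    @property
    def pulses_per_trial(self) -> int:
        return int(round(self.duration_s * self.pulse_rate_hz))

    def pulse_times(self, trial: int) -> np.ndarray:
        """Times of the individual stimulation pulses of one trial."""
        return self.onsets[trial] + np.arange(self.pulses_per_trial) / self.pulse_rate_hz


def _rng_for(config: SimConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams for states / LFP / hemodynamics
    return np.random.default_rng(np.random.SeedSequence([config.rng_seed, stream]))


def simulate_states(config: SimConfig, rng: np.random.Generator | None = None) -> GroundTruth:
    """Draw an alternating state sequence covering the configured duration.

    Dwell times are exponential with the configured per-state mean, shifted
    by ``dwell_floor_s`` so every visit exceeds the floor (mean preserved);
    with ``dwell_distribution="fixed"`` each visit lasts exactly its mean.
    The final visit is clipped at the recording end.
    """
    if rng is None:
        rng = _rng_for(config, 0)
    state = config.initial_state
    if state is None:
        state = SYNCHRONISED if rng.random() < 0.5 else DESYNCHRONISED
    other = {SYNCHRONISED: DESYNCHRONISED, DESYNCHRONISED: SYNCHRONISED}

    intervals: list[tuple[float, float, str]] = []
    t = 0.0
    while t < config.duration_s:
        mean = float(config.dwell_mean_s[state])
        if config.dwell_distribution == "fixed":
            dwell = mean
        else:
            dwell = config.dwell_floor_s + rng.exponential(mean - config.dwell_floor_s)
        end = min(t + dwell, config.duration_s)
        intervals.append((t, end, state))
        t = end
        state = other[state]
    return GroundTruth(intervals)


def _band_sos(rate: float) -> dict[str, np.ndarray]:
    out = {}
    for b in default_bands():
        out[b.name] = signal.butter(
            4, (b.lo_hz, b.hi_hz), btype="bandpass", fs=rate, output="sos"
        )
    return out


def _amplitude_envelope(n: int, rate: float, sigma: float, tau_s: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Slow log-normal multiplicative envelope with unit median."""
    if sigma <= 0:
        return np.ones(n)
    coarse_rate = 4.0  # Hz; envelope is smooth, no need for full rate
    n_coarse = max(int(np.ceil(n / rate * coarse_rate)) + 2, 8)
    z = rng.standard_normal(n_coarse)
    alpha = 1.0 / (tau_s * coarse_rate)
    z = signal.lfilter([alpha], [1.0, -(1.0 - alpha)], z)
    sd = z.std()
    if sd > 0:
        z = z / sd
    t_coarse = np.arange(n_coarse) / coarse_rate
    t = np.arange(n) / rate
    z_full = np.interp(t, t_coarse, z)
    return np.exp(sigma * z_full - 0.5 * sigma**2)


def _state_signal(params: StateParams, n: int, sos: Mapping[str, np.ndarray],
                  depth_gain: float, rng: np.random.Generator) -> np.ndarray:
    """One channel's worth of a single state's band-limited noise mixture."""
    w = params.normalised_weights
    x = np.zeros(n)
    for j, name in enumerate(BAND_ORDER):
        if w[j] == 0:
            continue
        comp = signal.sosfiltfilt(sos[name], rng.standard_normal(n))
        sd = comp.std()
        if sd > 0:
            comp = comp / sd
        target_rms = params.rms * np.sqrt(w[j])
        if name in ("delta", "theta"):
            target_rms *= depth_gain
        x += target_rms * comp
    return x


def _lfp_pulse_kernel(rate: float) -> np.ndarray:
    """Brief biphasic evoked-potential shape (~40 ms), peak amplitude 1."""
    t = np.arange(int(round(0.04 * rate))) / rate
    k = np.exp(-t / 0.008) - np.exp(-t / 0.004)
    return k / np.abs(k).max()


def simulate_lfp(config: SimConfig) -> tuple[LFPRecording, GroundTruth]:
    """Simulate a ground-truth-labelled multichannel LFP recording.

    For each channel the synchronised and desynchronised processes are
    synthesised for the full duration and the realised trace selects
    between them per sample according to the drawn state sequence; the
    shared slow amplitude envelope is then applied. If a stimulus schedule
    is configured, evoked pulse deflections with state-dependent adaptation
    are added on top.

    Deterministic given ``config.rng_seed``.
    """
    truth = simulate_states(config)
    rng = _rng_for(config, 1)
    rate = config.sample_rate_lfp
    n = int(round(config.duration_s * rate))
    sos = _band_sos(rate)

    desync_mask = truth.label_track(rate, n) == DESYNCHRONISED
    envelope = _amplitude_envelope(
        n, rate, config.amplitude_drift_sigma, config.amplitude_drift_tau_s, rng
    )
    gains = np.linspace(*config.depth_gain_range, config.n_channels)

    pulse_add = None
    if config.stim_schedule is not None and config.stim_schedule.n_trials > 0:
        trials = simulate_stimulus_trials(config)
        kernel = _lfp_pulse_kernel(rate)
        pulse_add = np.zeros(n)
        for tr in range(trials.n_trials):
            onset = trials.onsets[tr]
            state = str(truth.label_at(onset)[0])
            p = config.lfp_pulse_params[state]
            for i, tp in enumerate(trials.pulse_times(tr)):
                amp = p["steady"] + (p["first"] - p["steady"]) * np.exp(
                    -i / p["tau_pulses"]
                )
                start = int(round(tp * rate))
                stop = min(start + kernel.size, n)
                if start >= n:
                    break
                pulse_add[start:stop] += amp * kernel[: stop - start]

    samples = np.empty((config.n_channels, n))
    for c in range(config.n_channels):
        x_sync = _state_signal(config.sync_params, n, sos, gains[c], rng)
        x_desync = _state_signal(config.desync_params, n, sos, gains[c], rng)
        x = np.where(desync_mask, x_desync, x_sync)
        x *= envelope
        if pulse_add is not None:
            x = x + pulse_add
        samples[c] = x

    rec = LFPRecording(samples=samples, sample_rate=rate,
                       channel_ids=list(range(1, config.n_channels + 1)))
    return rec, truth


def _gamma_variate(t: np.ndarray, peak_s: float, shape: float) -> np.ndarray:
    """Gamma-variate kernel, zero for t<=0, unit peak at ``peak_s``."""
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos] / peak_s
    out[pos] = tp**shape * np.exp(shape * (1.0 - tp))
    return out


def simulate_hemodynamics(
    config: SimConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> HemoRecording:
    """Simulate concurrent Hbo/Hbr/Hbt series coupled to the state sequence.

    Each species follows its configured baseline offset (applied while the
    cortex is desynchronised, zero while synchronised) through a
    first-order lag of time constant ``hemo_lag_tau_s``, plus
    state-dependent evoked responses for any configured stimulus trials and
    additive white noise. Sampled at ``sample_rate_hemo`` (8 Hz by default,
    the effective rate of a 32 Hz camera cycling four wavelengths).

    Raises
    ------
    ValueError
        If the ground truth does not cover the configured duration.
    """
    if abs(truth.duration_s - config.duration_s) > 1e-6:
        raise ValueError(
            f"ground truth covers {truth.duration_s} s but config specifies "
            f"{config.duration_s} s"
        )
    if rng is None:
        rng = _rng_for(config, 2)
    rate = config.sample_rate_hemo
    n = int(round(config.duration_s * rate))
    t = np.arange(n) / rate
    desync = truth.label_at(t) == DESYNCHRONISED

    series: dict[str, np.ndarray] = {}
    alpha = (1.0 / rate) / config.hemo_lag_tau_s
    for sp in HEMO_SPECIES:
        target = np.where(desync, float(config.hemo_baseline_shift.get(sp, 0.0)), 0.0)
        # first-order lag toward the state's plateau, starting on-plateau
        zi = signal.lfilter_zi([alpha], [1.0, -(1.0 - alpha)]) * target[0]
        base, _ = signal.lfilter([alpha], [1.0, -(1.0 - alpha)], target, zi=zi)
        series[sp] = base + config.hemo_noise_sd * rng.standard_normal(n)

    if config.stim_schedule is not None and config.stim_schedule.n_trials > 0:
        trials = simulate_stimulus_trials(config)
        for tr in range(trials.n_trials):
            onset = trials.onsets[tr]
            state = str(truth.label_at(onset)[0])
            p = config.evoked_params[state]
            kern = _gamma_variate(t - onset, p["peak_s"], p["shape"])
            for sp in HEMO_SPECIES:
                series[sp] += p["amplitude"].get(sp, 0.0) * kern

    return HemoRecording(times=t, hbo=series["hbo"], hbr=series["hbr"],
                         hbt=series["hbt"])


def simulate_stimulus_trials(config: SimConfig) -> TrialSet:
    """Trial onsets and pulse-train structure from the configured schedule.

    Raises
    ------
    ValueError
        If no schedule is configured or trials exceed the duration.
    """
    if config.stim_schedule is None:
        raise ValueError("config has no stim_schedule")
    sched = config.stim_schedule
    if sched.n_trials == 0:
        return TrialSet(onsets=np.empty(0), duration_s=sched.duration_s,
                        pulse_rate_hz=sched.pulse_rate_hz)
    onsets = sched.onsets
    if onsets[-1] + sched.duration_s > config.duration_s:
        raise ValueError("trials exceed the configured recording duration")
    return TrialSet(onsets=onsets, duration_s=sched.duration_s,
                    pulse_rate_hz=sched.pulse_rate_hz)
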