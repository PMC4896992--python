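"""Plain-text readers/writers for the package's data products.

All formats are delimited text with a small ``# key: value`` header, so
files are portable and inspectable. Trained models are serialised to a
human-readable, versioned YAML file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .baselines import RMSSeries  # noqa: F401  (re-export convenience)
from .classifier import Bounds, ModelVectorSet, StateSegmentation
from .hemodynamics import HemoRecording
from .simulate import GroundTruth, TrialSet
from .spectral import BandPowerSeries, LFPRecording, WindowScheme

__all__ = [
    "write_lfp", "read_lfp",
    "write_intervals", "read_intervals",
    "write_hemo", "read_hemo",
    "write_trials", "read_trials",
    "write_band_powers", "read_band_powers",
    "write_segmentation", "read_segmentation",
    "write_model", "read_model",
]

MODEL_FORMAT_VERSION = 1


def _write_header(fh, meta: dict) -> None:
    for k, v in meta.items():
        fh.write(f"# {k}: {v}\n")


def _read_header(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].partition(":")
            meta[k.strip()] = v.strip()
    return meta


def write_lfp(path, rec: LFPRecording) -> None:
    """Delimited LFP: header (rate, channels, units) then one row per
    sample with a time column and one column per channel."""
    path = Path(path)
    t = rec.t0 + np.arange(rec.n_samples) / rec.sample_rate
    with open(path, "w") as fh:
        _write_header(fh, {
            "format": "cortstate-lfp",
            "sample_rate_hz": rec.sample_rate,
            "channels": ",".join(str(c) for c in rec.channel_ids),
            "units": "a.u.",
            "t0_s": rec.t0,
        })
        fh.write("t_s\t" + "\t".join(f"ch{c}" for c in rec.channel_ids) + "\n")
        np.savetxt(fh, np.column_stack([t, rec.samples.T]), fmt="%.6g",
                   delimiter="\t")


def read_lfp(path) -> LFPRecording:
    path = Path(path)
    meta = _read_header(path)
    data = np.loadtxt(path, comments="#", skiprows=len(meta) + 1, delimiter="\t")
    data = np.atleast_2d(data)
    channels = [int(c) for c in meta["channels"].split(",")]
    return LFPRecording(
        samples=data[:, 1:].T,
        sample_rate=float(meta["sample_rate_hz"]),
        channel_ids=channels,
        t0=float(meta.get("t0_s", 0.0)),
    )


def write_intervals(path, truth: GroundTruth) -> None:
    """Three-column labelled interval file: start_s, end_s, state."""
    with open(path, "w") as fh:
        _write_header(fh, {"format": "cortstate-intervals"})
        fh.write("start_s\tend_s\tstate\n")
        for start, end, state in truth.intervals:
            fh.write(f"{start:.6f}\t{end:.6f}\t{state}\n")


def read_intervals(path) -> GroundTruth:
    intervals = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("start_s") or not line.strip():
                continue
            start, end, state = line.strip().split("\t")
            intervals.append((float(start), float(end), state))
    return GroundTruth(intervals)


def write_hemo(path, hemo: HemoRecording) -> None:
    """Four-column micromolar series: t, hbo, hbr, hbt."""
    with open(path, "w") as fh:
        _write_header(fh, {"format": "cortstate-hemo", "units": "uM"})
        fh.write("t_s\thbo\thbr\thbt\n")
        np.savetxt(fh, np.column_stack([hemo.times, hemo.hbo, hemo.hbr, hemo.hbt]),
                   fmt="%.6g", delimiter="\t")


def read_hemo(path) -> HemoRecording:
    path = Path(path)
    meta = _read_header(path)
    data = np.loadtxt(path, comments="#", skiprows=len(meta) + 1, delimiter="\t")
    data = np.atleast_2d(data)
    return HemoRecording(times=data[:, 0], hbo=data[:, 1], hbr=data[:, 2],
                         hbt=data[:, 3])


def write_trials(path, trials: TrialSet) -> None:
    """Trial schedule: onset_s, duration_s, rate_hz per row."""
    with open(path, "w") as fh:
        _write_header(fh, {"format": "cortstate-trials"})
        fh.write("onset_s\tduration_s\trate_hz\n")
        for onset in trials.onsets:
            fh.write(f"{onset:.6f}\t{trials.duration_s:.6f}\t"
                     f"{trials.pulse_rate_hz:.6f}\n")


def read_trials(path) -> TrialSet:
    onsets, durations, rates = [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("onset_s") or not line.strip():
                continue
            o, d, r = line.strip().split("\t")
            onsets.append(float(o)); durations.append(float(d)); rates.append(float(r))
    if not onsets:
        return TrialSet(onsets=np.empty(0), duration_s=0.0, pulse_rate_hz=1.0)
    return TrialSet(onsets=np.array(onsets), duration_s=durations[0],
                    pulse_rate_hz=rates[0])


def write_band_powers(path, bp: BandPowerSeries) -> None:
    with open(path, "w") as fh:
        _write_header(fh, {
            "format": "cortstate-bandpowers",
            "window_s": bp.scheme.window_s,
            "step_s": bp.scheme.step_s,
            "role": bp.scheme.role,
            "channels": ",".join(str(c) for c in bp.channels_used),
            "normalisation": bp.normalisation,
        })
        fh.write("t_s\t" + "\t".join(bp.band_names) + "\n")
        np.savetxt(fh, np.column_stack([bp.times, bp.powers]), fmt="%.8g",
                   delimiter="\t")


def read_band_powers(path) -> BandPowerSeries:
    path = Path(path)
    meta = _read_header(path)
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                names = tuple(line.strip().split("\t")[1:])
                break
    data = np.loadtxt(path, comments="#", skiprows=len(meta) + 1, delimiter="\t")
    data = np.atleast_2d(data)
    scheme = WindowScheme(float(meta["window_s"]), float(meta["step_s"]),
                          meta.get("role", "classification"))
    return BandPowerSeries(
        times=data[:, 0], powers=data[:, 1:], scheme=scheme,
        channels_used=[int(c) for c in meta["channels"].split(",")],
        band_names=names, normalisation=meta.get("normalisation", "relative"),
    )


def write_segmentation(path, seg: StateSegmentation) -> None:
    with open(path, "w") as fh:
        _write_header(fh, {
            "format": "cortstate-segmentation",
            "window_s": seg.window_s,
            "step_s": seg.step_s,
        })
        fh.write("t_s\tstate\n")
        for t, lab in zip(seg.window_times, seg.labels):
            fh.write(f"{t:.6f}\t{lab}\n")


def read_segmentation(path) -> StateSegmentation:
    path = Path(path)
    meta = _read_header(path)
    times, labels = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("t_s") or not line.strip():
                continue
            t, lab = line.strip().split("\t")
            times.append(float(t)); labels.append(lab)
    return StateSegmentation(
        window_times=np.array(times), labels=np.array(labels, dtype=object),
        step_s=float(meta["step_s"]), window_s=float(meta["window_s"]),
    )


def write_model(path, model: ModelVectorSet) -> None:
    """Serialise a trained model to human-readable, versioned YAML."""
    doc = {
        "format": "cortstate-model",
        "version": MODEL_FORMAT_VERSION,
        "feature_config": dict(model.feature_config),
        "codes": list(model.codes),
        "bounds": {
            "ub": model.bounds.ub,
            "lb": model.bounds.lb,
            "source_state": model.bounds.source_state,
            "rounding_precision": model.bounds.rounding_precision,
        },
        "states": {
            s: {
                "vectors": model.vectors[s].tolist(),
                "counts": model.counts[s].tolist(),
                "variance_explained": float(model.variance_explained.get(s, 0.0)),
            }
            for s in model.states
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_model(path) -> ModelVectorSet:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("format") != "cortstate-model":
        raise ValueError(f"{path} is not a cortstate model file")
    b = doc["bounds"]
    bounds = Bounds(ub=float(b["ub"]), lb=float(b["lb"]),
                    source_state=b["source_state"],
                    rounding_precision=int(b["rounding_precision"]))
    vectors = {s: np.asarray(d["vectors"], dtype=int)
               for s, d in doc["states"].items()}
    counts = {s: np.asarray(d["counts"], dtype=int)
              for s, d in doc["states"].items()}
    variance = {s: float(d["variance_explained"])
                for s, d in doc["states"].items()}
    return ModelVectorSet(
        vectors=vectors, counts=counts, bounds=bounds,
        codes=tuple(doc["codes"]), variance_explained=variance,
        feature_config=doc.get("feature_config", {}),
    )
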