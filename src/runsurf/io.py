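"""Serialization: trials (CSV + JSON sidecar, or HDF5), tensors, models.

Per-trial CSV files carry one time column (seconds) and one column per
channel; a JSON sidecar holds the labels, sampling rate, ground-truth
heel strikes and the dropped flag.  The HDF5 container variant stores
the same content in one file for large datasets.  Tensors and trained
models round-trip through HDF5/NPZ with their metadata attached.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .model import ModelConfig, TrainedModel, build_baseline, build_final
from .preprocessing import SegmentTensor
from .synthetic import TrialRecording


def save_trials(trials: Sequence[TrialRecording], out_dir: str | Path) -> list[Path]:
    """Write one CSV + JSON sidecar per trial; returns the CSV paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for trial in trials:
        t = np.arange(trial.n_samples) / trial.sample_rate_hz
        frame = pd.DataFrame({"time_s": t} | {k: v for k, v in trial.channels.items()})
        csv_path = out_dir / f"{trial.trial_id}.csv"
        frame.to_csv(csv_path, index=False, float_format="%.6g")
        sidecar = {
            "trial_id": trial.trial_id,
            "subject_id": trial.subject_id,
            "surface": trial.surface_name,
            "sample_rate_hz": trial.sample_rate_hz,
            "true_heel_strikes": trial.true_heel_strikes.tolist(),
            "dropped_flag": bool(trial.dropped_flag),
        }
        (out_dir / f"{trial.trial_id}.json").write_text(
            json.dumps(sidecar, indent=1)
        )
        paths.append(csv_path)
    return paths


def load_trials(in_dir: str | Path) -> list[TrialRecording]:
    in_dir = Path(in_dir)
    trials = []
    for sidecar_path in sorted(in_dir.glob("*.json")):
        meta = json.loads(sidecar_path.read_text())
        frame = pd.read_csv(sidecar_path.with_suffix(".csv"))
        channels = {
            c: frame[c].to_numpy(dtype=np.float64)
            for c in frame.columns
            if c != "time_s"
        }
        trials.append(
            TrialRecording(
                trial_id=meta["trial_id"],
                subject_id=meta["subject_id"],
                surface_name=meta["surface"],
                sample_rate_hz=float(meta["sample_rate_hz"]),
                channels=channels,
                true_heel_strikes=np.asarray(meta["true_heel_strikes"], dtype=np.int64),
                dropped_flag=bool(meta["dropped_flag"]),
            )
        )
    return trials


def save_trials_hdf5(trials: Sequence[TrialRecording], path: str | Path) -> Path:
    """Single-file container: one group per trial."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as h5:
        for trial in trials:
            grp = h5.create_group(trial.trial_id)
            grp.attrs.update(
                subject_id=trial.subject_id,
                surface=trial.surface_name,
                sample_rate_hz=trial.sample_rate_hz,
                dropped_flag=bool(trial.dropped_flag),
            )
            grp.create_dataset("true_heel_strikes", data=trial.true_heel_strikes)
            data = grp.create_group("channels")
            for name, series in trial.channels.items():
                data.create_dataset(name, data=series)
    return path


def load_trials_hdf5(path: str | Path) -> list[TrialRecording]:
    trials = []
    with h5py.File(path, "r") as h5:
        for trial_id in sorted(h5):
            grp = h5[trial_id]
            trials.append(
                TrialRecording(
                    trial_id=trial_id,
                    subject_id=str(grp.attrs["subject_id"]),
                    surface_name=str(grp.attrs["surface"]),
                    sample_rate_hz=float(grp.attrs["sample_rate_hz"]),
                    channels={
                        name: grp["channels"][name][()]
                        for name in grp["channels"]
                    },
                    true_heel_strikes=grp["true_heel_strikes"][()],
                    dropped_flag=bool(grp.attrs["dropped_flag"]),
                )
            )
    return trials


def save_tensor(
    tensor: SegmentTensor, path: str | Path, config_hash: str | None = None
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("values", data=tensor.values)
        h5.create_dataset("labels", data=tensor.labels)
        h5.create_dataset(
            "subjects", data=np.asarray(tensor.subjects, dtype="S32")
        )
        h5.create_dataset(
            "channel_names", data=np.asarray(tensor.channel_names, dtype="S64")
        )
        h5.attrs["normalized_flag"] = bool(tensor.normalized_flag)
        if config_hash is not None:
            h5.attrs["config_hash"] = config_hash
    return path


def load_tensor(path: str | Path) -> SegmentTensor:
    with h5py.File(path, "r") as h5:
        return SegmentTensor(
            values=h5["values"][()],
            labels=h5["labels"][()],
            subjects=np.array([s.decode() for s in h5["subjects"][()]]),
            channel_names=[s.decode() for s in h5["channel_names"][()]],
            normalized_flag=bool(h5.attrs["normalized_flag"]),
        )


def _architecture_of(trained: TrainedModel) -> str:
    return (
        "baseline"
        if any(d.startswith("MaxPool") for d in trained.architecture)
        else "final"
    )


def save_model(trained: TrainedModel, path: str | Path) -> Path:
    """NPZ with the network state plus a JSON header of the config."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {
        "config": trained.config.to_dict(),
        "architecture": _architecture_of(trained),
        "input_frames": trained.input_frames,
        "input_channels": trained.input_channels,
        "stopped_epoch": trained.stopped_epoch,
        "best_epoch": trained.best_epoch,
        "history": trained.history,
    }
    state = trained.network.get_state()
    extras = {}
    if trained.input_mean is not None:
        extras["input_mean"] = trained.input_mean
        extras["input_sd"] = trained.input_sd
    np.savez(
        path,
        header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        **{f"state_{i}": arr for i, arr in enumerate(state)},
        **extras,
    )
    return path


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        state = [
            data[f"state_{i}"]
            for i in range(sum(1 for k in data.files if k.startswith("state_")))
        ]
        input_mean = data["input_mean"] if "input_mean" in data.files else None
        input_sd = data["input_sd"] if "input_sd" in data.files else None
    config = ModelConfig.from_dict(header["config"])
    builder = build_baseline if header["architecture"] == "baseline" else build_final
    network = builder(header["input_frames"], header["input_channels"], config)
    network.set_state(state)
    return TrainedModel(
        network=network,
        config=config,
        history=header["history"],
        stopped_epoch=header["stopped_epoch"],
        best_epoch=header["best_epoch"],
        input_frames=header["input_frames"],
        input_channels=header["input_channels"],
        input_mean=input_mean,
        input_sd=input_sd,
    )
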