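"""Readers and writers for EEG, design tensors, patterns and score series.

EEG comes in as BrainVision or EDF (through MNE, if installed) or as a
plain delimited channels-x-samples matrix with a JSON sidecar holding the
sampling rate and channel labels.  Design tensors and activation patterns
persist as HDF5 with their band/feature metadata in attributes; score
series as CSV with ``time_s,value,kind`` columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .design import DesignTensor, EEGRecording, FrequencyBandSet
from .optimize import ActivationPattern
from .scores import NFScoreSeries

__all__ = [
    "read_eeg",
    "read_eeg_text",
    "write_eeg_text",
    "save_design",
    "load_design",
    "save_pattern",
    "load_pattern",
    "read_scores",
    "write_scores",
]


def read_eeg_text(matrix_path: str | Path, sidecar_path: str | Path | None = None) -> EEGRecording:
    """Plain delimited matrix (rows = channels) + JSON sidecar dialect."""
    matrix_path = Path(matrix_path)
    if sidecar_path is None:
        sidecar_path = matrix_path.with_suffix(".json")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    data = np.loadtxt(matrix_path, delimiter=None, ndmin=2)
    return EEGRecording(
        data=data, srate=float(meta["srate"]), channel_names=list(meta["channel_names"])
    )


def write_eeg_text(rec: EEGRecording, matrix_path: str | Path) -> None:
    matrix_path = Path(matrix_path)
    np.savetxt(matrix_path, rec.data, fmt="%.6g")
    with open(matrix_path.with_suffix(".json"), "w") as fh:
        json.dump({"srate": rec.srate, "channel_names": rec.channel_names}, fh)


def read_eeg(path: str | Path, sidecar: str | Path | None = None) -> EEGRecording:
    """Dispatch on extension: .vhdr/.edf via MNE, anything else as text."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".vhdr", ".edf"):
        import mne  # optional dependency, only needed for these formats

        if suffix == ".vhdr":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        else:
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return EEGRecording(
            data=raw.get_data() * 1e6,  # volts -> microvolts
            srate=float(raw.info["sfreq"]),
            channel_names=list(raw.ch_names),
        )
    return read_eeg_text(path, sidecar)


def save_design(x: DesignTensor, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=x.values)
        fh.create_dataset("times", data=x.times)
        fh.attrs["mode"] = x.mode
        fh.attrs["n_prefix"] = x.n_prefix
        fh.attrs["electrodes"] = json.dumps([e for e, _ in x.feature_labels])
        fh.attrs["delays"] = json.dumps([d for _, d in x.feature_labels])
        fh.attrs["bands"] = json.dumps(list(x.band_set.bands))
        fh.attrs["band_width"] = x.band_set.width_hz
        fh.attrs["band_overlap"] = x.band_set.overlap_hz


def load_design(path: str | Path) -> DesignTensor:
    with h5py.File(path, "r") as fh:
        bands = FrequencyBandSet(
            bands=tuple(tuple(b) for b in json.loads(fh.attrs["bands"])),
            width_hz=float(fh.attrs["band_width"]),
            overlap_hz=float(fh.attrs["band_overlap"]),
        )
        labels = list(
            zip(json.loads(fh.attrs["electrodes"]),
                json.loads(fh.attrs["delays"]))
        )
        return DesignTensor(
            values=fh["values"][()],
            times=fh["times"][()],
            feature_labels=[(e, int(d)) for e, d in labels],
            band_set=bands,
            mode=str(fh.attrs["mode"]),
            n_prefix=int(fh.attrs["n_prefix"]),
        )


def save_pattern(alpha: ActivationPattern, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("weights", data=alpha.weights)
        if alpha.objective_trace is not None:
            fh.create_dataset("objective_trace", data=alpha.objective_trace)
        meta = {
            "lambda": alpha.lambda_,
            "rho": alpha.rho,
            "n_iter": alpha.n_iter,
            "feature_labels": alpha.feature_labels,
            "bands": None,
            "band_width": None,
            "band_overlap": None,
        }
        if alpha.band_set is not None:
            meta["bands"] = list(alpha.band_set.bands)
            meta["band_width"] = alpha.band_set.width_hz
            meta["band_overlap"] = alpha.band_set.overlap_hz
        fh.attrs["meta"] = json.dumps(meta)


def load_pattern(path: str | Path) -> ActivationPattern:
    with h5py.File(path, "r") as fh:
        meta = json.loads(fh.attrs["meta"])
        band_set = None
        if meta["bands"] is not None:
            band_set = FrequencyBandSet(
                bands=tuple(tuple(b) for b in meta["bands"]),
                width_hz=float(meta["band_width"]),
                overlap_hz=float(meta["band_overlap"]),
            )
        labels = meta["feature_labels"]
        return ActivationPattern(
            weights=fh["weights"][()],
            lambda_=float(meta["lambda"]),
            rho=float(meta["rho"]),
            feature_labels=None if labels is None
            else [(str(e), int(d)) for e, d in labels],
            band_set=band_set,
            objective_trace=fh["objective_trace"][()]
            if "objective_trace" in fh else None,
            n_iter=int(meta["n_iter"]),
        )


def write_scores(s: NFScoreSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": s.times, "value": s.values, "kind": s.kind}
    ).to_csv(path, index=False)


def read_scores(path: str | Path) -> NFScoreSeries:
    df = pd.read_csv(path)
    steps = np.diff(df["time_s"].to_numpy())
    if len(steps) and (np.any(steps <= 0)):
        raise ValueError("score series times must be strictly increasing")
    kinds = df["kind"].unique()
    if len(kinds) != 1:
        raise ValueError("score file mixes series kinds")
    return NFScoreSeries(
        values=df["value"].to_numpy(),
        kind=str(kinds[0]),
        times=df["time_s"].to_numpy(),
    )
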