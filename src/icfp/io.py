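"""Readers and writers for recordings, decompositions and feature tables.

Standard EEG formats (EDF, BrainVision) are read through MNE; a plain
delimited-matrix fallback with a small YAML sidecar covers everything else.
Fingerprint tables are tab-separated text with the fixed 14-column feature
header; decompositions are stored as two matrices plus metadata in an NPZ
container or as delimited text.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import FEATURE_NAMES, ArtifactTemplate
from .montage import ElectrodeMontage, read_montage
from .preprocess import EEGRecording, ICDecomposition

__all__ = [
    "read_recording",
    "read_matrix_recording",
    "write_matrix_recording",
    "save_decomposition",
    "load_decomposition",
    "write_fingerprints",
    "read_fingerprints",
    "write_template",
    "read_template",
]


def read_recording(path, montage: "ElectrodeMontage | str | Path") -> EEGRecording:
    """Read EDF or BrainVision EEG (by extension) into an EEGRecording.

    ``montage`` supplies the scalp polar coordinates (the spatial features
    need them); its labels must cover the recording's channels.
    """
    import mne

    path = Path(path)
    if path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported EEG format: {path.suffix} (use .edf or .vhdr)")
    if not isinstance(montage, ElectrodeMontage):
        montage = read_montage(montage)
    missing = [ch for ch in raw.ch_names if ch not in montage.labels]
    if missing:
        raise ValueError(f"channels missing from montage: {missing}")
    order = [montage.index(ch) for ch in raw.ch_names]
    sub = montage.subset(np.array(order))
    return EEGRecording(data=raw.get_data() * 1e6, fs=float(raw.info["sfreq"]), montage=sub)


def read_matrix_recording(data_path, meta_path) -> EEGRecording:
    """Delimited channels x samples matrix + YAML sidecar with fs and montage.

    The sidecar must define ``fs`` and per-channel ``labels``, ``theta``,
    ``radius`` lists.
    """
    data = np.loadtxt(data_path, delimiter="\t", ndmin=2)
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    montage = ElectrodeMontage(
        labels=tuple(meta["labels"]),
        theta=np.asarray(meta["theta"], float),
        radius=np.asarray(meta["radius"], float),
    )
    return EEGRecording(data=data, fs=float(meta["fs"]), montage=montage)


def write_matrix_recording(rec: EEGRecording, data_path, meta_path) -> None:
    np.savetxt(data_path, rec.data, delimiter="\t")
    meta = {
        "fs": float(rec.fs),
        "labels": list(rec.montage.labels),
        "theta": [float(v) for v in rec.montage.theta],
        "radius": [float(v) for v in rec.montage.radius],
    }
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh)


def save_decomposition(decomp: ICDecomposition, path) -> None:
    """Store weights, timecourses and metadata in one NPZ container."""
    extra = {}
    if decomp.montage is not None:
        extra = {
            "montage_labels": np.asarray(decomp.montage.labels),
            "montage_theta": decomp.montage.theta,
            "montage_radius": decomp.montage.radius,
        }
    np.savez_compressed(
        path,
        weights=decomp.weights,
        timecourses=decomp.timecourses,
        fs=decomp.fs,
        dataset_id=decomp.dataset_id,
        **extra,
    )


def load_decomposition(path) -> ICDecomposition:
    with np.load(path, allow_pickle=False) as z:
        montage = None
        if "montage_labels" in z:
            montage = ElectrodeMontage(
                labels=tuple(str(x) for x in z["montage_labels"]),
                theta=z["montage_theta"],
                radius=z["montage_radius"],
            )
        return ICDecomposition(
            weights=z["weights"],
            timecourses=z["timecourses"],
            fs=float(z["fs"]),
            montage=montage,
            dataset_id=str(z["dataset_id"]),
        )


def write_fingerprints(table: pd.DataFrame, path) -> None:
    cols = ["dataset_id", "ic_id", *FEATURE_NAMES]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"fingerprint table missing columns: {missing}")
    table[cols].to_csv(path, sep="\t", index=False)


def read_fingerprints(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"fingerprint file missing feature columns: {missing}")
    return df


def write_template(template: ArtifactTemplate, path) -> None:
    """Single-column waveform with rate/kind metadata in header comments."""
    header = f"fs={template.fs}\nkind={template.kind}\nduration={template.duration}"
    np.savetxt(path, template.waveform, header=header)


def read_template(path) -> ArtifactTemplate:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key] = val
    waveform = np.loadtxt(path)
    return ArtifactTemplate(
        waveform=waveform,
        fs=float(meta["fs"]),
        kind=meta.get("kind", "eyeblink"),
        duration=float(meta.get("duration", 4.0)),
    )
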