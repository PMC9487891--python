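"""Reading and writing the pipeline's file formats.

Recordings travel either as EDF (read via mne) or in a native text format:
a delimited sample matrix (``.tsv``, one row per sample, one column per
channel) next to a JSON sidecar holding labels, rate and tags.  The text
format round-trips float64 exactly and keeps test fixtures plain.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Recording

__all__ = [
    "write_recording",
    "read_recording",
    "write_subject_table",
    "read_subject_table",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording as ``<path>.tsv`` + ``<path>.json`` sidecar."""
    path = Path(path)
    if path.suffix != ".tsv":
        path = path.with_suffix(".tsv")
    np.savetxt(path, rec.data.T, fmt="%.17g", delimiter="\t")
    meta = {
        "labels": rec.labels,
        "rate": rec.rate,
        "subject_id": rec.subject_id,
        "condition": rec.condition,
        "n_samples": rec.n_samples,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def _read_native(path: Path) -> Recording:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed sidecar {sidecar}: {exc}") from exc
    for key in ("labels", "rate"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} lacks required key {key!r}")
    try:
        data = np.loadtxt(path, delimiter="\t", ndmin=2).T
    except ValueError as exc:
        raise ValueError(f"malformed or truncated matrix {path}: {exc}") from exc
    if "n_samples" in meta and data.shape[1] != meta["n_samples"]:
        raise ValueError(
            f"{path}: {data.shape[1]} samples on disk, sidecar promises "
            f"{meta['n_samples']} (truncated file?)"
        )
    if data.shape[0] != len(meta["labels"]):
        raise ValueError(
            f"{path}: {data.shape[0]} channels on disk, "
            f"{len(meta['labels'])} labels in sidecar"
        )
    return Recording(
        data, meta["labels"], float(meta["rate"]),
        meta.get("subject_id", "S0"), meta.get("condition", "EC"),
    )


def _read_edf(path: Path, subject_id: str, condition: str) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        raw.get_data(), list(raw.ch_names), float(raw.info["sfreq"]),
        subject_id, condition,
    )


def read_recording(
    path: str | Path,
    format: str | None = None,
    subject_id: str = "S0",
    condition: str = "EC",
) -> Recording:
    """Load a recording from EDF or the native tsv+JSON format.

    ``format`` is inferred from the suffix when not given (``.edf`` vs
    ``.tsv``).  Malformed or truncated files raise rather than loading
    silently short.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "native")
    if fmt == "edf":
        return _read_edf(path, subject_id, condition)
    if fmt == "native":
        return _read_native(path)
    raise ValueError(f"unknown recording format {fmt!r}")


def write_subject_table(df: pd.DataFrame, path: str | Path) -> None:
    pd.DataFrame(df).to_csv(path, index=False)


def read_subject_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"subject table lacks column(s) {sorted(missing)}")
    return df
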