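"""Readers and writers for the pipeline's on-disk formats.

Volumes are NIfTI-1 (uncompressed, for byte-stable reruns); event tables,
nuisance series and gaze logs are tab-separated text; ground truth and
configuration are YAML.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "save_nifti",
    "load_nifti",
    "write_tsv",
    "read_events_tsv",
    "read_gaze_tsv",
    "read_nuisance_tsv",
]

EVENT_COLUMNS = ("onset", "duration", "trial_type", "n_groups", "response", "rt")
GAZE_COLUMNS = ("t", "x", "y", "valid")


class ParseError(ValueError):
    """Malformed tabular input; the message names the offending line."""


def save_nifti(data4d: np.ndarray, path: str | Path, voxel_size_mm: float = 3.0) -> Path:
    """Write an (x, y, z, t) array as uncompressed NIfTI-1."""
    path = Path(path)
    affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(data4d, dtype=np.float64), affine)
    nib.save(img, path)
    return path


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format=None)
    return path


def _read_table(
    path: str | Path, required: tuple[str, ...], numeric: tuple[str, ...]
) -> pd.DataFrame:
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ParseError(f"{path.name} line 1: empty file")
    header = lines[0].split("\t")
    missing = [c for c in required if c not in header]
    if missing:
        raise ParseError(f"{path.name} line 1: missing columns {missing}")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ParseError(
                f"{path.name} line {lineno}: expected {len(header)} fields, got {len(parts)}"
            )
        row = dict(zip(header, parts))
        for col in numeric:
            if col in row:
                try:
                    row[col] = float(row[col])
                except ValueError as exc:
                    raise ParseError(
                        f"{path.name} line {lineno}: non-numeric value {row[col]!r} in {col}"
                    ) from exc
        rows.append(row)
    return pd.DataFrame(rows, columns=header)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    """BIDS-style events table (onset, duration, trial_type, n_groups, ...)."""
    df = _read_table(
        path,
        required=("onset", "duration", "trial_type", "n_groups"),
        numeric=("onset", "duration", "n_groups", "response", "rt"),
    )
    df["n_groups"] = df["n_groups"].astype(int)
    if not df["onset"].is_monotonic_increasing:
        raise ParseError(f"{Path(path).name}: onsets must be increasing")
    return df


def read_gaze_tsv(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, required=GAZE_COLUMNS, numeric=("t", "x", "y"))
    df["valid"] = df["valid"].astype(str).str.strip().isin(("1", "True", "true"))
    return df


def read_nuisance_tsv(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, required=(), numeric=())
    return df.astype(float)
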