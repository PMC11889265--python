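"""Readers and writers: NIfTI volumes, unit-labeled CSV tables, manifests.

All tables embed units in column headers (mCi, mL, Gy, months, h) and are
written with a fixed float format so reruns with the same seed are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

FLOAT_FORMAT = "%.6g"


def save_nifti(volume: np.ndarray, voxel_size_mm, path: Path | str) -> Path:
    """Save a 3D field (activity or 0/1 mask) with the given voxel spacing."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*voxel_size_mm, 1.0])
    data = volume.astype(np.uint8) if volume.dtype == bool else volume.astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine), str(path))
    return path


def load_nifti(path: Path | str) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load a volume and its voxel spacing (mm) from the affine."""
    img = nib.load(str(path))
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, dtype=float), voxel


def write_table(df: pd.DataFrame, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def write_json(obj, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")
    return path


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return json.loads(x.to_json(orient="split"))
    if isinstance(x, pd.Series):
        return x.to_dict()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def write_manifest(manifest: dict, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return path


def read_manifest(path: Path | str) -> dict:
    return yaml.safe_load(Path(path).read_text())


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a config for stamping outputs."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
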