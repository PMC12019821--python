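"""Export helpers: NIfTI volumes, CSV signal/report tables, JSON manifests."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


def save_nifti(volume: np.ndarray, voxel_size: float, path) -> Path:
    """Write a real-valued 3D/4D/5D volume with the voxel size in the header."""
    path = Path(path)
    data = np.abs(volume).astype(np.float32) if np.iscomplexobj(volume) else volume
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    zooms = (voxel_size,) * 3 + (1.0,) * (data.ndim - 3)
    img.header.set_zooms(zooms[: data.ndim])
    nib.save(img, path)
    return path


def save_signals_csv(timestamps: np.ndarray, path, **signals) -> Path:
    """Write time-series columns (e.g. cardiac/respiratory sources) to CSV."""
    path = Path(path)
    pd.DataFrame({"time_s": timestamps, **signals}).to_csv(path, index=False)
    return path


def save_json(obj: dict, path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default))
    return path
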