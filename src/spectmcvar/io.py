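"""Volume, mask and table I/O: NIfTI for images, CSV/JSON for tables."""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import ActivityImage, Grid3D, MuMap, ROISet


def _affine(grid: Grid3D) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    half = [(n - 1) / 2.0 * s for n, s in zip(grid.shape, grid.spacing)]
    aff[:3, 3] = [o - h for o, h in zip(grid.origin, half)]
    return aff


def save_volume(path, values: np.ndarray, grid: Grid3D):
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32),
                             _affine(grid)), str(path))


def load_volume(path) -> tuple[np.ndarray, Grid3D]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    data = np.asanyarray(img.dataobj).astype(np.float64)
    grid = Grid3D(data.shape, tuple(float(z) for z in zooms))
    return data, grid


def save_activity(path, act: ActivityImage):
    save_volume(path, act.values, act.grid)


def save_mumap(path, mu: MuMap):
    save_volume(path, mu.values, mu.grid)


def save_roiset(directory, rois: ROISet, prefix: str = "roi"):
    """One NIfTI mask per ROI plus a truth table CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in rois.rois:
        save_volume(directory / f"{prefix}_{r.label}.nii.gz",
                    r.mask.astype(np.uint8), rois.grid)
        rows.append({"label": r.label, "role": r.role,
                     "volume_mm3": float(r.mask.sum() * rois.grid.voxel_volume),
                     "true_activity": r.true_activity})
    df = pd.DataFrame(rows)
    df.to_csv(directory / f"{prefix}_truth.csv", index=False)
    return df


def save_json(path, obj):
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)
    Path(path).write_text(json.dumps(obj, indent=2, default=default))
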