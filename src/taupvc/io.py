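"""File I/O: NIfTI-1 volumes, frame-timing TSV, plasma TSV, masks, JSON.

Conventions
-----------
* 4D dynamic volumes and 3D label volumes are NIfTI-1 (via nibabel) with a
  diagonal affine built from the voxel size unless one is supplied.
* Frame timing is a sidecar TSV with columns frame_index, start_s, duration_s.
* Plasma input is a TSV with columns time_min, parent_plasma, whole_blood.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .image import DynamicImage, FrameSchedule
from .kinetics import PlasmaInput

__all__ = [
    "save_dynamic_image",
    "load_dynamic_image",
    "save_frames_tsv",
    "load_frames_tsv",
    "save_plasma_tsv",
    "load_plasma_tsv",
    "save_labels",
    "load_labels",
    "write_json",
]


def save_frames_tsv(frames: FrameSchedule, path) -> None:
    df = pd.DataFrame(
        {
            "frame_index": np.arange(frames.n_frames),
            "start_s": frames.start_s,
            "duration_s": frames.duration_s,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_frames_tsv(path) -> FrameSchedule:
    df = pd.read_csv(path, sep="\t").sort_values("frame_index")
    return FrameSchedule(df["start_s"].to_numpy(float), df["duration_s"].to_numpy(float))


def save_dynamic_image(img: DynamicImage, nifti_path, frames_path=None) -> None:
    nii = nib.Nifti1Image(np.asarray(img.voxel_data, dtype=np.float32), img.affine)
    nii.header.set_zooms((*img.voxel_size, 1.0))
    nib.save(nii, str(nifti_path))
    if frames_path is not None:
        save_frames_tsv(img.frames, frames_path)


def load_dynamic_image(nifti_path, frames_path) -> DynamicImage:
    nii = nib.load(str(nifti_path))
    data = np.asarray(nii.dataobj, dtype=np.float64)
    frames = load_frames_tsv(frames_path)
    voxel_size = np.asarray(nii.header.get_zooms()[:3], dtype=float)
    return DynamicImage(
        voxel_data=data, frames=frames, voxel_size=voxel_size, affine=np.asarray(nii.affine)
    )


def save_labels(labels: np.ndarray, voxel_size_mm, path) -> None:
    affine = np.diag([*np.asarray(voxel_size_mm, float), 1.0])
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine), str(path))


def load_labels(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).astype(np.int16)


def save_plasma_tsv(plasma: PlasmaInput, path, max_rows: int = 2000) -> None:
    """Write the plasma input; long fine-grid curves are thinned for storage."""
    n = len(plasma.times)
    step = max(1, int(np.ceil(n / max_rows)))
    idx = np.unique(np.concatenate([np.arange(0, n, step), [n - 1]]))
    pd.DataFrame(
        {
            "time_min": plasma.times[idx],
            "parent_plasma": plasma.parent_plasma[idx],
            "whole_blood": plasma.whole_blood[idx],
        }
    ).to_csv(path, sep="\t", index=False)


def load_plasma_tsv(path) -> PlasmaInput:
    df = pd.read_csv(path, sep="\t")
    return PlasmaInput(
        times=df["time_min"].to_numpy(float),
        parent_plasma=df["parent_plasma"].to_numpy(float),
        whole_blood=df["whole_blood"].to_numpy(float),
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")
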