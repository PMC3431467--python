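"""NIfTI and JSON input/output for volumes, masks and phantom geometry."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import CTVolume

__all__ = ["save_volume", "load_volume", "save_mask", "load_mask", "save_geometry", "load_geometry"]


def _affine(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def save_volume(vol: CTVolume, path: str | Path) -> Path:
    """Write a CT volume as NIfTI with voxel spacing in the header.

    The reconstruction label is stored in the header description field.
    """
    path = Path(path)
    img = nib.Nifti1Image(vol.values.astype(np.float32), _affine(vol.spacing_mm))
    img.header["descrip"] = vol.recon_label.encode()[:79]
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path, recon_label: str | None = None) -> CTVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    label = recon_label
    if label is None:
        descrip = img.header["descrip"].tobytes().split(b"\x00", 1)[0].decode(errors="replace")
        label = descrip or "unknown"
    return CTVolume(np.asarray(img.dataobj, dtype=np.float32), spacing, label)


def save_mask(mask: np.ndarray, spacing_mm, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(spacing_mm))
    nib.save(img, str(path))
    return path


def load_mask(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj) > 0, spacing


def save_geometry(geometry: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(geometry, indent=2, sort_keys=True) + "\n")
    return path


def load_geometry(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
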