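"""NIfTI / CSV / JSON persistence for volumes, masks and projection sets."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import ActivityVolume, RegionMask, VoxelGrid

__all__ = [
    "save_volume",
    "load_volume",
    "save_mask",
    "save_projections",
    "load_projections_images",
    "design_to_dict",
    "save_design",
    "save_profile",
]


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.voxel_size_mm
    aff[:3, 3] = grid.origin_mm
    return aff


def save_volume(volume: ActivityVolume, path) -> Path:
    """Write an activity volume as NIfTI (world mm affine)."""
    path = Path(path)
    nib.save(nib.Nifti1Image(volume.values.astype(np.float32), _affine(volume.grid)), path)
    return path


def load_volume(path, label: str = "") -> ActivityVolume:
    img = nib.load(str(path))
    aff = img.affine
    data = np.asarray(img.dataobj, dtype=float)
    grid = VoxelGrid(
        shape=data.shape,
        voxel_size_mm=tuple(float(aff[i, i]) for i in range(3)),
        origin_mm=tuple(float(aff[i, 3]) for i in range(3)),
    )
    return ActivityVolume(grid, data, label=label or Path(path).stem)


def save_mask(mask: RegionMask, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(mask.member.astype(np.uint8), _affine(mask.grid)), path)
    return path


def save_projections(pset, path_stem) -> tuple[Path, Path]:
    """Projection stack as NIfTI (nu, nv, n_proj) plus a JSON sidecar."""
    stem = Path(path_stem)
    img_path = stem.with_suffix(".nii.gz")
    stack = np.moveaxis(pset.images, 0, -1).astype(np.float32)
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = pset.detector_pixel_mm
    nib.save(nib.Nifti1Image(stack, aff), img_path)
    meta = {
        "design": design_to_dict(pset.design),
        "orbit": {
            "mode": pset.orbit.mode,
            "angles_deg": pset.orbit.angles_deg.tolist(),
            "head_index": [p.head_index for p in pset.orbit.poses],
        },
        "detector_pixel_mm": pset.detector_pixel_mm,
        "total_counts": pset.total_counts,
        "noise_seed": pset.noise_seed,
        "meta": {k: v for k, v in pset.meta.items() if np.isscalar(v) or isinstance(v, str)},
    }
    meta_path = stem.with_suffix(".json")
    meta_path.write_text(json.dumps(meta, indent=2))
    return img_path, meta_path


def load_projections_images(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)


def design_to_dict(design) -> dict:
    """Human-readable serialisation of a collimator design."""
    return {
        "family": design.family,
        "target_resolution_mm": design.target_resolution_mm,
        "n_pinholes": design.n_pinholes,
        "focal_length_mm": design.focal_length_mm,
        "ror_mm": design.ror_mm,
        "fov_diameter_mm": design.fov_diameter_mm,
        "detector": asdict(design.detector),
        "pinholes": [asdict(ph) for ph in design.pinholes],
    }


def save_design(design, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(design_to_dict(design), indent=2))
    return path


def save_profile(profile, path) -> Path:
    """Write a line profile as a two-column CSV (position_mm, value)."""
    import pandas as pd

    path = Path(path)
    pd.DataFrame(
        {"position_mm": profile.positions_mm, "value": profile.values}
    ).to_csv(path, index=False)
    return path
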