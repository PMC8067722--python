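"""NIfTI + JSON serialization of grids, fields and datasets.

A dataset directory holds one NIfTI-1 volume per field per visit day
(``phiT_day03.nii`` etc.), uint8 NIfTI masks, and a ``manifest.json`` with
the visit days, RT schedule, capacity bounds and file names.  The NIfTI
affine encodes the voxel spacing (mm).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import AnimalDataset, CapacityState, Grid3D, Visit


def _affine(grid: Grid3D) -> np.ndarray:
    return np.diag([grid.dx, grid.dy, grid.dz, 1.0])


def save_field(path: str | Path, values: np.ndarray, grid: Grid3D) -> None:
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), _affine(grid))
    nib.save(img, str(path))


def save_mask(path: str | Path, mask: np.ndarray, grid: Grid3D) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(grid))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def _day_tag(day: float) -> str:
    return f"{day:05.1f}".replace(".", "p")


def save_dataset(dataset: AnimalDataset, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    grid = dataset.grid
    save_mask(directory / "brain_mask.nii", grid.brain_mask, grid)
    save_mask(directory / "tissue_labels.nii", grid.tissue_labels, grid)
    visits = []
    for v in dataset.visits:
        tag = _day_tag(v.day)
        names = {"phi_T": f"phiT_{tag}.nii", "phi_V": f"phiV_{tag}.nii",
                 "tumor_mask": f"mask_{tag}.nii"}
        save_field(directory / names["phi_T"], v.phi_T, grid)
        save_field(directory / names["phi_V"], v.phi_V, grid)
        save_mask(directory / names["tumor_mask"], v.tumor_mask, grid)
        visits.append({"day": v.day, **names})
    manifest = {
        "grid": {"shape": list(grid.shape),
                 "spacing": [grid.dx, grid.dy, grid.dz]},
        "visits": visits,
        "rt_events": [[d, dose] for d, dose in dataset.rt_events],
        "phi_V_pretreatment_mean": dataset.phi_V_pretreatment_mean,
    }
    if dataset.capacity is not None:
        cap = dataset.capacity
        manifest["capacity"] = {"theta_min": cap.theta_min,
                                "theta_max": cap.theta_max,
                                "theta_V": cap.theta_V,
                                "phi_V_thresh": cap.phi_V_thresh}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory


def load_dataset(directory: str | Path) -> AnimalDataset:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    nx, ny, nz = manifest["grid"]["shape"]
    dx, dy, dz = manifest["grid"]["spacing"]
    brain = load_volume(directory / "brain_mask.nii").astype(bool)
    labels = load_volume(directory / "tissue_labels.nii").astype(np.uint8)
    grid = Grid3D(nx, ny, nz, dx, dy, dz, brain_mask=brain, tissue_labels=labels)
    visits = [
        Visit(day=float(v["day"]),
              phi_T=load_volume(directory / v["phi_T"]),
              phi_V=load_volume(directory / v["phi_V"]),
              tumor_mask=load_volume(directory / v["tumor_mask"]).astype(bool))
        for v in manifest["visits"]
    ]
    capacity = None
    if "capacity" in manifest:
        c = manifest["capacity"]
        capacity = CapacityState(
            theta_T=np.full(grid.shape, c["theta_max"]),
            theta_min=c["theta_min"], theta_max=c["theta_max"],
            theta_V=c["theta_V"], phi_V_thresh=c["phi_V_thresh"])
    return AnimalDataset(grid=grid, visits=visits,
                         rt_events=[(float(d), float(g)) for d, g in manifest["rt_events"]],
                         capacity=capacity,
                         phi_V_pretreatment_mean=manifest.get("phi_V_pretreatment_mean"))
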