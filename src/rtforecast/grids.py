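"""Voxel grids, scalar fields, and the derived geometry/capacity fields.

The study domain is a regular 3D voxel grid (default spacing 0.25 x 0.25 x
1.0 mm, matching small-animal MRI) carrying two volume-fraction fields: the
tumor cell volume fraction ``phi_T`` and the blood volume fraction
``phi_V``.  This module holds the grid/field containers plus the derived
fields the growth equations need:

* the vascularity-driven tumor carrying capacity ``theta_T`` (piecewise
  linear in ``phi_V`` up to a threshold, then saturated at ``theta_max``),
* the normalized distance-to-periphery field ``d`` (1 on the tumor rim,
  0 at the deepest interior voxel) that localizes angiogenesis vs.
  vascular regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

# tissue label codes
LABEL_OTHER = 0
LABEL_WHITE = 1
LABEL_GRAY = 2


@dataclass
class Grid3D:
    """Regular anisotropic voxel grid with a brain mask and tissue labels."""

    nx: int
    ny: int
    nz: int
    dx: float = 0.25
    dy: float = 0.25
    dz: float = 1.0
    brain_mask: np.ndarray | None = None
    tissue_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("grid spacings must be positive")
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.shape, dtype=bool)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != self.shape:
            raise ValueError("brain_mask shape mismatch")
        if not self.brain_mask.any():
            raise ValueError("brain_mask is empty")
        if self.tissue_labels is None:
            # default: everything gray matter
            self.tissue_labels = np.full(self.shape, LABEL_GRAY, dtype=np.uint8)
        self.tissue_labels = np.asarray(self.tissue_labels, dtype=np.uint8)
        if self.tissue_labels.shape != self.shape:
            raise ValueError("tissue_labels shape mismatch")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.dx, self.dy, self.dz)

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return self.dx * self.dy * self.dz

    def zeros(self) -> np.ndarray:
        return np.zeros(self.shape, dtype=float)


@dataclass
class ScalarField3D:
    """A named real-valued field on a :class:`Grid3D`."""

    values: np.ndarray
    name: str = ""
    grid: Grid3D | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.grid is not None and self.values.shape != self.grid.shape:
            raise ValueError(f"field {self.name!r} shape mismatch with grid")

    def validate_fraction(self) -> None:
        """Check the invariants of a volume-fraction field inside the mask."""
        v = self.values
        mask = self.grid.brain_mask if self.grid is not None else np.ones(v.shape, bool)
        inside = v[mask]
        if not np.all(np.isfinite(inside)):
            raise ValueError(f"field {self.name!r} has non-finite values in mask")
        if inside.size and (inside.min() < -1e-12 or inside.max() > 1 + 1e-12):
            raise ValueError(f"field {self.name!r} outside [0, 1]")


@dataclass
class CapacityState:
    """Carrying-capacity bookkeeping for the coupled tumor/vasculature system.

    ``theta_T`` is the voxelwise tumor carrying capacity, bounded by the
    smallest/largest tumor volume fractions observed in the calibration
    visits (``theta_min``/``theta_max``); ``theta_V`` is the (scalar) blood
    volume fraction carrying capacity; ``phi_V_thresh`` is the vascularity
    level above which a voxel supports the full ``theta_max``.
    """

    theta_T: np.ndarray
    theta_min: float
    theta_max: float
    theta_V: float
    phi_V_thresh: float

    def __post_init__(self) -> None:
        self.theta_T = np.asarray(self.theta_T, dtype=float)
        if not (0 < self.theta_min <= self.theta_max <= 1):
            raise ValueError("require 0 < theta_min <= theta_max <= 1")
        if not (0 < self.phi_V_thresh < self.theta_V):
            raise ValueError("require 0 < phi_V_thresh < theta_V")

    @property
    def theta_TV(self) -> np.ndarray:
        """Summed tumor + blood carrying capacity, voxelwise."""
        return self.theta_T + self.theta_V

    def replace(self, **kw) -> "CapacityState":
        d = dict(theta_T=self.theta_T, theta_min=self.theta_min,
                 theta_max=self.theta_max, theta_V=self.theta_V,
                 phi_V_thresh=self.phi_V_thresh)
        d.update(kw)
        return CapacityState(**d)


@dataclass
class DistanceField:
    """Normalized distance-to-periphery: 1 on the rim, 0 at maximal depth."""

    d: np.ndarray
    tumor_mask: np.ndarray


@dataclass
class Visit:
    day: float
    phi_T: np.ndarray
    phi_V: np.ndarray
    tumor_mask: np.ndarray


@dataclass
class AnimalDataset:
    """One animal's longitudinal maps, RT schedule and capacity bounds."""

    grid: Grid3D
    visits: list[Visit]
    rt_events: list[tuple[float, float]]  # (day, dose in Gy)
    capacity: CapacityState | None = None
    phi_V_pretreatment_mean: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        days = [v.day for v in self.visits]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("visit days must be strictly increasing")

    @property
    def visit_days(self) -> list[float]:
        return [v.day for v in self.visits]


def compute_distance_to_periphery(tumor_mask: np.ndarray, grid: Grid3D) -> DistanceField:
    """Normalized distance-to-periphery field of a tumor mask.

    The Euclidean distance (with anisotropic voxel spacings, in mm) from
    each tumor voxel to the nearest tumor *boundary* voxel is computed and
    linearly rescaled so that boundary voxels map to 1 and the deepest
    voxel maps to 0.  A tumor made entirely of boundary voxels gets
    ``d = 1`` everywhere (pure-periphery behavior).  ``d`` is 0 outside
    the mask.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if tumor_mask.shape != grid.shape:
        raise ValueError("tumor_mask shape mismatch")
    if not tumor_mask.any():
        raise ValueError("tumor mask is empty")
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    interior = ndimage.binary_erosion(tumor_mask, structure=structure, border_value=0)
    boundary = tumor_mask & ~interior
    d = np.zeros(grid.shape, dtype=float)
    if not interior.any():
        d[tumor_mask] = 1.0
        return DistanceField(d=d, tumor_mask=tumor_mask)
    # distance of every voxel to the nearest boundary-voxel center
    nonboundary = np.ones(grid.shape, dtype=bool)
    nonboundary[boundary] = False
    dist = ndimage.distance_transform_edt(nonboundary, sampling=grid.spacing)
    depth = dist[tumor_mask]
    dmax = depth.max()
    if dmax <= 0:
        d[tumor_mask] = 1.0
    else:
        d[tumor_mask] = 1.0 - depth / dmax
    return DistanceField(d=d, tumor_mask=tumor_mask)


def update_carrying_capacity(phi_V: np.ndarray, cap: CapacityState) -> np.ndarray:
    """Voxelwise tumor carrying capacity from the current vascularity.

    ``theta_T = theta_max`` wherever ``phi_V >= phi_V_thresh``; below the
    threshold it ramps linearly from ``theta_min`` (at ``phi_V = 0``) to
    ``theta_max`` (continuous at the threshold).
    """
    if cap.phi_V_thresh <= 0:
        raise ValueError("phi_V_thresh must be positive")
    phi_V = np.asarray(phi_V, dtype=float)
    ramp = cap.theta_min + phi_V * (cap.theta_max - cap.theta_min) / cap.phi_V_thresh
    theta = np.where(phi_V >= cap.phi_V_thresh, cap.theta_max, ramp)
    return np.clip(theta, cap.theta_min, cap.theta_max)


def assign_capacity_bounds(
    calibration_visits: Sequence[Visit],
    phi_V_thresh: float | None = None,
) -> CapacityState:
    """Capacity bounds from the measured maps of the calibration visits.

    ``theta_min``/``theta_max`` are the smallest/largest tumor volume
    fractions over tumor voxels across the calibration visits; ``theta_V``
    is the largest observed blood volume fraction over the same support.
    ``phi_V_thresh`` is a calibrated parameter; a placeholder (half of
    ``theta_V``) is used until the optimizer supplies one.
    """
    if not calibration_visits:
        raise ValueError("need at least one calibration visit")
    phis_T, phis_V = [], []
    for v in calibration_visits:
        m = np.asarray(v.tumor_mask, dtype=bool)
        if m.any():
            phis_T.append(np.asarray(v.phi_T)[m])
            phis_V.append(np.asarray(v.phi_V)[m])
    if not phis_T:
        raise ValueError("no tumor voxels in calibration visits")
    phi_T_all = np.concatenate(phis_T)
    phi_V_all = np.concatenate(phis_V)
    if not (phi_T_all.any() or phi_V_all.any()):
        raise ValueError("all-zero fields in calibration visits")
    theta_min = float(max(phi_T_all.min(), 1e-6))
    theta_max = float(min(phi_T_all.max(), 1.0))
    theta_V = float(min(phi_V_all.max(), 1.0))
    if theta_V <= 0:
        raise ValueError("no observed blood volume; theta_V undefined")
    if phi_V_thresh is None:
        phi_V_thresh = 0.5 * theta_V
    shape = np.asarray(calibration_visits[0].phi_T).shape
    cap = CapacityState(
        theta_T=np.full(shape, theta_max, dtype=float),
        theta_min=theta_min,
        theta_max=theta_max,
        theta_V=theta_V,
        phi_V_thresh=float(phi_V_thresh),
    )
    cap.theta_T = update_carrying_capacity(np.asarray(calibration_visits[0].phi_V), cap)
    return cap
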