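"""Voxel-grid geometry and dose-volume metric engine.

All physical lengths are centimetres, volumes cubic centimetres (cc) and
doses gray (Gy).  A :class:`DoseGrid` holds the absorbed-dose scalar field
of one (possibly summed) treatment plan; :class:`StructureMask` holds the
binary occupancy of one anatomical structure on the *same* grid.  Any
resampling between native formats happens once at ingest (see
:mod:`kbpdose.io`); every metric here assumes a single shared geometry.

Conventions, fixed once so that independent oracles agree:

* ``VxGy`` counts a voxel when its dose is **>= x** (inclusive threshold).
* ``Dq%`` is the dose of the voxel at descending rank ``ceil(q/100 * N)``
  among the N structure voxels (the minimum dose of the hottest q%), with
  no interpolation.
* Masks are binary; there is no partial-voxel weighting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np


class EmptyStructureError(ValueError):
    """A metric was requested for a structure with no voxels set."""


class GeometryMismatchError(ValueError):
    """Two grids that must share one geometry do not."""


@dataclass(frozen=True)
class GridGeometry:
    """Axis-aligned voxel lattice in physical patient coordinates.

    ``origin`` is the physical coordinate (cm) of the *center* of voxel
    ``(0, 0, 0)``; ``spacing`` is the per-axis voxel pitch (cm); ``shape``
    the voxel counts.  Array axes are (x, y, z).
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.shape) != 3:
            raise ValueError("origin, spacing and shape must be 3-vectors")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if any(int(n) < 1 for n in self.shape):
            raise ValueError(f"shape must be >= 1 per axis, got {self.shape}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in cc (spacings are in cm)."""
        return float(self.spacing[0] * self.spacing[1] * self.spacing[2])

    def axis_coordinates(self, axis: int) -> np.ndarray:
        """Physical center coordinates (cm) of voxels along ``axis``."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of voxel indices to physical coordinates."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


class StructureRole(str, Enum):
    TARGET = "target"
    OAR = "oar"


@dataclass
class DoseGrid:
    """3-D absorbed-dose field (Gy) with its geometry and prescription.

    ``prescription_dose`` is the total prescribed dose in Gy (76 Gy for the
    summed two-series prostate protocol this package defaults to).
    """

    geometry: GridGeometry
    dose: np.ndarray
    prescription_dose: float = 76.0

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=np.float64)
        if tuple(self.dose.shape) != tuple(self.geometry.shape):
            raise ValueError(
                f"dose array shape {self.dose.shape} does not match grid shape "
                f"{self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.dose)):
            raise ValueError("dose values must be finite")
        if np.any(self.dose < 0):
            raise ValueError("dose values must be non-negative")
        if self.prescription_dose <= 0:
            raise ValueError("prescription_dose must be > 0")

    def scaled(self, k: float) -> "DoseGrid":
        """Return a copy with all doses (and the prescription) scaled by k."""
        if k <= 0:
            raise ValueError("scale factor must be > 0")
        return DoseGrid(self.geometry, self.dose * k, self.prescription_dose * k)


@dataclass
class StructureMask:
    """Binary occupancy of one structure on the shared voxel grid."""

    name: str
    role: StructureRole
    occupancy: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if isinstance(self.role, str):
            self.role = StructureRole(self.role)
        if tuple(self.occupancy.shape) != tuple(self.geometry.shape):
            raise ValueError(
                f"mask {self.name!r}: occupancy shape {self.occupancy.shape} does "
                f"not match grid shape {self.geometry.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.occupancy))

    def is_empty(self) -> bool:
        return self.voxel_count == 0


def _require_non_empty(mask: StructureMask) -> None:
    if mask.is_empty():
        raise EmptyStructureError(f"structure {mask.name!r} has no voxels set")


def _require_same_geometry(a: StructureMask | DoseGrid, b: StructureMask | DoseGrid) -> None:
    if a.geometry != b.geometry:
        name_a = getattr(a, "name", "dose grid")
        name_b = getattr(b, "name", "dose grid")
        raise GeometryMismatchError(
            f"{name_a!r} and {name_b!r} are not on the same grid "
            f"({a.geometry} vs {b.geometry})"
        )


def structure_volume(mask: StructureMask) -> float:
    """Volume of a structure in cc: set-voxel count times voxel volume."""
    _require_non_empty(mask)
    return mask.voxel_count * mask.geometry.voxel_volume


def overlap_volume(a: StructureMask, b: StructureMask) -> float:
    """Volume (cc) of the voxelwise intersection of two structures."""
    _require_same_geometry(a, b)
    n = int(np.count_nonzero(a.occupancy & b.occupancy))
    return n * a.geometry.voxel_volume


def overlap_fraction(oar: StructureMask, ptv: StructureMask) -> float:
    """Percentage of the OAR volume lying inside the target:
    ``100 * V_OV(OAR/PTV) / V_OAR``, in [0, 100]."""
    _require_non_empty(oar)
    return 100.0 * overlap_volume(oar, ptv) / structure_volume(oar)


def centroid(mask: StructureMask) -> np.ndarray:
    """Center of mass of the structure: unweighted mean of set-voxel
    center coordinates, in cm."""
    _require_non_empty(mask)
    idx = np.argwhere(mask.occupancy)
    return mask.geometry.voxel_centers(idx).mean(axis=0)


def centroid_distance(a: StructureMask, b: StructureMask) -> float:
    """Euclidean distance (cm) between two structure centroids."""
    _require_same_geometry(a, b)
    return float(np.linalg.norm(centroid(a) - centroid(b)))


@dataclass
class Dvh:
    """Cumulative dose-volume histogram of one structure.

    ``cumulative_volume[i]`` is the volume (cc) receiving at least
    ``bin_edges[i]`` Gy; it is non-increasing and starts at the total
    structure volume.
    """

    bin_edges: np.ndarray
    cumulative_volume: np.ndarray
    total_volume: float
    structure: str = ""

    def volume_at(self, dose_gy: float) -> float:
        """Cumulative volume at the bin edge nearest below ``dose_gy``."""
        i = int(np.searchsorted(self.bin_edges, dose_gy, side="right")) - 1
        i = max(i, 0)
        return float(self.cumulative_volume[i])


DEFAULT_DVH_BIN_WIDTH = 0.05  # Gy; finer than the 0.1 Gy reporting precision


def cumulative_dvh(
    dose: DoseGrid, mask: StructureMask, bin_width: float = DEFAULT_DVH_BIN_WIDTH
) -> Dvh:
    """Cumulative DVH from the raw voxel doses of one structure."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    _require_same_geometry(dose, mask)
    _require_non_empty(mask)
    voxels = dose.dose[mask.occupancy]
    dmax = float(voxels.max())
    n_bins = int(math.floor(dmax / bin_width)) + 2  # last edge >= max dose
    edges = np.arange(n_bins) * bin_width
    counts = (voxels[None, :] >= edges[:, None]).sum(axis=1)
    vv = mask.geometry.voxel_volume
    return Dvh(
        bin_edges=edges,
        cumulative_volume=counts.astype(float) * vv,
        total_volume=voxels.size * vv,
        structure=mask.name,
    )


def v_dose(
    dose: DoseGrid, mask: StructureMask, threshold: float, unit: str = "cc"
) -> float:
    """VxGy: volume receiving at least ``threshold`` Gy, as cc or as a
    percentage of the structure volume.  Computed from voxels directly,
    never from a binned DVH."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    _require_same_geometry(dose, mask)
    _require_non_empty(mask)
    voxels = dose.dose[mask.occupancy]
    n_above = int(np.count_nonzero(voxels >= threshold))
    if unit == "cc":
        return n_above * mask.geometry.voxel_volume
    if unit in ("percent", "%"):
        return 100.0 * n_above / voxels.size
    raise ValueError(f"unit must be 'cc' or 'percent', got {unit!r}")


def d_at_volume_percent(dose: DoseGrid, mask: StructureMask, q: float) -> float:
    """Dq%: minimum dose (Gy) received by the hottest q% of the structure.

    Discrete convention: sort structure voxel doses descending and take the
    dose at rank ``ceil(q/100 * N)``.  Monotonically non-increasing in q.
    """
    if not 0 < q <= 100:
        raise ValueError(f"q must be in (0, 100], got {q}")
    _require_same_geometry(dose, mask)
    _require_non_empty(mask)
    voxels = np.sort(dose.dose[mask.occupancy])[::-1]
    rank = max(1, math.ceil(q / 100.0 * voxels.size))
    return float(voxels[rank - 1])


def mean_dose(dose: DoseGrid, mask: StructureMask) -> float:
    """Davg: arithmetic mean dose (Gy) over the structure voxels."""
    _require_same_geometry(dose, mask)
    _require_non_empty(mask)
    return float(dose.dose[mask.occupancy].mean())


def max_dose(dose: DoseGrid, mask: StructureMask) -> float:
    """Dmax: maximum voxel dose (Gy) inside the structure."""
    _require_same_geometry(dose, mask)
    _require_non_empty(mask)
    return float(dose.dose[mask.occupancy].max())


def sum_dose_grids(grids: Iterable[DoseGrid]) -> DoseGrid:
    """Voxelwise sum of plan dose grids sharing one geometry.

    Used to evaluate constraints that apply to the sum of a multi-series
    treatment (e.g. a 46 Gy series plus a 30 Gy boost); prescriptions add.
    """
    grids = list(grids)
    if not grids:
        raise ValueError("need at least one dose grid")
    total = grids[0].dose.copy()
    prescription = grids[0].prescription_dose
    for g in grids[1:]:
        _require_same_geometry(grids[0], g)
        total += g.dose
        prescription += g.prescription_dose
    return DoseGrid(grids[0].geometry, total, prescription)
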