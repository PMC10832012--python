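"""Synthetic pelvic phantom and training-cohort generator.

Two levels of synthesis, matching two levels of testing:

* :func:`make_phantom` / :func:`make_dose` build a full voxel phantom —
  analytic primitives for the targets (nested ellipsoids for PTV46/PTV76),
  a posterior rectal tube, an anterior-superior bladder sphere and a large
  superior peritoneal-cavity region that excludes the targets, bladder and
  rectum — plus a dose field with a prescription plateau inside the targets
  and exponential falloff with distance.  This exercises the metric engine
  end to end with geometry whose volumes and overlaps are known analytically.

* :func:`make_cohort` operates at the feature level: it draws geometric
  predictor values from stated ranges and generates response metrics from a
  known line y = A x + B plus Gaussian scatter.  Model fitting in a real
  clinic consumes treatment-planning-system output that no phantom can
  recreate, so parameter-recovery and interval-coverage tests run on these
  feature tables while the full phantom serves the dose-metric engine.

Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize

from .core import DoseGrid, GridGeometry, StructureMask, StructureRole
from .models import KbpModelSpec, default_model_specs

Vec3 = tuple[float, float, float]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and dose parameters of one synthetic pelvic phantom.

    Defaults give a 64^3 grid at 0.2 cm isotropic spacing (a 12.8 cm cube):
    desk-scale, yet with discretisation error on analytic volumes below a
    couple of percent.  Axes: x lateral, y anterior->posterior, z
    inferior->superior.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: Vec3 = (0.2, 0.2, 0.2)
    origin: Vec3 = (0.0, 0.0, 0.0)

    # nested ellipsoidal targets (centers/radii in cm)
    ptv46_center: Vec3 = (6.4, 6.4, 5.6)
    ptv46_radii: Vec3 = (3.2, 3.0, 3.4)
    ptv76_center: Vec3 = (6.4, 6.4, 5.0)
    ptv76_radii: Vec3 = (2.0, 2.0, 2.0)

    # margin between the CTVs (which the cavity excludes) and the PTVs
    ctv_margin_cm: float = 0.5

    # rectum: tube along z on the posterior side, grazing the boost target
    rectum_center: Vec3 = (6.4, 8.6, 5.2)
    rectum_radius: float = 1.0
    rectum_half_length: float = 3.0

    # bladder: sphere anterior-superior to the prostate
    bladder_center: Vec3 = (6.4, 4.4, 6.6)
    bladder_radius: float = 1.8

    # peritoneal cavity: superior box bounded by the pelvic wall, minus
    # CTVs, bladder and rectum
    cavity_z_range: tuple[float, float] = (7.2, 12.4)
    cavity_x_range: tuple[float, float] = (1.0, 11.8)
    cavity_y_range: tuple[float, float] = (2.0, 11.0)

    prescription_dose: float = 76.0
    target_doses: tuple[tuple[str, float], ...] = (("PTV76", 76.0), ("PTV46", 46.0))
    falloff_cm: float = 1.2  # exponential length scale of dose outside targets
    noise_sd: float = 0.0  # Gy, Gaussian, clipped at 0
    seed: int = 0

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(self.origin, self.spacing, self.shape)


def _coordinate_grids(geom: GridGeometry) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [geom.axis_coordinates(i) for i in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def ellipsoid_mask(geom: GridGeometry, center: Vec3, radii: Vec3) -> np.ndarray:
    if any(r <= 0 for r in radii):
        raise ValueError("ellipsoid radii must be positive")
    xx, yy, zz = _coordinate_grids(geom)
    return (
        ((xx - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((zz - center[2]) / radii[2]) ** 2
    ) <= 1.0


def cylinder_mask(
    geom: GridGeometry, center: Vec3, radius: float, half_length: float, axis: int = 2
) -> np.ndarray:
    """Solid tube of given radius around a line parallel to ``axis``."""
    if radius <= 0 or half_length <= 0:
        raise ValueError("cylinder radius and half_length must be positive")
    coords = _coordinate_grids(geom)
    radial = [c - center[i] for i, c in enumerate(coords) if i != axis]
    in_disc = radial[0] ** 2 + radial[1] ** 2 <= radius**2
    in_span = np.abs(coords[axis] - center[axis]) <= half_length
    return in_disc & in_span


def box_mask(
    geom: GridGeometry, x_range, y_range, z_range
) -> np.ndarray:
    xx, yy, zz = _coordinate_grids(geom)
    return (
        (xx >= x_range[0]) & (xx <= x_range[1])
        & (yy >= y_range[0]) & (yy <= y_range[1])
        & (zz >= z_range[0]) & (zz <= z_range[1])
    )


def make_phantom(spec: PhantomSpec) -> dict[str, StructureMask]:
    """Build the structure set of one phantom.

    PTV76 is forced to be a subset of PTV46 (boost inside the large
    target).  The cavity excludes the *CTVs* (targets shrunk by the
    PTV margin), bladder and rectum — so it can genuinely overlap the PTVs
    the way a contoured peritoneal cavity does.  A primitive that
    rasterises to an empty mask means the requested geometry is infeasible
    on this grid and raises.
    """
    geom = spec.geometry
    if spec.ctv_margin_cm < 0:
        raise ValueError("ctv_margin_cm must be >= 0")
    ptv76 = ellipsoid_mask(geom, spec.ptv76_center, spec.ptv76_radii)
    ptv46 = ellipsoid_mask(geom, spec.ptv46_center, spec.ptv46_radii) | ptv76
    shrink = lambda radii: tuple(max(r - spec.ctv_margin_cm, 0.1) for r in radii)
    ctv46 = ellipsoid_mask(geom, spec.ptv46_center, shrink(spec.ptv46_radii))
    ctv76 = ellipsoid_mask(geom, spec.ptv76_center, shrink(spec.ptv76_radii))
    rectum = cylinder_mask(geom, spec.rectum_center, spec.rectum_radius, spec.rectum_half_length)
    bladder = ellipsoid_mask(geom, spec.bladder_center, (spec.bladder_radius,) * 3)
    cavity = box_mask(geom, spec.cavity_x_range, spec.cavity_y_range, spec.cavity_z_range)
    cavity &= ~(ctv46 | ctv76 | bladder | rectum)

    arrays = {
        "PTV46": (ptv46, StructureRole.TARGET),
        "PTV76": (ptv76, StructureRole.TARGET),
        "Rectum": (rectum, StructureRole.OAR),
        "Bladder": (bladder, StructureRole.OAR),
        "PeritonealCavity": (cavity, StructureRole.OAR),
    }
    structures = {}
    for name, (occ, role) in arrays.items():
        if not occ.any():
            raise ValueError(f"phantom structure {name!r} is empty on this grid")
        structures[name] = StructureMask(name=name, role=role, occupancy=occ, geometry=geom)
    return structures


def make_dose(structures: dict[str, StructureMask], spec: PhantomSpec) -> DoseGrid:
    """Dose field: per-target prescription plateau + exponential falloff.

    Each target named in ``spec.target_doses`` contributes
    ``D_t * exp(-d_t / L)`` where ``d_t`` is the Euclidean distance (cm) to
    the target surface; the voxel dose is the maximum contribution.  A zero
    falloff scale degenerates to plateau-inside / zero-outside.  Optional
    Gaussian noise (sd in Gy) is added and clipped at zero; the field is
    reproducible from the spec's seed.
    """
    if spec.falloff_cm < 0:
        raise ValueError("falloff_cm must be >= 0")
    geom = spec.geometry
    dose = np.zeros(geom.shape, dtype=float)
    for target_name, level in spec.target_doses:
        if target_name not in structures:
            continue
        occ = structures[target_name].occupancy
        if spec.falloff_cm == 0:
            contrib = np.where(occ, level, 0.0)
        else:
            dist = ndimage.distance_transform_edt(~occ, sampling=geom.spacing)
            contrib = level * np.exp(-dist / spec.falloff_cm)
        np.maximum(dose, contrib, out=dose)
    if not any(name in structures for name, _ in spec.target_doses):
        raise ValueError("no target structure present to anchor the dose field")
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        dose = dose + rng.normal(0.0, spec.noise_sd, size=dose.shape)
    np.clip(dose, 0.0, None, out=dose)
    return DoseGrid(geom, dose, prescription_dose=spec.prescription_dose)


def _sphere_lens_volume(d: float, r1: float, r2: float) -> float:
    """Intersection volume of two spheres with center distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return 4.0 / 3.0 * np.pi * r**3
    return (
        np.pi
        * (r1 + r2 - d) ** 2
        * (d**2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
        / (12 * d)
    )


def sphere_offset_for_overlap(
    r_oar: float, r_ptv: float, overlap_fraction_pct: float
) -> float:
    """Center distance at which a spherical OAR shares the requested
    volume fraction (percent of the OAR) with a spherical target.

    Solves the sphere-sphere lens volume analytically (Brent root find on
    the closed form), so phantoms can be positioned to hit any overlap
    fraction from 0 to 100%.
    """
    if not 0 <= overlap_fraction_pct <= 100:
        raise ValueError("overlap fraction must be in [0, 100]")
    v_oar = 4.0 / 3.0 * np.pi * r_oar**3
    target = overlap_fraction_pct / 100.0 * v_oar
    if overlap_fraction_pct == 0:
        return r_oar + r_ptv
    full_at = abs(r_ptv - r_oar) if r_ptv >= r_oar else 0.0
    if target >= _sphere_lens_volume(full_at, r_oar, r_ptv) - 1e-12:
        return full_at
    return float(
        optimize.brentq(
            lambda d: _sphere_lens_volume(d, r_oar, r_ptv) - target,
            full_at + 1e-9,
            r_oar + r_ptv,
        )
    )


@dataclass(frozen=True)
class ModelTruth:
    """Ground-truth line of one model in a simulated training cohort."""

    slope: float
    intercept: float
    noise_sd: float
    x_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.x_range[0] > self.x_range[1] or self.x_range[0] < 0:
            raise ValueError("x_range must be ordered and non-negative")


def default_model_truths() -> dict[str, ModelTruth]:
    """Plausible prostate-cohort ground truths per default model.

    Chosen so that predictor ranges span the geometries a pelvic cohort
    shows (overlap fractions up to ~30%, cavity-to-target distances up to
    ~15 cm, cavity overlap x volume products of 10^4-10^5 cc^2) and the
    responses land near the metric scales of a summed 76 Gy protocol.
    """
    return {
        "rectum_v60": ModelTruth(0.90, 2.0, 1.5, (0.0, 30.0)),
        "rectum_v70": ModelTruth(0.70, 0.5, 1.0, (0.0, 30.0)),
        "bladder_v60": ModelTruth(0.85, 1.5, 1.5, (0.0, 30.0)),
        "bladder_v70": ModelTruth(0.65, 0.5, 1.0, (0.0, 30.0)),
        "cavity_davg": ModelTruth(-1.6, 35.0, 2.0, (5.0, 15.0)),
        "cavity_v45": ModelTruth(6.0, 5.0, 8.0, (0.0, 8.0)),
        "cavity_v15": ModelTruth(4.0e-3, 150.0, 60.0, (2.0e4, 1.5e5)),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Specification of one simulated training cohort."""

    n_plans: int = 25
    seed: int = 0
    truths: dict[str, ModelTruth] = field(default_factory=default_model_truths)

    def __post_init__(self) -> None:
        if self.n_plans < 3:
            raise ValueError("a cohort needs at least 3 plans")


def make_cohort(
    spec: CohortSpec, model_specs: list[KbpModelSpec] | None = None
):
    """Simulate a feature-level training cohort.

    For each model with a ground truth in the spec, predictor values are
    drawn uniformly from the truth's range and responses as
    ``y = A x + B + eps`` with ``eps ~ N(0, sd)`` — exactly the
    linear-Gaussian structure the fitter assumes, so recovery and coverage
    tests have a known truth.  Returns ``(table, truths)`` where the table
    is a DataFrame with columns ``x_<model_id>`` and ``y_<model_id>`` and
    one row per plan, and ``truths`` maps model ids to their generating
    :class:`ModelTruth`.
    """
    import pandas as pd

    if model_specs is None:
        model_specs = default_model_specs()
    rng = np.random.default_rng(spec.seed)
    data: dict[str, np.ndarray] = {}
    truths: dict[str, ModelTruth] = {}
    for ms in model_specs:
        truth = spec.truths.get(ms.model_id)
        if truth is None:
            continue
        x = rng.uniform(truth.x_range[0], truth.x_range[1], size=spec.n_plans)
        eps = rng.normal(0.0, truth.noise_sd, size=spec.n_plans) if truth.noise_sd > 0 else 0.0
        y = truth.slope * x + truth.intercept + eps
        data[f"x_{ms.model_id}"] = x
        data[f"y_{ms.model_id}"] = y
        truths[ms.model_id] = truth
    if not truths:
        raise ValueError("no model spec matches any ground truth in the cohort spec")
    table = pd.DataFrame(data, index=pd.RangeIndex(spec.n_plans, name="plan"))
    return table, truths
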