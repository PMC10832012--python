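"""Target-coverage indices and constraint-template auditing for one plan.

A plan is accepted when 95% of the PTV receives at least 95% of the
prescription and the maximum dose stays below 107%.  On top of that,
each organ at risk (OAR) carries dose-volume constraints from a clinic
template; the default template matches a national-recommendation set for
summed two-series prostate VMAT (peritoneal cavity Dmax < 54 Gy,
V45Gy < 150 cc, V15Gy < 830 cc; rectum/bladder VxGy limits; etc.).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import yaml

from .core import (
    DoseGrid,
    EmptyStructureError,
    StructureMask,
    d_at_volume_percent,
    max_dose,
    mean_dose,
    overlap_volume,
    structure_volume,
    v_dose,
)

_METRIC_RE = re.compile(r"^(?:(Dmax)|(Davg)|V(\d+(?:\.\d+)?)Gy|D(\d+(?:\.\d+)?)%)$")


@dataclass(frozen=True)
class DoseMetric:
    """One dose-volume metric descriptor: Dmax, Davg, VxGy or Dq%.

    ``unit`` is Gy for the dose-valued metrics and cc or percent for
    volume-valued VxGy.
    """

    kind: str  # "Dmax" | "Davg" | "V" | "D"
    value: float = 0.0  # threshold in Gy for V, percentile for D
    unit: str = "Gy"

    def __post_init__(self) -> None:
        if self.kind not in ("Dmax", "Davg", "V", "D"):
            raise ValueError(f"unknown metric kind {self.kind!r}")
        if self.kind == "V" and self.unit not in ("cc", "percent"):
            raise ValueError("VxGy unit must be 'cc' or 'percent'")
        if self.kind in ("Dmax", "Davg", "D") and self.unit != "Gy":
            raise ValueError(f"{self.kind} unit must be 'Gy'")
        if self.kind == "D" and not 0 < self.value <= 100:
            raise ValueError("Dq% percentile must be in (0, 100]")

    @classmethod
    def parse(cls, text: str, unit: str | None = None) -> "DoseMetric":
        """Parse descriptors like ``Dmax``, ``Davg``, ``V45Gy``, ``D95%``.

        A trailing ``(cc)``/``(%)``/``(Gy)`` annotation overrides ``unit``.
        """
        text = text.strip()
        m = re.match(r"^(.*?)\s*\((cc|%|percent|Gy)\)$", text)
        if m:
            text, unit = m.group(1), m.group(2)
        if unit == "%":
            unit = "percent"
        m = _METRIC_RE.match(text)
        if not m:
            raise ValueError(f"cannot parse dose metric {text!r}")
        if m.group(1):
            return cls("Dmax", unit="Gy")
        if m.group(2):
            return cls("Davg", unit="Gy")
        if m.group(3):
            return cls("V", float(m.group(3)), unit=unit or "cc")
        return cls("D", float(m.group(4)), unit="Gy")

    def __str__(self) -> str:
        if self.kind == "V":
            u = "%" if self.unit == "percent" else self.unit
            x = f"{self.value:g}"
            return f"V{x}Gy({u})"
        if self.kind == "D":
            return f"D{self.value:g}%"
        return self.kind

    def evaluate(self, dose: DoseGrid, mask: StructureMask) -> float:
        """Compute this metric for one structure on one dose grid."""
        if self.kind == "Dmax":
            return max_dose(dose, mask)
        if self.kind == "Davg":
            return mean_dose(dose, mask)
        if self.kind == "V":
            return v_dose(dose, mask, self.value, unit=self.unit)
        return d_at_volume_percent(dose, mask, self.value)


@dataclass(frozen=True)
class ConstraintEntry:
    """One clinical constraint: structure + metric + comparator + limit."""

    structure: str
    metric: DoseMetric
    limit: float
    comparator: str = "<"

    def __post_init__(self) -> None:
        if self.comparator not in ("<", "<="):
            raise ValueError("comparator must be '<' or '<='")
        if self.limit <= 0:
            raise ValueError("constraint limit must be positive")

    def passes(self, achieved: float) -> bool:
        return achieved < self.limit if self.comparator == "<" else achieved <= self.limit

    @property
    def key(self) -> str:
        return f"{self.structure}:{self.metric}"

    def __str__(self) -> str:
        u = {"percent": "%"}.get(self.metric.unit, self.metric.unit)
        return f"{self.structure} {self.metric} {self.comparator} {self.limit:g}{u}"


@dataclass
class ConstraintTemplate:
    """Editable set of OAR constraints, serializable to YAML."""

    entries: list[ConstraintEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [e.key for e in self.entries]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (structure, metric) constraint entries")

    def structures(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.structure)
        return list(seen)

    def to_yaml(self) -> str:
        data = [
            {
                "structure": e.structure,
                "metric": str(e.metric),
                "comparator": e.comparator,
                "limit": e.limit,
            }
            for e in self.entries
        ]
        return yaml.safe_dump({"constraints": data}, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ConstraintTemplate":
        data = yaml.safe_load(text)
        entries = [
            ConstraintEntry(
                structure=d["structure"],
                metric=DoseMetric.parse(d["metric"]),
                limit=float(d["limit"]),
                comparator=d.get("comparator", "<"),
            )
            for d in data["constraints"]
        ]
        return cls(entries)


def default_constraint_template() -> ConstraintTemplate:
    """The clinic template for summed prostate VMAT plans."""

    def e(structure: str, metric: str, limit: float) -> ConstraintEntry:
        return ConstraintEntry(structure, DoseMetric.parse(metric), limit)

    return ConstraintTemplate(
        [
            e("PeritonealCavity", "Dmax", 54.0),
            e("PeritonealCavity", "V45Gy(cc)", 150.0),
            e("PeritonealCavity", "V15Gy(cc)", 830.0),
            e("Rectum", "V40Gy(%)", 40.0),
            e("Rectum", "V60Gy(%)", 50.0),
            e("Rectum", "V70Gy(%)", 25.0),
            e("Rectum", "V75Gy(%)", 5.0),
            e("Bladder", "V60Gy(%)", 50.0),
            e("Bladder", "V70Gy(%)", 25.0),
            e("AnalCanal", "V55Gy(%)", 100.0),
            e("FemoralHeadRight", "V52Gy(%)", 10.0),
            e("FemoralHeadLeft", "V52Gy(%)", 10.0),
        ]
    )


def paddick_ci(
    dose: DoseGrid, ptv: StructureMask, reference_isodose: float | None = None
) -> float:
    """Paddick conformity index PCI = TV_PIV^2 / (TV * PIV).

    TV is the target volume, PIV the volume of the whole grid receiving at
    least ``reference_isodose`` (default: 95% of the prescription, the
    coverage acceptance level), and TV_PIV their intersection.  1 means the
    reference isodose conforms perfectly to the target; returns 0 with a
    warning when the isodose volume is empty.
    """
    if reference_isodose is None:
        reference_isodose = 0.95 * dose.prescription_dose
    if reference_isodose <= 0:
        raise ValueError("reference_isodose must be > 0")
    piv_mask = StructureMask(
        name=f"isodose>={reference_isodose:g}Gy",
        role="oar",
        occupancy=dose.dose >= reference_isodose,
        geometry=dose.geometry,
    )
    if piv_mask.is_empty():
        warnings.warn(
            f"no voxel reaches the {reference_isodose:g} Gy reference isodose; "
            "conformity index defined as 0",
            stacklevel=2,
        )
        return 0.0
    tv = structure_volume(ptv)
    piv = structure_volume(piv_mask)
    tv_piv = overlap_volume(ptv, piv_mask)
    return tv_piv**2 / (tv * piv)


def homogeneity_index(dose: DoseGrid, ptv: StructureMask) -> float:
    """HI = (D2% - D98%) / D50% inside the target; 0 is perfectly uniform."""
    d2 = d_at_volume_percent(dose, ptv, 2.0)
    d98 = d_at_volume_percent(dose, ptv, 98.0)
    d50 = d_at_volume_percent(dose, ptv, 50.0)
    if d50 == 0:
        raise ValueError("D50% is zero; homogeneity index undefined")
    return (d2 - d98) / d50


@dataclass
class CoverageResult:
    """PTV coverage: D95% and Dmax as percent of the prescription."""

    d95_percent: float
    dmax_percent: float
    coverage_pass: bool  # D95% >= 95
    dmax_pass: bool  # Dmax < 107

    @property
    def passed(self) -> bool:
        return self.coverage_pass and self.dmax_pass


def coverage_check(
    dose: DoseGrid, ptv: StructureMask, prescription: float | None = None
) -> CoverageResult:
    """Check the acceptance rule: D95% >= 95% of prescription, Dmax < 107%."""
    if prescription is None:
        prescription = dose.prescription_dose
    if prescription <= 0:
        raise ValueError("prescription must be > 0")
    d95 = 100.0 * d_at_volume_percent(dose, ptv, 95.0) / prescription
    dmax = 100.0 * max_dose(dose, ptv) / prescription
    return CoverageResult(
        d95_percent=d95,
        dmax_percent=dmax,
        coverage_pass=d95 >= 95.0,
        dmax_pass=dmax < 107.0,
    )


@dataclass
class ConstraintResult:
    entry: ConstraintEntry
    achieved: float | None
    evaluated: bool
    passed: bool | None


@dataclass
class PlanEvaluation:
    """All dose metrics, constraint verdicts and coverage of one plan."""

    plan_id: str
    metrics: dict[str, float]
    constraint_results: list[ConstraintResult]
    coverage: CoverageResult | None = None
    pci: float | None = None
    hi: float | None = None

    @property
    def all_constraints_pass(self) -> bool:
        return all(r.passed for r in self.constraint_results if r.evaluated)

    @property
    def missing_structures(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.constraint_results:
            if not r.evaluated:
                seen.setdefault(r.entry.structure)
        return list(seen)

    def metric(self, structure: str, metric: str) -> float:
        return self.metrics[f"{structure}:{DoseMetric.parse(metric)}"]


def evaluate_plan(
    dose: DoseGrid,
    structures: dict[str, StructureMask],
    template: ConstraintTemplate | None = None,
    plan_id: str = "plan",
    target_name: str = "PTV46",
) -> PlanEvaluation:
    """Evaluate one plan against a constraint template plus coverage indices.

    Structures named in the template but absent from the set are flagged as
    not evaluated rather than raising.  Coverage, PCI and HI are computed on
    ``target_name`` when that structure is present.
    """
    if template is None:
        template = default_constraint_template()
    metrics: dict[str, float] = {}
    results: list[ConstraintResult] = []
    for entry in template.entries:
        mask = structures.get(entry.structure)
        if mask is None or mask.is_empty():
            results.append(ConstraintResult(entry, None, evaluated=False, passed=None))
            continue
        achieved = entry.metric.evaluate(dose, mask)
        metrics[entry.key] = achieved
        results.append(
            ConstraintResult(entry, achieved, evaluated=True, passed=entry.passes(achieved))
        )

    coverage = pci = hi = None
    ptv = structures.get(target_name)
    if ptv is not None and not ptv.is_empty():
        coverage = coverage_check(dose, ptv)
        pci = paddick_ci(dose, ptv)
        try:
            hi = homogeneity_index(dose, ptv)
        except ValueError:  # D50% = 0 on a void plan
            hi = None
        metrics[f"{target_name}:D95%ofRx"] = coverage.d95_percent
        metrics[f"{target_name}:Dmax%ofRx"] = coverage.dmax_percent
        if hi is not None:
            metrics[f"{target_name}:HI"] = hi
        metrics[f"{target_name}:PCI"] = pci

    return PlanEvaluation(
        plan_id=plan_id,
        metrics=metrics,
        constraint_results=results,
        coverage=coverage,
        pci=pci,
        hi=hi,
    )
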