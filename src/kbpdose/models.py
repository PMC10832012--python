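"""Knowledge-based dose-prediction models.

The central idea: on a cohort of high-quality prior plans, each organ-at-risk
dose metric y (e.g. rectum V60Gy in %) is regressed on a single geometric
predictor x measured on the patient before optimisation:

    y = A * x + B + eps,   eps ~ N(0, sigma^2)

The predictors are purely geometric, so they are available before any dose
is computed:

* ``overlap_fraction`` — OAR volume inside the target, as % of the OAR;
* ``centroid_distance`` — distance between OAR and target centers of mass, cm;
* ``overlap_times_volume`` — absolute overlap volume times absolute OAR
  volume, cc^2 (see note below).

For a new patient the fitted line gives the dose a competent plan should
achieve, and a t-based 95% *prediction interval* for a single new plan
(not a mean-response confidence band — the clinical question is whether
this one plan is consistent with prior practice).  A plan whose achieved
metric lies above the upper bound is flagged suboptimal; below the lower
bound is merely informational, since lower OAR dose is desirable.

The default registry carries the seven prostate pairings: rectum and
bladder V60Gy(%)/V70Gy(%) against their overlap fraction with the boost
target PTV76, and three peritoneal-cavity models against PTV46 geometry
(Davg vs centroid distance, V45Gy(cc) vs overlap fraction, V15Gy(cc) vs
overlap x volume).

Unit note: the product predictor takes both factors as absolute volumes in
cc (product in cc^2).  A clinic preferring fraction x volume can register
its own spec; the registry is config-extensible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core import (
    DoseGrid,
    StructureMask,
    centroid_distance,
    overlap_fraction,
    overlap_volume,
    structure_volume,
)
from .quality import DoseMetric

MODEL_FILE_VERSION = "kbpdose-models/1"


class PredictorKind(str, Enum):
    OVERLAP_FRACTION = "overlap_fraction"  # %
    CENTROID_DISTANCE = "centroid_distance"  # cm
    OVERLAP_TIMES_VOLUME = "overlap_times_volume"  # cc^2


_PREDICTOR_UNITS = {
    PredictorKind.OVERLAP_FRACTION: "%",
    PredictorKind.CENTROID_DISTANCE: "cm",
    PredictorKind.OVERLAP_TIMES_VOLUME: "cc^2",
}


@dataclass(frozen=True)
class KbpModelSpec:
    """One OAR-metric / geometric-predictor pairing."""

    model_id: str
    oar: str
    response: DoseMetric
    predictor: PredictorKind
    target: str  # reference target volume, e.g. "PTV76" or "PTV46"

    @property
    def predictor_unit(self) -> str:
        return _PREDICTOR_UNITS[PredictorKind(self.predictor)]

    @property
    def response_unit(self) -> str:
        return {"percent": "%"}.get(self.response.unit, self.response.unit)

    def describe(self) -> str:
        return (
            f"{self.oar} {self.response} ~ {PredictorKind(self.predictor).value}"
            f"({self.oar}, {self.target})"
        )

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "oar": self.oar,
            "response": str(self.response),
            "predictor": PredictorKind(self.predictor).value,
            "target": self.target,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "KbpModelSpec":
        return cls(
            model_id=d["model_id"],
            oar=d["oar"],
            response=DoseMetric.parse(d["response"]),
            predictor=PredictorKind(d["predictor"]),
            target=d["target"],
        )


def default_model_specs() -> list[KbpModelSpec]:
    """The seven-model prostate registry."""
    m = DoseMetric.parse
    return [
        KbpModelSpec("rectum_v60", "Rectum", m("V60Gy(%)"), PredictorKind.OVERLAP_FRACTION, "PTV76"),
        KbpModelSpec("rectum_v70", "Rectum", m("V70Gy(%)"), PredictorKind.OVERLAP_FRACTION, "PTV76"),
        KbpModelSpec("bladder_v60", "Bladder", m("V60Gy(%)"), PredictorKind.OVERLAP_FRACTION, "PTV76"),
        KbpModelSpec("bladder_v70", "Bladder", m("V70Gy(%)"), PredictorKind.OVERLAP_FRACTION, "PTV76"),
        KbpModelSpec("cavity_davg", "PeritonealCavity", m("Davg"), PredictorKind.CENTROID_DISTANCE, "PTV46"),
        KbpModelSpec("cavity_v45", "PeritonealCavity", m("V45Gy(cc)"), PredictorKind.OVERLAP_FRACTION, "PTV46"),
        KbpModelSpec("cavity_v15", "PeritonealCavity", m("V15Gy(cc)"), PredictorKind.OVERLAP_TIMES_VOLUME, "PTV46"),
    ]


def extract_predictor(
    spec: KbpModelSpec, structures: Mapping[str, StructureMask]
) -> float:
    """Measure the geometric predictor of one model on a structure set."""
    try:
        oar = structures[spec.oar]
        target = structures[spec.target]
    except KeyError as exc:
        raise KeyError(
            f"model {spec.model_id!r} needs structure {exc.args[0]!r}, "
            f"which is missing from the set"
        ) from None
    kind = PredictorKind(spec.predictor)
    if kind is PredictorKind.OVERLAP_FRACTION:
        return overlap_fraction(oar, target)
    if kind is PredictorKind.CENTROID_DISTANCE:
        return centroid_distance(oar, target)
    return overlap_volume(oar, target) * structure_volume(oar)


def extract_features(
    structures: Mapping[str, StructureMask],
    specs: Sequence[KbpModelSpec] | None = None,
) -> dict[str, float]:
    """All geometric predictors of a registry, keyed by model id."""
    if specs is None:
        specs = default_model_specs()
    return {s.model_id: extract_predictor(s, structures) for s in specs}


@dataclass
class FittedKbpModel:
    """An ordinary-least-squares fit of one model spec.

    Stores everything a prediction interval needs: slope ``A``, intercept
    ``B``, training size ``n``, coefficient of determination ``r_squared``,
    residual standard deviation (sqrt(SSE/(n-2))), and the training
    predictor mean ``x_mean`` and centred sum of squares ``sxx``.
    """

    spec: KbpModelSpec
    slope: float
    intercept: float
    n: int
    r_squared: float
    residual_sd: float
    x_mean: float
    sxx: float

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("a fitted model needs n >= 3 training plans")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError(f"r_squared must lie in [0, 1], got {self.r_squared}")

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "slope": self.slope,
            "intercept": self.intercept,
            "n": self.n,
            "r_squared": self.r_squared,
            "residual_sd": self.residual_sd,
            "x_mean": self.x_mean,
            "sxx": self.sxx,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FittedKbpModel":
        return cls(
            spec=KbpModelSpec.from_dict(d["spec"]),
            slope=float(d["slope"]),
            intercept=float(d["intercept"]),
            n=int(d["n"]),
            r_squared=float(d["r_squared"]),
            residual_sd=float(d["residual_sd"]),
            x_mean=float(d["x_mean"]),
            sxx=float(d["sxx"]),
        )


def fit_model(
    spec: KbpModelSpec,
    x: Sequence[float],
    y: Sequence[float],
) -> FittedKbpModel:
    """Fit y = A x + B by ordinary least squares.

    A = Sxy/Sxx, B = ybar - A xbar; R^2 = 1 - SSE/SST; residual_sd =
    sqrt(SSE/(n-2)).  Degenerate predictors (all x equal) and n < 3 raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 training plans, got {n}")
    x_mean = float(x.mean())
    y_mean = float(y.mean())
    sxx = float(np.sum((x - x_mean) ** 2))
    if sxx == 0:
        raise ValueError("degenerate training set: all predictor values identical")
    sxy = float(np.sum((x - x_mean) * (y - y_mean)))
    slope = sxy / sxx
    intercept = y_mean - slope * x_mean
    residuals = y - (slope * x + intercept)
    sse = float(np.sum(residuals**2))
    sst = float(np.sum((y - y_mean) ** 2))
    r_squared = 1.0 if sst == 0 else max(0.0, 1.0 - sse / sst)
    residual_sd = float(np.sqrt(max(sse, 0.0) / (n - 2)))
    return FittedKbpModel(
        spec=spec,
        slope=slope,
        intercept=intercept,
        n=n,
        r_squared=min(r_squared, 1.0),
        residual_sd=residual_sd,
        x_mean=x_mean,
        sxx=sxx,
    )


@dataclass
class PredictionResult:
    """Point prediction and prediction-interval bounds for one new plan."""

    model_id: str
    x: float
    predicted: float
    lower: float
    upper: float
    level: float = 0.95

    @property
    def half_width(self) -> float:
        return (self.upper - self.lower) / 2.0


def predict_with_interval(
    model: FittedKbpModel, x: float, level: float = 0.95
) -> PredictionResult:
    """Expected metric and t-based prediction interval for one new plan.

    half-width = t_{(1+level)/2, n-2} * residual_sd *
                 sqrt(1 + 1/n + (x - x_mean)^2 / Sxx)

    The "+1" inside the root makes this a new-observation interval: it is
    expected to contain the achieved metric of a single future plan at the
    stated level, and is the band a planner compares a fresh optimisation
    against.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if not np.isfinite(model.residual_sd):
        raise ValueError("model residual_sd is not finite")
    predicted = model.predict(x)
    t = float(stats.t.ppf((1 + level) / 2.0, df=model.n - 2))
    half = t * model.residual_sd * np.sqrt(
        1.0 + 1.0 / model.n + (x - model.x_mean) ** 2 / model.sxx
    )
    return PredictionResult(
        model_id=model.spec.model_id,
        x=float(x),
        predicted=predicted,
        lower=predicted - half,
        upper=predicted + half,
        level=level,
    )


class FlagStatus(str, Enum):
    WITHIN = "within"
    ABOVE_UPPER = "above_upper"  # suboptimal: more OAR dose than predicted
    BELOW_LOWER = "below_lower"  # better than the model (informational)


@dataclass
class KbpFlag:
    """Verdict of one model on one plan."""

    model_id: str
    achieved: float
    prediction: PredictionResult
    status: FlagStatus

    @property
    def suboptimal(self) -> bool:
        return self.status is FlagStatus.ABOVE_UPPER


def flag_achieved(
    model: FittedKbpModel, x: float, achieved: float, level: float = 0.95
) -> KbpFlag:
    """Compare one achieved metric against its prediction band."""
    pred = predict_with_interval(model, x, level=level)
    if achieved > pred.upper:
        status = FlagStatus.ABOVE_UPPER
    elif achieved < pred.lower:
        status = FlagStatus.BELOW_LOWER
    else:
        status = FlagStatus.WITHIN
    return KbpFlag(model.spec.model_id, float(achieved), pred, status)


def audit_features(
    models: Sequence[FittedKbpModel],
    features: Mapping[str, float],
    achieved: Mapping[str, float],
    level: float = 0.95,
) -> list[KbpFlag]:
    """Audit pre-computed (predictor, achieved-metric) pairs.

    This is the manual-entry path: the planner types (or a script computes)
    the geometric predictors and the metrics the current optimisation
    achieved, and each model answers within / above / below its band.
    """
    flags = []
    for model in models:
        mid = model.spec.model_id
        if mid not in features or mid not in achieved:
            continue
        flags.append(flag_achieved(model, features[mid], achieved[mid], level=level))
    return flags


def audit_plan(
    dose: DoseGrid,
    structures: Mapping[str, StructureMask],
    models: Sequence[FittedKbpModel],
    level: float = 0.95,
) -> list[KbpFlag]:
    """Full audit of one plan: extract predictors, predict, compare achieved.

    Per-model failures (a missing structure, say) are collected and reported
    after the remaining models have been evaluated.
    """
    flags: list[KbpFlag] = []
    errors: list[str] = []
    for model in models:
        try:
            x = extract_predictor(model.spec, structures)
            achieved = model.spec.response.evaluate(dose, structures[model.spec.oar])
        except (KeyError, ValueError) as exc:
            errors.append(f"{model.spec.model_id}: {exc}")
            continue
        flags.append(flag_achieved(model, x, achieved, level=level))
    if errors and not flags:
        raise ValueError("no model could be audited: " + "; ".join(errors))
    return flags


def save_models(models: Iterable[FittedKbpModel], path) -> None:
    """Serialize fitted models to a versioned JSON text file."""
    payload = {
        "format": MODEL_FILE_VERSION,
        "models": [m.to_dict() for m in models],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def load_models(path) -> list[FittedKbpModel]:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != MODEL_FILE_VERSION:
        raise ValueError(
            f"unsupported model file format {payload.get('format')!r}; "
            f"expected {MODEL_FILE_VERSION!r}"
        )
    return [FittedKbpModel.from_dict(d) for d in payload["models"]]
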