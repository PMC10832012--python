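"""Before/after cohort comparison of plan metrics.

Two cohorts — plans optimised *with* the predictive models (WM) and plans
from before their deployment (WOM) — are compared metric by metric with
Mean(SD), the mean difference delta = mean(WM) - mean(WOM), and a
two-sided Mann-Whitney test at the 0.05 threshold.  Constraint-exceedance
rates (how many plans in a cohort violate one template entry) quantify the
clinical headline numbers.

Deltas are computed on unrounded means; only the formatted report rounds
(to one decimal), so a printed table may show a delta that differs in the
last digit from the difference of its printed means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quality import ConstraintEntry, PlanEvaluation

SIGNIFICANCE_LEVEL = 0.05
EXACT_MAX_N = 8  # exact Mann-Whitney enumeration up to this per-sample size


@dataclass
class MannWhitneyResult:
    u: float  # U statistic of the first sample
    p_value: float
    method: str  # "exact" | "asymptotic"


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], method: str = "auto"
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    ``method='auto'`` uses exact enumeration when both samples have at most
    8 observations and the pooled data carry no ties (deterministic for
    small cohorts), otherwise the normal approximation with midranks, tie
    correction and continuity correction.  Two samples with all values
    identical give U = n_a*n_b/2 and p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(u=a.size * b.size / 2.0, p_value=1.0, method="degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    if method == "auto":
        method = "exact" if max(a.size, b.size) <= EXACT_MAX_N and not has_ties else "asymptotic"
    if method == "exact" and has_ties:
        method = "asymptotic"  # exact null distribution assumes no ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return MannWhitneyResult(u=float(res.statistic), p_value=float(res.pvalue), method=method)


def cohort_delta(mean_wm: float, mean_wom: float) -> float:
    """The reported difference: mean(WM) - mean(WOM), on unrounded means."""
    return mean_wm - mean_wom


def _metric_values(
    plans: Sequence[PlanEvaluation] | Sequence[Mapping[str, float]], metric: str
) -> np.ndarray | None:
    """Collect one metric across a cohort; None when any plan lacks it."""
    values = []
    for plan in plans:
        table = plan.metrics if isinstance(plan, PlanEvaluation) else plan
        if metric not in table:
            return None
        values.append(float(table[metric]))
    return np.asarray(values)


def compare_cohorts(
    wm: Sequence[PlanEvaluation] | Sequence[Mapping[str, float]],
    wom: Sequence[PlanEvaluation] | Sequence[Mapping[str, float]],
    metrics: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-metric cohort comparison table.

    Accepts either :class:`PlanEvaluation` objects or plain
    ``{metric: value}`` mappings per plan.  Returns a DataFrame indexed by
    metric with columns ``wm_mean, wm_sd, wom_mean, wom_sd, delta, p_value,
    significant, n_wm, n_wom`` (sample SD, n-1 denominator).  Metrics
    missing from any plan are marked incomplete (NaN row entries).
    """
    if len(wm) == 0 or len(wom) == 0:
        raise ValueError("both cohorts must contain at least one plan")
    if metrics is None:
        first = wm[0].metrics if isinstance(wm[0], PlanEvaluation) else wm[0]
        metrics = list(first)
    rows = []
    for metric in metrics:
        va = _metric_values(wm, metric)
        vb = _metric_values(wom, metric)
        if va is None or vb is None:
            rows.append(
                dict.fromkeys(
                    ("wm_mean", "wm_sd", "wom_mean", "wom_sd", "delta", "p_value"),
                    np.nan,
                )
                | {"significant": False, "n_wm": len(wm), "n_wom": len(wom), "complete": False}
            )
            continue
        mean_wm, mean_wom = float(va.mean()), float(vb.mean())
        test = mann_whitney_u(va, vb)
        rows.append(
            {
                "wm_mean": mean_wm,
                "wm_sd": float(va.std(ddof=1)) if va.size > 1 else 0.0,
                "wom_mean": mean_wom,
                "wom_sd": float(vb.std(ddof=1)) if vb.size > 1 else 0.0,
                "delta": cohort_delta(mean_wm, mean_wom),
                "p_value": test.p_value,
                "significant": bool(test.p_value < SIGNIFICANCE_LEVEL),
                "n_wm": int(va.size),
                "n_wom": int(vb.size),
                "complete": True,
            }
        )
    return pd.DataFrame(rows, index=pd.Index(metrics, name="metric"))


def exceedance_rate(
    plans: Sequence[PlanEvaluation] | Sequence[Mapping[str, float]],
    entry: ConstraintEntry,
) -> tuple[int, float]:
    """How many plans of a cohort violate one constraint entry.

    Returns ``(count, percent)`` with percent = 100 * count / n over the
    plans in which the entry could be evaluated; the percent is unrounded.
    """
    count = 0
    n = 0
    for plan in plans:
        table = plan.metrics if isinstance(plan, PlanEvaluation) else plan
        if entry.key not in table:
            continue
        n += 1
        if not entry.passes(float(table[entry.key])):
            count += 1
    if n == 0:
        raise ValueError(f"constraint {entry.key!r} was evaluated in no plan")
    return count, 100.0 * count / n


def format_comparison(table: pd.DataFrame, decimals: int = 1) -> str:
    """Human-readable report: metric, WM Mean(SD), WOM Mean(SD), delta, p.

    Significant rows (p < 0.05) are starred.  Rounding happens here only.
    """
    lines = [f"{'metric':<36} {'WM Mean(SD)':>18} {'WOM Mean(SD)':>18} {'delta':>9} {'p':>8}"]
    for metric, row in table.iterrows():
        if not row.get("complete", True) or np.isnan(row["p_value"]):
            lines.append(f"{metric:<36} {'(incomplete)':>18}")
            continue
        star = " *" if row["significant"] else ""
        lines.append(
            f"{metric:<36} "
            f"{row['wm_mean']:>10.{decimals}f} ({row['wm_sd']:.{decimals}f}) "
            f"{row['wom_mean']:>10.{decimals}f} ({row['wom_sd']:.{decimals}f}) "
            f"{row['delta']:>9.{decimals}f} {row['p_value']:>8.3f}{star}"
        )
    return "\n".join(lines)
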