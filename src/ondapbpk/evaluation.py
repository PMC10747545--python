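"""Model qualification statistics.

For each study and PK parameter the observed/predicted ratio R is computed;
a model passes the standard acceptance criterion when every R lies in the
twofold range [0.5, 2.0]. Summary accuracy metrics:

* mean ratio — the arithmetic mean of the per-study ratios (this is what
  the published per-parameter "AFE" columns actually contain),
* AFE — the geometric average fold error, 10 ** mean(log10 fold error),
* RMSE — root mean squared observed-minus-predicted difference.

The arithmetic and geometric forms differ (e.g. IV AUC: 0.98 vs 0.965);
both are reported and labelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "StudyComparison",
    "EvaluationReport",
    "obs_pred_ratio",
    "fold_error",
    "mean_ratio",
    "afe_geometric",
    "rmse",
    "twofold_check",
    "evaluate_comparisons",
    "round_half_up",
]

TWOFOLD_LOW, TWOFOLD_HIGH = 0.5, 2.0


@dataclass(frozen=True)
class StudyComparison:
    """Observed vs predicted value of one PK parameter in one study."""

    study_id: str
    route: str          # "iv" | "oral"
    parameter: str      # "auc_0inf" | "cmax" | "cl"
    observed: float
    predicted: float

    def __post_init__(self) -> None:
        if self.observed <= 0 or self.predicted <= 0:
            raise ValueError(
                f"{self.study_id}/{self.parameter}: observed and predicted "
                "must be > 0")

    @property
    def ratio(self) -> float:
        return obs_pred_ratio(self.observed, self.predicted)


@dataclass(frozen=True)
class EvaluationReport:
    """Per-study ratios plus per-(route, parameter) summary statistics."""

    ratios: pd.DataFrame      # study_id, route, parameter, observed,
    #                           predicted, ratio, twofold_pass
    summary: pd.DataFrame     # route, parameter, n, mean_ratio, ratio_min,
    #                           ratio_max, afe_geometric, rmse
    overall_pass: bool
    n: int


def obs_pred_ratio(observed: float, predicted: float) -> float:
    """R = observed / predicted."""
    if predicted <= 0:
        raise ValueError("predicted must be > 0")
    return observed / predicted


def fold_error(observed: float, predicted: float,
               symmetric: bool = False) -> float:
    """Fold error; with ``symmetric=True`` returns max(R, 1/R) >= 1."""
    r = obs_pred_ratio(observed, predicted)
    return max(r, 1.0 / r) if symmetric else r


def mean_ratio(ratios) -> float:
    """Arithmetic mean of obs/pred ratios (the as-printed summary form)."""
    arr = np.asarray(list(ratios), dtype=float)
    if arr.size == 0:
        raise ValueError("mean_ratio needs at least one ratio")
    return float(arr.mean())


def afe_geometric(fold_errors) -> float:
    """Average fold error: 10 ** mean(log10 fold errors)."""
    arr = np.asarray(list(fold_errors), dtype=float)
    if arr.size == 0:
        raise ValueError("afe_geometric needs at least one fold error")
    if np.any(arr <= 0):
        raise ValueError("fold errors must be > 0")
    return float(10.0 ** np.mean(np.log10(arr)))


def rmse(observed, predicted) -> float:
    """Root mean squared error between observed and predicted vectors."""
    o = np.asarray(list(observed), dtype=float)
    p = np.asarray(list(predicted), dtype=float)
    if o.size != p.size:
        raise ValueError("observed and predicted must have equal length")
    if o.size == 0:
        raise ValueError("rmse needs at least one pair")
    return float(np.sqrt(np.mean((o - p) ** 2)))


def twofold_check(ratios) -> tuple[np.ndarray, bool]:
    """Per-entry pass flags for 0.5 <= R <= 2.0 and the overall verdict."""
    arr = np.asarray(list(ratios), dtype=float)
    flags = (arr >= TWOFOLD_LOW) & (arr <= TWOFOLD_HIGH)
    return flags, bool(flags.all())


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding used only at report rendering."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def evaluate_comparisons(comparisons: list[StudyComparison]) -> EvaluationReport:
    """Build the full qualification report from study comparisons."""
    if not comparisons:
        raise ValueError("no comparisons supplied")
    rows = []
    for c in comparisons:
        r = c.ratio
        rows.append({"study_id": c.study_id, "route": c.route,
                     "parameter": c.parameter, "observed": c.observed,
                     "predicted": c.predicted, "ratio": r,
                     "twofold_pass": TWOFOLD_LOW <= r <= TWOFOLD_HIGH})
    ratios = pd.DataFrame(rows)
    summaries = []
    for (route, parameter), grp in ratios.groupby(["route", "parameter"],
                                                  sort=False):
        summaries.append({
            "route": route, "parameter": parameter, "n": len(grp),
            "mean_ratio": mean_ratio(grp["ratio"]),
            "ratio_min": float(grp["ratio"].min()),
            "ratio_max": float(grp["ratio"].max()),
            "afe_geometric": afe_geometric(grp["ratio"]),
            "rmse": rmse(grp["observed"], grp["predicted"]),
        })
    return EvaluationReport(
        ratios=ratios, summary=pd.DataFrame(summaries),
        overall_pass=bool(ratios["twofold_pass"].all()), n=len(ratios))
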