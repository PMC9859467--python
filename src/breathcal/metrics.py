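"""Analytical performance metrics and grouped evaluation reports.

The quantifier is validated the way analytical chemists validate a
calibration: predictions at each known concentration are summarised by
accuracy, error magnitudes and repeatability, and the per-concentration
rows are aggregated into an overall row.

Definitions (BrACa = actual, BrACe = predicted, both in mcg/100 mL):

* ``MSE = mean((BrACe - BrACa)^2)``, ``RMSE = sqrt(MSE)``,
  ``MAE = mean(|BrACe - BrACa|)``;
* ``R^2 = 1 - SS_resid / SS_tot`` pooled over all pairs, with
  ``SS_tot`` taken about the mean of the actuals;
* per-trial ``accuracy% = 100 - 100 * |BrACa - BrACe| / BrACa`` for a
  positive actual; the group average accuracy therefore equals
  ``100 - 100 * MAE / actual``.  At an actual of zero, a trial is 100%
  accurate when predicted exactly zero and 0% otherwise — this keeps the
  zero row meaningful (a perfect zero classifier scores 100);
* ``sd`` is the sample standard deviation of the predictions (M - 1
  denominator) and ``RSD% = 100 * sd / mean(predictions)``.

Group metrics are aggregated unweighted across concentration groups:
overall accuracy / MSE / MAE are means of the group values and overall
RMSE is the square root of the overall MSE.  R^2 is always pooled.
Reported tables round half-up to two decimals at presentation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .util import round_half_up

__all__ = [
    "mse",
    "rmse",
    "mae",
    "r_squared",
    "accuracy_percent",
    "sd",
    "rsd",
    "GroupEvaluation",
    "EvaluationReport",
    "evaluate_group",
    "evaluate_overall",
    "evaluate_predictions",
    "split_dataset",
]


def _pairs(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one prediction pair")
    if a.shape != p.shape:
        raise ValueError("actual and predicted must have the same length")
    return a, p


def mse(actual, predicted) -> float:
    """Mean squared error, (mcg/100 mL)^2."""
    a, p = _pairs(actual, predicted)
    return float(np.mean((p - a) ** 2))


def rmse(actual, predicted) -> float:
    """Root mean squared error, mcg/100 mL."""
    return float(np.sqrt(mse(actual, predicted)))


def mae(actual, predicted) -> float:
    """Mean absolute error, mcg/100 mL."""
    a, p = _pairs(actual, predicted)
    return float(np.mean(np.abs(p - a)))


def r_squared(actual, predicted) -> float:
    """Coefficient of determination over pooled pairs.

    Raises ``ValueError`` when the actuals are constant (total sum of
    squares is zero and the statistic is undefined).
    """
    a, p = _pairs(actual, predicted)
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: actual concentrations are constant")
    ss_res = float(np.sum((a - p) ** 2))
    return 1.0 - ss_res / ss_tot


def accuracy_percent(actual: float, predicted: float) -> float:
    """Per-trial accuracy in percent (absolute relative error form)."""
    if actual < 0 or predicted < 0:
        raise ValueError("concentrations must be non-negative")
    if actual == 0:
        return 100.0 if predicted == 0 else 0.0
    return 100.0 - 100.0 * abs(actual - predicted) / actual


def sd(values) -> float:
    """Sample standard deviation (M - 1 denominator), mcg/100 mL."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("standard deviation needs at least two values")
    return float(np.std(v, ddof=1))


def rsd(values) -> float:
    """Relative standard deviation, 100 * sd / mean, in percent."""
    v = np.asarray(values, dtype=float)
    m = float(v.mean())
    if m <= 0:
        raise ValueError("RSD undefined for non-positive mean")
    return 100.0 * sd(v) / m


@dataclass(frozen=True)
class GroupEvaluation:
    """Metric row for one actual concentration (one table row)."""

    actual_concentration: float
    n: int
    mean_predicted: float
    avg_accuracy: float
    mse: float
    mae: float
    rmse: float
    sd: float
    rsd: float


def evaluate_group(actual: float, predictions: Sequence[float]) -> GroupEvaluation:
    """Summarise the predictions at one known concentration.

    With a single prediction the standard deviation (and hence RSD) is
    undefined and reported as NaN; RSD is 0 for perfectly repeatable
    predictions and NaN when the mean prediction is 0 with nonzero spread.
    """
    p = np.asarray(predictions, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one prediction")
    a = np.full_like(p, float(actual))
    acc = float(np.mean([accuracy_percent(actual, x) for x in p]))
    group_sd = sd(p) if p.size >= 2 else float("nan")
    mean_pred = float(p.mean())
    if np.isnan(group_sd):
        group_rsd = float("nan")
    elif group_sd == 0:
        group_rsd = 0.0
    elif mean_pred > 0:
        group_rsd = 100.0 * group_sd / mean_pred
    else:
        group_rsd = float("nan")
    return GroupEvaluation(
        actual_concentration=float(actual),
        n=int(p.size),
        mean_predicted=mean_pred,
        avg_accuracy=acc,
        mse=mse(a, p),
        mae=mae(a, p),
        rmse=rmse(a, p),
        sd=group_sd,
        rsd=group_rsd,
    )


_REPORT_COLUMNS = [
    "ActualConcentration",
    "N",
    "AveragePredicted",
    "AverageAccuracy",
    "MSE",
    "MAE",
    "RMSE",
    "R2",
    "StandardDeviation",
    "RSD",
]


@dataclass
class EvaluationReport:
    """Grouped evaluation with an overall row, mirroring a validation table."""

    groups: list[GroupEvaluation]
    overall_accuracy: float
    overall_mse: float
    overall_mae: float
    overall_rmse: float
    overall_r2: float
    meta: dict = field(default_factory=dict)

    def to_dataframe(self, decimals: int | None = 2) -> pd.DataFrame:
        """Tabulate group rows plus an Overall row.

        ``decimals`` applies half-up presentation rounding; pass ``None``
        for full precision.
        """
        rows = []
        for g in self.groups:
            rows.append(
                {
                    "ActualConcentration": g.actual_concentration,
                    "N": g.n,
                    "AveragePredicted": g.mean_predicted,
                    "AverageAccuracy": g.avg_accuracy,
                    "MSE": g.mse,
                    "MAE": g.mae,
                    "RMSE": g.rmse,
                    "R2": np.nan,
                    "StandardDeviation": g.sd,
                    "RSD": g.rsd,
                }
            )
        rows.append(
            {
                "ActualConcentration": "Overall",
                "N": int(sum(g.n for g in self.groups)),
                "AveragePredicted": np.nan,
                "AverageAccuracy": self.overall_accuracy,
                "MSE": self.overall_mse,
                "MAE": self.overall_mae,
                "RMSE": self.overall_rmse,
                "R2": self.overall_r2,
                "StandardDeviation": np.nan,
                "RSD": np.nan,
            }
        )
        df = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
        if decimals is not None:
            num = df.columns.drop(["ActualConcentration", "N"])
            df[num] = df[num].apply(lambda col: round_half_up(col.to_numpy(), decimals))
        return df

    def summary(self) -> str:
        return self.to_dataframe().to_string(index=False, na_rep="-")


def evaluate_overall(
    groups: Sequence[GroupEvaluation],
    actual=None,
    predicted=None,
    meta: dict | None = None,
) -> EvaluationReport:
    """Aggregate group rows into a report with an unweighted overall row.

    ``actual``/``predicted`` are the pooled pairs used for the overall
    R^2; when omitted (or when the actuals are constant) R^2 is NaN.
    """
    if not groups:
        raise ValueError("need at least one group")
    groups = sorted(groups, key=lambda g: g.actual_concentration)
    if actual is not None and predicted is not None:
        try:
            r2 = r_squared(actual, predicted)
        except ValueError:
            r2 = float("nan")
    else:
        r2 = float("nan")
    overall_mse = float(np.mean([g.mse for g in groups]))
    return EvaluationReport(
        groups=list(groups),
        overall_accuracy=float(np.mean([g.avg_accuracy for g in groups])),
        overall_mse=overall_mse,
        overall_mae=float(np.mean([g.mae for g in groups])),
        overall_rmse=float(np.sqrt(overall_mse)),
        overall_r2=r2,
        meta=meta or {},
    )


def evaluate_predictions(actual, predicted, meta: dict | None = None) -> EvaluationReport:
    """Group pooled (actual, predicted) pairs by actual and build a report."""
    a, p = _pairs(actual, predicted)
    groups = [
        evaluate_group(level, p[a == level]) for level in np.unique(a)
    ]
    return evaluate_overall(groups, a, p, meta=meta)


def split_dataset(items: Sequence, train_fraction: float = 0.9, seed: int = 0):
    """Random seeded partition into training and validation subsets.

    The training size is ``n * train_fraction`` rounded half up; the
    validation set is the complement.  The union is the input and the
    intersection is empty; identical seeds give identical partitions.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    items = list(items)
    n = len(items)
    n_train = int(np.floor(n * train_fraction + 0.5))
    order = np.random.default_rng(seed).permutation(n)
    train = [items[i] for i in sorted(order[:n_train])]
    valid = [items[i] for i in sorted(order[n_train:])]
    return train, valid
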