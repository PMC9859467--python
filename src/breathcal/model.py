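"""BrAC quantification: zero-threshold classifier and linear calibration.

The quantifier has two stages.

1. A four-rule threshold classifier decides whether a trace represents a
   zero concentration.  Applied in order, a trace is alcohol-free if

   * its peak (``max30``) is zero — no signal change at all;
   * the mode of its first ten readings (``mode10``) is zero — no
     sustained reaction;
   * ``mode10 / max30`` is below 0.8 — the peak is an isolated spike, not
     a plateau that the early readings fluctuate around;
   * ``max30 - avg20`` is below 1 count — an insufficient peak followed
     by a genuine downtrend, i.e. electrical noise.

   Comparisons are strict; a ratio of exactly 0.8 or a distance of exactly
   1 falls through to the next rule / to quantification.  The classifier
   guards the regression against false positives: clean samples still show
   a slight above-baseline bump (pump actuation, electrical noise) that a
   bare regression line would translate into a small positive BrAC.

2. Traces that survive the classifier are quantified with a linear
   calibration of concentration on peak counts.  The calibration is fitted
   by ordinary least squares to per-concentration averaged peaks — the
   ``max30`` values of the calibration trials averaged within each
   concentration — with the zero-concentration point excluded (the
   classifier, not the line, owns zero).  Predictions are clamped to the
   sensor's physical range [0, 300] mcg/100 mL.

The calibration follows the Model/Results convention: build a
:class:`BreathAlcoholModel` from calibration points (or directly from
traces), call :meth:`~BreathAlcoholModel.fit`, and use the returned
:class:`BreathAlcoholResults` to predict, quantify traces and produce
evaluation reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import stats

from .features import FeatureVector, extract_features
from .simulate import SensorTrace

__all__ = [
    "ThresholdParams",
    "CalibrationPoint",
    "BrACReading",
    "zero_rule",
    "classify_zero",
    "BreathAlcoholModel",
    "BreathAlcoholResults",
]


class ThresholdParams(BaseModel):
    """Thresholds of the zero classifier: mode/peak ratio and peak-mean distance."""

    ratio_threshold: float = Field(default=0.8, gt=0, lt=1)
    diff_threshold: float = Field(default=1.0, gt=0)

    model_config = {"frozen": True}


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration point: a concentration and its trial-averaged peak."""

    concentration: float
    mean_peak: float

    def __post_init__(self):
        if self.concentration < 0 or self.mean_peak < 0:
            raise ValueError("calibration points must be non-negative")


@dataclass(frozen=True)
class BrACReading:
    """A quantified breath sample: BrAC in mcg/100 mL and the zero flag.

    ``rule`` records which classifier rule fired (1-4), or 0 when the
    trace was quantified by the calibration line.
    """

    value: float
    is_zero_classified: bool
    rule: int = 0

    def __post_init__(self):
        if self.is_zero_classified and self.value != 0:
            raise ValueError("zero-classified readings must have value 0")


def zero_rule(features: FeatureVector, params: ThresholdParams | None = None) -> int:
    """Return the index (1-4) of the first zero rule that fires, else 0.

    Exactly one branch applies to any feature vector; rule order is fixed.
    """
    params = params or ThresholdParams()
    if features.max30 == 0:
        return 1
    if features.mode10 == 0:
        return 2
    if features.mode10 / features.max30 < params.ratio_threshold:
        return 3
    if features.max30 - features.avg20 < params.diff_threshold:
        return 4
    return 0


def classify_zero(features: FeatureVector, params: ThresholdParams | None = None) -> bool:
    """True when the four-rule threshold algorithm labels the trace zero."""
    return zero_rule(features, params) != 0


def _calibration_points_from_traces(traces: Iterable[SensorTrace]) -> list[CalibrationPoint]:
    peaks: dict[float, list[float]] = {}
    for tr in traces:
        if tr.true_concentration is None:
            raise ValueError("calibration traces must carry a true_concentration label")
        peaks.setdefault(tr.true_concentration, []).append(
            extract_features(tr).max30
        )
    return [
        CalibrationPoint(c, float(np.mean(v))) for c, v in sorted(peaks.items())
    ]


class BreathAlcoholModel:
    """Linear calibration of BrAC on averaged peak counts.

    Parameters
    ----------
    points : sequence of CalibrationPoint
        Per-concentration averaged peaks (``max30`` averaged over trials).
    exclude_zero : bool
        Drop the zero-concentration point before fitting (default); the
        threshold classifier handles zero, and including the clean-sample
        bump in the line would bias the intercept.  Setting this to False
        reproduces the rejected single-line alternative for comparison.
    thresholds : ThresholdParams
        Zero-classifier thresholds attached to fitted results.
    sensor_max : float
        Physical ceiling for predictions, mcg/100 mL.
    """

    def __init__(
        self,
        points: Sequence[CalibrationPoint],
        exclude_zero: bool = True,
        thresholds: ThresholdParams | None = None,
        sensor_max: float = 300.0,
    ):
        self.points = list(points)
        self.exclude_zero = exclude_zero
        self.thresholds = thresholds or ThresholdParams()
        self.sensor_max = sensor_max

    @classmethod
    def from_traces(
        cls,
        traces: Iterable[SensorTrace],
        exclude_zero: bool = True,
        thresholds: ThresholdParams | None = None,
        sensor_max: float = 300.0,
    ) -> "BreathAlcoholModel":
        """Build calibration points by averaging ``max30`` per concentration."""
        return cls(
            _calibration_points_from_traces(traces),
            exclude_zero=exclude_zero,
            thresholds=thresholds,
            sensor_max=sensor_max,
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        concentration_col: str = "concentration",
        peak_col: str = "mean_peak",
        **kwargs,
    ) -> "BreathAlcoholModel":
        points = [
            CalibrationPoint(row[concentration_col], row[peak_col])
            for _, row in df.iterrows()
        ]
        return cls(points, **kwargs)

    @property
    def fit_points(self) -> list[CalibrationPoint]:
        if self.exclude_zero:
            return [p for p in self.points if p.concentration != 0]
        return list(self.points)

    def fit(self) -> "BreathAlcoholResults":
        """Ordinary least squares of concentration (y) on mean peak (x)."""
        pts = self.fit_points
        if len(pts) < 2:
            raise ValueError("need at least two calibration points to fit a line")
        x = np.array([p.mean_peak for p in pts], dtype=float)
        y = np.array([p.concentration for p in pts], dtype=float)
        if np.ptp(x) == 0:
            raise ValueError("calibration peaks are all identical; line is undefined")
        res = stats.linregress(x, y)
        return BreathAlcoholResults(
            model=self,
            slope=float(res.slope),
            intercept=float(res.intercept),
            slope_stderr=float(res.stderr) if len(pts) > 2 else float("nan"),
            intercept_stderr=(
                float(res.intercept_stderr) if len(pts) > 2 else float("nan")
            ),
            rsquared=float(res.rvalue) ** 2,
            fitted_peak_range=(float(x.min()), float(x.max())),
        )


@dataclass
class BreathAlcoholResults:
    """Fitted calibration line with its uncertainties and the quantifier.

    ``slope`` is in mcg/100 mL per ADC count, ``intercept`` in mcg/100 mL.
    ``rsquared`` refers to the calibration fit over the averaged points
    (not to validation predictions).  Standard errors are NaN for a
    two-point fit, where the line is exact and residual variance is
    undefined.
    """

    model: BreathAlcoholModel
    slope: float
    intercept: float
    slope_stderr: float
    intercept_stderr: float
    rsquared: float
    fitted_peak_range: tuple[float, float]

    @property
    def params(self) -> pd.Series:
        return pd.Series({"intercept": self.intercept, "slope": self.slope})

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            {"intercept": self.intercept_stderr, "slope": self.slope_stderr}
        )

    @property
    def thresholds(self) -> ThresholdParams:
        return self.model.thresholds

    def predict(self, max30) -> float | np.ndarray:
        """Concentration for a peak count, clamped to [0, sensor_max]."""
        max30 = np.asarray(max30, dtype=float)
        if np.any(max30 < 0):
            raise ValueError("peak counts must be non-negative")
        raw = self.slope * max30 + self.intercept
        out = np.clip(raw, 0.0, self.model.sensor_max)
        return float(out) if out.ndim == 0 else out

    def quantify(
        self, trace: SensorTrace, thresholds: ThresholdParams | None = None
    ) -> BrACReading:
        """Run the full quantifier on a trace: classify zero, else predict."""
        feats = extract_features(trace)
        rule = zero_rule(feats, thresholds or self.thresholds)
        if rule:
            return BrACReading(0.0, True, rule)
        return BrACReading(self.predict(feats.max30), False, 0)

    def quantify_many(self, traces: Iterable[SensorTrace]) -> pd.DataFrame:
        """Quantify a collection of traces into a tidy frame."""
        rows = []
        for tr in traces:
            r = self.quantify(tr)
            rows.append(
                {
                    "trial_id": tr.trial_id,
                    "true_concentration": tr.true_concentration,
                    "predicted": r.value,
                    "is_zero_classified": r.is_zero_classified,
                    "rule": r.rule,
                }
            )
        return pd.DataFrame(rows)

    def evaluate(self, traces: Iterable[SensorTrace]):
        """Quantify labelled traces and build a grouped evaluation report."""
        from .metrics import evaluate_predictions

        df = self.quantify_many(list(traces))
        if df["true_concentration"].isna().any():
            raise ValueError("evaluation traces must carry true_concentration labels")
        return evaluate_predictions(
            df["true_concentration"].to_numpy(), df["predicted"].to_numpy()
        )

    def summary(self) -> str:
        """Plain-text summary of the fitted calibration."""
        pts = self.model.fit_points
        lines = [
            "Breath alcohol linear calibration (OLS)",
            "=" * 47,
            f"calibration points        {len(pts)}"
            + ("  (zero excluded)" if self.model.exclude_zero else ""),
            f"peak range (counts)       {self.fitted_peak_range[0]:.2f} - "
            f"{self.fitted_peak_range[1]:.2f}",
            f"slope  (mcg/100mL/count)  {self.slope:.6f}  (se {self.slope_stderr:.2g})",
            f"intercept (mcg/100mL)     {self.intercept:.6f}  (se {self.intercept_stderr:.2g})",
            f"R^2 of calibration fit    {self.rsquared:.6f}",
            f"zero rules                ratio < {self.thresholds.ratio_threshold}, "
            f"peak - avg20 < {self.thresholds.diff_threshold}",
            f"prediction clamp          [0, {self.model.sensor_max}] mcg/100 mL",
        ]
        return "\n".join(lines)

    def plot_calibration(self, ax=None):
        """Scatter the calibration points with the fitted line (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pts = self.model.fit_points
        x = np.array([p.mean_peak for p in pts])
        y = np.array([p.concentration for p in pts])
        ax.scatter(x, y, label="averaged peaks")
        grid = np.linspace(x.min(), x.max(), 50)
        ax.plot(grid, self.slope * grid + self.intercept, label="OLS fit")
        ax.set_xlabel("mean peak (ADC counts)")
        ax.set_ylabel("concentration (mcg/100 mL)")
        ax.legend()
        return ax

    # ---- persistence -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_stderr": self.slope_stderr,
            "intercept_stderr": self.intercept_stderr,
            "rsquared": self.rsquared,
            "fitted_peak_range": list(self.fitted_peak_range),
            "exclude_zero": self.model.exclude_zero,
            "sensor_max": self.model.sensor_max,
            "thresholds": self.model.thresholds.model_dump(),
            "created_from": [
                {"concentration": p.concentration, "mean_peak": p.mean_peak}
                for p in self.model.points
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "BreathAlcoholResults":
        model = BreathAlcoholModel(
            [
                CalibrationPoint(p["concentration"], p["mean_peak"])
                for p in d.get("created_from", [])
            ],
            exclude_zero=d["exclude_zero"],
            thresholds=ThresholdParams(**d["thresholds"]),
            sensor_max=d["sensor_max"],
        )
        return cls(
            model=model,
            slope=d["slope"],
            intercept=d["intercept"],
            slope_stderr=d.get("slope_stderr", float("nan")),
            intercept_stderr=d.get("intercept_stderr", float("nan")),
            rsquared=d.get("rsquared", float("nan")),
            fitted_peak_range=tuple(d["fitted_peak_range"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "BreathAlcoholResults":
        return cls.from_dict(json.loads(Path(path).read_text()))
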