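"""Signal features of the 0-1500 ms area of interest.

All downstream logic — the zero-threshold classifier and the linear
calibration — operates on seven summary features of the first 30 readings
of a trace (1.5 s at 50 ms sampling), which cover the peak and the start
of the downtrend:

* ``mode10`` — mode of readings 1-10 (the most repeated early value; for a
  genuine alcohol response the signal fluctuates near the peak here);
* ``max30`` — maximum of readings 1-30, the peak response;
* ``min30`` — minimum of readings 1-30, the end point of the window;
* ``avg20`` / ``avg30`` — means of readings 1-20 / 1-30;
* ``max_minus_avg20`` / ``max_minus_avg30`` — distances from the peak to
  those means.

Features are computed on the raw integer counts; no smoothing or baseline
subtraction is applied.  When several values are equally frequent in the
first ten readings, the largest is taken as the mode (fixed, documented
tie-break).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import SensorTrace

__all__ = ["FeatureVector", "extract_features", "AREA_OF_INTEREST"]

#: Number of readings in the area of interest.
AREA_OF_INTEREST = 30


@dataclass(frozen=True)
class FeatureVector:
    mode10: float
    max30: float
    min30: float
    avg20: float
    avg30: float
    max_minus_avg20: float
    max_minus_avg30: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mode10": self.mode10,
            "max30": self.max30,
            "min30": self.min30,
            "avg20": self.avg20,
            "avg30": self.avg30,
            "max_minus_avg20": self.max_minus_avg20,
            "max_minus_avg30": self.max_minus_avg30,
        }


def _mode_largest(values: np.ndarray) -> float:
    """Mode with ties broken toward the largest value."""
    uniq, counts = np.unique(values, return_counts=True)
    best = counts.max()
    return float(uniq[counts == best].max())


def extract_features(trace: SensorTrace | np.ndarray) -> FeatureVector:
    """Compute the seven features from the first 30 readings of a trace.

    Accepts a :class:`~breathcal.simulate.SensorTrace` or a plain array of
    counts.  Averages are exact floats; nothing is rounded.  Raises
    ``ValueError`` for traces shorter than 30 readings.
    """
    readings = trace.readings if isinstance(trace, SensorTrace) else np.asarray(trace)
    if readings.ndim != 1 or readings.size < AREA_OF_INTEREST:
        raise ValueError(
            f"need at least {AREA_OF_INTEREST} readings, got {readings.size}"
        )
    window = readings[:AREA_OF_INTEREST].astype(float)
    max30 = float(window.max())
    avg20 = float(window[:20].mean())
    avg30 = float(window.mean())
    return FeatureVector(
        mode10=_mode_largest(window[:10]),
        max30=max30,
        min30=float(window.min()),
        avg20=avg20,
        avg30=avg30,
        max_minus_avg20=max30 - avg20,
        max_minus_avg30=max30 - avg30,
    )
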