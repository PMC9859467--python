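"""CSV/JSON readers and writers shared across the package.

Traces are stored long-form, one row per reading, with columns
``trial_id, true_concentration, time_ms, count``; the writer/reader pair
round-trips exactly (counts are integers, labels floats, unlabeled traces
have an empty label field).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .features import extract_features
from .metrics import EvaluationReport
from .simulate import SAMPLING_INTERVAL_MS, SensorTrace

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_features_csv",
    "write_report_csv",
    "write_readings_csv",
    "read_readings_csv",
]


def write_traces_csv(traces: Iterable[SensorTrace], path: str | Path) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": tr.trial_id,
                    "true_concentration": tr.true_concentration,
                    "time_ms": tr.times_ms,
                    "count": tr.readings,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path: str | Path) -> list[SensorTrace]:
    df = pd.read_csv(path)
    traces = []
    # sort=False keeps file order; trial_id groups must be contiguous
    for trial_id, grp in df.groupby("trial_id", sort=False):
        grp = grp.sort_values("time_ms")
        conc = grp["true_concentration"].iloc[0]
        traces.append(
            SensorTrace(
                readings=grp["count"].to_numpy(dtype=np.int64),
                true_concentration=None if pd.isna(conc) else float(conc),
                trial_id=str(trial_id),
                sampling_interval_ms=SAMPLING_INTERVAL_MS,
            )
        )
    return traces


def write_features_csv(traces: Sequence[SensorTrace], path: str | Path) -> None:
    """One row per trace: trial_id, label and the seven features."""
    rows = []
    for tr in traces:
        row = {"trial_id": tr.trial_id, "true_concentration": tr.true_concentration}
        row.update(extract_features(tr).as_dict())
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_readings_csv(readings: pd.DataFrame, path: str | Path) -> None:
    readings.to_csv(path, index=False)


def read_readings_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_report_csv(
    report: EvaluationReport, path: str | Path, decimals: int | None = 2
) -> None:
    """Write a validation table with a provenance header (# comments)."""
    path = Path(path)
    header = "".join(f"# {k}: {v}\n" for k, v in report.meta.items())
    body = report.to_dataframe(decimals=decimals).to_csv(index=False)
    path.write_text(header + body)
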