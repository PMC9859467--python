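"""Configuration loading and the end-to-end pipeline."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from .metrics import EvaluationReport, split_dataset
from .model import BreathAlcoholModel, ThresholdParams
from .simulate import SimulationParams, generate_dataset
from .units import DeviceConstants

__all__ = ["Config", "ConfigError", "load_config", "save_config", "run_pipeline"]

logger = logging.getLogger("breathcal")


class ConfigError(ValueError):
    pass


class EvaluationSettings(BaseModel):
    train_fraction: float = Field(default=0.9, gt=0, lt=1)
    seed: int = 0

    model_config = {"frozen": True}


class Config(BaseModel):
    """Full run configuration; an empty document yields all defaults."""

    simulation: SimulationParams = Field(default_factory=SimulationParams)
    thresholds: ThresholdParams = Field(default_factory=ThresholdParams)
    constants: DeviceConstants = Field(default_factory=DeviceConstants)
    evaluation: EvaluationSettings = Field(default_factory=EvaluationSettings)

    model_config = {"frozen": True}

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:12]


def load_config(path: str | Path | None = None) -> Config:
    """Load and validate a JSON config; missing fields take defaults.

    Raises :class:`ConfigError` naming the offending field on invalid
    values.
    """
    if path is None:
        return Config()
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    try:
        return Config(**data)
    except ValidationError as exc:
        fields = ", ".join(
            ".".join(str(p) for p in err["loc"]) for err in exc.errors()
        )
        raise ConfigError(f"invalid config field(s): {fields}") from exc


def save_config(config: Config, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.model_dump(), indent=2))


def run_pipeline(config: Config | None = None, seed: int | None = None):
    """Simulate, split, calibrate, quantify and evaluate in one run.

    Stages: generate the wet-bath data set -> random 90/10 train/validation
    split -> fit the peak-averaged calibration on the training set (zero
    excluded) -> quantify every validation trace through the threshold
    classifier + line -> grouped evaluation report.  All randomness is
    derived from the single ``seed`` (defaulting to the configured one),
    so runs are reproducible.  Returns ``(report, results)``.
    """
    config = config or Config()
    if seed is None:
        seed = config.evaluation.seed
    ss = np.random.SeedSequence(seed)
    sim_seed, split_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))

    logger.info("simulating wet-bath data set (seed %d)", sim_seed)
    traces = generate_dataset(params=config.simulation, seed=sim_seed)
    logger.info("generated %d traces", len(traces))

    train, valid = split_dataset(
        traces, config.evaluation.train_fraction, seed=split_seed
    )
    logger.info("split into %d training / %d validation traces", len(train), len(valid))

    model = BreathAlcoholModel.from_traces(
        train,
        exclude_zero=True,
        thresholds=config.thresholds,
        sensor_max=config.constants.sensor_max,
    )
    results = model.fit()
    logger.info(
        "calibration: slope %.5f mcg/100mL/count, intercept %.5f",
        results.slope,
        results.intercept,
    )

    report = results.evaluate(valid)
    report.meta.update(
        {
            "seed": seed,
            "config_sha256": config.sha256(),
            "breathcal_version": __version__,
            "n_train": len(train),
            "n_validation": len(valid),
        }
    )
    logger.info("overall accuracy %.2f%%", report.overall_accuracy)
    return report, results
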