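"""Synthetic fuel-cell sensor traces and the Nernst open-circuit potential.

No raw sensor data are publicly deposited for this class of device, so the
package ships a simulator that emulates the wet-bath calibration protocol:
known air-ethanol concentrations are presented to a platinum fuel cell, the
amplified cell voltage is sampled every 50 ms by a 10-bit ADC, and each
trial is recorded as a short integer-count time series.  The simulator
reproduces the qualitative response dynamics of such sensors:

* the digital output reacts within ~200 ms of the sampling-pump release;
* the time to peak grows with concentration (higher concentrations need
  longer to reach their maximum response);
* after the peak the signal decays slowly back toward baseline;
* alcohol-free ("clean") samples still show a small above-baseline
  transient attributable to electrical noise and pump actuation, which is
  exactly what the zero-threshold classifier has to reject.

Peak amplitude is tied to the device constants: a concentration ``c``
produces an amplified voltage of ``sensitivity_mv * c`` which the ADC maps
to ``round(sensitivity_mv * c / adc_step_mv)`` counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .units import DeviceConstants, adc_step_mv
from .util import round_half_up

__all__ = [
    "GAS_CONSTANT",
    "FARADAY",
    "SAMPLING_INTERVAL_MS",
    "NernstParams",
    "nernst_ocp",
    "SensorTrace",
    "SimulationParams",
    "DEFAULT_CONCENTRATIONS",
    "generate_trace",
    "generate_dataset",
]

GAS_CONSTANT = 8.314  # J / (K mol)
FARADAY = 96485.0  # C / mol
SAMPLING_INTERVAL_MS = 50.0

#: Wet-bath calibration design: ten concentrations in mcg/100 mL.
DEFAULT_CONCENTRATIONS: tuple[float, ...] = (0, 4, 10, 20, 30, 40, 50, 100, 150, 200)

#: Trials per concentration in the calibration design (10 x 20 = 200 traces).
DEFAULT_TRIALS = 20


class NernstParams(BaseModel):
    """Inputs to the Nernst equation for the fuel-cell open-circuit potential.

    ``E = E0 + (R*T)/(n*F) * ln(Pr/Pp)`` with the gas constant R and the
    Faraday constant F fixed.  ``n`` defaults to 4, the electron count of
    the dominant ethanol-to-acetic-acid oxidation on platinum.
    """

    E0: float
    T: float = Field(default=298.15, gt=0, description="temperature, K")
    n: int = Field(default=4, ge=1, description="transferred electrons")
    Pr: float = Field(gt=0, description="partial pressure of reactants")
    Pp: float = Field(gt=0, description="partial pressure of products")

    model_config = {"frozen": True}


def nernst_ocp(params: NernstParams) -> float:
    """Open-circuit potential (volts) predicted by the Nernst equation.

    This is the thermodynamic ceiling of the cell voltage; an operating
    fuel cell delivers less after ohmic, activation and mass-transport
    losses, so the simulator does not use it directly — it is provided as
    the physical account of why pump actuation (which perturbs the
    reactant/product partial-pressure balance) moves a clean sample's
    signal slightly above baseline.
    """
    return params.E0 + (GAS_CONSTANT * params.T) / (params.n * FARADAY) * math.log(
        params.Pr / params.Pp
    )


@dataclass(frozen=True)
class SensorTrace:
    """A digitized fuel-cell response.

    Parameters
    ----------
    readings : np.ndarray
        Integer ADC counts in [0, 1023], sampled every 50 ms starting at
        the release of the sampling pump (t = 0).
    true_concentration : float or None
        Known wet-bath concentration in mcg/100 mL, if any.
    trial_id : str
        Identifier of the trial.
    sampling_interval_ms : float
        Fixed at 50 ms for this device.
    """

    readings: np.ndarray
    true_concentration: float | None = None
    trial_id: str = ""
    sampling_interval_ms: float = field(default=SAMPLING_INTERVAL_MS)

    def __post_init__(self):
        r = np.asarray(self.readings)
        if not np.issubdtype(r.dtype, np.integer):
            if not np.all(r == np.round(r)):
                raise ValueError("readings must be integers")
            r = r.astype(np.int64)
        if r.ndim != 1 or r.size < 30:
            raise ValueError("a trace needs at least 30 readings (0-1500 ms)")
        if r.min() < 0 or r.max() > 1023:
            raise ValueError("readings must lie in [0, 1023]")
        object.__setattr__(self, "readings", r)

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.readings.size) * self.sampling_interval_ms

    def __len__(self) -> int:
        return self.readings.size


class SimulationParams(BaseModel):
    """Tunable parameters of the trace simulator.

    Defaults mirror the prototype hardware (13 mV per mcg/100 mL
    sensitivity, 4.94 V / 1024-level ADC) and the observed signal shape.
    ``time_to_peak`` is modelled as ``base + slope * concentration`` ms,
    snapped to the 50 ms sampling grid, giving peaks from 200 ms at trace
    onset up to 1.4 s at the 300 mcg/100 mL sensor ceiling.  The rise is a
    saturating exponential (time constant a fifth of the time to peak), so
    the signal plateaus near its maximum well before the peak instant — the
    plateau is what makes the mode of the first ten readings track the
    peak for genuine alcohol responses.  Clean samples receive only a
    two-count pump/noise transient decaying within ~100 ms.
    """

    sensitivity_mv: float = Field(default=13.0, gt=0)
    adc_vref: float = Field(default=4.94, gt=0)
    adc_levels: int = Field(default=1024, gt=1)
    baseline: int = Field(default=0, ge=0)
    peak_time_base_ms: float = Field(default=200.0, gt=0)
    peak_time_slope_ms: float = Field(default=4.0, ge=0)
    rise_fraction: float = Field(default=0.2, gt=0, le=1)
    decay_rate_per_ms: float = Field(default=0.0003, ge=0)
    noise_amplitude: int = Field(default=1, ge=0)
    zero_bump_amplitude: int = Field(default=2, ge=0)
    zero_bump_decay_ms: float = Field(default=60.0, gt=0)
    n_readings: int = Field(default=60, ge=30)
    max_concentration: float = Field(default=300.0, gt=0)

    model_config = {"frozen": True}

    @property
    def adc_step(self) -> float:
        constants = DeviceConstants(
            adc_vref=self.adc_vref, adc_levels=self.adc_levels,
            sensitivity_mv=self.sensitivity_mv,
        )
        return adc_step_mv(constants)

    def peak_counts(self, concentration: float) -> int:
        """Noiseless peak height in counts above baseline."""
        return int(round_half_up(self.sensitivity_mv * concentration / self.adc_step))

    def peak_time_ms(self, concentration: float) -> float:
        """Time to peak, snapped to the sampling grid (>= one interval)."""
        raw = self.peak_time_base_ms + self.peak_time_slope_ms * concentration
        snapped = SAMPLING_INTERVAL_MS * round_half_up(raw / SAMPLING_INTERVAL_MS)
        return max(snapped, SAMPLING_INTERVAL_MS)

    @model_validator(mode="after")
    def _peak_fits_adc(self):
        top = self.baseline + self.peak_counts(self.max_concentration)
        if top > self.adc_levels - 1:
            raise ValueError(
                f"peak at {self.max_concentration} mcg/100 mL would be {top} counts, "
                f"beyond the ADC ceiling {self.adc_levels - 1}"
            )
        return self


def _response_curve(concentration: float, params: SimulationParams, t: np.ndarray) -> np.ndarray:
    """Noiseless continuous response (counts above baseline) at times t (ms)."""
    if concentration == 0:
        return np.zeros_like(t, dtype=float)
    amp = params.peak_counts(concentration)
    t_peak = params.peak_time_ms(concentration)
    tau = params.rise_fraction * t_peak
    rise = (1.0 - np.exp(-t / tau)) / (1.0 - np.exp(-t_peak / tau))
    decay = np.exp(-params.decay_rate_per_ms * (t - t_peak))
    return amp * np.where(t <= t_peak, rise, decay)


def _zero_bump(params: SimulationParams, t: np.ndarray) -> np.ndarray:
    """Pump-actuation transient for clean samples: a brief above-baseline bump."""
    return params.zero_bump_amplitude * np.exp(-t / params.zero_bump_decay_ms)


def generate_trace(
    concentration: float,
    params: SimulationParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    trial_id: str | None = None,
) -> SensorTrace:
    """Simulate one digitized sensor response at a known concentration.

    The noiseless signal rises from baseline to
    ``round(sensitivity_mv * c / adc_step)`` counts at a concentration-
    dependent peak time and then decays exponentially toward baseline;
    integer quantization (round half up) and additive integer noise of
    amplitude ``noise_amplitude`` are applied, and the result is clipped to
    the ADC range.  A zero concentration produces only the small pump
    transient plus noise.  Identical arguments and seed give identical
    traces.
    """
    params = params or SimulationParams()
    if not 0 <= concentration <= params.max_concentration:
        raise ValueError(
            f"concentration {concentration} outside [0, {params.max_concentration}]"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(params.n_readings) * SAMPLING_INTERVAL_MS
    if concentration == 0:
        signal = _zero_bump(params, t)
    else:
        signal = _response_curve(concentration, params, t)
    counts = round_half_up(signal) + params.baseline
    if params.noise_amplitude > 0:
        counts = counts + rng.integers(
            -params.noise_amplitude, params.noise_amplitude + 1, size=t.size
        )
    counts = np.clip(counts, 0, params.adc_levels - 1).astype(np.int64)
    if trial_id is None:
        trial_id = f"c{concentration:g}"
    return SensorTrace(
        readings=counts, true_concentration=float(concentration), trial_id=trial_id
    )


def generate_dataset(
    concentrations: Sequence[float] | None = None,
    trials_per_concentration: int = DEFAULT_TRIALS,
    params: SimulationParams | None = None,
    seed: int = 0,
) -> list[SensorTrace]:
    """Simulate a full wet-bath calibration data set.

    Defaults reproduce the calibration design: ten concentrations
    {0, 4, 10, 20, 30, 40, 50, 100, 150, 200} mcg/100 mL with twenty trials
    each, 200 traces in total.  Per-trace randomness is derived from
    ``seed`` via a spawned seed sequence, so the data set is reproducible
    and traces are mutually independent.
    """
    if concentrations is None:
        concentrations = DEFAULT_CONCENTRATIONS
    concentrations = list(concentrations)
    if not concentrations:
        raise ValueError("need at least one concentration")
    if trials_per_concentration < 1:
        raise ValueError("trials_per_concentration must be >= 1")
    params = params or SimulationParams()
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(concentrations) * trials_per_concentration)
    traces: list[SensorTrace] = []
    k = 0
    for c in concentrations:
        for i in range(trials_per_concentration):
            traces.append(
                generate_trace(
                    c, params, seed=children[k], trial_id=f"c{c:g}_t{i:02d}"
                )
            )
            k += 1
    return traces
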