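"""Device physical constants and unit conversions.

The analyzer digitizes the amplified fuel-cell voltage with a 10-bit ADC
referenced to the board supply, and reports breath alcohol content (BrAC)
in mcg ethanol / 100 mL breath.  Blood alcohol content (BAC, mg/100 mL) is
related to BrAC through the breath-to-blood ratio (BBR), a jurisdictional
constant (2300 in Malaysia).
"""

from __future__ import annotations

from pydantic import BaseModel, Field, field_validator

__all__ = [
    "DeviceConstants",
    "adc_step_mv",
    "digital_to_voltage",
    "brac_to_bac",
    "bac_to_brac",
]


class DeviceConstants(BaseModel):
    """Hardware constants of the breath-analyzer prototype.

    Attributes
    ----------
    adc_vref : float
        ADC reference voltage in volts; the full-scale input.
    adc_levels : int
        Number of quantization levels (10-bit converter: 1024, codes 0-1023).
    sensitivity_mv : float
        Amplified sensor sensitivity in mV per mcg/100 mL of BrAC.
    sensor_max : float
        Maximum detectable concentration in mcg/100 mL.
    bbr : float
        Breath-to-blood ratio (dimensionless).
    """

    adc_vref: float = Field(default=4.94, gt=0)
    adc_levels: int = Field(default=1024, gt=1)
    sensitivity_mv: float = Field(default=13.0, gt=0)
    sensor_max: float = Field(default=300.0, gt=0)
    bbr: float = Field(default=2300.0, gt=0)

    model_config = {"frozen": True}

    @field_validator("adc_levels")
    @classmethod
    def _power_of_two(cls, v: int) -> int:
        if v & (v - 1):
            raise ValueError("adc_levels must be a power of two")
        return v


def adc_step_mv(constants: DeviceConstants | None = None, *, divisor: int | None = None) -> float:
    """Voltage (mV) represented by one unit of the digital reading.

    The quantization step is ``1000 * adc_vref / adc_levels``.  With the
    default 4.94 V reference and 1024 levels this is 4.8242 mV (4.82 at two
    decimals).  ``divisor`` overrides the denominator for the alternative
    ``adc_levels - 1`` (code-span) convention, which would give 4.83 mV and
    is retained only for comparison.
    """
    constants = constants or DeviceConstants()
    d = divisor if divisor is not None else constants.adc_levels
    return 1000.0 * constants.adc_vref / d


def digital_to_voltage(count: int, constants: DeviceConstants | None = None) -> float:
    """Map an integer ADC code to the input voltage in mV."""
    constants = constants or DeviceConstants()
    if not 0 <= count <= constants.adc_levels - 1:
        raise ValueError(
            f"ADC count {count} outside [0, {constants.adc_levels - 1}]"
        )
    return count * adc_step_mv(constants)


def brac_to_bac(brac: float, bbr: float = 2300.0) -> float:
    """Convert BrAC (mcg/100 mL breath) to BAC (mg/100 mL blood).

    BAC = BrAC * BBR / 1000; the factor 1000 converts mcg to mg.  With the
    Malaysian BBR of 2300, 200 mcg/100 mL BrAC corresponds to 460 mg/100 mL
    BAC.
    """
    if brac < 0:
        raise ValueError("BrAC must be non-negative")
    if bbr <= 0:
        raise ValueError("BBR must be positive")
    return brac * bbr / 1000.0


def bac_to_brac(bac: float, bbr: float = 2300.0) -> float:
    """Exact inverse of :func:`brac_to_bac`."""
    if bac < 0:
        raise ValueError("BAC must be non-negative")
    if bbr <= 0:
        raise ValueError("BBR must be positive")
    return bac * 1000.0 / bbr
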