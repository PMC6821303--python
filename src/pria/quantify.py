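"""ΔS retardation statistic and accuracy metrics.

Each sample is split into a tagged aliquot (A part) and an untreated
control (B part), amplified in parallel. ΔS is the percent reduction of
the tagged credible slope relative to the control:

    ΔS = (S_control − S_tagged) / S_control × 100

ΔS is dimensionless, invariant to common rescaling of both channels, and
linear in the tagged-base content, which is what makes the calibration
lines work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .screening import ScreenConfig, ScreenResult, screen_credible_slope
from .trace import FluorescenceTrace

__all__ = ["SamplePair", "delta_s", "pair_delta_s", "screen_pair", "relative_error"]

#: relative-error conventions for measured-vs-reference comparisons
CONVENTIONS = ("reference_denominator", "measured_denominator")


@dataclass
class SamplePair:
    """Matched tagged (A) and control (B) traces and/or screened slopes."""

    tagged: FluorescenceTrace | None = None
    control: FluorescenceTrace | None = None
    tagged_slope: float | None = None
    control_slope: float | None = None
    tagged_result: ScreenResult | None = None
    control_result: ScreenResult | None = None
    label: str = ""


def delta_s(control_slope: float, tagged_slope: float) -> float:
    """Percent slope reduction of the tagged channel relative to control.

    May be negative when the tagged reaction ran faster than its control.
    """
    if not control_slope > 0:
        raise ValueError(f"control slope must be positive, got {control_slope}")
    return (control_slope - tagged_slope) / control_slope * 100.0


def screen_pair(pair: SamplePair, config: ScreenConfig | None = None) -> SamplePair:
    """Fill a pair's slopes by screening its traces; returns the same pair."""
    if pair.tagged is None or pair.control is None:
        raise ValueError("pair has no traces to screen")
    pair.tagged_result = screen_credible_slope(pair.tagged, config)
    pair.control_result = screen_credible_slope(pair.control, config)
    pair.tagged_slope = (
        pair.tagged_result.best.slope if pair.tagged_result.best else None
    )
    pair.control_slope = (
        pair.control_result.best.slope if pair.control_result.best else None
    )
    return pair


def pair_delta_s(pair: SamplePair, config: ScreenConfig | None = None) -> float:
    """ΔS of a pair, screening its traces first if slopes are absent."""
    if pair.control_slope is None or pair.tagged_slope is None:
        screen_pair(pair, config)
    return delta_s(pair.control_slope, pair.tagged_slope)


def relative_error(
    measured: float,
    reference: float,
    convention: str = "reference_denominator",
) -> float:
    """Percent deviation of a measured value from a reference value.

    ``reference_denominator``: (measured − reference)/reference × 100;
    ``measured_denominator``: (measured − reference)/measured × 100.
    Rounding to one decimal happens only at reporting time, never here.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    denom = reference if convention == "reference_denominator" else measured
    if denom == 0:
        raise ValueError("zero denominator in relative error")
    return (measured - reference) / denom * 100.0
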