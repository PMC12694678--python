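"""Wristband wear verification from light level and contact temperature.

A wristband is judged *worn* only when two conditions hold at once:

* the backscattered-light segment mean S_AVG lies between a lower and an
  upper threshold (below: light lost into a dark background; above:
  reflection from a bright surface — both mean no skin contact), and
* the contact temperature strictly exceeds T_ht (default 27 °C, the
  midpoint between worn-wrist and free-lying mean temperatures).

S_AVG thresholds are per-tail KDE quantiles of a worn-state corpus; the
tail probability (default 2.5% per side) is the "personal margin"
absorbing skin-tone and placement variation.  Boundary semantics: the
S_AVG range is inclusive at both ends, the temperature comparison is
strict.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import InvalidParameterError
from .kde import fit_h1_calibration

__all__ = [
    "DEFAULT_T_HT",
    "DEFAULT_P_TAIL",
    "WearCalibration",
    "WearDecision",
    "wear_thresholds",
    "decide_wear",
    "midpoint_temperature_threshold",
]

DEFAULT_T_HT = 27.0  # degC
DEFAULT_P_TAIL = 0.025


@dataclass(frozen=True)
class WearCalibration:
    """S_AVG range, temperature threshold and the tail probability used."""

    s_avg_low: float
    s_avg_high: float
    t_ht: float = DEFAULT_T_HT
    p_tail: float = DEFAULT_P_TAIL

    def __post_init__(self) -> None:
        if not self.s_avg_low < self.s_avg_high:
            raise InvalidParameterError(
                f"need s_avg_low < s_avg_high, got [{self.s_avg_low}, {self.s_avg_high}]"
            )
        if not (0.0 < self.p_tail < 0.5):
            raise InvalidParameterError(f"p_tail must lie in (0, 0.5), got {self.p_tail}")


@dataclass(frozen=True)
class WearDecision:
    worn: bool
    s_avg: float
    temperature: float
    reasons: tuple[str, ...]  # failed conditions: below-range | above-range | cold


def wear_thresholds(
    s_avg_samples,
    p_tail: float = DEFAULT_P_TAIL,
    t_ht: float = DEFAULT_T_HT,
) -> WearCalibration:
    """Derive the S_AVG range as KDE quantiles of a worn-state corpus."""
    if not (0.0 < p_tail < 0.5):
        raise InvalidParameterError(f"p_tail must lie in (0, 0.5), got {p_tail}")
    _, model = fit_h1_calibration(s_avg_samples, p_tail)
    return WearCalibration(
        s_avg_low=model.quantile(p_tail),
        s_avg_high=model.quantile(1.0 - p_tail),
        t_ht=t_ht,
        p_tail=p_tail,
    )


def decide_wear(s_avg: float, temperature: float, cal: WearCalibration) -> WearDecision:
    """Worn iff S_AVG in [low, high] (inclusive) and temperature > T_ht (strict)."""
    reasons = []
    if s_avg < cal.s_avg_low:
        reasons.append("below-range")
    elif s_avg > cal.s_avg_high:
        reasons.append("above-range")
    if not temperature > cal.t_ht:
        reasons.append("cold")
    return WearDecision(
        worn=not reasons,
        s_avg=float(s_avg),
        temperature=float(temperature),
        reasons=tuple(reasons),
    )


def midpoint_temperature_threshold(worn_mean_degc: float, free_mean_degc: float) -> float:
    """T_ht as the midpoint of worn vs. free-lying mean contact temperatures."""
    return 0.5 * (worn_mean_degc + free_mean_degc)
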