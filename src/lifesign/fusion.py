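"""State fusion, telemetry codec, and calibration persistence.

Pulse and motion are classified independently and combined only at the
logical level into a 2-bit lifesign code::

    code = 2 * pulse + motion
    0: no pulse, no motion      ("dead, not moving")
    1: no pulse, motion         ("dead, moving" - band carried, not worn)
    2: pulse, no motion         ("alive, not moving")
    3: pulse, motion            ("alive, moving")

The code travels inside an 8-character field ``59000X00`` of a 6-field
semicolon-separated text message::

    <unix epoch>;<locator MAC>;<band MAC>;59000X00;<RSSI dBi>;<battery V>

Wear status is carried *alongside* the code, never folded into it: the
wire protocol transmits only X in 0-3, and wear disambiguates the
"no pulse" cases in logs.  Negative RSSI is serialized with an ASCII
hyphen-minus; a Unicode minus on input is normalized when parsing.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, asdict
from pathlib import Path

from .exceptions import MessageFormatError
from .motion import (
    DEFAULT_MOTION_THRESHOLD,
    AccelBuffer,
    MotionDecision,
    decide_motion,
    motion_indicator,
)
from .pulse import (
    DEFAULT_F_MAX,
    DEFAULT_F_MIN,
    PPGSegment,
    PulseDecision,
    detect_pulse,
    segment_mean,
)
from .wear import DEFAULT_P_TAIL, DEFAULT_T_HT, WearCalibration, WearDecision, decide_wear

__all__ = [
    "STATE_LABELS",
    "LifesignState",
    "LifesignMessage",
    "WindowResult",
    "DetectorCalibration",
    "fuse_state",
    "encode_lifesign",
    "parse_lifesign",
    "run_window",
]

STATE_LABELS = {
    0: "dead, not moving",
    1: "dead, moving",
    2: "alive, not moving",
    3: "alive, moving",
}

_MAC_RE = re.compile(r"^[0-9A-Fa-f]{2}(?::[0-9A-Fa-f]{2}){5}$")
_LIFESIGN_RE = re.compile(r"^59000([0-3])00$")


@dataclass(frozen=True)
class LifesignState:
    """Fused pulse/motion decision pair and its 2-bit wire code."""

    pulse: bool
    motion: bool

    @property
    def code(self) -> int:
        return 2 * int(self.pulse) + int(self.motion)

    @property
    def label(self) -> str:
        return STATE_LABELS[self.code]


def fuse_state(pulse, motion) -> LifesignState:
    """Combine per-window pulse and motion decisions into a lifesign state.

    Accepts the decision objects or plain booleans.
    """
    p = pulse.detected if isinstance(pulse, PulseDecision) else bool(pulse)
    m = motion.moving if isinstance(motion, MotionDecision) else bool(motion)
    return LifesignState(pulse=p, motion=m)


@dataclass(frozen=True)
class LifesignMessage:
    """One 6-field telemetry record as published under ``<main>/tracking``."""

    epoch: int
    locator_mac: str
    band_mac: str
    code: int
    rssi_dbi: int
    battery_v: float

    @property
    def lifesign(self) -> str:
        return f"59000{self.code}00"


def _validate_message(msg: LifesignMessage) -> None:
    if not isinstance(msg.code, int) or not 0 <= msg.code <= 3:
        raise MessageFormatError(f"lifesign code must be an integer 0-3, got {msg.code!r}")
    for label, mac in (("locator", msg.locator_mac), ("band", msg.band_mac)):
        if not _MAC_RE.match(mac):
            raise MessageFormatError(f"{label} MAC {mac!r} is not 6 colon-separated hex octets")


def encode_lifesign(msg: LifesignMessage) -> str:
    """Serialize to the 6-field semicolon wire format."""
    _validate_message(msg)
    return (
        f"{msg.epoch};{msg.locator_mac};{msg.band_mac};"
        f"{msg.lifesign};{msg.rssi_dbi};{msg.battery_v:g}"
    )


def parse_lifesign(line: str) -> LifesignMessage:
    """Parse and validate one wire-format line.

    Raises :class:`MessageFormatError` naming the offending field index
    (0-based) on any grammar violation.
    """
    fields = line.strip().replace("−", "-").split(";")
    if len(fields) != 6:
        raise MessageFormatError(f"expected 6 semicolon-separated fields, got {len(fields)}")
    try:
        epoch = int(fields[0])
    except ValueError:
        raise MessageFormatError(f"field 0: epoch {fields[0]!r} is not an integer") from None
    for i in (1, 2):
        if not _MAC_RE.match(fields[i]):
            raise MessageFormatError(f"field {i}: bad MAC address {fields[i]!r}")
    m = _LIFESIGN_RE.match(fields[3])
    if not m:
        raise MessageFormatError(f"field 3: lifesign {fields[3]!r} does not match 59000[0-3]00")
    try:
        rssi = int(fields[4])
    except ValueError:
        raise MessageFormatError(f"field 4: RSSI {fields[4]!r} is not an integer") from None
    try:
        battery = float(fields[5])
    except ValueError:
        raise MessageFormatError(f"field 5: battery {fields[5]!r} is not a number") from None
    return LifesignMessage(
        epoch=epoch,
        locator_mac=fields[1],
        band_mac=fields[2],
        code=int(m.group(1)),
        rssi_dbi=rssi,
        battery_v=battery,
    )


@dataclass(frozen=True)
class DetectorCalibration:
    """All thresholds needed to run one window, plus the acquisition settings.

    Raw-DFT thresholds are only comparable at the (fs, tau) they were
    derived with, so both are stored here and the CLI refuses to mix them.
    Wear fields may be ``None`` when only pulse calibration was performed.
    """

    fs: float = 1000.0
    tau: float = 4.0
    f_min: float = DEFAULT_F_MIN
    f_max: float = DEFAULT_F_MAX
    t_h: float = 10000.0
    p_md: float | None = None
    s_avg_low: float | None = None
    s_avg_high: float | None = None
    p_tail: float = DEFAULT_P_TAIL
    t_ht: float = DEFAULT_T_HT
    motion_threshold: float = DEFAULT_MOTION_THRESHOLD
    kde_summary: dict | None = None  # n, sigma, h of the calibration corpus

    @property
    def wear(self) -> WearCalibration | None:
        if self.s_avg_low is None or self.s_avg_high is None:
            return None
        return WearCalibration(
            s_avg_low=self.s_avg_low,
            s_avg_high=self.s_avg_high,
            t_ht=self.t_ht,
            p_tail=self.p_tail,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorCalibration":
        known = {k: d[k] for k in cls.__dataclass_fields__ if k in d}
        return cls(**known)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "DetectorCalibration":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class WindowResult:
    """Everything one 4 s window yields: fused state plus raw decisions."""

    state: LifesignState
    pulse: PulseDecision
    motion: MotionDecision
    wear: WearDecision | None  # None when temperature or wear calibration missing


def run_window(
    seg: PPGSegment,
    accel: AccelBuffer,
    temperature: float | None,
    calib: DetectorCalibration,
    suppress_when_unworn: bool = False,
) -> WindowResult:
    """Run all three detectors on one synchronized window.

    Wear status annotates the result but does not alter the lifesign code
    unless ``suppress_when_unworn`` is set, in which case a pulse decision
    on a provably unworn band is downgraded to "no pulse".  A missing
    temperature leaves wear undetermined (``None``) while the code is
    still computed.
    """
    pulse = detect_pulse(seg, calib.t_h, calib.f_min, calib.f_max)
    mot = decide_motion(motion_indicator(accel), calib.motion_threshold)
    wear_cal = calib.wear
    wear = None
    if temperature is not None and wear_cal is not None:
        wear = decide_wear(segment_mean(seg), temperature, wear_cal)
    pulse_flag = pulse.detected
    if suppress_when_unworn and wear is not None and not wear.worn:
        pulse_flag = False
    return WindowResult(
        state=LifesignState(pulse=pulse_flag, motion=mot.moving),
        pulse=pulse,
        motion=mot,
        wear=wear,
    )
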