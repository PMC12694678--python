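"""Seeded synthetic PPG and accelerometer generators.

The generators emulate the bench scenarios the detectors must separate:

* ``free_lying`` — band on a table, LEDs facing up: a low noise floor
  (counts capped well under 7e3, sample sd ~70) whose mean tracks LED
  drive only weakly (optical crosstalk).
* ``artificial_skin`` — skin-like reflector without a pulse: on-skin mean
  level (~2.1e5 counts at high drive) with sd ~300 noise.
* ``fingertip`` — clean, regular pulse train on the on-skin baseline.
* ``wrist_rest`` — realistic wrist pulses: per-beat amplitude jitter and a
  secondary (dicrotic) bump giving multi-peaked, irregular cycles.
* ``wrist_moving`` — wrist pulses plus a band-limited (0.5-3 Hz) motion
  artifact that deliberately overlaps the pulse band.
* ``not_worn_moving`` — the band waved around but not worn: noise floor
  plus a weak baseline wobble (no reflective surface, so optical coupling
  variation stays small).

Pulse peak-to-peak amplitude follows the LED drive through a saturating
brightness->S_pp curve; baseline levels scale with drive.  Every stream
is bit-exactly reproducible from its config (scenario, parameters, seed).

Units: PPG streams are integer ADC counts; accelerometer streams are g.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "SCENARIOS",
    "PULSE_SCENARIOS",
    "ACTIVITIES",
    "ScenarioConfig",
    "brightness_to_current",
    "brightness_to_spp",
    "generate_ppg",
    "generate_accel",
]

SCENARIOS = (
    "free_lying",
    "artificial_skin",
    "fingertip",
    "wrist_rest",
    "wrist_moving",
    "not_worn_moving",
)
PULSE_SCENARIOS = frozenset({"fingertip", "wrist_rest", "wrist_moving"})
_MOVING_SCENARIOS = frozenset({"wrist_moving", "not_worn_moving"})
ACTIVITIES = ("rest", "walking", "carried")

# LED drive calibration points: (register value, LED current mA).
_CURRENT_PTS = ((10.0, 1.8), (190.0, 32.21))
# Pulse peak-to-peak calibration points and the saturation knee.
_SPP_PTS = ((20.0, 220.0), (200.0, 2770.0))
_SPP_KNEE = 130.0
_SPP_POST_KNEE_SLOPE_FRAC = 0.1  # slope beyond the knee, fraction of pre-knee

# Noise floors (ADC counts, sample sd) for off-skin vs. on-skin coupling.
_NOISE_SD_OFF_SKIN = 70.0
_NOISE_SD_ON_SKIN = 300.0

# Pulse cycle template (phase units within one beat period).  Widths keep the
# cycle bimodal while letting harmonics decay fast enough that the fundamental
# stays the strongest in-band line even when it falls between DFT bins.
_SYSTOLIC_POS, _SYSTOLIC_WIDTH = 0.18, 0.07
_DICROTIC_POS, _DICROTIC_WIDTH = 0.45, 0.10

_GAIT_HZ = 1.9  # typical step cadence; deliberately off the 2 Hz stride lattice


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one synthetic PPG stream."""

    scenario: str
    hr_bpm: float = 72.0
    fs: float = 1000.0
    duration: float = 60.0
    led_brightness: int = 170
    seed: int = 0
    artifact_level: float | None = None  # None -> per-scenario default

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise InvalidParameterError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if self.scenario in PULSE_SCENARIOS and not (30.0 <= self.hr_bpm <= 240.0):
            raise InvalidParameterError(
                f"hr_bpm must lie in [30, 240] for pulse scenarios, got {self.hr_bpm}"
            )
        if self.fs <= 8.0:
            raise InvalidParameterError(f"fs must exceed 8 Hz, got {self.fs}")
        if self.duration <= 0:
            raise InvalidParameterError(f"duration must be positive, got {self.duration}")
        if not (0 <= self.led_brightness <= 255):
            raise InvalidParameterError(
                f"led_brightness must lie in [0, 255], got {self.led_brightness}"
            )
        if self.artifact_level is None:
            object.__setattr__(
                self,
                "artifact_level",
                0.5 if self.scenario in _MOVING_SCENARIOS else 0.0,
            )
        elif self.artifact_level < 0:
            raise InvalidParameterError("artifact_level must be >= 0")


def brightness_to_current(led_brightness: float) -> float:
    """LED current (mA) for a drive register value, via the measured linear fit."""
    if not (0 <= led_brightness <= 255):
        raise InvalidParameterError(
            f"led_brightness must lie in [0, 255], got {led_brightness}"
        )
    (b0, i0), (b1, i1) = _CURRENT_PTS
    return i0 + (i1 - i0) * (led_brightness - b0) / (b1 - b0)


def brightness_to_spp(led_brightness: float) -> float:
    """Expected pulse peak-to-peak amplitude (counts) for a drive value.

    Piecewise-linear saturating curve through the two measured points
    with a knee at drive 130, beyond which the slope drops to 10% of the
    pre-knee slope; clamped at zero and monotone nondecreasing.
    """
    if not (0 <= led_brightness <= 255):
        raise InvalidParameterError(
            f"led_brightness must lie in [0, 255], got {led_brightness}"
        )
    (b0, s0), (b1, s1) = _SPP_PTS
    # Solve the pre-knee slope so the curve passes through both points.
    pre = (s1 - s0) / ((_SPP_KNEE - b0) + _SPP_POST_KNEE_SLOPE_FRAC * (b1 - _SPP_KNEE))
    post = _SPP_POST_KNEE_SLOPE_FRAC * pre
    s_knee = s0 + pre * (_SPP_KNEE - b0)
    if led_brightness <= _SPP_KNEE:
        return max(0.0, s0 + pre * (led_brightness - b0))
    return s_knee + post * (led_brightness - _SPP_KNEE)


def _lowpass_noise(rng, n, fs, cutoff_hz, rms):
    """Zero-mean Gaussian drift confined below ``cutoff_hz`` with the given rms.

    Streams too short to contain any non-DC bin under the cutoff get no
    drift at all (all zeros) rather than a spuriously amplified constant.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec *= np.exp(-0.5 * (f / cutoff_hz) ** 2)
    spec[0] = 0.0
    out = np.fft.irfft(spec, n)
    scale = out.std()
    return out * (rms / scale) if scale > rms * 1e-9 else np.zeros(n)


def _bandlimited_artifact(rng, n, fs, rms, f_lo=0.5, f_hi=3.0):
    """Random-walk-like disturbance confined to [f_lo, f_hi] Hz.

    Built from white noise with a 1/f in-band weighting (random-walk
    spectrum), so the artifact sits exactly on top of the pulse band.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    weight = np.zeros_like(f)
    band = (f >= f_lo) & (f <= f_hi)
    weight[band] = 1.0 / f[band]
    out = np.fft.irfft(spec * weight, n)
    scale = out.std()
    return out * (rms / scale) if scale > rms * 1e-9 else np.zeros(n)


def _pulse_template(u, dicrotic):
    """Beat-phase template: systolic peak plus a delayed dicrotic bump."""
    g = np.exp(-0.5 * ((u - _SYSTOLIC_POS) / _SYSTOLIC_WIDTH) ** 2)
    if dicrotic:
        g = g + dicrotic * np.exp(-0.5 * ((u - _DICROTIC_POS) / _DICROTIC_WIDTH) ** 2)
    return g


def _pulse_train(rng, t, fs, hr_bpm, spp, dicrotic, amp_jitter_sd):
    f0 = hr_bpm / 60.0
    phase = t * f0
    u = np.mod(phase, 1.0)
    beat = np.floor(phase).astype(np.int64)
    fine = _pulse_template(np.linspace(0.0, 1.0, 2048, endpoint=False), dicrotic)
    scale = spp / float(np.ptp(fine))
    amps = np.ones(int(beat[-1]) + 1)
    if amp_jitter_sd:
        amps = np.maximum(0.2, 1.0 + amp_jitter_sd * rng.standard_normal(amps.size))
    return scale * amps[beat] * _pulse_template(u, dicrotic)


def generate_ppg(cfg: ScenarioConfig) -> np.ndarray:
    """Generate one integer-valued PPG stream for a scenario config."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    b = float(cfg.led_brightness)

    on_skin = cfg.scenario not in ("free_lying", "not_worn_moving")
    if on_skin:
        base = 1050.0 * b  # ~2.1e5 counts at drive 200
        noise_sd = _NOISE_SD_ON_SKIN
    else:
        base = 3000.0 + 10.0 * b  # weak optical crosstalk only
        noise_sd = _NOISE_SD_OFF_SKIN

    # Per-stream placement/subject offset plus slow (<0.05 Hz) baseline drift:
    # these spread S_AVG across windows so the wear-range calibration has a
    # distribution to estimate.
    sig = base + rng.normal(0.0, 0.01 * base)
    sig = sig + _lowpass_noise(rng, n, cfg.fs, cutoff_hz=0.05, rms=0.002 * base)

    if cfg.scenario in PULSE_SCENARIOS:
        spp = brightness_to_spp(b)
        if cfg.scenario == "fingertip":
            dicrotic, jitter = 0.25, 0.02
        else:
            dicrotic, jitter = 0.4, 0.2
        sig = sig + _pulse_train(rng, t, cfg.fs, cfg.hr_bpm, spp, dicrotic, jitter)

    if cfg.artifact_level > 0:
        if cfg.scenario == "wrist_moving":
            rms = cfg.artifact_level * brightness_to_spp(b)
        else:
            rms = cfg.artifact_level * noise_sd
        sig = sig + _bandlimited_artifact(rng, n, cfg.fs, rms)

    sig = sig + rng.normal(0.0, noise_sd, n)
    return np.rint(sig).astype(np.int64)


def generate_accel(
    activity: str,
    duration: float,
    fs: float = 100.0,
    seed: int = 0,
    noise_sd: float = 0.01,
    gait_amp: float = 0.25,
) -> np.ndarray:
    """Generate an (n, 3) accelerometer stream in g.

    ``rest``: gravity offset on z plus white sensor noise.  ``walking``:
    rest plus a 1.9 Hz gait oscillation with per-axis amplitude and phase.
    ``carried``: the band swung in a hand - same motion signature as
    walking, but with no pulse counterpart on the PPG side.  Set
    ``noise_sd=0`` for an exactly constant rest stream.
    """
    if activity not in ACTIVITIES:
        raise InvalidParameterError(
            f"unknown activity {activity!r}; expected one of {ACTIVITIES}"
        )
    if duration <= 0 or fs <= 0:
        raise InvalidParameterError("duration and fs must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    out = np.zeros((n, 3))
    out[:, 2] = 1.0  # gravity
    if activity in ("walking", "carried"):
        amps = gait_amp * np.array([1.0, 0.8, 1.2])
        phases = np.array([0.0, 2.1, 4.2]) + rng.uniform(0.0, 2.0 * np.pi)
        for ax in range(3):
            out[:, ax] += amps[ax] * np.sin(2.0 * np.pi * _GAIT_HZ * t + phases[ax])
    if noise_sd:
        out += rng.normal(0.0, noise_sd, out.shape)
    return out
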