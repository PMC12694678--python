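"""Spectral pulse detection from wrist PPG segments.

The detector decides, for every ``tau``-second window of photodetector
counts, between H1 ("a pulse is present") and H0 ("no pulse"), without
ever reporting an absolute heart rate.  The pipeline is

    segment -> mean removal -> DFT amplitude spectrum
            -> peak search in the physiologic band [f_min, f_max]
            -> compare the peak amplitude S_max against a threshold T_h.

Amplitudes are magnitudes of the *unnormalized* DFT sum, so any threshold
is only meaningful for the exact ``(fs, tau)`` it was calibrated with;
:class:`~lifesign.fusion.DetectorCalibration` stores both for that reason.
The window length follows from the slowest detectable pulse: two full
cycles at ``min_bpm`` beats per minute, i.e. ``tau = 2 * 60 / min_bpm``
(4 s at the default 30 BPM floor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "DEFAULT_FS",
    "DEFAULT_MIN_BPM",
    "DEFAULT_F_MIN",
    "DEFAULT_F_MAX",
    "DEFAULT_THRESHOLD",
    "PPGSegment",
    "CenteredSegment",
    "AmplitudeSpectrum",
    "SpectralPeak",
    "PulseDecision",
    "tau_from_min_bpm",
    "samples_per_segment",
    "segment_stream",
    "segment_mean",
    "remove_dc",
    "amplitude_spectrum",
    "find_pulse_peak",
    "decide_pulse",
    "detect_pulse",
    "segment_statistics",
]

#: Device defaults: 1 kHz sampling, 30 BPM floor, 0.5-4.0 Hz pulse band,
#: and a fixed fallback threshold of 10 000 (raw DFT counts).
DEFAULT_FS = 1000.0
DEFAULT_MIN_BPM = 30.0
DEFAULT_F_MIN = 0.5
DEFAULT_F_MAX = 4.0
DEFAULT_THRESHOLD = 10000.0

_MIN_SPECTRUM_LEN = 8


def tau_from_min_bpm(min_bpm: float = DEFAULT_MIN_BPM) -> float:
    """Segment duration (s) covering two full cycles at the slowest pulse."""
    if min_bpm <= 0:
        raise InvalidParameterError(f"min_bpm must be positive, got {min_bpm}")
    return 2.0 * 60.0 / min_bpm


def samples_per_segment(tau: float, fs: float) -> int:
    """Number of samples N_IR = tau * fs, rounded to the nearest integer."""
    if fs <= 0 or tau <= 0:
        raise InvalidParameterError(f"fs and tau must be positive, got fs={fs}, tau={tau}")
    return int(round(tau * fs))


@dataclass(frozen=True)
class PPGSegment:
    """One ``tau``-second window of raw photodetector counts S_IR(n)."""

    samples: np.ndarray
    fs: float
    tau: float
    meta: dict | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if self.fs <= 0 or self.tau <= 0:
            raise InvalidParameterError(
                f"fs and tau must be positive, got fs={self.fs}, tau={self.tau}"
            )
        if arr.ndim != 1 or arr.size == 0:
            raise InvalidInputError("segment must be a non-empty 1-D sample array")
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("segment contains non-finite samples")
        n_expected = samples_per_segment(self.tau, self.fs)
        if arr.size != n_expected:
            raise InvalidInputError(
                f"segment length {arr.size} != round(tau*fs) = {n_expected}"
            )
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class CenteredSegment:
    """Mean-removed segment S_P(n) plus the removed mean S_AVG."""

    sp: np.ndarray
    s_avg: float
    fs: float


@dataclass(frozen=True)
class AmplitudeSpectrum:
    """One-sided magnitudes |S_F(m)| at frequencies f = m * fs / N_IR."""

    amplitudes: np.ndarray
    freqs: np.ndarray


@dataclass(frozen=True)
class SpectralPeak:
    """In-band spectral maximum: coarse pulse frequency and its amplitude."""

    f_hr: float
    s_max: float


@dataclass(frozen=True)
class PulseDecision:
    """Outcome of the S_max >= T_h comparison (H1 if True)."""

    detected: bool
    s_max: float
    f_hr: float
    threshold_used: float


def segment_stream(stream, fs: float, tau: float = 4.0) -> list[PPGSegment]:
    """Split a sample stream into consecutive non-overlapping segments.

    A trailing remainder shorter than one segment is discarded; an empty
    stream yields an empty list.
    """
    n = samples_per_segment(tau, fs)
    arr = np.asarray(stream, dtype=float)
    if arr.size and not np.all(np.isfinite(arr)):
        raise InvalidInputError("stream contains non-finite samples")
    k = arr.size // n
    return [PPGSegment(arr[i * n : (i + 1) * n], fs=fs, tau=tau) for i in range(k)]


def segment_mean(seg: PPGSegment) -> float:
    """Segment mean S_AVG — the backscattered-light level used by wear detection."""
    return float(np.mean(seg.samples))


def remove_dc(seg: PPGSegment) -> CenteredSegment:
    """Subtract the segment mean, keeping S_AVG for downstream wear checks."""
    s_avg = segment_mean(seg)
    return CenteredSegment(sp=seg.samples - s_avg, s_avg=s_avg, fs=seg.fs)


def amplitude_spectrum(cs: CenteredSegment) -> AmplitudeSpectrum:
    """One-sided magnitudes of the plain (unnormalized) DFT sum.

    Matches the direct O(N^2) evaluation of the transform to floating
    precision; bin spacing is ``fs / N``.
    """
    sp = np.asarray(cs.sp, dtype=float)
    if sp.size < _MIN_SPECTRUM_LEN:
        raise InvalidInputError(
            f"segment too short for spectral analysis ({sp.size} < {_MIN_SPECTRUM_LEN})"
        )
    amps = np.abs(np.fft.rfft(sp))
    freqs = np.fft.rfftfreq(sp.size, d=1.0 / cs.fs)
    return AmplitudeSpectrum(amplitudes=amps, freqs=freqs)


def find_pulse_peak(
    spec: AmplitudeSpectrum,
    f_min: float = DEFAULT_F_MIN,
    f_max: float = DEFAULT_F_MAX,
) -> SpectralPeak:
    """Argmax of the amplitude over bins with f_min <= f <= f_max (inclusive).

    Ties break toward the lowest frequency (the conservative physiologic
    choice); the DC bin is excluded as long as f_min > 0.
    """
    if not (0 < f_min < f_max):
        raise InvalidParameterError(f"need 0 < f_min < f_max, got [{f_min}, {f_max}]")
    band = (spec.freqs >= f_min) & (spec.freqs <= f_max)
    if not np.any(band):
        raise InvalidParameterError(
            f"no spectral bins inside [{f_min}, {f_max}] Hz"
        )
    amps = spec.amplitudes[band]
    freqs = spec.freqs[band]
    i = int(np.argmax(amps))  # argmax returns the first (lowest-f) maximum
    return SpectralPeak(f_hr=float(freqs[i]), s_max=float(amps[i]))


def decide_pulse(peak: SpectralPeak, threshold: float) -> PulseDecision:
    """H1 (pulse detected) iff s_max >= threshold; ties accept H1."""
    if threshold < 0:
        raise InvalidParameterError(f"threshold must be >= 0, got {threshold}")
    return PulseDecision(
        detected=bool(peak.s_max >= threshold),
        s_max=peak.s_max,
        f_hr=peak.f_hr,
        threshold_used=float(threshold),
    )


def detect_pulse(
    seg: PPGSegment,
    threshold: float = DEFAULT_THRESHOLD,
    f_min: float = DEFAULT_F_MIN,
    f_max: float = DEFAULT_F_MAX,
) -> PulseDecision:
    """Full per-segment pipeline: DC removal, spectrum, peak search, decision."""
    peak = find_pulse_peak(amplitude_spectrum(remove_dc(seg)), f_min, f_max)
    return decide_pulse(peak, threshold)


def segment_statistics(
    stream,
    fs: float,
    tau: float = 4.0,
    f_min: float = DEFAULT_F_MIN,
    f_max: float = DEFAULT_F_MAX,
) -> pd.DataFrame:
    """Vectorized per-segment statistics for a whole stream.

    Returns a frame with one row per complete segment and columns
    ``segment, start_s, s_avg, f_hr, s_max``.  This is the workhorse for
    calibration corpora and the evaluation harness; results are identical
    to running :func:`detect_pulse` segment by segment.
    """
    n = samples_per_segment(tau, fs)
    arr = np.asarray(stream, dtype=float)
    if arr.size and not np.all(np.isfinite(arr)):
        raise InvalidInputError("stream contains non-finite samples")
    if not (0 < f_min < f_max):
        raise InvalidParameterError(f"need 0 < f_min < f_max, got [{f_min}, {f_max}]")
    k = arr.size // n
    cols = ["segment", "start_s", "s_avg", "f_hr", "s_max"]
    if k == 0:
        return pd.DataFrame(columns=cols)
    x = arr[: k * n].reshape(k, n)
    s_avg = x.mean(axis=1)
    spec = np.abs(np.fft.rfft(x - s_avg[:, None], axis=1))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    band = (freqs >= f_min) & (freqs <= f_max)
    if not np.any(band):
        raise InvalidParameterError(f"no spectral bins inside [{f_min}, {f_max}] Hz")
    sub = spec[:, band]
    idx = sub.argmax(axis=1)
    return pd.DataFrame(
        {
            "segment": np.arange(k),
            "start_s": np.arange(k) * tau,
            "s_avg": s_avg,
            "f_hr": freqs[band][idx],
            "s_max": sub[np.arange(k), idx],
        }
    )
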