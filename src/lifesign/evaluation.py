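"""Classifier metrics and the calibration / scenario experiment harnesses.

``compute_metrics`` turns a worn-vs-detected confusion matrix into the
standard report (sensitivity, specificity, precision, accuracy, F1).
``calibration_experiment`` replays the threshold-calibration protocol:
split the H1 statistic corpus half/half at random, fit the KDE and derive
thresholds on one half, and measure the obtained miss fraction on the
other.  ``scenario_experiment`` runs the full four-scenario bench
simulation (worn/not-worn x still/moving) end to end and tabulates the
lifesign-code reading distribution together with the collapsed 2x2
confusion matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import CalibrationError
from .fusion import DetectorCalibration, LifesignState
from .kde import KernelDensityModel, fit_h1_calibration
from .motion import DEFAULT_MOTION_THRESHOLD, buffers_from_stream, motion_indicator
from .pulse import segment_statistics
from .synth import ScenarioConfig, generate_accel, generate_ppg
from .wear import wear_thresholds

__all__ = [
    "PMD_GRID",
    "ConfusionMatrix",
    "MetricReport",
    "ScenarioResult",
    "compute_metrics",
    "calibration_experiment",
    "worn_corpus",
    "scenario_experiment",
]

#: Default assumed-miss-probability grid for the calibration experiment.
PMD_GRID = (0.005, 0.01, 0.02, 0.05, 0.1, 0.2)

_REST_HR_RANGE = (55.0, 95.0)
_MOVING_HR_RANGE = (75.0, 130.0)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts or rates; positive class = wristband worn / pulse present."""

    tp: float
    fn: float
    fp: float
    tn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise CalibrationError("confusion cells must be nonnegative")


@dataclass(frozen=True)
class MetricReport:
    """TPR/TNR/PPV/ACC in percent, F1 as a fraction; NaN marks undefined."""

    tpr: float
    tnr: float
    ppv: float
    acc: float
    f1: float


def _ratio(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else math.nan


def compute_metrics(cm: ConfusionMatrix) -> MetricReport:
    """Sensitivity, specificity, precision, accuracy (%) and F1 score.

    A zero denominator yields NaN for that metric rather than an error;
    all metrics are invariant to scaling the whole matrix, so rates and
    counts are interchangeable.
    """
    total = cm.tp + cm.fn + cm.fp + cm.tn
    f1_den = 2.0 * cm.tp + cm.fp + cm.fn
    return MetricReport(
        tpr=_ratio(cm.tp, cm.tp + cm.fn),
        tnr=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        acc=_ratio(cm.tp + cm.tn, total),
        f1=2.0 * cm.tp / f1_den if f1_den > 0 else math.nan,
    )


def calibration_experiment(
    h1_stats,
    p_md_grid=PMD_GRID,
    split_seed: int = 0,
) -> pd.DataFrame:
    """Assumed vs. obtained miss probability on a random half/half split.

    Returns a frame with columns ``assumed_pmd, threshold, obtained_pmd``;
    ``obtained_pmd`` is the fraction of held-out H1 statistics at or below
    the threshold derived from the calibration half.
    """
    x = np.asarray(h1_stats, dtype=float).ravel()
    if x.size < 200:
        raise CalibrationError(
            f"calibration experiment needs >= 200 H1 statistics, got {x.size}"
        )
    grid = sorted(float(p) for p in p_md_grid)
    if not all(0.0 < p < 1.0 for p in grid):
        raise CalibrationError("p_md grid values must lie in (0, 1)")
    rng = np.random.default_rng(split_seed)
    perm = rng.permutation(x.size)
    half = x.size // 2
    model = KernelDensityModel.fit(x[perm[:half]])
    test = x[perm[half:]]
    rows = []
    for p in grid:
        th = model.quantile(p)
        rows.append(
            {"assumed_pmd": p, "threshold": th, "obtained_pmd": float((test <= th).mean())}
        )
    return pd.DataFrame(rows)


def _spawn_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)


def _scenario_stats(
    scenario: str,
    n_windows: int,
    ss: np.random.SeedSequence,
    fs: float,
    tau: float,
    f_min: float,
    f_max: float,
    led_brightness: int,
    windows_per_stream: int = 20,
) -> pd.DataFrame:
    """Per-window (s_avg, s_max, f_hr) over several independent streams.

    Streams carry independent subject offsets and, for pulse scenarios,
    per-stream heart rates drawn from a realistic range, so the pooled
    statistics mimic a multi-subject corpus.  Fifty streams per thousand
    windows keep stream-level clustering (each stream has one rate, hence
    one spectral-leakage loss) from dominating pooled tail quantiles; a
    handful of streams would act like a tiny subject panel and make
    calibrated thresholds unstable.
    """
    hr_lo, hr_hi = (
        _MOVING_HR_RANGE if scenario == "wrist_moving" else _REST_HR_RANGE
    )
    frames = []
    remaining = n_windows
    while remaining > 0:
        k = min(windows_per_stream, remaining)
        child = ss.spawn(1)[0]
        hr_rng = np.random.default_rng(child.generate_state(1)[0])
        cfg = ScenarioConfig(
            scenario=scenario,
            hr_bpm=float(hr_rng.uniform(hr_lo, hr_hi)),
            fs=fs,
            duration=k * tau,
            led_brightness=led_brightness,
            seed=_spawn_seed(child),
        )
        frames.append(segment_statistics(generate_ppg(cfg), fs, tau, f_min, f_max))
        remaining -= k
    return pd.concat(frames, ignore_index=True)


def worn_corpus(
    n_rest: int,
    n_moving: int,
    seed: int,
    fs: float = 1000.0,
    tau: float = 4.0,
    f_min: float = 0.5,
    f_max: float = 4.0,
    led_brightness: int = 170,
) -> pd.DataFrame:
    """Pooled worn-wrist segment statistics (rest + moving windows)."""
    ss = np.random.SeedSequence(seed)
    parts = []
    for scenario, n in (("wrist_rest", n_rest), ("wrist_moving", n_moving)):
        if n > 0:
            df = _scenario_stats(scenario, n, ss, fs, tau, f_min, f_max, led_brightness)
            df["scenario"] = scenario
            parts.append(df)
    return pd.concat(parts, ignore_index=True)


@dataclass(frozen=True)
class ScenarioResult:
    """Output of the four-scenario bench simulation."""

    readings: pd.DataFrame  # per-scenario reading-code distribution (%)
    confusion: ConfusionMatrix  # worn vs. pulse-detected, counts
    metrics: MetricReport
    worn_detection_pct: float
    calibration: DetectorCalibration


_SCENARIO_TABLE = (
    # (position, condition, ppg scenario, accel activity, worn ground truth)
    ("placed on the wrist", "quiescence", "wrist_rest", "rest", True),
    ("not placed on the hand", "quiescence", "free_lying", "rest", False),
    ("placed on the wrist", "while moving", "wrist_moving", "walking", True),
    ("not placed on the hand", "while moving", "not_worn_moving", "carried", False),
)


def scenario_experiment(
    n_trials: int = 250,
    seed: int = 0,
    p_md: float = 0.1,
    n_calibration: int = 1000,
    fs: float = 1000.0,
    tau: float = 4.0,
    f_min: float = 0.5,
    f_max: float = 4.0,
    led_brightness: int = 170,
    motion_threshold: float = DEFAULT_MOTION_THRESHOLD,
) -> ScenarioResult:
    """Calibrate, then simulate all four scenarios and tabulate readings.

    The pulse threshold is the P_MD-quantile of S_max over a separate
    worn-window calibration corpus (half rest, half moving); the wear
    range comes from the same corpus's S_AVG values.  Each scenario
    contributes ``n_trials`` windows; readings are reported as the
    percentage of windows yielding each lifesign code, and the collapsed
    worn-vs-detected confusion matrix with its metric report.
    """
    ss = np.random.SeedSequence(seed)
    cal_ss, test_ss = ss.spawn(2)

    cal = worn_corpus(
        n_calibration // 2,
        n_calibration - n_calibration // 2,
        _spawn_seed(cal_ss),
        fs,
        tau,
        f_min,
        f_max,
        led_brightness,
    )
    th_spec, _ = fit_h1_calibration(cal["s_max"].to_numpy(), p_md)
    wear_cal = wear_thresholds(cal["s_avg"].to_numpy())
    calib = DetectorCalibration(
        fs=fs,
        tau=tau,
        f_min=f_min,
        f_max=f_max,
        t_h=th_spec.threshold,
        p_md=p_md,
        s_avg_low=wear_cal.s_avg_low,
        s_avg_high=wear_cal.s_avg_high,
        p_tail=wear_cal.p_tail,
        t_ht=wear_cal.t_ht,
        motion_threshold=motion_threshold,
    )

    rows = []
    tp = fn = fp = tn = 0
    worn_detected = worn_total = 0
    accel_fs = 100.0
    for position, condition, ppg_scenario, activity, worn in _SCENARIO_TABLE:
        sc_ss = test_ss.spawn(1)[0]
        stats = _scenario_stats(
            ppg_scenario, n_trials, sc_ss, fs, tau, f_min, f_max, led_brightness
        )
        detected = stats["s_max"].to_numpy() >= calib.t_h
        accel = generate_accel(
            activity, duration=n_trials * tau, fs=accel_fs, seed=_spawn_seed(sc_ss)
        )
        moving = np.array(
            [
                motion_indicator(buf) > motion_threshold
                for buf in buffers_from_stream(accel, accel_fs, window_s=tau)
            ]
        )[:n_trials]
        codes = np.array(
            [LifesignState(bool(p), bool(m)).code for p, m in zip(detected, moving)]
        )
        counts = np.bincount(codes, minlength=4)
        rows.append(
            {
                "position": position,
                "condition": condition,
                **{f"reading_{c}": 100.0 * counts[c] / n_trials for c in range(4)},
            }
        )
        n_det = int(detected[:n_trials].sum())
        if worn:
            tp += n_det
            fn += n_trials - n_det
            worn_detected += n_det
            worn_total += n_trials
        else:
            fp += n_det
            tn += n_trials - n_det

    cm = ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)
    return ScenarioResult(
        readings=pd.DataFrame(rows),
        confusion=cm,
        metrics=compute_metrics(cm),
        worn_detection_pct=100.0 * worn_detected / worn_total,
        calibration=calib,
    )
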