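"""Gaussian kernel density estimation with Scott's-rule bandwidth.

Used to calibrate detection thresholds from a corpus of segment
statistics.  For a pulse detector the threshold T_h is the P_MD-quantile
of the S_max distribution under H1 (pulse present): P_MD = Pr(S_max <=
T_h | H1) is the assumed miss-detection probability, and the same
machinery yields two-sided quantiles of S_AVG for wear verification and
upper quantiles of the motion indicator.

The density is the equal-weight Gaussian mixture

    f_h(x) = 1 / (sqrt(2 pi) n h sigma) * sum_i exp(-(x - x_i)^2 / (2 h^2 sigma^2))

with the Scott factor h = n^(-1/5) and sigma the sample standard
deviation (n-1 denominator), so the effective bandwidth is h * sigma.
The CDF is the matching mixture of normal CDFs — exact and monotone,
which makes quantile inversion by bracketed root finding safe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .exceptions import (
    CalibrationError,
    DegenerateDistributionError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "KernelDensityModel",
    "ThresholdSpec",
    "scott_bandwidth",
    "kde_pdf",
    "kde_cdf",
    "threshold_for_pmd",
    "fit_h1_calibration",
]

#: Quantile bracket: this many effective bandwidths beyond the sample range,
#: doubled on failure up to _BRACKET_RETRIES times.
_BRACKET_BW = 10.0
_BRACKET_RETRIES = 5


def scott_bandwidth(n: int) -> float:
    """Univariate Scott factor h = n^(-1/5) (dimensionless)."""
    if n < 1:
        raise InvalidParameterError(f"sample count must be >= 1, got {n}")
    return float(n) ** (-1.0 / 5.0)


@dataclass(frozen=True)
class ThresholdSpec:
    """A threshold together with the tail probability it was derived from."""

    p_md: float
    threshold: float


@dataclass(frozen=True)
class KernelDensityModel:
    """Fitted KDE: samples, Scott factor ``h`` and effective bandwidth ``bw``."""

    samples: np.ndarray
    n: int
    sigma: float
    h: float
    bw: float

    @classmethod
    def fit(cls, samples) -> "KernelDensityModel":
        x = np.asarray(samples, dtype=float).ravel()
        if x.size < 2:
            raise CalibrationError(f"need at least 2 samples, got {x.size}")
        if not np.all(np.isfinite(x)):
            raise InvalidInputError("calibration samples contain non-finite values")
        sigma = float(np.std(x, ddof=1))
        if sigma == 0.0:
            raise DegenerateDistributionError("all calibration samples are identical")
        h = scott_bandwidth(x.size)
        return cls(samples=x, n=x.size, sigma=sigma, h=h, bw=h * sigma)

    def pdf(self, x):
        """Mixture density; vectorized over ``x``."""
        x = np.asarray(x, dtype=float)
        z = (x[..., None] - self.samples) / self.bw
        out = np.exp(-0.5 * z * z).sum(axis=-1) / (
            np.sqrt(2.0 * np.pi) * self.n * self.bw
        )
        return out if out.ndim else float(out)

    def cdf(self, x):
        """Closed-form mixture CDF (1/n) * sum_i Phi((x - x_i) / bw)."""
        x = np.asarray(x, dtype=float)
        out = norm.cdf((x[..., None] - self.samples) / self.bw).mean(axis=-1)
        return out if out.ndim else float(out)

    def quantile(self, p: float) -> float:
        """Unique root of cdf(x) = p, by bracketed root finding.

        Bracket is the sample range padded by 10 effective bandwidths,
        doubled up to 5 times if the requested probability lies outside.
        """
        if not (0.0 < p < 1.0):
            raise InvalidParameterError(f"probability must lie in (0, 1), got {p}")
        pad = _BRACKET_BW * self.bw
        lo = float(self.samples.min()) - pad
        hi = float(self.samples.max()) + pad
        for _ in range(_BRACKET_RETRIES + 1):
            if self.cdf(lo) <= p <= self.cdf(hi):
                return float(brentq(lambda x: self.cdf(x) - p, lo, hi, maxiter=200))
            width = hi - lo
            lo -= width
            hi += width
        raise InvalidParameterError(
            f"quantile {p} not bracketable within the expanded sample range"
        )


def kde_pdf(model: KernelDensityModel, x):
    """Estimated probability density f_h(x)."""
    return model.pdf(x)


def kde_cdf(model: KernelDensityModel, x):
    """Estimated cumulative probability Pr(X <= x)."""
    return model.cdf(x)


def threshold_for_pmd(model: KernelDensityModel, p_md: float) -> ThresholdSpec:
    """Decision threshold whose KDE-CDF equals the assumed miss probability."""
    return ThresholdSpec(p_md=float(p_md), threshold=model.quantile(p_md))


def fit_h1_calibration(
    s_max_values,
    p_md: float,
    min_samples: int = 10,
) -> tuple[ThresholdSpec, KernelDensityModel]:
    """Fit the H1 statistic density and derive the threshold for ``p_md``.

    ``s_max_values`` are segment statistics from pulse-bearing (H1)
    segments; the same entry point serves S_AVG (wear) and motion
    indicator corpora.
    """
    x = np.asarray(s_max_values, dtype=float).ravel()
    if x.size < min_samples:
        raise CalibrationError(
            f"calibration needs >= {min_samples} segment statistics, got {x.size}"
        )
    model = KernelDensityModel.fit(x)
    return threshold_for_pmd(model, p_md), model
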