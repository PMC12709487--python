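"""Transforms of the fractal-dimension map and distribution summaries.

Raw Df distributions of two tissue cohorts can overlap heavily.  Two
monotone transforms sharpen the contrast:

* ``lnDf`` — elementwise natural log; for Df in (0, 2) this amplifies
  relative differences between group means.
* ``Dtf = Df / (Dfmax - Df)`` — a functional transform that diverges as
  Df approaches the maximum dimension recorded across the analyzed image
  set, stretching the right tail where diseased tissue concentrates.
  ``lnDtf`` is its log.

The distribution of each variable is summarized by a fixed-bin histogram
(70 bins), a least-squares polynomial smoothing of the histogram curve,
and a Gaussian fit whose peak/width/goodness score characterize how
Gaussian-like (regular) versus long-tailed (disordered) the texture is.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TransformParams",
    "DistributionSummary",
    "GaussianFit",
    "log_transform",
    "functional_transform",
    "estimate_distribution",
    "polynomial_smooth",
    "gaussian_fit",
    "summarize_distribution",
]

DEFAULT_BINS = 70
DEFAULT_POLY_DEGREE = 8


@dataclass(frozen=True)
class TransformParams:
    """Parameters of the functional transform Df -> Df/(Dfmax - Df).

    ``df_max`` is the maximum Df recorded across all images analyzed
    together (both groups pooled); ``epsilon_guard`` keeps the map finite
    for the sub-box that attains the maximum itself.
    """

    df_max: float
    epsilon_guard: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 < self.df_max <= 2.0:
            raise ValueError("df_max must lie in (0, 2]")
        if self.epsilon_guard <= 0:
            raise ValueError("epsilon_guard must be positive")

    @classmethod
    def from_values(cls, values: np.ndarray, epsilon_guard: float = 1e-6
                    ) -> "TransformParams":
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            raise ValueError("no finite values to take a maximum over")
        return cls(df_max=float(v.max()), epsilon_guard=epsilon_guard)


@dataclass(frozen=True)
class GaussianFit:
    peak: float            # location of the maximum
    sigma: float           # standard deviation
    height: float          # value at the peak
    chi_square_score: float  # goodness percentage in [0, 100]
    converged: bool


@dataclass(frozen=True)
class DistributionSummary:
    """Histogram of a metric with optional smoothing and Gaussian fit."""

    bin_edges: np.ndarray          # length n_bins + 1
    probabilities: np.ndarray      # length n_bins, sums to 1
    degenerate: bool = False       # all input values identical
    smoothed: np.ndarray | None = None
    gaussian: GaussianFit | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_bins(self) -> int:
        return len(self.probabilities)


def log_transform(values: np.ndarray) -> np.ndarray:
    """Elementwise natural log; non-positive or missing entries become NaN."""
    v = np.asarray(values, dtype=float)
    out = np.full_like(v, np.nan)
    ok = np.isfinite(v) & (v > 0)
    out[ok] = np.log(v[ok])
    return out


def functional_transform(values: np.ndarray, params: TransformParams) -> np.ndarray:
    """Dtf = Df / (df_max + guard - Df), elementwise; NaN propagates.

    Strictly increasing in Df, so sub-box rank order is preserved while
    spacing widens toward df_max.
    """
    v = np.asarray(values, dtype=float)
    finite = v[np.isfinite(v)]
    if finite.size and finite.max() > params.df_max + 1e-12:
        raise ValueError(
            f"df_max {params.df_max} is below the largest value "
            f"{finite.max():.6f} in the map"
        )
    out = np.full_like(v, np.nan)
    ok = np.isfinite(v)
    out[ok] = v[ok] / (params.df_max + params.epsilon_guard - v[ok])
    return out


def estimate_distribution(values: np.ndarray, n_bins: int = DEFAULT_BINS
                          ) -> DistributionSummary:
    """Equal-width histogram over [min, max], normalized to probabilities."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least two finite values for a histogram")
    if v.min() == v.max():
        # all mass at one point: a single-bin degenerate summary
        edges = np.array([v.min() - 0.5, v.min() + 0.5])
        return DistributionSummary(bin_edges=edges, probabilities=np.array([1.0]),
                                   degenerate=True)
    counts, edges = np.histogram(v, bins=n_bins)
    probs = counts / counts.sum()
    return DistributionSummary(bin_edges=edges, probabilities=probs)


def polynomial_smooth(summary: DistributionSummary,
                      degree: int = DEFAULT_POLY_DEGREE) -> DistributionSummary:
    """Least-squares polynomial smoothing of the histogram curve.

    Fitted values are floored at zero (probabilities cannot be negative).
    """
    if summary.degenerate:
        return replace(summary, smoothed=summary.probabilities.copy())
    if degree >= summary.n_bins:
        raise ValueError("polynomial degree must be below the number of bins")
    x, y = summary.bin_centers, summary.probabilities
    poly = np.polynomial.Polynomial.fit(x, y, degree)
    fitted = np.maximum(poly(x), 0.0)
    return replace(summary, smoothed=fitted)


def _gauss(x: np.ndarray, height: float, peak: float, sigma: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((x - peak) / sigma) ** 2)


def _score(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Goodness percentage: 100*(1 - SS_res/SS_tot), clipped to [0, 100].

    An R^2-style convention for "how Gaussian the histogram looks";
    100 means the fitted curve passes through every bin probability.
    """
    ss_res = float(np.sum((observed - fitted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        return 100.0 if ss_res == 0.0 else 0.0
    return float(np.clip(100.0 * (1.0 - ss_res / ss_tot), 0.0, 100.0))


def gaussian_fit(summary: DistributionSummary) -> GaussianFit:
    """Nonlinear least-squares Gaussian fit to the bin probabilities.

    Falls back to moment estimates (histogram mean/std) if the optimizer
    fails to converge; the fallback is flagged via ``converged=False``.
    """
    x, y = summary.bin_centers, summary.probabilities
    if (y > 0).sum() < 5:
        raise ValueError("need at least five non-empty bins for a Gaussian fit")
    mean0 = float(np.sum(x * y))
    var0 = float(np.sum((x - mean0) ** 2 * y))
    sigma0 = max(np.sqrt(var0), 1e-12)
    p0 = (float(y.max()), mean0, sigma0)
    try:
        popt, _ = curve_fit(_gauss, x, y, p0=p0, maxfev=20000)
        height, peak, sigma = popt
        sigma = abs(float(sigma))
        if sigma <= 0 or not np.all(np.isfinite(popt)):
            raise RuntimeError("degenerate optimum")
        fitted = _gauss(x, height, peak, sigma)
        return GaussianFit(peak=float(peak), sigma=sigma, height=float(height),
                           chi_square_score=_score(y, fitted), converged=True)
    except (RuntimeError, ValueError):
        fitted = _gauss(x, *p0)
        return GaussianFit(peak=mean0, sigma=sigma0, height=float(y.max()),
                           chi_square_score=_score(y, fitted), converged=False)


def summarize_distribution(values: np.ndarray, n_bins: int = DEFAULT_BINS,
                           degree: int = DEFAULT_POLY_DEGREE
                           ) -> DistributionSummary:
    """Histogram + polynomial smoothing + Gaussian fit in one call."""
    summary = polynomial_smooth(estimate_distribution(values, n_bins), degree)
    if summary.degenerate or (summary.probabilities > 0).sum() < 5:
        return summary
    return replace(summary, gaussian=gaussian_fit(summary))
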