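"""Chhabra–Jensen multifractal spectrum of a grayscale image.

A single fractal dimension summarizes a texture with one number; the
multifractal spectrum f(alpha) resolves it into the dimensions of the
iso-singularity sets — f(alpha) is the fractal dimension of the set of
points whose local measure scales like eps^alpha.  Heterogeneous textures
produce broad spectra, near-homogeneous ones collapse toward the single
point (2, 2) of the plane.

The direct (Chhabra–Jensen) estimator avoids the Legendre transform.  For
each moment order q, the box measure P_i(eps) (box intensity mass over
total mass) is reweighted into

    mu_i(q, eps) = P_i^q / sum_j P_j^q,

and the singularity strength and spectrum value follow as cross-scale
regression slopes:

    alpha(q) = d[ sum_i mu_i ln P_i ] / d ln eps,
    f(q)     = d[ sum_i mu_i ln mu_i ] / d ln eps,

with tau(q) = q*alpha(q) - f(q).  Regressing over several scales (rather
than evaluating a single-scale ratio) makes the estimate robust to
lattice effects; the per-q regression R^2 is kept as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .image_io import GrayImage

__all__ = [
    "MultifractalSpectrum",
    "SpectrumMetrics",
    "default_q_grid",
    "default_mfa_scales",
    "normalized_measure",
    "chhabra_weights",
    "spectrum",
    "spectrum_metrics",
]

#: Moment orders q from -10 to +10 in steps of 0.5.
def default_q_grid(q_min: float = -10.0, q_max: float = 10.0,
                   q_step: float = 0.5) -> np.ndarray:
    n = int(round((q_max - q_min) / q_step))
    return q_min + q_step * np.arange(n + 1)


def default_mfa_scales(side: int) -> list[int]:
    """Dyadic box scales side/64 .. side/4 (e.g. 8..128 for a 512 image)."""
    scales = [s for s in (side // 64, side // 32, side // 16, side // 8, side // 4)
              if s >= 2]
    if len(scales) < 3:
        raise ValueError(f"image side {side} too small for a three-scale fit")
    return scales


@dataclass(frozen=True)
class MultifractalSpectrum:
    q_values: np.ndarray
    alpha: np.ndarray        # singularity strength alpha(q)
    f_alpha: np.ndarray      # spectrum f(alpha(q))
    tau: np.ndarray          # mass exponent tau(q) = q*alpha - f
    scales_used: np.ndarray
    r2_alpha: np.ndarray     # per-q regression R^2 of the alpha fit
    r2_f: np.ndarray         # per-q regression R^2 of the f fit


@dataclass(frozen=True)
class SpectrumMetrics:
    """Width, peak location and signed asymmetry of an f(alpha) curve."""

    width: float          # alpha_max - alpha_min
    peak_alpha: float     # alpha at the f maximum (q = 0)
    asymmetry: float      # (alpha_max - peak) - (peak - alpha_min)


def normalized_measure(img: GrayImage | np.ndarray, eps: int) -> np.ndarray:
    """Box probabilities P_i = box intensity mass / total mass, at scale eps.

    Returned as the (side/eps, side/eps) grid; entries sum to one.
    """
    px = img if isinstance(img, np.ndarray) else img.pixels
    px = np.asarray(px, dtype=float)
    side = px.shape[0]
    if px.ndim != 2 or px.shape[1] != side:
        raise ValueError("normalized_measure expects a square image")
    if eps <= 0 or side % eps != 0:
        raise ValueError(f"scale {eps} must divide the image side {side}")
    total = px.sum()
    if total <= 0:
        raise ValueError("image has zero total intensity")
    m = side // eps
    sums = px.reshape(m, eps, m, eps).sum(axis=(1, 3))
    return sums / total


def chhabra_weights(P: np.ndarray, q: float) -> np.ndarray:
    """Normalized q-moments mu_i = P_i^q / sum_j P_j^q over non-empty boxes.

    Computed in log space so strongly negative q does not overflow.
    """
    p = np.asarray(P, dtype=float).ravel()
    p = p[p > 0]
    if p.size == 0:
        raise ValueError("no boxes with positive measure")
    logp = np.log(p)
    logw = q * logp - logsumexp(q * logp)
    return np.exp(logw)


def _slope_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope of y on x and the regression R^2."""
    xm, ym = x - x.mean(), y - y.mean()
    sxx = float(np.dot(xm, xm))
    slope = float(np.dot(xm, ym)) / sxx
    ss_tot = float(np.dot(ym, ym))
    if ss_tot == 0.0:
        return slope, 1.0
    resid = ym - slope * xm
    return slope, 1.0 - float(np.dot(resid, resid)) / ss_tot


def spectrum(
    img: GrayImage | np.ndarray,
    q_grid: np.ndarray | None = None,
    scales: list[int] | None = None,
) -> MultifractalSpectrum:
    """Estimate the full f(alpha) spectrum of one grayscale image.

    Boxes with zero intensity mass are dropped before forming the
    q-weights (their log-measure is undefined); the measure itself is the
    raw intensity mass, so the analysis runs on the grayscale raster, not
    a binarized one.
    """
    px = img if isinstance(img, np.ndarray) else img.pixels
    px = np.asarray(px, dtype=float)
    side = px.shape[0]
    if q_grid is None:
        q_grid = default_q_grid()
    if scales is None:
        scales = default_mfa_scales(side)
    if len(scales) < 3:
        raise ValueError("need at least three scales for the regressions")

    log_eps = np.log(np.asarray(scales, dtype=float))
    # per-scale log box probabilities, zero boxes dropped
    logps = []
    for eps in scales:
        p = normalized_measure(px, eps).ravel()
        p = p[p > 0]
        if p.size == 0:
            raise ValueError("image has no boxes with positive measure")
        logps.append(np.log(p))

    nq = len(q_grid)
    alpha = np.empty(nq)
    f_alpha = np.empty(nq)
    r2_a = np.empty(nq)
    r2_f = np.empty(nq)
    for k, q in enumerate(q_grid):
        num_a = np.empty(len(scales))
        num_f = np.empty(len(scales))
        for j, logp in enumerate(logps):
            logw = q * logp - logsumexp(q * logp)
            w = np.exp(logw)
            num_a[j] = float(np.dot(w, logp))
            num_f[j] = float(np.dot(w, logw))
        alpha[k], r2_a[k] = _slope_r2(log_eps, num_a)
        f_alpha[k], r2_f[k] = _slope_r2(log_eps, num_f)
    tau = q_grid * alpha - f_alpha
    return MultifractalSpectrum(q_values=np.asarray(q_grid, dtype=float),
                                alpha=alpha, f_alpha=f_alpha, tau=tau,
                                scales_used=np.asarray(scales, dtype=int),
                                r2_alpha=r2_a, r2_f=r2_f)


def spectrum_metrics(s: MultifractalSpectrum) -> SpectrumMetrics:
    """Width, peak alpha (at q = 0) and signed asymmetry of a spectrum.

    Positive asymmetry means the spectrum extends further toward large
    alpha (sparse regions) than toward small alpha (dense regions).
    """
    a_min, a_max = float(s.alpha.min()), float(s.alpha.max())
    k0 = int(np.argmin(np.abs(s.q_values)))
    peak = float(s.alpha[k0])
    return SpectrumMetrics(width=a_max - a_min, peak_alpha=peak,
                           asymmetry=(a_max - peak) - (peak - a_min))
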