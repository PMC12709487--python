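"""Synthetic images with analytically known texture parameters.

The study design this package targets — two cohorts of brightfield tissue
images, one structurally regular and one disordered — is emulated here
with generators whose ground truth is known in closed form:

* :func:`sierpinski_carpet` — a deterministic fractal of box-counting
  dimension ln 8 / ln 3, the oracle for the box-counting estimator.
* :func:`multiplicative_cascade` — a randomized four-weight quadrant
  cascade whose multifractal spectrum is known exactly
  (tau(q) = -log2 sum p_i^q), the oracle for the Chhabra–Jensen
  estimator.
* :func:`disorder_field` — a stationary Gaussian random intensity field
  with controlled relative fluctuation strength dn and exponential
  correlation length lc, the knobs of the structural disorder parameter
  Ld = <dn> * lc probed by the IPR analysis.
* :func:`make_cohorts` — labeled "control" / "disease" image sets
  combining a cascade texture with a disorder field, with every
  generating parameter recorded in a manifest.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .image_io import BinaryImage, GrayImage

__all__ = [
    "CascadeParams",
    "DisorderFieldParams",
    "CohortSpec",
    "Cohorts",
    "sierpinski_carpet",
    "vicsek_cross",
    "multiplicative_cascade",
    "analytic_cascade_spectrum",
    "disorder_field",
    "make_cohorts",
    "default_cohort_spec",
    "CONTROL_PRESET",
    "DISEASE_PRESET",
]


@dataclass(frozen=True)
class CascadeParams:
    """Randomized multiplicative cascade: four quadrant weights, a depth.

    At every subdivision each cell's mass is split among its four
    children in the fixed proportions ``quadrant_weights``, but which
    child gets which weight is shuffled per cell — the image looks
    irregular while the analytic spectrum depends only on the weights.
    """

    quadrant_weights: tuple[float, float, float, float]
    levels: int
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.quadrant_weights, dtype=float)
        if w.shape != (4,) or np.any(w < 0):
            raise ValueError("need four non-negative quadrant weights")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("quadrant weights must sum to 1")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")

    @property
    def side(self) -> int:
        return 2 ** self.levels


@dataclass(frozen=True)
class DisorderFieldParams:
    """Correlated Gaussian intensity field parameters.

    ``dn`` is the relative fluctuation strength (field std / mean),
    ``lc`` the exponential correlation length in pixels,
    ``base_intensity`` the mean gray level of the exported image.
    """

    dn: float
    lc: float
    side: int = 512
    base_intensity: float = 180.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dn < 0:
            raise ValueError("dn must be non-negative")
        if self.lc < 1:
            raise ValueError("lc must be at least one pixel")
        if not 0 < self.base_intensity <= 255:
            raise ValueError("base_intensity must lie in (0, 255]")


@dataclass(frozen=True)
class GroupPreset:
    """Generating parameters of one cohort arm."""

    dn: float
    lc: float
    cascade_weights: tuple[float, float, float, float] | None = None


#: Low-disorder arm: weak short-range fluctuations, near-uniform cascade.
CONTROL_PRESET = GroupPreset(dn=0.05, lc=2.0,
                             cascade_weights=(0.28, 0.26, 0.24, 0.22))
#: High-disorder arm: doubled fluctuation strength, doubled correlation
#: length, more heterogeneous cascade weights.
DISEASE_PRESET = GroupPreset(dn=0.10, lc=4.0,
                             cascade_weights=(0.31, 0.27, 0.23, 0.19))


@dataclass(frozen=True)
class CohortSpec:
    """A two-arm synthetic study: n images per arm, one preset per arm."""

    n_images: int
    control: GroupPreset
    disease: GroupPreset
    side: int = 512
    base_intensity: float = 180.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("need at least one image per group")
        if self.side < 4 or (self.side & (self.side - 1)) != 0:
            raise ValueError("side must be a power of two >= 4")


@dataclass(frozen=True)
class Cohorts:
    """Labeled image sets plus the ground-truth manifest."""

    groups: dict[str, list[GrayImage]]
    manifest: pd.DataFrame


def sierpinski_carpet(levels: int) -> BinaryImage:
    """Deterministic Sierpinski carpet: 3^levels side, 8^levels foreground.

    Its box-counting dimension is ln 8 / ln 3 ~ 1.8928 at every depth.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    cell = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=bool)
    carpet = cell.copy()
    for _ in range(levels - 1):
        carpet = np.kron(carpet, cell)
    return BinaryImage(pixels=carpet, threshold_fraction=0.5)


def vicsek_cross(levels: int) -> BinaryImage:
    """Vicsek (cross) fractal, dimension ln 5 / ln 3 ~ 1.465."""
    if levels < 1:
        raise ValueError("levels must be >= 1")
    cell = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    cross = cell.copy()
    for _ in range(levels - 1):
        cross = np.kron(cross, cell)
    return BinaryImage(pixels=cross, threshold_fraction=0.5)


def multiplicative_cascade(params: CascadeParams) -> tuple[np.ndarray, GrayImage]:
    """Randomized quadrant cascade; returns (exact measure, exported image).

    The measure sums to one at every recursion level; the exported image
    is the measure linearly rescaled to [0, 255] for file export.
    """
    rng = np.random.default_rng(params.seed)
    w = np.asarray(params.quadrant_weights, dtype=float)
    m = np.ones((1, 1))
    for _ in range(params.levels):
        s = m.shape[0]
        # one independent permutation of the four weights per parent cell
        perms = rng.permuted(np.tile(w, (s * s, 1)), axis=1)
        quads = perms.reshape(s, s, 2, 2)
        m = (m[:, :, None, None] * quads).transpose(0, 2, 1, 3).reshape(2 * s, 2 * s)
    peak = m.max()
    img = GrayImage(pixels=m * (255.0 / peak) if peak > 0 else m)
    return m, img


def analytic_cascade_spectrum(
    weights: Sequence[float], q_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form (tau, alpha, f) of the four-weight quadrant cascade.

    tau(q) = -log2(sum p_i^q);  alpha = dtau/dq;  f = q*alpha - tau.
    Valid for any positive weights summing to one, independent of depth
    and of the per-cell shuffling.
    """
    p = np.asarray(weights, dtype=float)
    if np.any(p <= 0):
        raise ValueError("analytic spectrum needs strictly positive weights")
    if abs(p.sum() - 1.0) > 1e-12:
        raise ValueError("weights must sum to 1")
    q = np.asarray(q_grid, dtype=float)
    pq = p[None, :] ** q[:, None]
    z = pq.sum(axis=1)
    tau = -np.log2(z)
    alpha = -(pq * np.log(p)[None, :]).sum(axis=1) / (np.log(2.0) * z)
    f = q * alpha - tau
    return tau, alpha, f


def _correlated_unit_field(side: int, lc: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-std Gaussian field with exponential correlation lc.

    Spectral synthesis: the periodic embedding of exp(-r/lc) is Fourier
    transformed, negative spectral weights (from the embedding) are
    clipped, and white noise is filtered by the square-root spectrum.
    The realization is re-standardized sample-wise so the requested
    fluctuation amplitude is exact up to clipping in the caller.
    """
    ax = np.minimum(np.arange(side), side - np.arange(side)).astype(float)
    r = np.hypot(ax[:, None], ax[None, :])
    spec = np.fft.fft2(np.exp(-r / lc)).real
    spec = np.clip(spec, 0.0, None)
    white = rng.standard_normal((side, side))
    g = np.fft.ifft2(np.sqrt(spec) * np.fft.fft2(white)).real
    g -= g.mean()
    sd = g.std()
    if sd == 0:
        return g
    return g / sd


def disorder_field(params: DisorderFieldParams) -> GrayImage:
    """Correlated intensity field I = base * (1 + dn * g), clipped to [0, 255].

    g is the unit-variance exponentially correlated Gaussian field, so
    the sample relative fluctuation matches dn exactly before clipping;
    presets keep 3*dn*base inside the dynamic range so clipping touches
    well under 1% of pixels.
    """
    rng = np.random.default_rng(params.seed)
    if params.dn == 0:
        return GrayImage(pixels=np.full((params.side, params.side),
                                        float(params.base_intensity)))
    g = _correlated_unit_field(params.side, params.lc, rng)
    px = params.base_intensity * (1.0 + params.dn * g)
    return GrayImage(pixels=np.clip(px, 0.0, 255.0))


def _cohort_image(preset: GroupPreset, side: int, base: float,
                  seed_field: int, seed_cascade: int) -> GrayImage:
    """One synthetic tissue image: cascade texture times disorder field."""
    tex = np.ones((side, side))
    if preset.cascade_weights is not None:
        levels = int(np.log2(side))
        m, _ = multiplicative_cascade(CascadeParams(
            quadrant_weights=preset.cascade_weights, levels=levels,
            seed=seed_cascade))
        tex = m / m.mean()
    fld = disorder_field(DisorderFieldParams(
        dn=preset.dn, lc=preset.lc, side=side, base_intensity=base,
        seed=seed_field))
    px = fld.pixels * tex
    return GrayImage(pixels=np.clip(px, 0.0, 255.0))


def make_cohorts(spec: CohortSpec) -> Cohorts:
    """Generate the labeled two-arm study with a ground-truth manifest.

    Per-image seeds are spawned deterministically from the master seed,
    so the same spec regenerates bit-identical images.
    """
    groups: dict[str, list[GrayImage]] = {}
    rows = []
    presets = {"control": spec.control, "disease": spec.disease}
    for gi, (name, preset) in enumerate(presets.items()):
        imgs = []
        for i in range(spec.n_images):
            ss = np.random.SeedSequence(
                entropy=spec.master_seed, spawn_key=(gi, i))
            seed_field, seed_cascade = ss.generate_state(2).tolist()
            img = _cohort_image(preset, spec.side, spec.base_intensity,
                                seed_field, seed_cascade)
            imgs.append(img)
            rows.append({
                "image_id": f"{name}_{i:02d}", "group": name,
                "dn": preset.dn, "lc": preset.lc,
                "cascade_weights": preset.cascade_weights,
                "side": spec.side, "base_intensity": spec.base_intensity,
                "seed_field": seed_field, "seed_cascade": seed_cascade,
            })
        groups[name] = imgs
    return Cohorts(groups=groups, manifest=pd.DataFrame(rows))


def default_cohort_spec(master_seed: int = 0, n_images: int = 10,
                        side: int = 512) -> CohortSpec:
    """The shipped two-arm study: 10 + 10 images, 512 px, default presets."""
    return CohortSpec(n_images=n_images, control=CONTROL_PRESET,
                      disease=DISEASE_PRESET, side=side,
                      master_seed=master_seed)
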