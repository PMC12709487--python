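"""Box-counting fractal dimension maps and their parameter sweeps.

The box-counting dimension of a binary pattern is the scaling exponent
relating the number of occupied grid cells N(eps) to the cell size eps:
N(eps) ~ eps^(-Df), estimated as the least-squares slope of ln N(eps)
against ln(1/eps).  A space-filling block gives Df = 2, an isolated pixel
Df = 0, and fractal sets fall in between (e.g. the Sierpinski carpet at
ln 8 / ln 3 ~ 1.8928).

The pipeline computes Df not once per image but per 32x32 sub-box, turning
a 512x512 image into a 16x16 map of 256 local dimensions whose
distribution, rather than its mean alone, carries the texture signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .image_io import BinaryImage, GrayImage, binarize, partition

__all__ = [
    "BoxCountCurve",
    "FractalMap",
    "SweepTable",
    "default_scales",
    "box_count",
    "fit_dimension",
    "fractal_map",
    "pooled_df_values",
    "sweep_length_scale",
    "sweep_threshold",
]

DEFAULT_BLOCK_SIDE = 32
DEFAULT_THRESHOLD = 0.65


@dataclass(frozen=True)
class BoxCountCurve:
    """N(eps) over a set of grid scales for one sub-box."""

    scales: np.ndarray            # strictly increasing eps, pixels
    counts: np.ndarray            # N(eps), same length
    block_coord: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        s = np.asarray(self.scales, dtype=int)
        c = np.asarray(self.counts, dtype=int)
        if s.ndim != 1 or s.shape != c.shape:
            raise ValueError("scales and counts must be matching 1-D arrays")
        if np.any(np.diff(s) <= 0):
            raise ValueError("scales must be strictly increasing")
        object.__setattr__(self, "scales", s)
        object.__setattr__(self, "counts", c)


@dataclass(frozen=True)
class FractalMap:
    """Per-sub-box Df values on the partition grid.

    Degenerate sub-boxes (no foreground, or occupied at fewer than two
    scales) hold NaN and are excluded from the mean/std, never counted as
    zero — a zero would drag group means toward empty glass rather than
    tissue.
    """

    df_values: np.ndarray         # (n, n) float with NaN for degenerate blocks
    block_side: int
    threshold_fraction: float
    curves: tuple[BoxCountCurve, ...] = field(default=(), repr=False)

    @property
    def defined(self) -> np.ndarray:
        return self.df_values[np.isfinite(self.df_values)]

    @property
    def mean(self) -> float:
        d = self.defined
        return float(d.mean()) if d.size else float("nan")

    @property
    def std(self) -> float:
        d = self.defined
        return float(d.std()) if d.size else float("nan")

    @property
    def n_defined(self) -> int:
        return int(np.isfinite(self.df_values).sum())


@dataclass(frozen=True)
class SweepTable:
    """Per-group mean/std of a metric along one swept parameter."""

    parameter: str                # "length_scale" | "threshold"
    table: pd.DataFrame           # columns: parameter value, group, mean, std, n
    best_mean_gap: float | None = None   # parameter value maximizing |mean gap|
    best_std_gap: float | None = None    # parameter value maximizing |std gap|


def default_scales(block_side: int) -> list[int]:
    """Dyadic grid scales 2, 4, ... up to half the block side.

    The full-block scale (N = 1 always) carries no information about the
    pattern and is left out of the fit.
    """
    if block_side < 4:
        raise ValueError("block side must be at least 4 for a two-scale fit")
    scales = []
    e = 2
    while e <= block_side // 2:
        scales.append(e)
        e *= 2
    return scales


def box_count(
    block: BinaryImage | np.ndarray,
    scales: Sequence[int] | None = None,
    block_coord: tuple[int, int] = (0, 0),
) -> BoxCountCurve:
    """Count non-empty grid cells of each scale covering a binary block."""
    px = block if isinstance(block, np.ndarray) else block.pixels
    px = np.asarray(px, dtype=bool)
    side = px.shape[0]
    if px.ndim != 2 or px.shape[1] != side:
        raise ValueError("box_count expects a square 2-D block")
    if scales is None:
        scales = default_scales(side)
    counts = []
    for eps in scales:
        if eps <= 0 or side % eps != 0:
            raise ValueError(f"scale {eps} does not divide the block side {side}")
        m = side // eps
        occupied = px.reshape(m, eps, m, eps).any(axis=(1, 3))
        counts.append(int(occupied.sum()))
    return BoxCountCurve(scales=np.asarray(scales, dtype=int),
                         counts=np.asarray(counts, dtype=int),
                         block_coord=block_coord)


def fit_dimension(curve: BoxCountCurve) -> float:
    """Least-squares slope of ln N(eps) vs ln(1/eps), clipped to [0, 2].

    Only scales with N(eps) > 0 enter the fit; with fewer than two usable
    scales the block is degenerate and NaN is returned.
    """
    mask = curve.counts > 0
    if mask.sum() < 2:
        return float("nan")
    x = np.log(1.0 / curve.scales[mask].astype(float))
    y = np.log(curve.counts[mask].astype(float))
    slope = np.polyfit(x, y, 1)[0]
    return float(np.clip(slope, 0.0, 2.0))


def fractal_map(
    img: BinaryImage,
    block_side: int = DEFAULT_BLOCK_SIDE,
    scales: Sequence[int] | None = None,
) -> FractalMap:
    """Df per sub-box: the fractal map of one binary image."""
    side = img.pixels.shape[0]
    if side % block_side != 0:
        raise ValueError(f"block_side {block_side} must divide image side {side}")
    if scales is None:
        scales = default_scales(block_side)
    n = side // block_side
    df = np.full((n, n), np.nan)
    curves = []
    for blk in partition(img, block_side):
        curve = box_count(blk.pixels, scales, block_coord=(blk.row, blk.col))
        curves.append(curve)
        df[blk.row, blk.col] = fit_dimension(curve)
    return FractalMap(df_values=df, block_side=block_side,
                      threshold_fraction=img.threshold_fraction,
                      curves=tuple(curves))


def pooled_df_values(
    imgs: Iterable[GrayImage],
    block_side: int = DEFAULT_BLOCK_SIDE,
    threshold_fraction: float = DEFAULT_THRESHOLD,
    invert: bool = False,
) -> np.ndarray:
    """All defined sub-box Df values of a set of images, concatenated."""
    vals = []
    for img in imgs:
        fmap = fractal_map(binarize(img, threshold_fraction, invert=invert),
                           block_side)
        vals.append(fmap.defined)
    return np.concatenate(vals) if vals else np.empty(0)


def _group_rows(
    groups: Mapping[str, Sequence[GrayImage]],
    parameter: str,
    value: float,
    values_fn,
) -> list[dict]:
    rows = []
    for group, imgs in groups.items():
        vals = values_fn(imgs)
        rows.append({
            parameter: value,
            "group": group,
            "mean": float(np.mean(vals)) if len(vals) else float("nan"),
            "std": float(np.std(vals)) if len(vals) else float("nan"),
            "n": int(len(vals)),
        })
    return rows


def _gap_argmax(table: pd.DataFrame, parameter: str, col: str) -> float | None:
    """Parameter value with the largest absolute between-group gap in `col`."""
    groups = table["group"].unique()
    if len(groups) != 2:
        return None
    a, b = groups
    pa = table[table.group == a].set_index(parameter)[col]
    pb = table[table.group == b].set_index(parameter)[col]
    gap = (pa - pb).abs().dropna()
    if gap.empty:
        return None
    return float(gap.idxmax())


def sweep_length_scale(
    groups: Mapping[str, Sequence[GrayImage]],
    block_sides: Sequence[int] = (32, 64, 128, 256, 512),
    threshold_fraction: float = DEFAULT_THRESHOLD,
    invert: bool = False,
) -> SweepTable:
    """Pooled Df mean/std per group as the sub-box side varies.

    At block side 512 the whole image is a single box, giving one Df per
    image; small sides trade statistical stability for spatial detail.
    """
    if not groups or any(len(v) == 0 for v in groups.values()):
        raise ValueError("every group needs at least one image")
    rows = []
    for bs in block_sides:
        rows += _group_rows(
            groups, "length_scale", bs,
            lambda imgs, bs=bs: pooled_df_values(imgs, bs, threshold_fraction,
                                                 invert),
        )
    table = pd.DataFrame(rows)
    return SweepTable(parameter="length_scale", table=table,
                      best_mean_gap=_gap_argmax(table, "length_scale", "mean"),
                      best_std_gap=_gap_argmax(table, "length_scale", "std"))


def sweep_threshold(
    groups: Mapping[str, Sequence[GrayImage]],
    fractions: Sequence[float],
    block_side: int = DEFAULT_BLOCK_SIDE,
    invert: bool = False,
) -> SweepTable:
    """Pooled Df mean/std per group as the binary threshold varies.

    Also reports the fraction maximizing the between-group mean gap and
    the one maximizing the std gap — the two calibration optima used to
    pick a working threshold.
    """
    if len(fractions) == 0:
        raise ValueError("fractions must be non-empty")
    if any(not 0.0 <= f <= 1.0 for f in fractions):
        raise ValueError("threshold fractions must lie in [0, 1]")
    if not groups or any(len(v) == 0 for v in groups.values()):
        raise ValueError("every group needs at least one image")
    rows = []
    for frac in fractions:
        rows += _group_rows(
            groups, "threshold", frac,
            lambda imgs, f=frac: pooled_df_values(imgs, block_side, f, invert),
        )
    table = pd.DataFrame(rows)
    return SweepTable(parameter="threshold", table=table,
                      best_mean_gap=_gap_argmax(table, "threshold", "mean"),
                      best_std_gap=_gap_argmax(table, "threshold", "std"))
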