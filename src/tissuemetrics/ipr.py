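"""Light-localization (inverse participation ratio) disorder analysis.

Transmission intensity tracks local mass density, and mass density tracks
refractive index, so the relative intensity fluctuation inside an image
block is an *optical potential*: on-site energies

    eps_i = (I_i - I0) / I0,        I0 = block mean intensity,

placed on an L x L lattice with nearest-neighbor hopping t form an
Anderson tight-binding Hamiltonian

    H = sum_i eps_i |i><i| + t sum_<ij> (|i><j| + |j><i|).

Disorder localizes the eigenfunctions, and the inverse participation
ratio IPR = sum_i |psi_i|^4 of a unit-normalized state measures how
localized it is: 1/N for a fully extended state, 1 for a state on one
site.  The block-level observable is the mean IPR over all N = L^2
eigenstates; it grows with both the fluctuation strength <dn> and the
spatial correlation length lc of the intensity field, i.e. with the
structural disorder parameter Ld = <dn> * lc.

Normalization convention: reported IPR = L^2 * sum psi^4 (area
normalized), so the extended-state floor is O(1) and localization raises
the value; the raw sum psi^4 is kept alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .boxcount import SweepTable
from .image_io import GrayImage, partition

__all__ = [
    "OpticalPotential",
    "TBMHamiltonian",
    "IPRResult",
    "GroupIPRStats",
    "optical_potential",
    "build_hamiltonian",
    "eigen_ipr",
    "ipr_map",
    "sweep_ipr_scale",
    "group_ipr_stats",
    "clean_lattice_mean_ipr",
]

DEFAULT_IPR_BLOCK = 32
DEFAULT_HOPPING = 1.0


@dataclass(frozen=True)
class OpticalPotential:
    """Zero-mean on-site energy field eps_i = dI/I0 of one block."""

    values: np.ndarray              # (L, L) dimensionless
    block_coord: tuple[int, int]
    i0: float                       # reference intensity (block mean)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("optical potential must be a square 2-D field")
        if not np.all(np.isfinite(v)):
            raise ValueError("optical potential must be finite everywhere")
        if abs(v.mean()) > 1e-9:
            raise ValueError("optical potential must be zero-mean")
        object.__setattr__(self, "values", v)

    @property
    def side(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class TBMHamiltonian:
    """Dense symmetric tight-binding operator on an L x L open lattice."""

    matrix: np.ndarray              # (L^2, L^2) symmetric
    side: int
    hopping: float

    @property
    def dimension(self) -> int:
        return self.side ** 2


@dataclass(frozen=True)
class IPRResult:
    """Block-resolved mean-IPR heatmap of one image.

    ``per_block`` holds the area-normalized block means (NaN for skipped
    degenerate blocks); ``per_block_raw`` the corresponding raw
    sum(psi^4) means.
    """

    per_block: np.ndarray
    per_block_raw: np.ndarray
    block_side: int

    @property
    def defined(self) -> np.ndarray:
        return self.per_block[np.isfinite(self.per_block)]

    @property
    def image_mean(self) -> float:
        d = self.defined
        return float(d.mean()) if d.size else float("nan")

    @property
    def image_std(self) -> float:
        d = self.defined
        return float(d.std()) if d.size else float("nan")


@dataclass(frozen=True)
class GroupIPRStats:
    """Pooled block-level IPR statistics of two labeled groups."""

    table: pd.DataFrame                 # group, mean, std, n_blocks
    mean_pct_difference: float          # disease vs control, % of control
    std_pct_difference: float


def optical_potential(block: GrayImage | np.ndarray,
                      block_coord: tuple[int, int] = (0, 0)
                      ) -> OpticalPotential | None:
    """Relative intensity fluctuation field of one block; None if I0 = 0.

    Zero-mean by construction and invariant under a global intensity
    rescaling (dI/I0 is dimensionless).
    """
    px = block if isinstance(block, np.ndarray) else block.pixels
    px = np.asarray(px, dtype=float)
    i0 = float(px.mean())
    if i0 <= 0.0:
        return None
    return OpticalPotential(values=px / i0 - 1.0, block_coord=block_coord, i0=i0)


def build_hamiltonian(pot: OpticalPotential,
                      t: float = DEFAULT_HOPPING) -> TBMHamiltonian:
    """Assemble the dense L^2 x L^2 operator with open boundaries.

    Diagonal = on-site energies in row-major site order; off-diagonal t on
    the 2*L*(L-1) nearest-neighbor bonds of the open L x L grid.
    """
    L = pot.side
    if L < 2:
        raise ValueError("lattice side must be at least 2")
    n = L * L
    H = np.zeros((n, n))
    H[np.diag_indices(n)] = pot.values.ravel()
    idx = np.arange(n).reshape(L, L)
    right = np.stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()])
    down = np.stack([idx[:-1, :].ravel(), idx[1:, :].ravel()])
    for pairs in (right, down):
        H[pairs[0], pairs[1]] = t
        H[pairs[1], pairs[0]] = t
    return TBMHamiltonian(matrix=H, side=L, hopping=float(t))


def eigen_ipr(H: TBMHamiltonian) -> tuple[np.ndarray, float, float]:
    """Diagonalize and return (per-state raw IPRs, block mean reported IPR,
    block mean raw IPR).

    All N = L^2 eigenstates enter the mean — no energy windowing — and
    the reported value is the area-normalized L^2 * sum(psi^4).
    """
    mat = H.matrix
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("Hamiltonian must be symmetric")
    _, vecs = np.linalg.eigh(mat)
    raw = np.sum(vecs ** 4, axis=0)          # one IPR per eigenstate (column)
    mean_raw = float(raw.mean())
    return raw, H.dimension * mean_raw, mean_raw


def ipr_map(img: GrayImage, block_side: int = DEFAULT_IPR_BLOCK,
            hopping: float = DEFAULT_HOPPING) -> IPRResult:
    """Block-mean IPR heatmap of one image (16 x 16 cells at 512/32).

    Blocks with identical potentials (e.g. bare glass or saturated
    regions) share one diagonalization: the eigenproblem depends only on
    the potential, so results are memoized within the call.
    """
    side = img.pixels.shape[0]
    if side % block_side != 0:
        raise ValueError(f"block_side {block_side} must divide image side {side}")
    n = side // block_side
    out = np.full((n, n), np.nan)
    out_raw = np.full((n, n), np.nan)
    cache: dict[bytes, tuple[float, float]] = {}
    for blk in partition(img, block_side):
        pot = optical_potential(blk.pixels, (blk.row, blk.col))
        if pot is None:
            continue                          # degenerate block, recorded as NaN
        key = pot.values.tobytes()
        if key not in cache:
            _, reported, raw = eigen_ipr(build_hamiltonian(pot, hopping))
            cache[key] = (reported, raw)
        out[blk.row, blk.col], out_raw[blk.row, blk.col] = cache[key]
    return IPRResult(per_block=out, per_block_raw=out_raw, block_side=block_side)


def sweep_ipr_scale(
    groups: Mapping[str, Sequence[GrayImage]],
    block_sides: Sequence[int] = (2, 4, 8, 16, 32),
    hopping: float = DEFAULT_HOPPING,
) -> SweepTable:
    """Pooled block-IPR mean/std per group at each lattice size."""
    if not groups or any(len(v) == 0 for v in groups.values()):
        raise ValueError("every group needs at least one image")
    rows = []
    for bs in block_sides:
        for group, imgs in groups.items():
            vals = np.concatenate(
                [ipr_map(img, bs, hopping).defined for img in imgs])
            rows.append({
                "length_scale": bs, "group": group,
                "mean": float(vals.mean()) if vals.size else float("nan"),
                "std": float(vals.std()) if vals.size else float("nan"),
                "n": int(vals.size),
            })
    table = pd.DataFrame(rows)
    return SweepTable(parameter="length_scale", table=table)


def group_ipr_stats(
    results: Mapping[str, Sequence[IPRResult]],
    control: str = "control",
    disease: str = "disease",
) -> GroupIPRStats:
    """Pooled block-level mean/std per group, with relative % differences.

    Pooling flattens every defined heatmap cell of every image of a group
    into one sample before taking moments, so images with more defined
    blocks weigh proportionally more.
    """
    if not results or any(len(v) == 0 for v in results.values()):
        raise ValueError("every group needs at least one result")
    rows = {}
    for group, items in results.items():
        vals = np.concatenate([r.defined for r in items])
        rows[group] = {
            "group": group,
            "mean": float(vals.mean()) if vals.size else float("nan"),
            "std": float(vals.std()) if vals.size else float("nan"),
            "n_blocks": int(vals.size),
        }
    table = pd.DataFrame(list(rows.values()))
    mean_pct = std_pct = float("nan")
    if control in rows and disease in rows:
        c, d = rows[control], rows[disease]
        if c["mean"] != 0:
            mean_pct = 100.0 * (d["mean"] - c["mean"]) / c["mean"]
        if c["std"] != 0:
            std_pct = 100.0 * (d["std"] - c["std"]) / c["std"]
    return GroupIPRStats(table=table, mean_pct_difference=mean_pct,
                         std_pct_difference=std_pct)


def clean_lattice_mean_ipr(side: int, hopping: float = DEFAULT_HOPPING) -> float:
    """Mean reported IPR of the disorder-free L x L open lattice.

    The floor against which disordered blocks are compared; computed by
    direct diagonalization of the zero-potential Hamiltonian.
    """
    pot = OpticalPotential(values=np.zeros((side, side)), block_coord=(0, 0),
                           i0=1.0)
    _, reported, _ = eigen_ipr(build_hamiltonian(pot, hopping))
    return reported
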