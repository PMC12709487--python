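"""Tight-binding Hamiltonian construction and IPR statistics."""

import numpy as np
import pytest

from tissuemetrics.image_io import GrayImage
from tissuemetrics.ipr import (
    OpticalPotential, build_hamiltonian, clean_lattice_mean_ipr, eigen_ipr,
    group_ipr_stats, ipr_map, optical_potential, sweep_ipr_scale,
)
from tissuemetrics.synth import DisorderFieldParams, disorder_field

# Mean reported IPR of the disorder-free 16x16 open lattice, frozen from a
# one-off direct diagonalization.
CLEAN_16 = 2.3416643237995554


class TestOpticalPotential:
    def test_uniform_block_is_zero(self):
        pot = optical_potential(np.full((4, 4), 120.0))
        assert np.all(pot.values == 0.0)
        assert pot.i0 == 120.0

    def test_hand_computed_two_by_two(self):
        # intensities (100, 100, 100, 200): I0 = 125
        px = np.array([[100.0, 100.0], [100.0, 200.0]])
        pot = optical_potential(px)
        assert np.allclose(pot.values,
                           np.array([[-0.2, -0.2], [-0.2, 0.6]]))
        assert abs(pot.values.mean()) < 1e-12

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        px = rng.uniform(50, 200, (8, 8))
        p1 = optical_potential(px)
        p2 = optical_potential(2.0 * px)
        assert np.allclose(p1.values, p2.values)

    def test_zero_intensity_block_skipped(self):
        assert optical_potential(np.zeros((4, 4))) is None


class TestHamiltonian:
    def test_two_by_two_clean_eigenvalues(self):
        pot = OpticalPotential(values=np.zeros((2, 2)), block_coord=(0, 0),
                               i0=1.0)
        H = build_hamiltonian(pot, t=1.0)
        evals = np.linalg.eigvalsh(H.matrix)
        assert np.allclose(evals, [-2.0, 0.0, 0.0, 2.0], atol=1e-12)

    def test_edge_count_three_by_three(self):
        pot = OpticalPotential(values=np.zeros((3, 3)), block_coord=(0, 0),
                               i0=1.0)
        H = build_hamiltonian(pot, t=1.0)
        off = H.matrix.copy()
        np.fill_diagonal(off, 0.0)
        assert (off != 0).sum() == 2 * 12          # 2*L*(L-1) = 12 bonds

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(5, 5))
        pot = OpticalPotential(values=v - v.mean(), block_coord=(0, 0), i0=1.0)
        H = build_hamiltonian(pot, t=0.7).matrix
        assert np.array_equal(H, H.T)

    def test_constant_shift_moves_spectrum(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(4, 4))
        v -= v.mean()
        pot = OpticalPotential(values=v, block_coord=(0, 0), i0=1.0)
        H = build_hamiltonian(pot).matrix
        c = 0.37
        e0 = np.linalg.eigvalsh(H)
        e1 = np.linalg.eigvalsh(H + c * np.eye(len(H)))
        assert np.allclose(e1, e0 + c, atol=1e-10)


class TestEigenIPR:
    def test_uniform_state_floor(self):
        n = 1024
        v = np.full(n, 1 / np.sqrt(n))
        assert np.sum(v ** 4) == pytest.approx(1 / n)
        # reported convention: N * raw = 1.0 for the fully extended state
        assert n * np.sum(v ** 4) == pytest.approx(1.0)

    def test_delta_state_ceiling(self):
        v = np.zeros(1024)
        v[17] = 1.0
        assert np.sum(v ** 4) == 1.0               # raw; reported = L^2

    def test_deep_trap_localizes_one_state(self):
        v = np.zeros((6, 6))
        v[3, 3] = 1000.0
        v -= v.mean()
        pot = OpticalPotential(values=v, block_coord=(0, 0), i0=1.0)
        raw, _, _ = eigen_ipr(build_hamiltonian(pot))
        assert raw.max() > 0.99                    # one near-delta eigenstate

    def test_eigenvector_orthonormality_and_floor(self):
        rng = np.random.default_rng(3)
        v = rng.normal(scale=0.3, size=(8, 8))
        v -= v.mean()
        pot = OpticalPotential(values=v, block_coord=(0, 0), i0=1.0)
        H = build_hamiltonian(pot)
        _, vecs = np.linalg.eigh(H.matrix)
        assert np.allclose(vecs.T @ vecs, np.eye(64), atol=1e-8)
        raw, _, _ = eigen_ipr(H)
        assert raw.sum() >= 1.0                    # >= N * (1/N)

    def test_clean_lattice_frozen_constant(self):
        assert clean_lattice_mean_ipr(16) == pytest.approx(CLEAN_16, abs=1e-8)


class TestIPRMap:
    def test_uniform_image_all_blocks_at_clean_floor(self):
        img = GrayImage(pixels=np.full((64, 64), 150.0))
        res = ipr_map(img, 16)
        assert res.per_block.shape == (4, 4)
        assert np.allclose(res.per_block, CLEAN_16, atol=1e-10)
        assert res.image_std == pytest.approx(0.0, abs=1e-12)

    def test_single_disordered_block_elevates_one_cell(self):
        rng = np.random.default_rng(4)
        px = np.full((64, 64), 150.0)
        px[16:32, 32:48] += rng.normal(scale=25.0, size=(16, 16))
        px = np.clip(px, 0, 255)
        res = ipr_map(GrayImage(pixels=px), 16)
        elevated = res.per_block > CLEAN_16 + 0.05
        assert elevated.sum() == 1 and elevated[1, 2]

    def test_blocks_never_below_clean_floor(self):
        f = disorder_field(DisorderFieldParams(dn=0.08, lc=2, side=64, seed=5))
        res = ipr_map(f, 16)
        assert np.all(res.defined >= CLEAN_16 - 1e-6)


class TestGroupStats:
    def test_paper_std_arithmetic(self):
        # printed group STDs 1.261 vs 1.563: a ~24% relative increase
        assert 100 * (1.563 - 1.261) / 1.261 == pytest.approx(24.0, abs=0.5)

    def test_identical_groups_zero_difference(self):
        img = GrayImage(pixels=np.full((32, 32), 100.0))
        r = ipr_map(img, 16)
        stats = group_ipr_stats({"control": [r], "disease": [r]})
        assert stats.mean_pct_difference == pytest.approx(0.0, abs=1e-9)

    def test_pooled_stats_equal_flat_recomputation(self):
        rng = np.random.default_rng(6)
        imgs = [GrayImage(pixels=np.clip(
            150 + rng.normal(scale=20, size=(32, 32)), 0, 255))
            for _ in range(3)]
        results = [ipr_map(i, 16) for i in imgs]
        stats = group_ipr_stats({"control": results[:1],
                                 "disease": results[1:]})
        flat = np.concatenate([r.defined for r in results[1:]])
        row = stats.table.set_index("group").loc["disease"]
        assert row["mean"] == pytest.approx(flat.mean(), abs=1e-12)
        assert row["std"] == pytest.approx(flat.std(), abs=1e-12)


class TestDisorderResponse:
    def test_mean_ipr_increases_with_dn(self):
        """Block mean IPR non-decreasing along a fluctuation-strength
        ladder at fixed correlation length (10 seeds, L=16)."""
        ok = 0
        for seed in range(10):
            vals = []
            for dn in (0.02, 0.04, 0.06, 0.08, 0.10):
                f = disorder_field(DisorderFieldParams(
                    dn=dn, lc=3, side=64, seed=1000 + seed))
                vals.append(ipr_map(f, 16).image_mean)
            ok += all(a <= b for a, b in zip(vals, vals[1:]))
        assert ok >= 9

    def test_sweep_scale_separates_cohorts_most_at_large_blocks(self):
        """Between-group IPR gap grows with lattice size."""
        rng_groups = {}
        for name, dn in (("control", 0.03), ("disease", 0.10)):
            rng_groups[name] = [
                disorder_field(DisorderFieldParams(
                    dn=dn, lc=2, side=64, seed=s + (0 if name == "control"
                                                    else 50)))
                for s in range(2)]
        sweep = sweep_ipr_scale(rng_groups, block_sides=(2, 8, 16))
        t = sweep.table.pivot(index="length_scale", columns="group",
                              values="mean")
        gap = (t["disease"] - t["control"]).abs()
        assert gap[16] >= gap[2]

    def test_uniform_cohorts_zero_gap(self):
        img = GrayImage(pixels=np.full((32, 32), 140.0))
        sweep = sweep_ipr_scale({"control": [img], "disease": [img]},
                                block_sides=(2, 4, 8))
        t = sweep.table.pivot(index="length_scale", columns="group",
                              values="mean")
        assert np.allclose(t["control"], t["disease"])
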