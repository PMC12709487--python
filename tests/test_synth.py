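"""Synthetic generators: deterministic fractals, cascades, disorder fields."""

import itertools

import numpy as np
import pytest

from tissuemetrics.synth import (
    CONTROL_PRESET, DISEASE_PRESET, CascadeParams, CohortSpec,
    DisorderFieldParams, analytic_cascade_spectrum, default_cohort_spec,
    disorder_field, make_cohorts, multiplicative_cascade, sierpinski_carpet,
    vicsek_cross,
)


class TestDeterministicFractals:
    def test_carpet_level_one(self):
        c = sierpinski_carpet(1)
        assert c.pixels.shape == (3, 3)
        assert c.foreground_count == 8
        assert not c.pixels[1, 1]

    def test_carpet_level_three_counts(self):
        c = sierpinski_carpet(3)
        assert c.pixels.shape == (27, 27)
        assert c.foreground_count == 8 ** 3

    def test_carpet_self_similarity(self):
        big = sierpinski_carpet(4)
        small = sierpinski_carpet(3)
        # top-left third of level k is level k-1
        assert np.array_equal(big.pixels[:27, :27], small.pixels)

    def test_vicsek_counts(self):
        v = vicsek_cross(3)
        assert v.foreground_count == 5 ** 3


class TestCascade:
    def test_uniform_weights_uniform_measure(self):
        m, img = multiplicative_cascade(
            CascadeParams((0.25, 0.25, 0.25, 0.25), 4, seed=0))
        assert np.allclose(m, 1 / 256)
        assert np.allclose(img.pixels, 255.0)

    def test_mass_conserved(self):
        for levels in (1, 3, 6, 9):
            m, _ = multiplicative_cascade(
                CascadeParams((0.4, 0.3, 0.2, 0.1), levels, seed=1))
            assert m.sum() == pytest.approx(1.0, abs=1e-12)
            assert m.shape == (2 ** levels, 2 ** levels)

    @pytest.mark.parametrize("levels", [1, 2, 3, 4])
    def test_box_masses_are_weight_products(self, levels):
        """Every cell mass is a product of `levels` weights, and the full
        multiset of masses matches exhaustive enumeration of weight
        assignments (shuffling permutes positions, never values)."""
        w = (0.4, 0.3, 0.2, 0.1)
        m, _ = multiplicative_cascade(CascadeParams(w, levels, seed=7))
        got = np.sort(m.ravel())
        expected = []
        for combo in itertools.product(range(4), repeat=levels):
            # each level contributes one of the four weights; multiplicity
            # handled by enumerating all 4^levels paths
            expected.append(np.prod([w[i] for i in combo]))
        assert np.allclose(got, np.sort(expected), atol=1e-12)

    def test_seeded_reproducibility(self):
        p = CascadeParams((0.4, 0.3, 0.2, 0.1), 6, seed=42)
        m1, _ = multiplicative_cascade(p)
        m2, _ = multiplicative_cascade(p)
        assert np.array_equal(m1, m2)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CascadeParams((0.5, 0.3, 0.2, 0.2), 3)


class TestAnalyticSpectrum:
    def test_tau_zero_at_q_one(self):
        tau, _, _ = analytic_cascade_spectrum((0.4, 0.3, 0.2, 0.1),
                                              np.array([1.0]))
        assert tau[0] == pytest.approx(0.0, abs=1e-12)

    def test_support_dimension_at_q_zero(self):
        tau, _, f = analytic_cascade_spectrum((0.4, 0.3, 0.2, 0.1),
                                              np.array([0.0]))
        assert tau[0] == pytest.approx(-2.0)
        assert f[0] == pytest.approx(2.0)

    def test_hand_computed_tau_two(self):
        tau, _, _ = analytic_cascade_spectrum((0.7, 0.1, 0.1, 0.1),
                                              np.array([2.0]))
        assert tau[0] == pytest.approx(-np.log2(0.52), abs=1e-12)

    def test_alpha_is_tau_derivative(self):
        q = np.linspace(-5, 5, 201)
        tau, alpha, _ = analytic_cascade_spectrum((0.4, 0.3, 0.2, 0.1), q)
        num = np.gradient(tau, q)
        assert np.allclose(alpha[5:-5], num[5:-5], atol=1e-3)


class TestDisorderField:
    def test_zero_dn_is_uniform(self):
        f = disorder_field(DisorderFieldParams(dn=0.0, lc=3, side=64))
        assert np.all(f.pixels == 180.0)

    def test_relative_fluctuation_matches_dn(self):
        f = disorder_field(DisorderFieldParams(dn=0.1, lc=4, side=256,
                                               base_intensity=150, seed=3))
        rel = f.pixels.std() / f.pixels.mean()
        assert rel == pytest.approx(0.1, rel=0.1)

    def test_autocorrelation_at_lag_lc(self):
        """Sample autocorrelation at lag lc close to 1/e, averaged over
        seeds (exponential correlation model)."""
        lc = 4
        acs = []
        for seed in range(10):
            f = disorder_field(DisorderFieldParams(dn=0.1, lc=lc, side=512,
                                                   seed=seed))
            g = f.pixels - f.pixels.mean()
            ac = (g[:, :-lc] * g[:, lc:]).mean() / g.var()
            acs.append(ac)
        assert np.mean(acs) == pytest.approx(np.exp(-1), rel=0.25)

    def test_seeds_differ_but_stats_match(self):
        p1 = DisorderFieldParams(dn=0.08, lc=3, side=256, seed=1)
        p2 = DisorderFieldParams(dn=0.08, lc=3, side=256, seed=2)
        f1, f2 = disorder_field(p1), disorder_field(p2)
        assert not np.array_equal(f1.pixels, f2.pixels)
        assert abs(f1.pixels.mean() - f2.pixels.mean()) / 180.0 < 0.01
        assert abs(f1.pixels.std() - f2.pixels.std()) / f1.pixels.std() < 0.1


class TestCohorts:
    def test_regeneration_is_bit_identical(self):
        spec = default_cohort_spec(master_seed=5, n_images=2, side=64)
        a, b = make_cohorts(spec), make_cohorts(spec)
        for g in a.groups:
            for ia, ib in zip(a.groups[g], b.groups[g]):
                assert np.array_equal(ia.pixels, ib.pixels)

    def test_counts_and_manifest(self):
        spec = default_cohort_spec(master_seed=1, n_images=3, side=64)
        c = make_cohorts(spec)
        assert sorted(c.groups) == ["control", "disease"]
        assert all(len(v) == 3 for v in c.groups.values())
        assert len(c.manifest) == 6
        assert set(c.manifest.columns) >= {"image_id", "group", "dn", "lc",
                                           "cascade_weights", "seed_field"}
        row = c.manifest[c.manifest.group == "disease"].iloc[0]
        assert row.dn == DISEASE_PRESET.dn and row.lc == DISEASE_PRESET.lc

    def test_presets_are_directionally_ordered(self):
        assert DISEASE_PRESET.dn > CONTROL_PRESET.dn
        assert DISEASE_PRESET.lc > CONTROL_PRESET.lc
        cw, dw = CONTROL_PRESET.cascade_weights, DISEASE_PRESET.cascade_weights
        assert np.std(dw) > np.std(cw)

    def test_identical_presets_are_exchangeable(self):
        spec = CohortSpec(n_images=2, control=CONTROL_PRESET,
                          disease=CONTROL_PRESET, side=64, master_seed=9)
        c = make_cohorts(spec)
        # same parameters, different seeds: images differ but moments agree
        m_c = np.mean([i.pixels.mean() for i in c.groups["control"]])
        m_d = np.mean([i.pixels.mean() for i in c.groups["disease"]])
        assert abs(m_c - m_d) / m_c < 0.05
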