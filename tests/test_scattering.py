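"""Partial g(r), Faber-Ziman S(Q), Debye oracle, transforms, coordination."""
import numpy as np
import pytest

from epsrlite.molecule import build_indomethacin_z
from epsrlite.refine import Configuration
from epsrlite.scattering import (PairFunctionSet, ScatteringPattern, XRayWeights,
                                 debye_oracle, dr_from_sq, faber_ziman_total,
                                 gr_from_dr, partial_gr, running_coordination,
                                 total_pattern, xray_form_factor)


def _weights_single(n=1):
    return XRayWeights.from_types(["C1"], ["C"])


class TestFormFactors:
    def test_forward_limit_is_electron_count(self):
        q0 = np.array([1e-6])
        for el, z in (("H", 1), ("C", 6), ("N", 7), ("O", 8), ("Cl", 17)):
            assert xray_form_factor(el, q0)[0] == pytest.approx(z, abs=0.05)

    def test_weights_sum_to_one(self, template):
        w = XRayWeights.from_types(template.atom_types, template.elements)
        q = np.linspace(0.5, 25, 50)
        total = sum(w.weight(a, b, q)
                    for i, a in enumerate(w.types)
                    for b in w.types[i:])
        np.testing.assert_allclose(total, 1.0, atol=1e-12)


class TestPartialGr:
    def test_poisson_gas_gives_unit_g(self, template):
        # a pseudo-random single-type gas: use one atom per "molecule"
        rng = np.random.default_rng(0)
        n = 2000
        L = 40.0
        # single-site template stand-in via raw PairFunctionSet arithmetic is
        # not available; instead scatter whole molecules and test the C-C
        # channel at liquid-like distances where packing correlations vanish
        pos = rng.uniform(0, L, (n, 1, 3))
        from dataclasses import dataclass

        class OneSite:
            n_sites = 1
            atom_types = ["C1"]
            elements = ["C"]

        cfg = Configuration.__new__(Configuration)
        cfg.template = OneSite()
        cfg.box_length = L
        cfg.positions = pos
        pfs = partial_gr(cfg, r_max=12.0, dr=0.05)
        g = pfs.g("C1", "C1")
        sel = (pfs.r > 4) & (pfs.r < 8)
        assert abs(g[sel].mean() - 1.0) < 0.05

    def test_two_atom_hand_normalization(self):
        class OneSite:
            n_sites = 1
            atom_types = ["O1"]
            elements = ["O"]

        d = 3.13
        L = 60.0
        cfg = Configuration.__new__(Configuration)
        cfg.template = OneSite()
        cfg.box_length = L
        cfg.positions = np.array([[[10.0, 10, 10]], [[10.0 + d, 10, 10]]])
        dr = 0.05
        pfs = partial_gr(cfg, r_max=20.0, dr=dr)
        g = pfs.g("O1", "O1")
        b = int(d / dr)
        edges = (b * dr, (b + 1) * dr)
        shell = 4 * np.pi / 3 * (edges[1] ** 3 - edges[0] ** 3)
        expected = 1.0 / (1.0 * shell / L ** 3)  # one pair, one ideal pair density
        assert g[b] == pytest.approx(expected)
        assert np.count_nonzero(g) == 1

    def test_symmetry_of_channels(self, small_config):
        pfs = partial_gr(small_config, dr=0.1)
        np.testing.assert_array_equal(pfs.g("O2", "O1"), pfs.g("O1", "O2"))

    def test_r_max_beyond_half_box_raises(self, small_config):
        with pytest.raises(ValueError):
            partial_gr(small_config, r_max=small_config.box_length)


class TestFaberZiman:
    def test_uniform_g_gives_unit_s(self, template):
        # counts exactly equal to the ideal counts -> S(Q) == 1 everywhere
        r = (np.arange(200) + 0.5) * 0.05
        pfs = PairFunctionSet(r=r, dr=0.05, pair_keys=[("C1", "C1")],
                              counts=np.zeros((1, 200)),
                              n_of_type={"C1": 500}, n_atoms=500,
                              volume=40.0 ** 3)
        pfs.counts[0] = pfs.ideal_counts("C1", "C1")
        q = np.linspace(0.5, 20, 100)
        s = faber_ziman_total(pfs, _weights_single(), q)
        np.testing.assert_allclose(s.s, 1.0, atol=1e-12)

    def test_single_type_collapses_to_lone_channel(self):
        r = (np.arange(200) + 0.5) * 0.05
        counts = np.zeros((1, 200))
        counts[0, 60] = 500.0
        pfs = PairFunctionSet(r=r, dr=0.05, pair_keys=[("C1", "C1")],
                              counts=counts, n_of_type={"C1": 500},
                              n_atoms=500, volume=40.0 ** 3)
        q = np.linspace(0.5, 20, 100)
        s = faber_ziman_total(pfs, _weights_single(), q, background="none")
        d = r[60]
        expected = 1.0 + (2.0 * 500.0 / 500) * np.sin(q * d) / (q * d)
        np.testing.assert_allclose(s.s, expected, rtol=1e-12)

    def test_cluster_agrees_with_debye_oracle(self, open_cluster):
        q = np.arange(1.0, 20.0 + 1e-9, 0.05)
        s_fz = total_pattern(open_cluster, q, dr=0.02, broadening=0.0,
                             background="none")
        s_or = debye_oracle(open_cluster, q)
        assert np.abs(s_fz.s - s_or.s).max() < 0.02


class TestDebyeOracle:
    def test_homonuclear_diatomic_closed_form(self, template):
        class OneSite:
            n_sites = 1
            atom_types = ["C1"]
            elements = ["C"]

        d = 1.5
        cfg = Configuration.__new__(Configuration)
        cfg.template = OneSite()
        cfg.box_length = 100.0
        cfg.positions = np.array([[[40.0, 40, 40]], [[40.0 + d, 40, 40]]])
        q = np.linspace(0.2, 20, 200)
        s = debye_oracle(cfg, q)
        np.testing.assert_allclose(s.s, 1 + np.sin(q * d) / (q * d), atol=1e-10)

    def test_low_q_limit_of_diatomic_is_two(self):
        class OneSite:
            n_sites = 1
            atom_types = ["C1"]
            elements = ["C"]

        cfg = Configuration.__new__(Configuration)
        cfg.template = OneSite()
        cfg.box_length = 100.0
        cfg.positions = np.array([[[40.0, 40, 40]], [[41.5, 40, 40]]])
        s = debye_oracle(cfg, np.array([1e-5]))
        assert s.s[0] == pytest.approx(2.0, abs=1e-6)

    def test_single_atom_is_flat(self):
        class OneSite:
            n_sites = 1
            atom_types = ["C1"]
            elements = ["C"]

        cfg = Configuration.__new__(Configuration)
        cfg.template = OneSite()
        cfg.box_length = 50.0
        cfg.positions = np.array([[[25.0, 25, 25]]])
        s = debye_oracle(cfg, np.linspace(0.5, 20, 50))
        np.testing.assert_allclose(s.s, 1.0)


class TestTransforms:
    def test_flat_s_transforms_to_zero(self):
        q = np.arange(0.5, 25, 0.025)
        pat = ScatteringPattern(q=q, s=np.ones_like(q))
        d = dr_from_sq(pat, np.arange(0.05, 10, 0.05))
        np.testing.assert_array_equal(d, 0.0)

    def test_linearity(self):
        rng = np.random.default_rng(3)
        q = np.arange(0.5, 25, 0.05)
        s1 = 1 + 0.5 * np.exp(-(q - 2) ** 2)
        s2 = 1 + 0.3 * np.sin(q) / q
        r = np.arange(0.05, 12, 0.05)
        alpha = 0.3
        mix = ScatteringPattern(q=q, s=alpha * s1 + (1 - alpha) * s2)
        d_mix = dr_from_sq(mix, r)
        d_lin = alpha * dr_from_sq(ScatteringPattern(q=q, s=s1), r) \
            + (1 - alpha) * dr_from_sq(ScatteringPattern(q=q, s=s2), r)
        np.testing.assert_allclose(d_mix, d_lin, atol=1e-10)

    def test_gaussian_bump_gives_damped_sine(self):
        # Q[S-1] a narrow Gaussian at Q0 -> D(r) ~ damped sin(Q0 r)
        q = np.arange(0.01, 40, 0.01)
        q0, sig = 3.0, 0.05
        bump = np.exp(-0.5 * ((q - q0) / sig) ** 2)
        pat = ScatteringPattern(q=q, s=1 + bump / q)
        r = np.arange(0.5, 8, 0.01)
        d = dr_from_sq(pat, r)
        expected = (2 / np.pi) * sig * np.sqrt(2 * np.pi) * np.sin(q0 * r) \
            * np.exp(-0.5 * (sig * r) ** 2)
        np.testing.assert_allclose(d, expected, atol=0.02 * np.abs(expected).max())

    def test_round_trip_preserves_first_peak(self, small_config):
        q = np.arange(0.5, 25.0 + 1e-9, 0.025)
        pat = total_pattern(small_config, q, dr=0.05, broadening=0.05)
        r = np.arange(0.025, 8, 0.05)
        d = dr_from_sq(pat, r, window="lorch")
        sel = (r > 0.8) & (r < 1.8)
        peak_r = r[sel][np.argmax(d[sel])]
        assert abs(peak_r - 1.380) <= 0.05

    def test_gr_conversion(self):
        r = np.arange(0.5, 10, 0.1)
        d = np.zeros_like(r)
        np.testing.assert_allclose(gr_from_dr(d, r, 0.09), 1.0)


class TestRunningCoordination:
    def test_ideal_gas_closed_form(self):
        r = (np.arange(400) + 0.5) * 0.05
        pfs = PairFunctionSet(r=r, dr=0.05, pair_keys=[("C1", "C1")],
                              counts=np.zeros((1, 400)),
                              n_of_type={"C1": 1000}, n_atoms=1000,
                              volume=50.0 ** 3)
        pfs.counts[0] = pfs.ideal_counts("C1", "C1")
        rho = 1000 / 50.0 ** 3
        for rr in (3.0, 6.0, 10.0):
            expected = 4 * np.pi / 3 * rho * rr ** 3
            assert running_coordination(pfs, "C1", "C1", rr) == \
                pytest.approx(expected, rel=1e-6)

    def test_monotone_nondecreasing(self, dimer_config):
        pfs = partial_gr(dimer_config, dr=0.05)
        vals = [running_coordination(pfs, "O2", "O1", rr)
                for rr in np.arange(0.5, 10, 0.25)]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_dimer_fixture_reaches_unity(self, dimer_config):
        pfs = partial_gr(dimer_config, dr=0.05)
        assert running_coordination(pfs, "O2", "O1", 3.2) == pytest.approx(1.0, abs=0.02)

    def test_isolated_fixture_is_zero(self, isolated_config):
        pfs = partial_gr(isolated_config, dr=0.05)
        assert running_coordination(pfs, "O2", "O1", 3.2) == 0.0

    def test_unknown_type_raises(self, dimer_config):
        pfs = partial_gr(dimer_config, dr=0.05)
        with pytest.raises(KeyError):
            running_coordination(pfs, "O2", "Zz", 3.2)
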