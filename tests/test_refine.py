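"""Monte Carlo engine: acceptance rule, sweeps, empirical potential, refine."""
import numpy as np
import pytest

from epsrlite.forcefield import KB, PairPotentialTable, total_energy
from epsrlite.refine import (Configuration, EmpiricalPotential, MoveSet, Sampler,
                             Schedule, metropolis_accept, mc_sweep, r_factor,
                             refine, update_empirical_potential)
from epsrlite.scattering import ScatteringPattern, XRayWeights
from epsrlite.synth import FixtureSpec, forward_observe, make_motif_configuration

from conftest import FIXTURE_DENSITY


def _tiny_config(seed=21, n=8):
    spec = FixtureSpec(n_molecules=n, density=FIXTURE_DENSITY,
                       composition={"isolated": 1.0}, seed=seed)
    return make_motif_configuration(spec)


class TestMetropolis:
    def test_decrease_always_accepted(self):
        for draw in (0.0, 0.5, 0.999999):
            assert metropolis_accept(-5.0, 300.0, draw)

    def test_zero_change_accepted(self):
        assert metropolis_accept(0.0, 300.0, 0.999999)

    def test_boltzmann_branch(self):
        du = KB * 300.0  # exp(-1) ~ 0.3679
        assert metropolis_accept(du, 300.0, 0.36)
        assert not metropolis_accept(du, 300.0, 0.37)

    def test_half_probability_at_kt_ln2(self, rng):
        du = KB * 300.0 * np.log(2.0)
        draws = rng.random(100_000)
        acc = np.mean([metropolis_accept(du, 300.0, d) for d in draws])
        assert acc == pytest.approx(0.5, abs=0.005)

    def test_invalid_temperature(self):
        with pytest.raises(ValueError):
            metropolis_accept(1.0, 0.0, 0.5)


class TestSweep:
    def test_zero_amplitude_moveset_changes_nothing(self, table):
        cfg = _tiny_config()
        before = cfg.positions.copy()
        ms = MoveSet(translation=0.0, rotation=0.0, group_rotation=0.0)
        _cfg, acc = mc_sweep(cfg, ms, table, rng=np.random.default_rng(0))
        np.testing.assert_allclose(cfg.positions, before, atol=1e-12)
        assert acc == 1.0

    def test_near_infinite_temperature_accepts_everything(self, table):
        cfg = _tiny_config()
        s = Sampler(cfg, table, MoveSet(translation=0.05, rotation=2.0,
                                        group_rotation=2.0),
                    temperature=1e9, rng=np.random.default_rng(1))
        acc = np.mean([s.sweep() for _ in range(5)])
        assert acc > 0.95  # only hard-floor overlaps can reject

    def test_fixed_seed_reproducible_trajectory(self, table):
        out = []
        for _ in range(2):
            cfg = _tiny_config()
            s = Sampler(cfg, table, MoveSet.flexible(),
                        rng=np.random.default_rng(42))
            for _k in range(5):
                s.sweep()
            out.append(cfg.positions.copy())
        np.testing.assert_array_equal(out[0], out[1])

    def test_incremental_energy_matches_full_recomputation(self, table):
        """Oracle equivalence: the sum of accepted incremental changes equals
        the difference of full energy recomputations."""
        cfg = _tiny_config()
        e0 = total_energy(cfg, table).total
        s = Sampler(cfg, table, MoveSet.flexible(), rng=np.random.default_rng(3))
        du_sum = 0.0
        for _ in range(40):
            m = int(s.rng.integers(cfg.n_molecules))
            subset = np.arange(41, dtype=np.int64) + m * 41
            u_old, _ = s._subset_energy(subset)
            cfg.positions[m] += s.rng.uniform(-0.2, 0.2, 3)
            u_new, dmin = s._subset_energy(subset)
            if dmin < 1.0:
                cfg.positions[m] -= 0  # keep it; floor only guards MC moves
            du_sum += u_new - u_old
        e1 = total_energy(cfg, table).total
        assert e1 - e0 == pytest.approx(du_sum, rel=1e-7, abs=1e-6)

    def test_density_never_changes(self, table):
        cfg = _tiny_config()
        rho = cfg.density
        s = Sampler(cfg, table, MoveSet.flexible(), rng=np.random.default_rng(4))
        for _ in range(10):
            s.sweep()
        assert cfg.density == rho

    def test_boltzmann_reweighting_between_temperatures(self, table):
        """Long runs at two temperatures: the mean energy at the hotter
        temperature must exceed the colder one (equilibrium consistency)."""
        means = {}
        for T in (150.0, 1200.0):
            cfg = _tiny_config(seed=33, n=6)
            s = Sampler(cfg, table, MoveSet(translation=0.15, rotation=5.0,
                                            group_rotation=5.0),
                        temperature=T, rng=np.random.default_rng(8))
            for _ in range(60):  # equilibrate
                s.sweep()
            es = []
            for _ in range(60):
                s.sweep()
                es.append(total_energy(cfg, table, tables=s.tables).total)
            means[T] = np.mean(es)
        assert means[1200.0] > means[150.0]


class TestEmpiricalPotential:
    def _weights(self, template):
        return XRayWeights.from_types(template.elements, template.elements)

    def test_no_difference_no_update(self, template):
        q = np.arange(0.5, 25, 0.05)
        s = ScatteringPattern(q=q, s=1 + 0.3 * np.sin(q) / q)
        ep = EmpiricalPotential.zeros(15.0)
        ep2 = update_empirical_potential(ep, s, s, self._weights(template), 0.05)
        np.testing.assert_array_equal(ep2.values, 0.0)

    def test_cap_respected(self, template):
        q = np.arange(0.5, 25, 0.05)
        t = ScatteringPattern(q=q, s=np.ones_like(q))
        m = ScatteringPattern(q=q, s=1 + 50 * np.exp(-(q - 2) ** 2))
        ep = EmpiricalPotential.zeros(15.0, amplitude_cap=2.0)
        for _ in range(30):
            ep = update_empirical_potential(ep, m, t, self._weights(template), 0.05)
        assert np.abs(ep.values).max() <= 2.0 + 1e-12

    def test_excess_model_peak_gives_repulsive_bump(self, template):
        """Forward-construct a Gaussian excess in g at r0 = 3 A, invert: the
        update must be positive with its maximum within +-0.2 A of r0."""
        rho = 0.05
        r0, sig = 3.0, 0.15
        q = np.arange(0.1, 30, 0.02)
        r_fine = np.arange(0.01, 15, 0.01)
        dg = np.exp(-0.5 * ((r_fine - r0) / sig) ** 2)
        integrand = r_fine ** 2 * dg
        qr = np.outer(q, r_fine)
        ds = 4 * np.pi * rho * np.trapezoid(
            integrand * np.sin(qr) / qr, r_fine, axis=1)
        t = ScatteringPattern(q=q, s=np.ones_like(q))
        m = ScatteringPattern(q=q, s=1 + ds)
        ep = EmpiricalPotential.zeros(12.0)
        ep2 = update_empirical_potential(ep, m, t, self._weights(template), rho)
        for ch in range(len(ep2.channels)):
            v = ep2.values[ch]
            if np.abs(v).max() == 0:
                continue
            peak_r = ep2.r[np.argmax(v)]
            assert abs(peak_r - r0) <= 0.2
            assert v.max() > 0

    def test_grid_mismatch_rejected(self, template):
        a = ScatteringPattern(q=np.arange(0.5, 10, 0.1), s=np.ones(95))
        b = ScatteringPattern(q=np.arange(0.5, 10, 0.05), s=np.ones(190))
        ep = EmpiricalPotential.zeros(10.0)
        with pytest.raises(ValueError):
            update_empirical_potential(ep, a, b, self._weights(
                make_motif_configuration(FixtureSpec(
                    n_molecules=1, density=0.01, seed=0)).template), 0.05)


class TestRFactor:
    def test_zero_iff_identical(self):
        q = np.arange(0.5, 20, 0.05)
        s = ScatteringPattern(q=q, s=1 + np.sin(q) / q)
        assert r_factor(s, s) == 0.0
        s2 = ScatteringPattern(q=q, s=s.s + 0.01)
        assert r_factor(s2, s) > 0.0


class TestRefine:
    def test_self_target_fit_is_immediately_tiny(self, table):
        cfg = _tiny_config(seed=55, n=16)
        q = np.arange(0.5, 25.0 + 1e-9, 0.05)
        target = forward_observe(cfg, q_grid=q, noise_sigma=0.0)
        sched = Schedule(n_equil_sweeps=20, ep_period=10, n_collect=5,
                         collect_stride=1, min_cycles=0, patience=2)
        res = refine(target, cfg, table=table, schedule=sched, seed=2)
        assert res.trace[0] < 1e-3

    def test_unphysical_target_rejected(self, table):
        cfg = _tiny_config(seed=55, n=4)
        q = np.arange(0.5, 25, 0.05)
        bad = ScatteringPattern(q=q, s=np.full_like(q, 3.0))
        with pytest.raises(ValueError, match="high Q"):
            refine(bad, cfg, table=table)

    def test_ensemble_averaging_reduces_variance(self, table):
        cfg = _tiny_config(seed=56, n=8)
        q = np.arange(0.5, 25.0 + 1e-9, 0.1)
        target = forward_observe(cfg, q_grid=q, noise_sigma=0.0)
        sched = Schedule(n_equil_sweeps=10, ep_period=10, n_collect=30,
                         collect_stride=1, min_cycles=0, patience=2,
                         pattern_stride=5)
        res = refine(target, cfg, table=table, schedule=sched, seed=3)
        assert len(res.ensemble) == 30
        from epsrlite.scattering import partial_gr

        avg_g = res.pair_functions.g("O2", "O1")
        snap = partial_gr(res.config, dr=res.pair_functions.dr,
                          include="inter", by="type").g("O2", "O1")
        # averaged histogram is smoother: smaller bin-to-bin fluctuation
        assert np.abs(np.diff(avg_g)).sum() <= np.abs(np.diff(snap)).sum() + 1e-9

    def test_box_length_constant_during_refinement(self, table):
        cfg = _tiny_config(seed=57, n=6)
        q = np.arange(0.5, 25.0 + 1e-9, 0.1)
        target = forward_observe(cfg, q_grid=q)
        sched = Schedule(n_equil_sweeps=10, ep_period=5, n_collect=3,
                         collect_stride=1, min_cycles=0, patience=2)
        res = refine(target, cfg, table=table, schedule=sched, seed=4)
        assert res.config.box_length == cfg.box_length
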