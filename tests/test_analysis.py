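"""Hydrogen-bond graphs, chain statistics, conformer angles, dipole contacts."""
import numpy as np
import pytest

from epsrlite.analysis import (HBond, HBondCriterion, HBondGraph, angle_distribution,
                               cluster_stats, dipole_contacts, find_hbonds,
                               sample_report)
from epsrlite.molecule import build_indomethacin_z, o3_n_cl_angle, rotate_group
from epsrlite.refine import Configuration
from epsrlite.synth import FixtureSpec, make_motif_configuration


def brute_force_edges(config, criterion=HBondCriterion()):
    """O(N^2) rescan of all donor-acceptor pairs, independent of find_hbonds."""
    tpl = config.template
    L = config.box_length
    donor = tpl.site_of_type(criterion.donor_type)
    out = set()
    for i in range(config.n_molecules):
        for j in range(config.n_molecules):
            if i == j:
                continue
            for t in criterion.acceptor_types:
                a = tpl.site_of_type(t)
                d = config.positions[i, donor] - config.positions[j, a]
                d -= L * np.round(d / L)
                if np.linalg.norm(d) <= criterion.distance_cutoff:
                    out.add((i, j, a))
    return out


class TestFindHbonds:
    def test_isolated_fixture_has_no_edges(self, isolated_config):
        assert find_hbonds(isolated_config).edges == []

    def test_dimer_fixture_topology(self, dimer_config):
        g = find_hbonds(dimer_config)
        # two mutual O2->O1 edges per pair, one distinct neighbor each
        assert len(g.edges) == 64
        nbrs = g.neighbor_graph()
        assert all(d == 1 for _n, d in nbrs.degree())
        for e in g.edges:
            assert e.donor_mol != e.acceptor_mol
            assert e.distance == pytest.approx(2.67, abs=0.01)

    def test_matches_brute_force_scan(self, small_config):
        g = find_hbonds(small_config)
        got = {(e.donor_mol, e.acceptor_mol, e.acceptor_site) for e in g.edges}
        assert got == brute_force_edges(small_config)

    def test_angle_filter_keeps_real_bonds(self, dimer_config):
        strict = HBondCriterion(angle_min=120.0)
        loose = find_hbonds(dimer_config)
        filtered = find_hbonds(dimer_config, strict)
        assert len(filtered.edges) <= len(loose.edges)


class TestClusterStats:
    def _graph(self, n, edges):
        return HBondGraph(n, [HBond(i, j, 0, 0, 2.7) for i, j in edges])

    def test_all_dimers(self):
        edges = []
        for k in range(32):
            edges += [(2 * k, 2 * k + 1), (2 * k + 1, 2 * k)]
        st = cluster_stats(self._graph(64, edges))
        assert st.fraction_one_neighbor == pytest.approx(100.0)
        assert st.chain_size_histogram == {2: pytest.approx(100.0)}

    def test_all_isolated(self):
        st = cluster_stats(self._graph(64, []))
        assert st.fraction_nonbonded == pytest.approx(100.0)

    def test_constructed_mixture_matches_hand_count(self):
        # 27 isolated + 12 dimers (24) + 3 open trimers (9) + 1 tetramer
        # with a bifurcated center (64 molecules total)
        edges = []
        m = 27
        for _ in range(12):
            edges += [(m, m + 1)]
            m += 2
        for _ in range(3):
            edges += [(m, m + 1), (m + 1, m + 2)]
            m += 3
        # center m+1 bonded to three neighbors
        edges += [(m, m + 1), (m + 2, m + 1), (m + 3, m + 1)]
        m += 4
        assert m == 64
        st = cluster_stats(self._graph(64, edges))
        # neighbor counts: 27 isolated; 24 dimer + 6 trimer-end + 3 leaf = 33
        # with one neighbor; 3 trimer middles + the bifurcated center = 4 multi
        assert st.fraction_nonbonded == pytest.approx(100 * 27 / 64)
        assert st.fraction_one_neighbor == pytest.approx(100 * 33 / 64)
        assert st.fraction_multi == pytest.approx(100 * 4 / 64)
        assert st.chain_size_histogram == {
            1: pytest.approx(100 * 27 / 64),
            2: pytest.approx(100 * 24 / 64),
            3: pytest.approx(100 * 9 / 64),
            4: pytest.approx(100 * 4 / 64),
        }

    def test_fractions_sum_to_100(self, small_config):
        st = cluster_stats(find_hbonds(small_config))
        assert st.fraction_nonbonded + st.fraction_one_neighbor \
            + st.fraction_multi == pytest.approx(100.0, abs=1e-9)
        assert sum(st.chain_size_histogram.values()) == pytest.approx(100.0)
        assert sum(st.bonds_per_molecule_histogram.values()) == pytest.approx(100.0)

    def test_relabeling_invariance(self):
        edges = [(0, 1), (1, 2), (4, 5)]
        st1 = cluster_stats(self._graph(8, edges))
        perm = {0: 7, 1: 3, 2: 0, 3: 1, 4: 6, 5: 2, 6: 4, 7: 5}
        st2 = cluster_stats(self._graph(8, [(perm[i], perm[j]) for i, j in edges]))
        assert st1 == st2

    def test_doubly_bonded_dimer_counts_one_neighbor(self):
        st = cluster_stats(self._graph(2, [(0, 1), (1, 0)]))
        assert st.fraction_one_neighbor == pytest.approx(100.0)


class TestAngleDistribution:
    def test_identical_conformers_give_delta(self, isolated_config):
        edges, dens = angle_distribution([isolated_config], bin_width=2.0)
        assert np.count_nonzero(dens) == 1

    def test_histogram_integrates_to_one(self, small_config):
        edges, dens = angle_distribution([small_config], bin_width=2.0)
        assert np.sum(dens * np.diff(edges)) == pytest.approx(1.0, abs=1e-9)

    def test_swept_group_matches_per_conformer_oracle(self, template):
        # rotate the benzoyl group through a range; histogram support must
        # match the per-conformer angles exactly
        g = next(gr for gr in template.rotatable_groups if gr.name == "benzoyl")
        configs = []
        angles = []
        for ang in np.linspace(-60, 60, 13):
            pos = rotate_group(template.positions, g, ang)
            angles.append(o3_n_cl_angle(template, pos))
            configs.append(Configuration(template, 50.0, pos[None] + 25.0))
        edges, dens = angle_distribution(configs, bin_width=2.0)
        support = edges[:-1][dens > 0]
        assert support.min() <= min(angles) <= support.max() + 2.0
        assert support.min() <= max(angles) <= support.max() + 2.0
        # every conformer angle falls in an occupied bin
        for a in angles:
            b = int(a // 2.0)
            assert dens[b] > 0

    def test_empty_ensemble_raises(self):
        with pytest.raises(ValueError):
            angle_distribution([])


class TestDipoleContacts:
    def _with_contact(self, template, d):
        # put molecule B's O1 at distance d from molecule A's C4
        a = template.positions + 30.0
        c4 = a[template.site_of_type("C4")]
        b = template.positions.copy()
        o1 = template.site_of_type("O1")
        b = b + (c4 + np.array([d, 0, 0]) - b[o1])
        return Configuration(template, 60.0, np.stack([a, b]))

    def test_contact_inside_cutoff_found(self, template):
        cfg = self._with_contact(template, 3.1)
        contacts, per_mol = dipole_contacts(cfg, cutoff=3.2)
        assert (0, 1, pytest.approx(3.1)) in [
            (i, j, d) for i, j, d in contacts]

    def test_contact_outside_cutoff_missed(self, template):
        cfg = self._with_contact(template, 3.1)
        contacts, _ = dipole_contacts(cfg, cutoff=3.0)
        assert not any(i == 0 and j == 1 for i, j, _d in contacts)

    def test_matches_brute_force(self, small_config):
        contacts, _ = dipole_contacts(small_config, cutoff=4.0)
        tpl = small_config.template
        L = small_config.box_length
        c4, o1 = tpl.site_of_type("C4"), tpl.site_of_type("O1")
        expected = set()
        for i in range(small_config.n_molecules):
            for j in range(small_config.n_molecules):
                if i == j:
                    continue
                d = small_config.positions[i, c4] - small_config.positions[j, o1]
                d -= L * np.round(d / L)
                if np.linalg.norm(d) <= 4.0:
                    expected.add((i, j))
        assert {(i, j) for i, j, _d in contacts} == expected


class TestSampleReport:
    def test_fixture_columns(self, dimer_config, isolated_config):
        df = sample_report({"dimers": [dimer_config], "isolated": [isolated_config]})
        assert df.loc["dimers", "n_O2_O1"] == pytest.approx(1.0, abs=0.02)
        assert df.loc["isolated", "n_O2_O1"] == 0.0
        assert df.loc["isolated", "pct_nonbonded"] == pytest.approx(100.0)
        assert df.loc["dimers", "pct_one_neighbor"] == pytest.approx(100.0)

    def test_determinism(self, small_config):
        df1 = sample_report({"a": [small_config]})
        df2 = sample_report({"a": [small_config]})
        assert df1.equals(df2)
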