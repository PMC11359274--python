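"""Hydrogen-bond networks, chain statistics, conformer angles, dipole contacts.

A hydrogen bond is defined geometrically, mirroring the use of the first
minimum of the donor-acceptor partial g(r): the carboxylic-acid donor
oxygen O2 within 3.2 A (minimum-image) of an acceptor oxygen — the acid
carbonyl O1, the amide carbonyl O3 or, optionally, the methoxy O4 — on a
different molecule.  An optional O2-H2...acceptor angle filter (> 120 deg)
is available but off by default.

Chain statistics follow the molecule-level graph: parallel edges between
two molecules (the doubly bonded carboxylic dimer) collapse to a single
neighbor relation, and "chain size" is the connected-component size.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .refine import Configuration

__all__ = [
    "HBondCriterion",
    "HBond",
    "HBondGraph",
    "ClusterStats",
    "find_hbonds",
    "cluster_stats",
    "angle_distribution",
    "dipole_contacts",
    "sample_report",
]


@dataclass(frozen=True)
class HBondCriterion:
    donor_type: str = "O2"
    acceptor_types: tuple[str, ...] = ("O1", "O3", "O4")
    distance_cutoff: float = 3.2  # A, the g_O2O1(r) first minimum
    angle_min: float | None = None  # optional O2-H2...acceptor angle floor, deg

    def __post_init__(self):
        if self.distance_cutoff <= 0:
            raise ValueError("distance_cutoff must be positive")


@dataclass(frozen=True)
class HBond:
    donor_mol: int
    acceptor_mol: int
    donor_site: int
    acceptor_site: int
    distance: float


@dataclass
class HBondGraph:
    n_molecules: int
    edges: list[HBond]

    def neighbor_graph(self) -> nx.Graph:
        """Undirected molecule-level graph with parallel edges collapsed."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n_molecules))
        for e in self.edges:
            g.add_edge(e.donor_mol, e.acceptor_mol)
        return g


@dataclass
class ClusterStats:
    fraction_nonbonded: float      # % of molecules with no neighbor
    fraction_one_neighbor: float   # % with exactly one distinct neighbor
    fraction_multi: float          # % with two or more
    chain_size_histogram: dict[int, float]        # size -> % of molecules
    bonds_per_molecule_histogram: dict[int, float]  # neighbor count -> % of molecules
    chain_size_bond_histogram: dict[int, float]   # size -> % of hydrogen bonds


def _min_image(diff: np.ndarray, L: float) -> np.ndarray:
    return diff - L * np.rint(diff / L)


def find_hbonds(config: Configuration,
                criterion: HBondCriterion = HBondCriterion()) -> HBondGraph:
    """Directed donor->acceptor hydrogen bonds under the distance criterion."""
    tpl = config.template
    L = config.box_length
    donor_site = tpl.site_of_type(criterion.donor_type)
    h_site = tpl.site_of_type("H2")
    acc_sites = [tpl.site_of_type(t) for t in criterion.acceptor_types]
    donors = config.positions[:, donor_site, :]        # (n_mol, 3)
    hs = config.positions[:, h_site, :]
    edges: list[HBond] = []
    n = config.n_molecules
    for acc_t, acc_site in zip(criterion.acceptor_types, acc_sites):
        accs = config.positions[:, acc_site, :]
        diff = _min_image(donors[:, None, :] - accs[None, :, :], L)
        dist = np.sqrt((diff ** 2).sum(axis=2))
        dist[np.arange(n), np.arange(n)] = np.inf  # same molecule
        dm, am = np.where(dist <= criterion.distance_cutoff)
        for i, j in zip(dm, am):
            if criterion.angle_min is not None:
                v1 = _min_image(hs[i] - donors[i], L)
                v2 = _min_image(accs[j] - hs[i], L)
                # angle at H2 between O2->H2 and H2->acceptor
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if 180.0 - ang < criterion.angle_min:
                    continue
            edges.append(HBond(int(i), int(j), donor_site, acc_site,
                               float(dist[i, j])))
    return HBondGraph(n_molecules=n, edges=edges)


def cluster_stats(graph: HBondGraph, n_molecules: int | None = None) -> ClusterStats:
    """Neighbor-count fractions and chain-size histograms (percent scales)."""
    if n_molecules is None:
        n_molecules = graph.n_molecules
    g = graph.neighbor_graph()
    g.add_nodes_from(range(n_molecules))
    degree = dict(g.degree())
    n0 = sum(1 for d in degree.values() if d == 0)
    n1 = sum(1 for d in degree.values() if d == 1)
    nm = n_molecules - n0 - n1
    comp_sizes = [len(c) for c in nx.connected_components(g)]
    size_hist: dict[int, float] = {}
    for s in comp_sizes:
        size_hist[s] = size_hist.get(s, 0.0) + 100.0 * s / n_molecules
    bonds_hist: dict[int, float] = {}
    for d in degree.values():
        bonds_hist[d] = bonds_hist.get(d, 0.0) + 100.0 / n_molecules
    # percent of neighbor relations (collapsed bonds) per chain size
    n_bonds = g.number_of_edges()
    bond_size_hist: dict[int, float] = {}
    if n_bonds:
        for c in nx.connected_components(g):
            e = g.subgraph(c).number_of_edges()
            if e:
                s = len(c)
                bond_size_hist[s] = bond_size_hist.get(s, 0.0) + 100.0 * e / n_bonds
    return ClusterStats(
        fraction_nonbonded=100.0 * n0 / n_molecules,
        fraction_one_neighbor=100.0 * n1 / n_molecules,
        fraction_multi=100.0 * nm / n_molecules,
        chain_size_histogram=dict(sorted(size_hist.items())),
        bonds_per_molecule_histogram=dict(sorted(bonds_hist.items())),
        chain_size_bond_histogram=dict(sorted(bond_size_hist.items())),
    )


def angle_distribution(ensemble, bin_width: float = 2.0,
                       angle_range: tuple[float, float] = (0.0, 180.0)):
    """Pooled per-molecule O3-N-Cl angle histogram, normalized to unit area.

    ``ensemble`` is an iterable of Configurations; returns (bin_edges,
    density) with density integrating to 1 over the range.
    """
    from .molecule import o3_n_cl_angle

    angles = []
    for config in ensemble:
        tpl = config.template
        for m in range(config.n_molecules):
            angles.append(o3_n_cl_angle(tpl, config.positions[m]))
    if not angles:
        raise ValueError("empty ensemble")
    nbins = int(round((angle_range[1] - angle_range[0]) / bin_width))
    density, edges = np.histogram(angles, bins=nbins, range=angle_range,
                                  density=True)
    return edges, density


def dipole_contacts(config: Configuration, cutoff: float = 3.2):
    """Intermolecular C4...O1 contacts within the cutoff (minimum image).

    Returns (list of (mol_c4, mol_o1, distance), mean contacts per molecule).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    tpl = config.template
    L = config.box_length
    c4 = config.positions[:, tpl.site_of_type("C4"), :]
    o1 = config.positions[:, tpl.site_of_type("O1"), :]
    n = config.n_molecules
    diff = _min_image(c4[:, None, :] - o1[None, :, :], L)
    dist = np.sqrt((diff ** 2).sum(axis=2))
    dist[np.arange(n), np.arange(n)] = np.inf
    im, jm = np.where(dist <= cutoff)
    contacts = [(int(i), int(j), float(dist[i, j])) for i, j in zip(im, jm)]
    return contacts, len(contacts) / n


def sample_report(ensembles: dict, criterion: HBondCriterion = HBondCriterion(),
                  coordination_r: float = 3.2):
    """Per-sample comparison table over refined (or synthetic) ensembles.

    ``ensembles`` maps a sample name to an object with ``pair_functions``
    (type-level PairFunctionSet), ``pattern`` (ScatteringPattern) and
    ``ensemble_configurations()`` — a RefineResult qualifies — or to a plain
    list of Configurations.  Returns a pandas DataFrame with per-sample
    n_O2-O1(r), n_O2-O3(r), cluster fractions, FSDP position/height and the
    mean O3-N-Cl angle.
    """
    import pandas as pd

    from .molecule import o3_n_cl_angle
    from .scattering import fsdp, partial_gr, running_coordination, total_pattern

    rows = []
    for name, res in ensembles.items():
        if isinstance(res, (list, tuple)):
            configs = list(res)
            counts = None
            for c in configs:
                p = partial_gr(c, dr=0.05, include="inter", by="type")
                counts = p.counts if counts is None else counts + p.counts
            pfs = p
            pfs.counts = counts / len(configs)
            pattern = total_pattern(configs[-1],
                                    np.arange(0.5, 25.0 + 1e-9, 0.025))
        else:
            configs = res.ensemble_configurations()
            pfs = res.pair_functions
            pattern = res.pattern
        stats = None
        angles = []
        agg = np.zeros(3)
        for c in configs:
            st = cluster_stats(find_hbonds(c, criterion))
            agg += [st.fraction_nonbonded, st.fraction_one_neighbor,
                    st.fraction_multi]
            for m in range(c.n_molecules):
                angles.append(o3_n_cl_angle(c.template, c.positions[m]))
        agg /= len(configs)
        q_pos, q_height = fsdp(pattern)
        rows.append({
            "sample": name,
            "n_O2_O1": running_coordination(pfs, "O2", "O1", coordination_r),
            "n_O2_O3": running_coordination(pfs, "O2", "O3", coordination_r),
            "pct_nonbonded": agg[0],
            "pct_one_neighbor": agg[1],
            "pct_multi": agg[2],
            "fsdp_q": q_pos,
            "fsdp_height": q_height,
            "mean_o3_n_cl_angle": float(np.mean(angles)),
        })
    return pd.DataFrame(rows).set_index("sample")
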