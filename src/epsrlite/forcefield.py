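"""Reference interaction potentials for the refinement.

The intermolecular reference potential is a per-type Lennard-Jones +
Coulomb model with Lorentz-Berthelot mixing, a soft half-harmonic
minimum-distance constraint on intermolecular oxygen-oxygen contacts
(default 2.6 A), and an optional tabulated empirical-potential
perturbation.  Intramolecular geometry is held by harmonic bond terms;
intramolecular LJ/Coulomb pairs are excluded (the molecules move as
semi-rigid bodies, so conformers never sample the excluded interactions).

The published charge set is deliberately unbalanced: the acceptor oxygens,
carbonyl carbons and the acid donor hydrogen carry
(-0.6) + (-0.6) + (-0.4) + 0.7 + 0.7 + 0.8 = +0.6 e net per molecule.
It is kept verbatim; ``neutralize=True`` spreads the compensating charge
uniformly over all sites instead (off by default).

Two sites the published table does not parameterize (the ring nitrogen and
the methoxy oxygen) are given oxygen-like LJ parameters and zero charge.

The Coulomb constant is k_C = 1389.3545764438293 kJ mol^-1 A e^-2.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import COULOMB_K, energy_subset, energy_total
from .molecule import MoleculeTemplate

__all__ = [
    "KB",
    "COULOMB_K",
    "PairPotentialTable",
    "SoftConstraint",
    "EnergyBreakdown",
    "reference_pair_energy",
    "constraint_energy",
    "total_energy",
    "PairTables",
]

KB = 0.00831446261815324  # kJ mol^-1 K^-1

# epsilon (kJ/mol), sigma (A), partial charge (e)
_DEFAULT_PARAMS: dict[str, tuple[float, float, float]] = {
    "O1": (0.65, 3.1, -0.6),
    "O2": (0.65, 3.1, -0.6),
    "O3": (0.65, 3.1, -0.4),
    "C4": (0.8, 3.7, 0.7),
    "C8": (0.8, 3.7, 0.7),
    "H2": (0.0, 0.0, 0.8),
    "H1": (0.0, 0.0, 0.0),
    "C1": (0.8, 3.7, 0.0),
    "C2": (0.8, 3.7, 0.0),
    "C3": (0.8, 3.7, 0.0),
    "C5": (0.8, 3.7, 0.0),
    "C6": (0.8, 3.7, 0.0),
    "C7": (0.8, 3.7, 0.0),
    "C9": (0.8, 3.7, 0.0),
    "C10": (0.8, 3.7, 0.0),
    "Cl": (0.8, 3.2, 0.0),
    # untyped in the published table; oxygen-like LJ, zero charge
    "N": (0.65, 3.1, 0.0),
    "O4": (0.65, 3.1, 0.0),
}


@dataclass(frozen=True)
class SoftConstraint:
    """Half-harmonic intermolecular O-O minimum-distance penalty."""

    min_distance: float = 2.6  # A
    stiffness: float = 1000.0  # kJ mol^-1 A^-2


@dataclass(frozen=True)
class EnergyBreakdown:
    lj: float
    coulomb: float
    intramolecular: float
    constraint: float
    empirical: float

    @property
    def total(self) -> float:
        return self.lj + self.coulomb + self.intramolecular + self.constraint + self.empirical


class PairPotentialTable:
    """Per-atom-type LJ parameters and partial charges."""

    def __init__(self, params: dict[str, tuple[float, float, float]] | None = None,
                 neutralize: bool = False):
        self.params = dict(_DEFAULT_PARAMS if params is None else params)
        self.neutralize = neutralize

    def lookup(self, atom_type: str) -> tuple[float, float, float]:
        try:
            return self.params[atom_type]
        except KeyError:
            raise KeyError(f"no force-field parameters for atom type {atom_type!r}") from None

    def charge(self, atom_type: str, template: MoleculeTemplate | None = None) -> float:
        q = self.lookup(atom_type)[2]
        if self.neutralize and template is not None:
            q -= self.molecular_charge(template) / template.n_sites
        return q

    def molecular_charge(self, template: MoleculeTemplate) -> float:
        """Net charge of one molecule under the raw (printed) charge set."""
        return float(sum(self.lookup(t)[2] for t in template.atom_types))

    @classmethod
    def from_toml(cls, path, neutralize: bool = False) -> "PairPotentialTable":
        """Read a ``[forcefield]`` table; unknown atom types are rejected."""
        import tomllib

        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        block = doc.get("forcefield", doc)
        params = {}
        for key, val in block.items():
            if key not in _DEFAULT_PARAMS:
                raise KeyError(f"unknown atom type in force-field table: {key!r}")
            eps, sigma, q = float(val["epsilon"]), float(val["sigma"]), float(val["charge"])
            params[key] = (eps, sigma, q)
        for key in _DEFAULT_PARAMS:
            params.setdefault(key, _DEFAULT_PARAMS[key])
        return cls(params, neutralize=neutralize)


def reference_pair_energy(table: PairPotentialTable, type_a: str, type_b: str,
                          r: float) -> float:
    """LJ + bare Coulomb energy of one pair at separation r (no cutoff shifts).

    Lorentz-Berthelot mixing: arithmetic-mean sigma, geometric-mean epsilon.
    """
    if r <= 0:
        raise ValueError("pair separation must be positive")
    ea, sa, qa = table.lookup(type_a)
    eb, sb, qb = table.lookup(type_b)
    eps = np.sqrt(ea * eb)
    sig = 0.5 * (sa + sb)
    lj = 0.0
    if eps > 0:
        sr6 = (sig / r) ** 6
        lj = 4.0 * eps * (sr6 * sr6 - sr6)
    return float(lj + COULOMB_K * qa * qb / r)


def constraint_energy(r: float, constraint: SoftConstraint = SoftConstraint()) -> float:
    """Soft O-O penalty: zero at and beyond the minimum distance, half-harmonic below."""
    if r <= 0:
        raise ValueError("pair separation must be positive")
    if r >= constraint.min_distance:
        return 0.0
    d = constraint.min_distance - r
    return 0.5 * constraint.stiffness * d * d


class PairTables:
    """Precomputed per-type-pair parameter matrices for the numba kernels."""

    def __init__(self, table: PairPotentialTable, template: MoleculeTemplate,
                 cutoff: float, constraint: SoftConstraint = SoftConstraint(),
                 ep_channels: list[tuple[str, str]] | None = None):
        types = sorted(set(template.atom_types))
        self.type_index = {t: i for i, t in enumerate(types)}
        self.types = types
        nt = len(types)
        eps = np.zeros((nt, nt))
        sig = np.zeros((nt, nt))
        qq = np.zeros((nt, nt))
        elem = {t: next(s.element for s in template.sites if s.atom_type == t) for t in types}
        for a in types:
            ea, sa, qa = table.lookup(a)
            qa = table.charge(a, template)
            for b in types:
                eb, sb, qb = table.lookup(b)
                qb = table.charge(b, template)
                i, j = self.type_index[a], self.type_index[b]
                eps[i, j] = np.sqrt(ea * eb)
                sig[i, j] = 0.5 * (sa + sb)
                qq[i, j] = qa * qb
        self.cutoff = float(cutoff)
        sr6 = np.zeros_like(sig)
        mask = eps > 0
        sr6[mask] = (sig[mask] / self.cutoff) ** 6
        self.ljshift = 4.0 * eps * (sr6 ** 2 - sr6)
        self.eps, self.sig, self.qq = eps, sig, qq
        self.oo = np.array(
            [[elem[a] == "O" and elem[b] == "O" for b in types] for a in types],
            dtype=np.bool_,
        )
        self.constraint = constraint
        # empirical-potential channels: unordered heavy-element pairs
        if ep_channels is None:
            heavy = ["C", "N", "O", "Cl"]
            ep_channels = [(heavy[i], heavy[j]) for i in range(len(heavy))
                           for j in range(i, len(heavy))]
        self.ep_channels = ep_channels
        chan_of = {frozenset(p): k for k, p in enumerate(ep_channels)}
        self.chan = np.full((nt, nt), -1, dtype=np.int64)
        for a in types:
            for b in types:
                key = frozenset((elem[a], elem[b]))
                if key in chan_of:
                    self.chan[self.type_index[a], self.type_index[b]] = chan_of[key]

    def type_codes(self, atom_types: list[str]) -> np.ndarray:
        return np.array([self.type_index[t] for t in atom_types], dtype=np.int64)


_EMPTY_EP = np.zeros((1, 0))


def total_energy(config, table: PairPotentialTable, ep=None,
                 constraint: SoftConstraint = SoftConstraint(),
                 tables: PairTables | None = None,
                 cutoff: float | None = None) -> EnergyBreakdown:
    """Total potential energy of a configuration.

    Sums shifted LJ and shifted-force Coulomb terms over all atom pairs on
    distinct molecules within the cutoff (half the box length by default),
    harmonic intramolecular bond terms, the soft O-O constraint, and (when
    given) the empirical potential.  Raises on overlapping atoms (r < 0.1 A).
    """
    L = config.box_length
    rc = L / 2.0 if cutoff is None else min(cutoff, L / 2.0)
    if tables is None:
        tables = PairTables(table, config.template, rc, constraint)
    pos = config.flat_positions()
    codes = tables.type_codes(config.template.atom_types * config.n_molecules)
    mol_ids = config.mol_ids()
    if ep is None:
        ep_table, ep_dr = _EMPTY_EP, 1.0
    else:
        ep_table, ep_dr = ep.values, ep.dr
    lj, coul, cons, epe, dmin, imin, jmin = energy_total(
        pos, codes, mol_ids, L, rc, tables.eps, tables.sig, tables.qq,
        tables.ljshift, tables.oo, constraint.min_distance, constraint.stiffness,
        tables.chan, ep_table, ep_dr)
    if dmin < 0.1:
        raise ValueError(
            f"overlapping atoms: flat indices {imin} and {jmin} at r = {dmin:.4f} A")
    intra = 0.0
    for m in range(config.n_molecules):
        p = config.positions[m]
        for i, j, b0, k in config.template.bonds:
            b = np.linalg.norm(p[i] - p[j])
            intra += 0.5 * k * (b - b0) ** 2
    return EnergyBreakdown(lj=float(lj), coulomb=float(coul), intramolecular=float(intra),
                           constraint=float(cons), empirical=float(epe))
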