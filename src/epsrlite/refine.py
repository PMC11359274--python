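"""Metropolis Monte Carlo with iterative empirical-potential refinement.

The model is an NVT-style ensemble of semi-rigid molecules in a cubic
periodic box.  Moves are molecular translations, rigid rotations and
internal group rotations; each is accepted by the Metropolis rule on the
incremental intermolecular energy change.  Between blocks of sweeps the
model structure factor is compared with the target pattern and an r-space
perturbation ("empirical potential") is accumulated on heavy-element pair
channels: the sine back-transform of the data-model S(Q) difference,
converted to a pair-distribution correction and applied with the sign
convention that an excess model peak in g(r) at r0 produces a repulsive
bump near r0.  Once the goodness of fit plateaus the potential is frozen
and structural data are collected over an ensemble of configurations.

The goodness-of-fit metric is this package's own definition,
R = sum[S_model - S_target]^2 / sum[S_target - 1]^2 on the shared Q grid.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ._kernels import energy_subset
from .forcefield import KB, PairPotentialTable, PairTables, SoftConstraint
from .molecule import MoleculeTemplate, rotate_group
from .scattering import (PairFunctionSet, ScatteringPattern, XRayWeights,
                         dr_from_sq, partial_gr, total_pattern)

__all__ = [
    "Configuration",
    "MoveSet",
    "EmpiricalPotential",
    "Schedule",
    "RefineResult",
    "RefinementDiverged",
    "metropolis_accept",
    "mc_sweep",
    "update_empirical_potential",
    "r_factor",
    "refine",
]

HARD_FLOOR = 1.0  # A; any intermolecular contact below this auto-rejects a move


class RefinementDiverged(RuntimeError):
    """The fit metric kept increasing past the configured patience."""


@dataclass
class Configuration:
    """Periodic cubic box of molecule instances.

    ``positions`` has shape (n_molecules, n_sites, 3); molecules are stored
    contiguously (atoms of a molecule are never wrapped apart — the molecular
    center is kept in the box and minimum-image distances take care of the
    rest; :meth:`wrapped_positions` gives a per-atom wrapped view for export).
    """

    template: MoleculeTemplate
    box_length: float
    positions: np.ndarray
    rng_seed: int | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[1] != self.template.n_sites:
            raise ValueError("positions must be (n_molecules, n_sites, 3)")

    @property
    def n_molecules(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0] * self.positions.shape[1]

    @property
    def density(self) -> float:
        """Atomic number density, atoms per A^3."""
        return self.n_atoms / self.box_length ** 3

    @staticmethod
    def box_length_for(n_molecules: int, n_sites: int, density: float) -> float:
        return (n_molecules * n_sites / density) ** (1.0 / 3.0)

    def flat_positions(self) -> np.ndarray:
        return self.positions.reshape(-1, 3)

    def mol_ids(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_molecules), self.template.n_sites)

    def wrapped_positions(self) -> np.ndarray:
        return np.mod(self.flat_positions(), self.box_length)

    def copy(self) -> "Configuration":
        return Configuration(self.template, self.box_length,
                             self.positions.copy(), self.rng_seed)


@dataclass
class MoveSet:
    """Move amplitudes (A / degrees) and per-move-type attempt weights."""

    translation: float = 0.3
    rotation: float = 10.0
    group_rotation: float = 10.0
    weights: tuple[float, float, float] = (0.4, 0.3, 0.3)

    def __post_init__(self):
        if self.translation < 0 or self.rotation < 0 or self.group_rotation < 0:
            raise ValueError("move amplitudes must be non-negative")
        if any(w < 0 for w in self.weights) or sum(self.weights) <= 0:
            raise ValueError("weights must be non-negative and not all zero")

    @classmethod
    def flexible(cls) -> "MoveSet":
        return cls()

    @classmethod
    def rigid(cls, slight_variation: float = 2.0) -> "MoveSet":
        """Rigid-molecule moves: group rotations off (or a few degrees only)."""
        if slight_variation <= 0:
            return cls(group_rotation=0.0, weights=(0.5, 0.5, 0.0))
        return cls(group_rotation=slight_variation, weights=(0.45, 0.35, 0.2))


@dataclass
class EmpiricalPotential:
    """Tabulated r-space energy perturbation per heavy-element pair channel."""

    r: np.ndarray
    dr: float
    channels: list[tuple[str, str]]
    values: np.ndarray  # (n_channels, len(r)), kJ/mol
    amplitude_cap: float = 2.0  # kJ/mol
    update_rate: float = 0.1

    HEAVY = ("C", "Cl", "N", "O")

    @classmethod
    def zeros(cls, r_max: float, dr: float = 0.05,
              amplitude_cap: float = 2.0, update_rate: float = 0.1) -> "EmpiricalPotential":
        heavy = cls.HEAVY
        channels = [(heavy[i], heavy[j]) for i in range(len(heavy))
                    for j in range(i, len(heavy))]
        nr = int(round(r_max / dr)) + 1
        r = np.arange(nr) * dr
        return cls(r=r, dr=dr, channels=channels,
                   values=np.zeros((len(channels), nr)),
                   amplitude_cap=amplitude_cap, update_rate=update_rate)

    def channel(self, a: str, b: str) -> int:
        key = frozenset((a, b))
        for i, p in enumerate(self.channels):
            if frozenset(p) == key:
                return i
        raise KeyError(f"no empirical-potential channel ({a}, {b})")


def metropolis_accept(delta_u: float, temperature: float, uniform_draw: float) -> bool:
    """Accept iff the energy decreases, or with Boltzmann probability if not."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_u <= 0:
        return True
    return uniform_draw < math.exp(-delta_u / (KB * temperature))


def r_factor(s_model: ScatteringPattern, s_target: ScatteringPattern) -> float:
    """Goodness of fit sum[S_model - S_target]^2 / sum[S_target - 1]^2."""
    s_model.require_same_grid(s_target)
    denom = float(np.sum((s_target.s - 1.0) ** 2))
    if denom == 0:
        return float(np.sum((s_model.s - s_target.s) ** 2))
    return float(np.sum((s_model.s - s_target.s) ** 2) / denom)


class Sampler:
    """Mutable Monte Carlo state over a configuration (internal helper).

    Holds the precomputed pair tables and per-atom code arrays so single-
    molecule moves only recompute the moved atoms' interactions.
    """

    def __init__(self, config: Configuration, table: PairPotentialTable,
                 moveset: MoveSet, temperature: float = 300.0,
                 ep: EmpiricalPotential | None = None,
                 constraint: SoftConstraint = SoftConstraint(),
                 rng: np.random.Generator | None = None):
        self.config = config
        self.table = table
        self.moveset = moveset
        self.temperature = temperature
        self.constraint = constraint
        self.rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
        L = config.box_length
        self.cutoff = L / 2.0
        self.tables = PairTables(table, config.template, self.cutoff, constraint)
        self.codes = self.tables.type_codes(
            config.template.atom_types * config.n_molecules)
        self._mol_ids = config.mol_ids()
        self.ep = ep
        self.n_attempted = 0
        self.n_accepted = 0
        self.n_overlap_rejected = 0

    # -- energy of a subset of one molecule's atoms against all others ----
    def _subset_energy(self, subset: np.ndarray) -> tuple[float, float]:
        if self.ep is None:
            ep_table, ep_dr = np.zeros((1, 0)), 1.0
        else:
            ep_table, ep_dr = self.ep.values, self.ep.dr
        lj, coul, cons, epe, dmin = energy_subset(
            self.config.flat_positions(), self.codes, self._mol_ids, subset,
            self.config.box_length, self.cutoff,
            self.tables.eps, self.tables.sig, self.tables.qq, self.tables.ljshift,
            self.tables.oo, self.constraint.min_distance, self.constraint.stiffness,
            self.tables.chan, ep_table, ep_dr)
        return lj + coul + cons + epe, dmin

    def _attempt(self, m: int) -> None:
        cfg = self.config
        ns = cfg.template.n_sites
        kind = self.rng.choice(3, p=self._wnorm)
        groups = cfg.template.rotatable_groups
        if kind == 2 and not groups:
            kind = 0
        old = cfg.positions[m].copy()
        if kind == 2:
            g = groups[self.rng.integers(len(groups))]
            amp = min(self.moveset.group_rotation, g.max_amplitude)
            subset_local = np.asarray(g.moved_sites, dtype=np.int64)
        else:
            subset_local = np.arange(ns, dtype=np.int64)
        subset = subset_local + m * ns
        self.n_attempted += 1
        u_old, _ = self._subset_energy(subset)
        if kind == 0:
            disp = self.rng.uniform(-self.moveset.translation,
                                    self.moveset.translation, 3)
            cfg.positions[m] += disp
        elif kind == 1:
            axis = self.rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            ang = np.deg2rad(self.rng.uniform(-self.moveset.rotation,
                                              self.moveset.rotation))
            center = cfg.positions[m].mean(axis=0)
            v = cfg.positions[m] - center
            c, s = np.cos(ang), np.sin(ang)
            cfg.positions[m] = center + (v * c + np.cross(axis, v) * s
                                         + np.outer(v @ axis, axis) * (1 - c))
        else:
            ang = self.rng.uniform(-amp, amp)
            cfg.positions[m] = rotate_group(cfg.positions[m], g, ang)
        u_new, dmin = self._subset_energy(subset)
        if dmin < HARD_FLOOR:
            cfg.positions[m] = old
            self.n_overlap_rejected += 1
            return
        if metropolis_accept(u_new - u_old, self.temperature, self.rng.random()):
            self.n_accepted += 1
            # keep the molecular center inside the box
            center = cfg.positions[m].mean(axis=0)
            shift = np.floor(center / cfg.box_length) * cfg.box_length
            if np.any(shift):
                cfg.positions[m] -= shift
        else:
            cfg.positions[m] = old

    @property
    def _wnorm(self):
        w = np.asarray(self.moveset.weights, dtype=float)
        return w / w.sum()

    def sweep(self) -> float:
        """One attempted move per molecule on average; returns the sweep
        acceptance ratio (overlap auto-rejections count as rejections)."""
        a0, t0 = self.n_accepted, self.n_attempted
        for _ in range(self.config.n_molecules):
            m = int(self.rng.integers(self.config.n_molecules))
            self._attempt(m)
        return (self.n_accepted - a0) / max(self.n_attempted - t0, 1)

    def autotune(self, acceptance: float, lo: float = 0.3, hi: float = 0.5) -> None:
        """Nudge move amplitudes toward the target acceptance window."""
        if acceptance > hi:
            f = 1.05
        elif acceptance < lo:
            f = 0.95
        else:
            return
        ms = self.moveset

        def scaled(v, lo, hi):
            return float(np.clip(v * f, lo, hi)) if v > 0 else v

        self.moveset = replace(
            ms,
            translation=scaled(ms.translation, 0.01, 1.5),
            rotation=scaled(ms.rotation, 0.2, 45.0),
            group_rotation=scaled(ms.group_rotation, 0.2, 60.0),
        )


def mc_sweep(config: Configuration, moveset: MoveSet, table: PairPotentialTable,
             ep: EmpiricalPotential | None = None, temperature: float = 300.0,
             rng: np.random.Generator | None = None,
             sampler: Sampler | None = None) -> tuple[Configuration, float]:
    """Run one Monte Carlo sweep; returns (updated config, acceptance ratio).

    A convenience wrapper over :class:`Sampler` for one-off sweeps; the
    configuration is modified in place and also returned.
    """
    if sampler is None:
        sampler = Sampler(config, table, moveset, temperature, ep, rng=rng)
    acc = sampler.sweep()
    return sampler.config, acc


def update_empirical_potential(ep: EmpiricalPotential, s_model: ScatteringPattern,
                               s_target: ScatteringPattern, weights: XRayWeights,
                               rho: float, temperature: float = 300.0) -> EmpiricalPotential:
    """One empirical-potential refinement step from the data-model difference.

    The S(Q) difference is sine-transformed (Lorch windowed) to a D(r)-scale
    difference and converted to a g(r)-scale correction; every heavy-element
    channel present in ``weights`` receives the full
    ``update_rate * kB * T`` bump of that shared profile, and the reference
    potential decides which channels can respond (an excess model peak in g
    at r0 produces a repulsive bump near r0).  Scaling minority channels
    down by their Faber-Ziman weight instead leaves the perturbation unable
    to move weakly weighted partials at all — the X-ray pattern constrains
    the aggregate, not the decomposition.  Values are clipped to the cap.
    """
    s_model.require_same_grid(s_target)
    delta = ScatteringPattern(q=s_model.q, s=1.0 + (s_model.s - s_target.s))
    d_of_r = dr_from_sq(delta, ep.r, window="lorch")
    with np.errstate(invalid="ignore", divide="ignore"):
        dg = np.where(ep.r > 1e-9, d_of_r / (4.0 * np.pi * rho * ep.r), 0.0)
    known = set(weights.types)
    active = np.array([1.0 if {a, b} <= known else 0.0 for a, b in ep.channels])
    if active.max() <= 0:
        return ep
    bump = ep.update_rate * KB * temperature * dg
    new_values = ep.values + np.outer(active, bump)
    new_values = np.clip(new_values, -ep.amplitude_cap, ep.amplitude_cap)
    return replace(ep, values=new_values)


@dataclass
class Schedule:
    """Refinement schedule (desk-scale defaults; the full-scale ensemble of
    >= 10000 configurations is reached by raising ``n_collect``)."""

    n_equil_sweeps: int = 2000
    ep_period: int = 50
    n_collect: int = 500
    collect_stride: int = 2
    temperature: float = 300.0
    plateau_tol: float = 0.02
    patience: int = 5
    min_cycles: int = 5
    autotune: bool = True
    pattern_stride: int = 10
    ep_cap: float = 2.0
    ep_rate: float = 0.1
    sq_dr: float = 0.05
    broadening: float = 0.05


@dataclass
class RefineResult:
    config: Configuration
    ensemble: list[np.ndarray]            # collected per-molecule positions
    pair_functions: PairFunctionSet       # ensemble-averaged, type channels
    pattern: ScatteringPattern            # ensemble-averaged model S(Q)
    trace: list[float]                    # FitMetric per refinement cycle
    ep: EmpiricalPotential
    acceptance: float

    def ensemble_configurations(self):
        tpl = self.config.template
        L = self.config.box_length
        return [Configuration(tpl, L, p) for p in self.ensemble]


def refine(target: ScatteringPattern, config0: Configuration,
           table: PairPotentialTable | None = None,
           moveset: MoveSet | None = None,
           schedule: Schedule | None = None,
           constraint: SoftConstraint = SoftConstraint(),
           seed: int | None = None) -> RefineResult:
    """Refine a configuration against a target S(Q) and collect an ensemble.

    Alternates Monte Carlo sweep blocks with empirical-potential updates
    until the fit metric plateaus (or the equilibration budget is spent),
    then freezes the potential and move amplitudes and collects the
    requested number of configurations.  Fully seeded and deterministic.
    """
    # the target must look like a physical interference function
    hi = target.s[target.q >= 0.9 * target.q[-1]]
    if hi.size and abs(float(np.mean(hi)) - 1.0) > 0.2:
        raise ValueError("target S(Q) does not approach 1 at high Q")
    if table is None:
        table = PairPotentialTable()
    if moveset is None:
        moveset = MoveSet.flexible()
    if schedule is None:
        schedule = Schedule()
    config = config0.copy()
    if seed is None:
        seed = config0.rng_seed if config0.rng_seed is not None else 0
    rng = np.random.default_rng(seed)
    weights = XRayWeights.from_types(config.template.elements,
                                     config.template.elements)
    ep = EmpiricalPotential.zeros(r_max=config.box_length / 2.0, dr=schedule.sq_dr,
                                  amplitude_cap=schedule.ep_cap,
                                  update_rate=schedule.ep_rate)
    sampler = Sampler(config, table, moveset, schedule.temperature, ep,
                      constraint, rng)

    def model_pattern() -> ScatteringPattern:
        return total_pattern(config, target.q, dr=schedule.sq_dr,
                             broadening=schedule.broadening)

    trace: list[float] = []
    n_cycles = max(schedule.n_equil_sweeps // schedule.ep_period, 1)
    rho = config.density
    for cycle in range(n_cycles + 1):
        s_model = model_pattern()
        r = r_factor(s_model, target)
        trace.append(r)
        if len(trace) > schedule.patience and cycle >= schedule.min_cycles:
            recent = min(trace[-schedule.patience:])
            earlier = min(trace[:-schedule.patience])
            if recent >= (1.0 - schedule.plateau_tol) * earlier:
                break
            if all(trace[-k - 1] > trace[-k - 2] for k in range(schedule.patience - 1)) \
                    and recent > 5.0 * min(trace):
                raise RefinementDiverged(
                    f"fit metric rose for {schedule.patience} cycles "
                    f"(R = {r:.4g}, best {min(trace):.4g})")
        if cycle == n_cycles:
            break
        sampler.ep = update_empirical_potential(
            ep, s_model, target, weights, rho, schedule.temperature)
        ep = sampler.ep
        for _ in range(schedule.ep_period):
            acc = sampler.sweep()
            if schedule.autotune:
                sampler.autotune(acc)

    # ---- collection with frozen potential and amplitudes ----------------
    type_pfs_counts = None
    s_accum = None
    n_patterns = 0
    ensemble: list[np.ndarray] = []
    for k in range(schedule.n_collect):
        for _ in range(schedule.collect_stride):
            sampler.sweep()
        ensemble.append(config.positions.copy())
        pfs_k = partial_gr(config, dr=schedule.sq_dr, include="inter", by="type")
        if type_pfs_counts is None:
            pfs_proto = pfs_k
            type_pfs_counts = pfs_k.counts.astype(float)
        else:
            type_pfs_counts += pfs_k.counts
        if k % schedule.pattern_stride == 0:
            s_k = model_pattern()
            s_accum = s_k.s.copy() if s_accum is None else s_accum + s_k.s
            n_patterns += 1
    avg_pfs = PairFunctionSet(
        r=pfs_proto.r, dr=pfs_proto.dr, pair_keys=pfs_proto.pair_keys,
        counts=type_pfs_counts / len(ensemble), n_of_type=pfs_proto.n_of_type,
        n_atoms=pfs_proto.n_atoms, volume=pfs_proto.volume, kind="inter")
    avg_pattern = ScatteringPattern(q=target.q, s=s_accum / n_patterns)
    acceptance = sampler.n_accepted / max(sampler.n_attempted, 1)
    return RefineResult(config=config, ensemble=ensemble, pair_functions=avg_pfs,
                        pattern=avg_pattern, trace=trace, ep=ep,
                        acceptance=acceptance)
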