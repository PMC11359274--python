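"""Semi-rigid molecular template for the indomethacin Z isomer.

The template carries an idealized Z-isomer geometry (41 atoms, C19H16ClNO4)
with per-site atom types used throughout the scattering and hydrogen-bond
analysis: O1 (acid carbonyl acceptor), O2 (acid hydroxyl donor), O3 (amide
carbonyl acceptor), O4 (methoxy), C1..C10 carbon classes, N, Cl, H1 (carbon-
bound hydrogens) and H2 (the acid donor hydrogen).  Geometry is held by
harmonic bond terms; conformational freedom enters only through five
rotatable groups linking the indole, benzoyl, methoxy and carboxylic-acid
units (including the chlorobenzyl ring spin).

The only experimentally pinned geometric quantity is the mean C-X bond
length (X = C, N, O) of 1.380 A in the reference crystal; ``bond_expansion``
lengthens the molecule uniformly so the mean C-X bond is 1.380 + expansion.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _geometry

__all__ = [
    "AtomSite",
    "RotatableGroup",
    "MoleculeTemplate",
    "MoveRejected",
    "build_indomethacin_z",
    "rotate_group",
    "o3_n_cl_angle",
]

FORMULA = "C19H16ClNO4"
REFERENCE_MEAN_CX = 1.380  # A, gamma-form crystal value
DEFAULT_BOND_K = 2500.0  # kJ mol^-1 A^-2, harmonic bond stiffness


class MoveRejected(Exception):
    """A conformational move violated an amplitude restriction."""


@dataclass(frozen=True)
class AtomSite:
    site_id: int
    atom_type: str
    element: str
    reference_position: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "reference_position", np.asarray(self.reference_position, dtype=float)
        )


@dataclass(frozen=True)
class RotatableGroup:
    """A rigid internal rotation about the axis through two bonded sites."""

    name: str
    axis: tuple[int, int]
    moved_sites: tuple[int, ...]
    max_amplitude: float = 180.0  # degrees

    def __post_init__(self):
        if set(self.axis) & set(self.moved_sites):
            raise ValueError(f"group {self.name}: moved set must exclude axis sites")


@dataclass(frozen=True)
class MoleculeTemplate:
    sites: tuple[AtomSite, ...]
    bonds: tuple[tuple[int, int, float, float], ...]  # (i, j, b0 A, k kJ/mol/A^2)
    rotatable_groups: tuple[RotatableGroup, ...]
    bond_expansion: float = 0.0

    # ---- derived views -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def atom_types(self) -> list[str]:
        return [s.atom_type for s in self.sites]

    @property
    def elements(self) -> list[str]:
        return [s.element for s in self.sites]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.reference_position for s in self.sites])

    def site_of_type(self, atom_type: str) -> int:
        """Index of the unique site with the given type."""
        idx = [s.site_id for s in self.sites if s.atom_type == atom_type]
        if len(idx) != 1:
            raise ValueError(f"type {atom_type!r} matches {len(idx)} sites, expected 1")
        return idx[0]

    def sites_of_element(self, element: str) -> list[int]:
        return [s.site_id for s in self.sites if s.element == element]

    @property
    def formula(self) -> str:
        from collections import Counter

        counts = Counter(self.elements)
        out = []
        for el in ("C", "H", "Cl", "N", "O"):
            n = counts.pop(el, 0)
            if n:
                out.append(el + (str(n) if n > 1 else ""))
        assert not counts
        return "".join(out)

    def cx_bond_lengths(self) -> np.ndarray:
        """Current C-X (X = C, N, O) bond lengths from reference positions."""
        pos = self.positions
        out = []
        for i, j, _b0, _k in self.bonds:
            ei, ej = self.sites[i].element, self.sites[j].element
            if {ei, ej} <= {"C", "N", "O"} and "C" in (ei, ej):
                out.append(np.linalg.norm(pos[i] - pos[j]))
        return np.asarray(out)

    @property
    def mean_cx_bond_length(self) -> float:
        return float(self.cx_bond_lengths().mean())


def build_indomethacin_z(
    bond_expansion: float = 0.0,
    flexible: bool = True,
    restricted_amplitude: float = 5.0,
    bond_k: float = DEFAULT_BOND_K,
) -> MoleculeTemplate:
    """Build the indomethacin Z-isomer template.

    Parameters
    ----------
    bond_expansion:
        Uniform lengthening of the mean C-X bond, in A (0 to 0.05). The whole
        molecule is scaled by (1.380 + expansion)/1.380 so the mean C-X bond
        length is exactly ``1.380 + bond_expansion``.
    flexible:
        If True the five group rotations are unrestricted (semi-rigid model);
        if False their amplitude is limited to ``restricted_amplitude``
        degrees (rigid model with slight variation).
    """
    if not 0.0 <= bond_expansion <= 0.05:
        raise ValueError("bond_expansion must be in [0, 0.05] A")
    scale = (REFERENCE_MEAN_CX + bond_expansion) / REFERENCE_MEAN_CX
    sites = tuple(
        AtomSite(i, t, e, np.array([x, y, z]) * scale)
        for i, (t, e, x, y, z) in enumerate(_geometry.ATOMS)
    )
    pos = np.array([s.reference_position for s in sites])
    bonds = tuple(
        (i, j, float(np.linalg.norm(pos[i] - pos[j])), bond_k)
        for i, j in _geometry.BONDS
    )
    amp = 180.0 if flexible else restricted_amplitude
    groups = tuple(
        RotatableGroup(name, (a, b), tuple(mv), amp)
        for name, (a, b), mv in _geometry.ROTATABLE_GROUPS
    )
    return MoleculeTemplate(sites, bonds, groups, bond_expansion)


def rotate_group(
    positions: np.ndarray,
    group: RotatableGroup,
    angle: float,
    enforce_amplitude: bool = False,
) -> np.ndarray:
    """Rigidly rotate a group's moved sites about its axis.

    ``positions`` is the (n_sites, 3) conformer; ``angle`` is in degrees.
    Returns a new array; non-moved sites are untouched.  With
    ``enforce_amplitude`` set, an angle beyond the group's ``max_amplitude``
    raises :class:`MoveRejected` (the rejected-move signal used by the rigid
    models).
    """
    if enforce_amplitude and abs(angle) > group.max_amplitude + 1e-12:
        raise MoveRejected(
            f"angle {angle:.3f} deg exceeds max amplitude {group.max_amplitude} deg"
        )
    positions = np.asarray(positions, dtype=float)
    a, b = group.axis
    origin = positions[a]
    axis = positions[b] - origin
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("degenerate rotation axis")
    k = axis / norm
    theta = np.deg2rad(angle)
    moved = np.asarray(group.moved_sites, dtype=int)
    v = positions[moved] - origin
    # Rodrigues rotation
    rotated = (
        v * np.cos(theta)
        + np.cross(k, v) * np.sin(theta)
        + np.outer(v @ k, k) * (1.0 - np.cos(theta))
    )
    out = positions.copy()
    out[moved] = origin + rotated
    return out


def o3_n_cl_angle(template: MoleculeTemplate, positions: np.ndarray | None = None) -> float:
    """Intramolecular O3-N-Cl angle (degrees), vertex at the amide nitrogen."""
    if positions is None:
        positions = template.positions
    positions = np.asarray(positions, dtype=float)
    o3 = positions[template.site_of_type("O3")]
    n = positions[template.site_of_type("N")]
    cl = positions[template.site_of_type("Cl")]
    v1, v2 = o3 - n, cl - n
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("degenerate O3-N or N-Cl vector")
    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))
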