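"""File formats: two-column S(Q)/D(r) ASCII, extended XYZ, PDB export, manifests.

Coordinates are Cartesian Angstrom with the origin at the box corner;
extended XYZ is the canonical configuration format (with per-atom type
labels and molecule ids), PDB export is lossy (types collapse to elements)
and one-way.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .molecule import MoleculeTemplate, build_indomethacin_z
from .refine import Configuration
from .scattering import ScatteringPattern

__all__ = [
    "write_template_xyz",
    "read_template_xyz",
    "read_sq",
    "write_sq",
    "write_dr",
    "write_xyz",
    "read_xyz",
    "write_pdb",
    "write_manifest",
    "file_checksum",
]


def write_template_xyz(path, template: MoleculeTemplate) -> None:
    """Serialize a molecule template as extended XYZ with type labels.

    Reference positions are written at full repr precision, so a round trip
    reproduces them bit for bit; bonds and rotatable groups are rebuilt
    from the packaged topology on read.
    """
    with open(path, "w") as fh:
        fh.write(f"{template.n_sites}\n")
        fh.write('Properties=species:S:1:pos:R:3:atom_type:S:1 '
                 f"bond_expansion={float(template.bond_expansion)!r}\n")
        for s_ in template.sites:
            x, y, z = (float(v) for v in s_.reference_position)
            fh.write(f"{s_.element} {x!r} {y!r} {z!r} {s_.atom_type}\n")


def read_template_xyz(path) -> MoleculeTemplate:
    """Read a template written by :func:`write_template_xyz`."""
    with open(path) as fh:
        n = int(fh.readline())
        header = fh.readline()
        rows = [fh.readline().split() for _ in range(n)]
    expansion = 0.0
    for tok in header.split():
        if tok.startswith("bond_expansion="):
            expansion = float(tok.split("=", 1)[1])
    template = build_indomethacin_z(bond_expansion=expansion)
    pos = np.array([[float(r[1]), float(r[2]), float(r[3])] for r in rows])
    types = [r[4] for r in rows]
    if types != template.atom_types:
        raise ValueError(f"{path}: atom types do not match the packaged template")
    if not np.array_equal(pos, template.positions):
        raise ValueError(f"{path}: positions do not match the packaged template")
    return template


def read_sq(path) -> ScatteringPattern:
    """Read a two-column (Q, S) ASCII table; '#' comments and blanks allowed.

    Q must be strictly increasing and finite; violations raise with the
    offending line number.  An optional third column is read as per-point
    uncertainty.
    """
    q, s, sig = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least two columns")
            try:
                vals = [float(p) for p in parts[:3]]
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric value") from None
            if not all(np.isfinite(vals)):
                raise ValueError(f"{path}:{lineno}: non-finite value")
            if q and vals[0] <= q[-1]:
                raise ValueError(
                    f"{path}:{lineno}: Q not strictly increasing "
                    f"({vals[0]} after {q[-1]})")
            q.append(vals[0])
            s.append(vals[1])
            if len(parts) >= 3:
                sig.append(vals[2])
    if not q:
        raise ValueError(f"{path}: no data rows")
    sigma = np.array(sig) if len(sig) == len(q) else None
    return ScatteringPattern(q=np.array(q), s=np.array(s), sigma=sigma)


def write_sq(path, pattern: ScatteringPattern, label: str = "S(Q)") -> None:
    with open(path, "w") as fh:
        fh.write(f"# Q (1/Angstrom)   {label} (dimensionless)\n")
        for i in range(pattern.q.size):
            row = f"{float(pattern.q[i])!r} {float(pattern.s[i])!r}"
            if pattern.sigma is not None:
                row += f" {float(pattern.sigma[i])!r}"
            fh.write(row + "\n")


def write_dr(path, r: np.ndarray, d: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("# r (Angstrom)   D(r)\n")
        for ri, di in zip(r, d):
            fh.write(f"{float(ri)!r} {float(di)!r}\n")


def write_xyz(path, config: Configuration, comment: str = "") -> None:
    """Extended XYZ with Lattice, per-atom type labels and molecule ids."""
    L = config.box_length
    tpl = config.template
    pos = config.wrapped_positions()
    mol = config.mol_ids()
    types = tpl.atom_types * config.n_molecules
    elements = tpl.elements * config.n_molecules
    with open(path, "w") as fh:
        fh.write(f"{config.n_atoms}\n")
        fh.write(
            f'Lattice="{float(L)!r} 0.0 0.0 0.0 {float(L)!r} 0.0 0.0 0.0 {float(L)!r}" '
            'Properties=species:S:1:pos:R:3:atom_type:S:1:mol_id:I:1 '
            f'bond_expansion={float(tpl.bond_expansion)!r}'
            + (f" comment={json.dumps(comment)}" if comment else "") + "\n")
        for i in range(config.n_atoms):
            x, y, z = (float(v) for v in pos[i])
            fh.write(f"{elements[i]} {x!r} {y!r} {z!r} {types[i]} {mol[i]}\n")


def read_xyz(path, template: MoleculeTemplate | None = None) -> Configuration:
    """Read a configuration written by :func:`write_xyz`."""
    with open(path) as fh:
        n = int(fh.readline())
        header = fh.readline()
        rows = [fh.readline().split() for _ in range(n)]
    lat = header.split('Lattice="', 1)[1].split('"', 1)[0].split()
    L = float(lat[0])
    expansion = 0.0
    for tok in header.split():
        if tok.startswith("bond_expansion="):
            expansion = float(tok.split("=", 1)[1])
    if template is None:
        template = build_indomethacin_z(bond_expansion=expansion)
    ns = template.n_sites
    if n % ns:
        raise ValueError(f"{path}: atom count {n} not a multiple of {ns}")
    pos = np.array([[float(r[1]), float(r[2]), float(r[3])] for r in rows])
    mol = np.array([int(r[5]) for r in rows])
    order = np.argsort(mol, kind="stable")
    pos = pos[order].reshape(n // ns, ns, 3)
    # un-wrap each molecule so its atoms are contiguous around site 0
    ref = pos[:, :1, :]
    pos = pos - L * np.rint((pos - ref) / L)
    return Configuration(template=template, box_length=L, positions=pos)


def write_pdb(path, config: Configuration) -> None:
    """Lossy PDB export for visualization (types collapse to elements)."""
    pos = config.wrapped_positions()
    elements = config.template.elements * config.n_molecules
    mol = config.mol_ids()
    L = config.box_length
    with open(path, "w") as fh:
        fh.write(f"CRYST1{L:9.3f}{L:9.3f}{L:9.3f}  90.00  90.00  90.00 P 1\n")
        for i in range(config.n_atoms):
            el = elements[i]
            fh.write(
                f"HETATM{i + 1:5d} {el:<4s}IMC {chr(65 + mol[i] % 26)}{mol[i] % 9999:4d}"
                f"    {pos[i, 0]:8.3f}{pos[i, 1]:8.3f}{pos[i, 2]:8.3f}"
                f"  1.00  0.00          {el:>2s}\n")
        fh.write("END\n")


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, *, seeds: dict, parameters: dict,
                   inputs: dict | None = None, trace=None) -> dict:
    """Reproducibility manifest: version, config hash, seeds, input checksums.

    The config hash covers parameters and seeds (not timestamps), so reruns
    with identical inputs produce identical hashes.
    """
    from . import __version__

    inputs = inputs or {}
    checksums = {str(k): file_checksum(v) for k, v in inputs.items()}
    hashed = json.dumps({"parameters": parameters, "seeds": seeds,
                         "inputs": checksums}, sort_keys=True)
    import datetime

    doc = {
        "tool": "epsrlite",
        "version": __version__,
        "config_hash": hashlib.sha256(hashed.encode()).hexdigest(),
        "seeds": seeds,
        "parameters": parameters,
        "input_checksums": checksums,
        "fit_trace": list(map(float, trace)) if trace is not None else None,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
    return doc
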