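"""Readers and writers for the plain-text formats the pipeline consumes.

* reduced SAXS curves: 2-3 column whitespace/comma ASCII (q in 1/Angstrom,
  absolute intensity in 1/mm, optional 1-sigma), '#' comments;
* molecular configurations: GRO (fixed-column, nm, box line; multi-frame
  concatenations supported) and extended XYZ (Angstrom, box on the comment
  line, molecule typing from a sidecar file);
* AFM force curves and diameter lists: CSV.

Interface conventions: distances nm, q 1/Angstrom, angles degrees.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .constants import MM_INV_TO_A_INV
from .errors import ParseError, TypingError
from .mdstruct import MolecularConfiguration
from .nanomech import ForceCurve

__all__ = [
    "read_scattering_ascii",
    "write_scattering_ascii",
    "read_configuration",
    "read_trajectory",
    "write_gro",
    "write_xyz",
    "read_force_curves_csv",
    "write_force_curves_csv",
]

#: GRO residue-name aliases -> molecule types
RESNAME_TYPES = {
    "sol": "water",
    "hoh": "water",
    "wat": "water",
    "tip3": "water",
    "act": "acetone",
    "ace": "acetone",
    "thf": "thf",
    "dxn": "dxn",
    "diox": "dxn",
    "dms": "dmso",
    "dmso": "dmso",
}

_ELEMENT_GUESS_TWO = {"cl", "na", "br", "mg", "ca", "fe", "zn"}


def _element_from_name(name: str) -> str:
    """Guess an element symbol from an atom name (GRO carries no element field)."""
    stripped = "".join(c for c in name if c.isalpha())
    if stripped[:2].lower() in _ELEMENT_GUESS_TWO:
        return stripped[:2].capitalize()
    return stripped[:1].upper()


# --------------------------------------------------------------------------
# SAXS curves
# --------------------------------------------------------------------------


def read_scattering_ascii(path):
    """Read a reduced SAXS curve (q 1/A, I 1/mm, optional sigma) into a
    :class:`~lnpkit.saxs.ScatteringCurve` with intensities converted to the
    internal absolute unit 1/Angstrom."""
    from .saxs import ScatteringCurve

    rows = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.replace(",", " ").split()
            if len(parts) not in (2, 3):
                raise ParseError(f"{path.name}:{lineno}: expected 2-3 columns, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise ParseError(f"{path.name}:{lineno}: non-numeric value") from None
    if not rows:
        raise ParseError(f"{path.name}: no data rows")
    ncols = min(len(r) for r in rows)
    data = np.asarray([r[:ncols] for r in rows])
    q = data[:, 0]
    if np.any(np.diff(q) <= 0):
        bad = int(np.flatnonzero(np.diff(q) <= 0)[0]) + 2
        raise ParseError(f"{path.name}: q not strictly increasing at data row {bad}")
    sigma = data[:, 2] if ncols == 3 else None
    return ScatteringCurve.from_mm_inv(q, data[:, 1], sigma)


def write_scattering_ascii(curve, path, header: str = "") -> None:
    """Write a curve as 'q[1/A]  I[1/mm]  (sigma[1/mm])' ASCII, 12 significant digits."""
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# q[1/A]  I[1/mm]" + ("  sigma[1/mm]\n" if curve.sigma is not None else "\n"))
        for k in range(len(curve)):
            cols = [curve.q[k], curve.intensity[k] / MM_INV_TO_A_INV]
            if curve.sigma is not None:
                cols.append(curve.sigma[k] / MM_INV_TO_A_INV)
            fh.write("  ".join(f"{v:.12e}" for v in cols) + "\n")


# --------------------------------------------------------------------------
# molecular configurations
# --------------------------------------------------------------------------


def _parse_gro_frame(lines, start, path):
    try:
        natoms = int(lines[start + 1].strip())
    except (IndexError, ValueError):
        raise ParseError(f"{path}:{start + 2}: expected atom count") from None
    end = start + 2 + natoms
    if end >= len(lines) + 1 or len(lines) < end + 1:
        raise ParseError(f"{path}: truncated frame starting at line {start + 1}")
    resids, resnames, names, xyz = [], [], [], []
    for ln in range(start + 2, end):
        line = lines[ln]
        try:
            resids.append(int(line[0:5]))
            resnames.append(line[5:10].strip())
            names.append(line[10:15].strip())
            xyz.append([float(line[20:28]), float(line[28:36]), float(line[36:44])])
        except (ValueError, IndexError):
            raise ParseError(f"{path}:{ln + 1}: malformed GRO atom line") from None
    box_parts = lines[end].split()
    if len(box_parts) < 3:
        raise ParseError(f"{path}:{end + 1}: malformed box line")
    box = [float(v) for v in box_parts[:3]]
    if any(b <= 0 for b in box):
        raise ParseError(f"{path}:{end + 1}: box edges must be positive")
    # renumber molecules contiguously (GRO resid wraps at 100000)
    mol_ids, current, last = [], -1, None
    for r in resids:
        if r != last:
            current += 1
            last = r
        mol_ids.append(current)
    types = [RESNAME_TYPES.get(rn.lower(), rn.lower()) for rn in resnames]
    config = MolecularConfiguration(
        coordinates=np.asarray(xyz),
        elements=np.asarray([_element_from_name(n) for n in names], dtype=object),
        atom_names=np.asarray(names, dtype=object),
        molecule_ids=np.asarray(mol_ids, dtype=int),
        molecule_types=np.asarray(types, dtype=object),
        box=np.asarray(box),
    )
    return config, end + 1


def _read_sidecar(path):
    """Typing sidecar: lines '<type> <n_molecules> <atoms_per_molecule>' in file order."""
    runs = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.split()
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 'type n_molecules atoms_per_molecule'")
            try:
                runs.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer count") from None
    return runs


def _parse_xyz_frame(lines, start, path, sidecar_runs):
    try:
        natoms = int(lines[start].strip())
    except (IndexError, ValueError):
        raise ParseError(f"{path}:{start + 1}: expected atom count") from None
    comment = lines[start + 1] if start + 1 < len(lines) else ""
    import re

    m = re.search(r'box\s*=\s*"?\s*([\d.eE+-]+)\s+([\d.eE+-]+)\s+([\d.eE+-]+)', comment)
    if m is None:
        raise ParseError(f'{path}:{start + 2}: comment line must carry box="Lx Ly Lz" in Angstrom')
    box = np.asarray([float(g) for g in m.groups()]) / 10.0  # Angstrom -> nm
    end = start + 2 + natoms
    if len(lines) < end:
        raise ParseError(f"{path}: truncated XYZ frame starting at line {start + 1}")
    elements, xyz = [], []
    for ln in range(start + 2, end):
        parts = lines[ln].split()
        if len(parts) < 4:
            raise ParseError(f"{path}:{ln + 1}: expected 'symbol x y z'")
        elements.append(parts[0])
        try:
            xyz.append([float(v) / 10.0 for v in parts[1:4]])  # Angstrom -> nm
        except ValueError:
            raise ParseError(f"{path}:{ln + 1}: non-numeric coordinate") from None
    if sidecar_runs is None:
        raise TypingError(
            f"{path}: XYZ input requires a typing sidecar ('type n_molecules atoms_per_molecule')"
        )
    mol_ids = np.empty(natoms, dtype=int)
    mol_types = np.empty(natoms, dtype=object)
    cursor, mol_id = 0, 0
    for t, n_mol, n_at in sidecar_runs:
        for _ in range(n_mol):
            if cursor + n_at > natoms:
                raise ParseError(f"{path}: sidecar describes more atoms than frame holds")
            mol_ids[cursor : cursor + n_at] = mol_id
            mol_types[cursor : cursor + n_at] = t
            cursor += n_at
            mol_id += 1
    if cursor != natoms:
        raise ParseError(f"{path}: sidecar covers {cursor} atoms, frame has {natoms}")
    names = np.asarray([f"{el}{k}" for k, el in enumerate(elements)], dtype=object)
    config = MolecularConfiguration(
        coordinates=np.asarray(xyz),
        elements=np.asarray(elements, dtype=object),
        atom_names=names,
        molecule_ids=mol_ids,
        molecule_types=mol_types,
        box=box,
    )
    return config, end


def read_trajectory(path, fmt: str | None = None, typing_sidecar=None):
    """Read all frames of a (possibly concatenated) GRO or extended-XYZ file."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    lines = path.read_text().splitlines()
    sidecar_runs = _read_sidecar(typing_sidecar) if typing_sidecar is not None else None
    frames = []
    cursor = 0
    while cursor < len(lines):
        if not lines[cursor].strip():
            cursor += 1
            continue
        if fmt == "gro":
            config, cursor = _parse_gro_frame(lines, cursor, path.name)
        elif fmt == "xyz":
            config, cursor = _parse_xyz_frame(lines, cursor, path.name, sidecar_runs)
        else:
            raise ParseError(f"unrecognised configuration format {fmt!r}")
        frames.append(config)
    if not frames:
        raise ParseError(f"{path.name}: no frames found")
    return frames


def read_configuration(path, fmt: str | None = None, typing_sidecar=None):
    """Read the first frame of a GRO or extended-XYZ file."""
    return read_trajectory(path, fmt=fmt, typing_sidecar=typing_sidecar)[0]


_TYPE_RESNAMES = {"water": "SOL", "acetone": "ACT", "thf": "THF", "dxn": "DXN", "dmso": "DMS"}


def write_gro(config: MolecularConfiguration, path, title: str = "lnpkit configuration",
              append: bool = False) -> None:
    """Write a configuration as a GRO frame (fixed columns, nm)."""
    path = Path(path)
    with path.open("a" if append else "w") as fh:
        fh.write(title + "\n")
        fh.write(f"{config.n_atoms:5d}\n")
        for i in range(config.n_atoms):
            resid = (config.molecule_ids[i] % 99999) + 1
            resname = _TYPE_RESNAMES.get(str(config.molecule_types[i]),
                                         str(config.molecule_types[i])[:5].upper())
            x, y, z = config.coordinates[i]
            fh.write(
                f"{resid:5d}{resname:<5s}{config.atom_names[i]:>5s}{(i % 99999) + 1:5d}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
            )
        fh.write(f"{config.box[0]:10.5f}{config.box[1]:10.5f}{config.box[2]:10.5f}\n")


def write_xyz(config: MolecularConfiguration, path, append: bool = False) -> None:
    """Write a configuration as extended XYZ (Angstrom, box on the comment line)."""
    path = Path(path)
    bx = config.box * 10.0
    with path.open("a" if append else "w") as fh:
        fh.write(f"{config.n_atoms}\n")
        fh.write(f'box="{bx[0]:.6f} {bx[1]:.6f} {bx[2]:.6f}"\n')
        for i in range(config.n_atoms):
            x, y, z = config.coordinates[i] * 10.0
            fh.write(f"{config.elements[i]:<2s} {x:15.8f} {y:15.8f} {z:15.8f}\n")


# --------------------------------------------------------------------------
# force curves and diameter lists
# --------------------------------------------------------------------------


def read_force_curves_csv(path, tip_radius: float = 50.0, poisson_ratio: float = 0.3):
    """Read force curves from CSV.

    Either columns ``indentation_nm, force_nN`` (one curve) or long format
    with an additional ``curve_id`` column.  Returns a list of ForceCurve.
    """
    frame = pd.read_csv(path)
    required = {"indentation_nm", "force_nN"}
    if not required <= set(frame.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    groups = (
        [(None, frame)] if "curve_id" not in frame.columns else frame.groupby("curve_id")
    )
    curves = []
    for _, g in groups:
        g = g.sort_values("indentation_nm")
        curves.append(
            ForceCurve(
                g["indentation_nm"].to_numpy(),
                g["force_nN"].to_numpy(),
                tip_radius=tip_radius,
                poisson_ratio=poisson_ratio,
            )
        )
    return curves


def write_force_curves_csv(curves, path) -> None:
    """Write force curves in long CSV format (curve_id, indentation_nm, force_nN)."""
    rows = []
    for cid, c in enumerate(curves):
        for d, f in zip(c.indentation, c.force):
            rows.append({"curve_id": cid, "indentation_nm": d, "force_nN": f})
    pd.DataFrame(rows).to_csv(path, index=False)
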