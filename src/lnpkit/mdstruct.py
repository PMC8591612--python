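"""Configuration-level structural analysis of molecular simulation frames.

Operates on static molecular configurations (single frames or frame
sequences from an orthorhombic periodic box): geometric hydrogen-bond
detection, radial distribution functions, Shrake-Rupley solvent-accessible
surface area, and solvent-box mass-fraction accounting.

Geometric H-bond criterion (strict inequalities): a donor-H/acceptor
triple is a hydrogen bond iff the heavy-atom donor-acceptor distance is
< 0.35 nm and the hydrogen-donor-acceptor angle -- the angle at the
*donor* between the D->H and D->A vectors -- is < 30 degrees.
Intra-molecular donor/acceptor pairs are excluded by default.

All distances in nm; angles in degrees; areas in nm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import BONDI_RADII_NM, molecule_molar_mass
from .errors import InvalidInputError, SelectionError

__all__ = [
    "MolecularConfiguration",
    "HBondCriteria",
    "RdfSpec",
    "minimum_image_displacement",
    "find_donors",
    "find_hydrogen_bonds",
    "hbond_timeseries",
    "radial_distribution",
    "solvent_accessible_area",
    "box_mass_fractions",
    "select_atoms",
]

#: covalent cutoff used to associate an H with its donor heavy atom, nm
_COVALENT_H_CUTOFF = 0.12


@dataclass(frozen=True)
class MolecularConfiguration:
    """Labelled atom coordinates in an orthorhombic periodic box.

    coordinates : (N, 3) array, nm
    elements : (N,) element symbols
    atom_names : (N,) atom labels (e.g. ``OW``, ``C1``)
    molecule_ids : (N,) integer molecule index per atom
    molecule_types : (N,) molecule-type label per atom (``water``, ...)
    box : (3,) orthorhombic edge lengths, nm
    """

    coordinates: np.ndarray
    elements: np.ndarray
    atom_names: np.ndarray
    molecule_ids: np.ndarray
    molecule_types: np.ndarray
    box: np.ndarray

    def __post_init__(self):
        xyz = np.asarray(self.coordinates, dtype=float)
        box = np.asarray(self.box, dtype=float)
        object.__setattr__(self, "coordinates", xyz)
        object.__setattr__(self, "box", box)
        for name in ("elements", "atom_names", "molecule_types"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=object))
        object.__setattr__(self, "molecule_ids", np.asarray(self.molecule_ids, dtype=int))
        n = xyz.shape[0]
        if xyz.ndim != 2 or xyz.shape[1] != 3 or not np.all(np.isfinite(xyz)):
            raise InvalidInputError("coordinates must be a finite (N, 3) array")
        for name in ("elements", "atom_names", "molecule_ids", "molecule_types"):
            if getattr(self, name).shape != (n,):
                raise InvalidInputError(f"{name} must have length {n}")
        if box.shape != (3,) or np.any(box <= 0):
            raise InvalidInputError("box must be three positive edge lengths")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond cutoffs (strict inequalities)."""

    max_da_distance: float = 0.35  # nm, heavy-atom donor-acceptor
    max_hda_angle: float = 30.0  # degrees, vertex at the donor

    def __post_init__(self):
        if self.max_da_distance <= 0:
            raise InvalidInputError("max_da_distance must be positive")
        if not 0 < self.max_hda_angle <= 180:
            raise InvalidInputError("max_hda_angle must lie in (0, 180]")


@dataclass(frozen=True)
class RdfSpec:
    """Selection and binning of a radial distribution function."""

    group_a: np.ndarray  # atom indices
    group_b: np.ndarray
    bin_width: float  # nm
    r_max: float  # nm, must be <= half the smallest box edge

    def __post_init__(self):
        object.__setattr__(self, "group_a", np.asarray(self.group_a, dtype=int))
        object.__setattr__(self, "group_b", np.asarray(self.group_b, dtype=int))
        if self.bin_width <= 0 or self.r_max <= 0:
            raise InvalidInputError("bin_width and r_max must be positive")
        if self.group_a.size == 0 or self.group_b.size == 0:
            raise SelectionError("RDF groups must be non-empty")


def minimum_image_displacement(p1, p2, box):
    """Minimum-image displacement p2 - p1 and its length in a periodic box.

    Each component is wrapped into [-L/2, L/2).  Returns (vector, distance).
    """
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise InvalidInputError("box edges must be positive")
    d = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    d = d - box * np.floor(d / box + 0.5)
    return d, float(np.linalg.norm(d)) if d.ndim == 1 else np.linalg.norm(d, axis=-1)


def _mi_vectors(d, box):
    """Vectorised minimum-image wrap of displacement array d (..., 3)."""
    return d - box * np.floor(d / box + 0.5)


def select_atoms(
    config: MolecularConfiguration,
    molecule_type: str | None = None,
    atom_name: str | None = None,
    element: str | None = None,
) -> np.ndarray:
    """Indices of atoms matching all given (type, name, element) filters."""
    mask = np.ones(config.n_atoms, dtype=bool)
    if molecule_type is not None:
        mask &= config.molecule_types == molecule_type
    if atom_name is not None:
        mask &= config.atom_names == atom_name
    if element is not None:
        mask &= config.elements == element
    return np.flatnonzero(mask)


def find_donors(
    config: MolecularConfiguration, donor_elements: tuple[str, ...] = ("O", "N")
) -> np.ndarray:
    """Infer (heavy, H) donor pairs: H within 0.12 nm of an O/N in the same molecule.

    Returns an (n, 2) index array.  Each H is assigned to its nearest
    eligible heavy atom.
    """
    pairs = []
    h_idx = np.flatnonzero(config.elements == "H")
    heavy_idx = np.flatnonzero(np.isin(config.elements, donor_elements))
    for h in h_idx:
        same_mol = heavy_idx[config.molecule_ids[heavy_idx] == config.molecule_ids[h]]
        if same_mol.size == 0:
            continue
        d = _mi_vectors(config.coordinates[same_mol] - config.coordinates[h], config.box)
        dist = np.linalg.norm(d, axis=1)
        k = np.argmin(dist)
        if dist[k] < _COVALENT_H_CUTOFF:
            pairs.append((int(same_mol[k]), int(h)))
    return np.asarray(pairs, dtype=int).reshape(-1, 2)


def _cell_list_candidates(donor_xyz, acceptor_xyz, box, cutoff):
    """Yield (donor_row, acceptor_rows) candidate pairs via a periodic cell list.

    Falls back to all-pairs when the box is too small for 3 cells per edge.
    """
    ncell = np.maximum(np.floor(box / cutoff).astype(int), 1)
    if np.any(ncell < 3):
        all_rows = np.arange(acceptor_xyz.shape[0])
        for i in range(donor_xyz.shape[0]):
            yield i, all_rows
        return
    inv_cell = ncell / box
    acc_cells = np.floor((acceptor_xyz % box) * inv_cell).astype(int) % ncell
    table: dict[tuple[int, int, int], list[int]] = {}
    for row, c in enumerate(map(tuple, acc_cells)):
        table.setdefault(c, []).append(row)
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    don_cells = np.floor((donor_xyz % box) * inv_cell).astype(int) % ncell
    for i, c in enumerate(don_cells):
        rows: list[int] = []
        for off in offsets:
            key = tuple((c + off) % ncell)
            rows.extend(table.get(key, ()))
        yield i, np.asarray(rows, dtype=int)


def find_hydrogen_bonds(
    config: MolecularConfiguration,
    criteria: HBondCriteria = HBondCriteria(),
    donors: np.ndarray | None = None,
    acceptors: np.ndarray | None = None,
    exclude_intramolecular: bool = True,
) -> list[tuple[int, int, int]]:
    """All (donor, hydrogen, acceptor) triples satisfying the geometric criteria.

    ``donors`` is an (n, 2) array of (heavy, H) index pairs (inferred from
    covalent O-H/N-H geometry when omitted); ``acceptors`` an index array
    (defaults to all O and N atoms).  Neighbour search uses a periodic cell
    list; results are identical to the all-pairs computation.
    """
    if donors is None:
        donors = find_donors(config)
    else:
        donors = np.asarray(donors, dtype=int).reshape(-1, 2)
        for heavy, h in donors:
            if config.elements[h] != "H":
                raise SelectionError(f"donor pair ({heavy}, {h}): atom {h} is not a hydrogen")
            _, dist = minimum_image_displacement(
                config.coordinates[heavy], config.coordinates[h], config.box
            )
            if dist >= _COVALENT_H_CUTOFF:
                raise SelectionError(
                    f"donor heavy atom {heavy} has no attached hydrogen at index {h}"
                )
    if acceptors is None:
        acceptors = np.flatnonzero(np.isin(config.elements, ("O", "N")))
    acceptors = np.asarray(acceptors, dtype=int)
    if donors.size == 0 or acceptors.size == 0:
        raise SelectionError("donor and acceptor selections must be non-empty")

    xyz, box = config.coordinates, config.box
    cos_max = np.cos(np.deg2rad(criteria.max_hda_angle))
    bonds: list[tuple[int, int, int]] = []
    donor_xyz = xyz[donors[:, 0]]
    for row, acc_rows in _cell_list_candidates(
        donor_xyz, xyz[acceptors], box, criteria.max_da_distance
    ):
        heavy, h = donors[row]
        cand = acceptors[acc_rows]
        cand = cand[cand != heavy]
        if exclude_intramolecular:
            cand = cand[config.molecule_ids[cand] != config.molecule_ids[heavy]]
        if cand.size == 0:
            continue
        v_da = _mi_vectors(xyz[cand] - xyz[heavy], box)
        dist = np.linalg.norm(v_da, axis=1)
        close = dist < criteria.max_da_distance
        if not np.any(close):
            continue
        v_dh = _mi_vectors(xyz[h] - xyz[heavy], box)
        v_dh = v_dh / np.linalg.norm(v_dh)
        cosang = (v_da[close] @ v_dh) / dist[close]
        ok = cosang > cos_max  # strict: angle < max_hda_angle
        for a in cand[close][ok]:
            bonds.append((int(heavy), int(h), int(a)))
    bonds.sort()
    return bonds


def hbond_timeseries(
    configs: list[MolecularConfiguration],
    criteria: HBondCriteria = HBondCriteria(),
    donors: np.ndarray | None = None,
    acceptors: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-frame hydrogen-bond counts aggregated by molecule-type pair.

    Returns a DataFrame indexed by frame with one column per
    ``donorType-acceptorType`` pair plus a ``total`` column.  Frames must
    share an identical topology (elements and molecule labels).
    """
    if not configs:
        raise InvalidInputError("hbond_timeseries requires at least one frame")
    ref = configs[0]
    for k, c in enumerate(configs[1:], start=1):
        if (
            c.n_atoms != ref.n_atoms
            or not np.array_equal(c.elements, ref.elements)
            or not np.array_equal(c.molecule_ids, ref.molecule_ids)
            or not np.array_equal(c.molecule_types, ref.molecule_types)
        ):
            raise InvalidInputError(f"frame {k} topology differs from frame 0")
    rows = []
    for c in configs:
        bonds = find_hydrogen_bonds(c, criteria, donors=donors, acceptors=acceptors)
        counts: dict[str, int] = {}
        for heavy, _h, a in bonds:
            key = f"{c.molecule_types[heavy]}-{c.molecule_types[a]}"
            counts[key] = counts.get(key, 0) + 1
        counts["total"] = len(bonds)
        rows.append(counts)
    frame = pd.DataFrame(rows).fillna(0).astype(int)
    frame.index.name = "frame"
    return frame


def radial_distribution(
    configs: list[MolecularConfiguration], spec: RdfSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Radial distribution function g(r) between two atom groups.

    Pair histogram of minimum-image distances, normalised per frame by the
    ideal-gas expectation ``N_a * rho_b * V_shell``; self pairs (identical
    atom index) are excluded.  Returns (bin_centres, g).
    """
    if not configs:
        raise InvalidInputError("radial_distribution requires at least one frame")
    box = configs[0].box
    if spec.r_max > min(box) / 2.0 + 1e-12:
        raise InvalidInputError(
            f"r_max = {spec.r_max} nm exceeds half the smallest box edge ({min(box) / 2.0} nm)"
        )
    edges = np.arange(0.0, spec.r_max + spec.bin_width, spec.bin_width)
    edges = edges[edges <= spec.r_max + 1e-12]
    hist = np.zeros(edges.size - 1)
    volume = float(np.prod(box))
    n_a, n_b = spec.group_a.size, spec.group_b.size
    for c in configs:
        if c.n_atoms <= max(spec.group_a.max(), spec.group_b.max()):
            raise InvalidInputError("RDF selection indices exceed atom count")
        pa = c.coordinates[spec.group_a]
        pb = c.coordinates[spec.group_b]
        d = _mi_vectors(pa[:, None, :] - pb[None, :, :], c.box)
        dist = np.linalg.norm(d, axis=-1)
        self_pair = spec.group_a[:, None] == spec.group_b[None, :]
        dist = dist[~self_pair]
        hist += np.histogram(dist, bins=edges)[0]
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    rho_b = n_b / volume
    norm = len(configs) * n_a * rho_b * shell
    centres = 0.5 * (edges[:-1] + edges[1:])
    return centres, hist / norm


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit sphere point set (Fibonacci lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def solvent_accessible_area(
    config: MolecularConfiguration,
    atom_radii: dict[str, float] | None = None,
    probe: float = 0.14,
    n_sphere_points: int = 960,
    selection: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Shrake-Rupley solvent-accessible surface area, PBC-aware, in nm^2.

    Each selected atom is covered with a deterministic Fibonacci lattice of
    ``n_sphere_points`` test points at radius ``r_i + probe``; the exposed
    fraction of points gives the per-atom area.  ``atom_radii`` maps element
    symbols to van der Waals radii in nm (Bondi radii by default).

    Returns (total_area, per_atom_areas) with per-atom entries ordered as
    the selection.
    """
    if atom_radii is None:
        atom_radii = BONDI_RADII_NM
    if probe < 0:
        raise InvalidInputError("probe radius must be >= 0")
    sel = (
        np.arange(config.n_atoms) if selection is None else np.asarray(selection, dtype=int)
    )
    radii = np.empty(config.n_atoms)
    for i, el in enumerate(config.elements):
        if el not in atom_radii:
            raise InvalidInputError(f"no van der Waals radius for element {el!r}")
        radii[i] = atom_radii[el]
    sphere = _fibonacci_sphere(n_sphere_points)
    xyz, box = config.coordinates, config.box
    areas = np.zeros(sel.size)
    ext = radii + probe
    for out_row, i in enumerate(sel):
        # neighbours whose accessible spheres can occlude atom i's surface
        d = _mi_vectors(xyz - xyz[i], box)
        dist = np.linalg.norm(d, axis=1)
        near = np.flatnonzero((dist < ext[i] + ext) & (np.arange(config.n_atoms) != i))
        pts = sphere * ext[i]  # test points relative to atom i
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j in near:
            dj = pts - d[j]  # neighbour placed at its minimum-image position
            d2 = np.einsum("ij,ij->i", dj, dj)
            tol = 1e-9 * ext[j] ** 2
            occluded = d2 < ext[j] ** 2 - tol
            if j < i:
                # boundary tie-break: points exactly on a lower-index
                # neighbour's sphere belong to that neighbour, so exactly
                # coincident atoms contribute the area of one atom in total
                occluded |= np.abs(d2 - ext[j] ** 2) <= tol
            exposed &= ~occluded
        areas[out_row] = 4.0 * np.pi * ext[i] ** 2 * exposed.mean()
    return float(areas.sum()), areas


def box_mass_fractions(
    molecule_counts: dict[str, int], molar_masses: dict[str, float] | None = None
) -> dict[str, float]:
    """Mass fractions w_t = n_t M_t / sum(n M) of a molecule-count map.

    ``molar_masses`` maps type -> g/mol; omitted entries are resolved from
    the built-in solvent formula table (``water``, ``acetone``, ...).
    """
    masses = {}
    for t, n in molecule_counts.items():
        if n <= 0:
            raise InvalidInputError(f"count for {t!r} must be positive")
        m = (molar_masses or {}).get(t)
        masses[t] = m if m is not None else molecule_molar_mass(t)
        if masses[t] <= 0:
            raise InvalidInputError(f"molar mass for {t!r} must be positive")
    total = sum(molecule_counts[t] * masses[t] for t in molecule_counts)
    return {t: molecule_counts[t] * masses[t] / total for t in molecule_counts}
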