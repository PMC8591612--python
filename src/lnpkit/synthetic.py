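"""Synthetic-data generators with known ground truth for every pipeline input.

Each generator is deterministic under a fixed integer seed and returns the
synthetic object together with a machine-readable truth dict that the test
suite consumes.  The emulated study conditions are:

* absolute-scale SAXS curves of dilute polydisperse lignin-nanoparticle
  spheres in water (mean diameter 44 nm, SD 16 nm; concentration
  6.7 mg/mL at particle density 1.4 g/cm^3, i.e. phi = 4.79e-3; contrast
  (12.6 - 9.469)e-6 A^-2) with flat background and multiplicative
  Gaussian counting-style noise;
* Hertzian AFM force curves (tip radius 50 nm, nu = 0.3, particle moduli
  0.3-4 GPa) with additive force noise and an optional stiff-substrate
  sub-population;
* orthorhombic solvent boxes at prescribed weight fractions, built from
  rigid idealised molecule templates placed uniformly at random (ideal-gas
  statistics by construction; no energetics);
* idealised donor-H/acceptor scenes with planted hydrogen bonds (10%
  inside both cutoffs) and decoys violating exactly one criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import LNP_DENSITY, SLD_WATER_1E6, molecule_molar_mass
from .errors import GenerationError, InvalidInputError
from .mdstruct import HBondCriteria, MolecularConfiguration
from .nanomech import DEFAULT_POISSON, DEFAULT_TIP_RADIUS, ForceCurve, hertz_force
from .saxs import ScatteringCurve, SphereLogNormalModel, model_intensity
from .sizestats import lognormal_params_from_moments

__all__ = [
    "GeneratorConfig",
    "LNP_ACETONE_SAXS_MODEL",
    "make_saxs_curve",
    "make_force_curves",
    "make_particle_records",
    "make_solvent_box",
    "make_hbond_scene",
    "MOLECULE_TEMPLATES",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """A named scenario plus its seed and parameter overrides."""

    seed: int
    scenario: str
    parameters: dict[str, Any] = field(default_factory=dict)


def _default_lnp_model() -> SphereLogNormalModel:
    """Paper-conditions SAXS model: 44 +- 16 nm spheres, 6.7 mg/mL at 1.4 g/cm^3."""
    median, sigma_log = lognormal_params_from_moments(44.0, 16.0)
    return SphereLogNormalModel(
        median_diameter=median,
        sigma_log=sigma_log,
        volume_fraction=6.7e-3 / LNP_DENSITY,
        contrast=(12.6 - SLD_WATER_1E6) * 1e-6,
        background=1e-9,  # absolute 1/Angstrom (0.01 mm^-1, water-level flat residual)
    )


LNP_ACETONE_SAXS_MODEL = _default_lnp_model()


def make_saxs_curve(
    model: SphereLogNormalModel | None = None,
    q_grid: np.ndarray | None = None,
    noise_fraction: float = 0.01,
    seed: int = 0,
) -> tuple[ScatteringCurve, dict]:
    """Synthetic absolute-scale SAXS curve with multiplicative Gaussian noise.

    Defaults emulate the instrument range (q = 0.003-0.3 1/A, 400 points,
    log-spaced) and the LNP dispersion conditions.  ``sigma`` on the curve
    is the true per-point noise level; ``noise_fraction = 0`` returns the
    exact model intensity.
    """
    if model is None:
        model = _default_lnp_model()
    if q_grid is None:
        q_grid = np.geomspace(0.003, 0.3, 400)
    if noise_fraction < 0:
        raise InvalidInputError("noise_fraction must be >= 0")
    rng = np.random.default_rng(seed)
    i_true = model_intensity(q_grid, model)
    if noise_fraction > 0:
        i_obs = i_true * (1.0 + noise_fraction * rng.standard_normal(q_grid.size))
        sigma = noise_fraction * i_true
        curve = ScatteringCurve(q_grid, i_obs, sigma)
    else:
        curve = ScatteringCurve(q_grid, i_true)
    truth = {
        "median_diameter": model.median_diameter,
        "sigma_log": model.sigma_log,
        "mean_diameter": model.mean_diameter,
        "sd_diameter": model.sd_diameter,
        "volume_fraction": model.volume_fraction,
        "contrast": model.contrast,
        "background": model.background,
        "noise_fraction": noise_fraction,
        "seed": seed,
    }
    return curve, truth


def make_force_curves(
    modulus: float = 2.7,
    tip_radius: float = DEFAULT_TIP_RADIUS,
    n_curves: int = 100,
    noise: float = 0.02,
    substrate_mix: float = 0.0,
    max_indentation: float = 3.0,
    n_points: int = 200,
    seed: int = 0,
    poisson_ratio: float = DEFAULT_POISSON,
) -> tuple[list[ForceCurve], dict]:
    """Hertzian force curves with additive Gaussian noise.

    ``noise`` is the SD of the additive force noise as a fraction of the
    maximum force.  A fraction ``substrate_mix`` of the curves is replaced
    by stiff-substrate responses with moduli drawn uniformly from 6-12 GPa
    (all above the 4 GPa substrate line).  Truth records the per-curve
    modulus and substrate flag.
    """
    if modulus <= 0 or n_curves < 1 or noise < 0 or not 0 <= substrate_mix <= 1:
        raise InvalidInputError("invalid generator parameters")
    rng = np.random.default_rng(seed)
    n_sub = int(round(substrate_mix * n_curves))
    is_sub = np.zeros(n_curves, dtype=bool)
    is_sub[rng.choice(n_curves, size=n_sub, replace=False)] = True
    delta = np.linspace(0.0, max_indentation, n_points)
    curves, e_true = [], []
    for k in range(n_curves):
        e = float(rng.uniform(6.0, 12.0)) if is_sub[k] else modulus
        f = hertz_force(delta, e, tip_radius, poisson_ratio)
        if noise > 0:
            f = f + noise * f.max() * rng.standard_normal(n_points)
        curves.append(ForceCurve(delta, f, tip_radius, poisson_ratio))
        e_true.append(e)
    truth = {
        "modulus": modulus,
        "moduli": e_true,
        "substrate": is_sub.tolist(),
        "substrate_mix": substrate_mix,
        "noise": noise,
        "seed": seed,
    }
    return curves, truth


def make_particle_records(
    n_records: int = 200,
    modulus_range: tuple[float, float] = (0.5, 3.5),
    height_range: tuple[float, float] = (20.0, 80.0),
    substrate_mix: float = 0.0,
    modulus_noise_sd: float = 0.3,
    seed: int = 0,
):
    """Particle (height, modulus) records with a planted substrate fraction.

    Particle records have size-independent moduli drawn uniformly from
    ``modulus_range`` plus Gaussian noise; substrate-affected records get
    heights below 15 nm and moduli above 4 GPa so the flagging rule
    identifies them exactly.  Returns (records, truth).
    """
    from .nanomech import ParticleRecord

    rng = np.random.default_rng(seed)
    n_sub = int(round(substrate_mix * n_records))
    is_sub = np.zeros(n_records, dtype=bool)
    is_sub[rng.choice(n_records, size=n_sub, replace=False)] = True
    records = []
    for k in range(n_records):
        if is_sub[k]:
            h = float(rng.uniform(3.0, 12.0))
            e = float(rng.uniform(5.0, 10.0))
        else:
            h = float(rng.uniform(*height_range))
            e = float(
                np.clip(
                    rng.uniform(*modulus_range) + modulus_noise_sd * rng.standard_normal(),
                    0.05,
                    3.9,
                )
            )
        records.append(ParticleRecord(height=h, modulus=e, stiffness=e * 10.0))
    truth = {"substrate": is_sub.tolist(), "substrate_mix": substrate_mix, "seed": seed}
    return records, truth


# --------------------------------------------------------------------------
# molecular scenes
# --------------------------------------------------------------------------

# Rigid idealised molecule templates: (elements, atom_names, coordinates nm).
# Geometries are schematic (correct bond-length scale, simplified H
# placement) -- sufficient for H-bond/RDF/SASA testing, no energetics.
_T = {
    "water": (
        ["O", "H", "H"],
        ["OW", "HW1", "HW2"],
        [[0.0, 0.0, 0.0], [0.09572, 0.0, 0.0], [-0.02400, 0.09268, 0.0]],
    ),
    "acetone": (
        ["C", "O", "C", "C", "H", "H", "H", "H", "H", "H"],
        ["C2", "O1", "C1", "C3", "H11", "H12", "H13", "H31", "H32", "H33"],
        [
            [0.0, 0.0, 0.0],
            [0.0, 0.1229, 0.0],
            [-0.1282, -0.0773, 0.0],
            [0.1282, -0.0773, 0.0],
            [-0.2150, -0.0150, 0.0],
            [-0.1350, -0.1400, 0.0890],
            [-0.1350, -0.1400, -0.0890],
            [0.2150, -0.0150, 0.0],
            [0.1350, -0.1400, 0.0890],
            [0.1350, -0.1400, -0.0890],
        ],
    ),
    "thf": (
        ["O", "C", "C", "C", "C", "H", "H", "H", "H", "H", "H", "H", "H"],
        ["O1", "C1", "C2", "C3", "C4", "H1a", "H1b", "H2a", "H2b", "H3a", "H3b", "H4a", "H4b"],
        [
            [0.0, 0.1170, 0.0],
            [0.1150, 0.0330, 0.0],
            [0.0710, -0.1120, 0.0],
            [-0.0710, -0.1120, 0.0],
            [-0.1150, 0.0330, 0.0],
            [0.1780, 0.0520, 0.0890],
            [0.1780, 0.0520, -0.0890],
            [0.1100, -0.1640, 0.0890],
            [0.1100, -0.1640, -0.0890],
            [-0.1100, -0.1640, 0.0890],
            [-0.1100, -0.1640, -0.0890],
            [-0.1780, 0.0520, 0.0890],
            [-0.1780, 0.0520, -0.0890],
        ],
    ),
    "dxn": (
        ["O", "C", "C", "O", "C", "C", "H", "H", "H", "H", "H", "H", "H", "H"],
        ["O1", "C2", "C3", "O4", "C5", "C6",
         "H2a", "H2b", "H3a", "H3b", "H5a", "H5b", "H6a", "H6b"],
        [
            [0.1370, 0.0300, 0.0],
            [0.0720, 0.1400, 0.0520],
            [-0.0720, 0.1400, -0.0520],
            [-0.1370, 0.0300, 0.0],
            [-0.0720, -0.1400, -0.0520],
            [0.0720, -0.1400, 0.0520],
            [0.1100, 0.2300, 0.0100],
            [0.0850, 0.1400, 0.1610],
            [-0.1100, 0.2300, -0.0100],
            [-0.0850, 0.1400, -0.1610],
            [-0.1100, -0.2300, -0.0100],
            [-0.0850, -0.1400, -0.1610],
            [0.1100, -0.2300, 0.0100],
            [0.0850, -0.1400, 0.1610],
        ],
    ),
    "dmso": (
        ["S", "O", "C", "C", "H", "H", "H", "H", "H", "H"],
        ["S1", "O1", "C1", "C2", "H11", "H12", "H13", "H21", "H22", "H23"],
        [
            [0.0, 0.0, 0.0],
            [0.0, 0.1531, 0.0],
            [-0.1504, -0.0700, 0.0370],
            [0.1504, -0.0700, 0.0370],
            [-0.2300, -0.0100, 0.0800],
            [-0.1400, -0.1600, 0.1000],
            [-0.1750, -0.1000, -0.0640],
            [0.2300, -0.0100, 0.0800],
            [0.1400, -0.1600, 0.1000],
            [0.1750, -0.1000, -0.0640],
        ],
    ),
}

MOLECULE_TEMPLATES = {
    name: (list(e), list(a), np.asarray(c, dtype=float)) for name, (e, a, c) in _T.items()
}


def _choose_counts(fractions: dict[str, float], total_molecules: int) -> dict[str, int]:
    """Integer molecule counts hitting target weight fractions.

    Minimises the squared weight-fraction error subject to the counts
    summing exactly to ``total_molecules``: continuous solution n_t
    proportional to w_t/M_t rounded by largest remainder, then a
    zero-sum +-span local search.
    """
    types = sorted(fractions)
    masses = {t: molecule_molar_mass(t) for t in types}
    raw = np.array([fractions[t] / masses[t] for t in types])
    raw = raw / raw.sum() * total_molecules
    base = np.maximum(np.floor(raw).astype(int), 1)
    # largest-remainder top-up to the exact total
    remainder = raw - np.floor(raw)
    short = total_molecules - int(base.sum())
    if short > 0:
        for idx in np.argsort(remainder)[::-1][:short]:
            base[idx] += 1

    def err(counts):
        tot = sum(c * masses[t] for t, c in zip(types, counts))
        return sum(
            (c * masses[t] / tot - fractions[t]) ** 2 for t, c in zip(types, counts)
        )

    best, best_err = tuple(base), err(base)
    span = 6 if len(types) <= 3 else 1
    if len(types) <= 5:
        from itertools import product

        for deltas in product(range(-span, span + 1), repeat=len(types)):
            if sum(deltas) != 0:
                continue
            cand = base + np.array(deltas)
            if np.any(cand < 1):
                continue
            e = err(cand)
            if e < best_err - 1e-15:
                best, best_err = tuple(cand), e
    return dict(zip(types, (int(c) for c in best)))


def _random_rotations(n: int, rng) -> np.ndarray:
    """n uniform random rotation matrices from the seeded generator."""
    quat = rng.standard_normal((n, 4))
    quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    return Rotation.from_quat(quat).as_matrix()


def make_solvent_box(
    composition: dict[str, float],
    box: float | tuple[float, float, float] = 5.316,
    total_molecules: int = 1000,
    seed: int = 0,
) -> tuple[MolecularConfiguration, dict]:
    """Random solvent box at prescribed weight fractions (ideal-gas statistics).

    Molecule counts are integer-optimised against the target weight
    fractions; rigid molecule templates are placed uniformly at random
    with uniform random orientations and no overlap check, so the centres
    follow ideal-gas statistics by construction.
    """
    total_frac = sum(composition.values())
    if abs(total_frac - 1.0) > 1e-6:
        raise InvalidInputError(f"weight fractions sum to {total_frac}; must be 1")
    box_arr = np.asarray([box] * 3 if np.isscalar(box) else box, dtype=float)
    if np.any(box_arr <= 0):
        raise InvalidInputError("box edges must be positive")
    counts = _choose_counts(composition, total_molecules)
    # sanity gate: a filled box denser than ~2x water-like packing is a
    # mis-specified request, not a fixture
    n_atoms_total = sum(len(MOLECULE_TEMPLATES[t][0]) * c for t, c in counts.items())
    if n_atoms_total / np.prod(box_arr) > 250.0:
        raise GenerationError(
            f"{n_atoms_total} atoms in a {np.prod(box_arr):.1f} nm^3 box is unphysically dense"
        )
    rng = np.random.default_rng(seed)
    elements, names, mol_ids, mol_types, coords = [], [], [], [], []
    mol_id = 0
    for t in sorted(counts):
        els, ans, template = MOLECULE_TEMPLATES[t]
        n = counts[t]
        centres = rng.uniform(0.0, box_arr, size=(n, 3))
        rots = _random_rotations(n, rng)
        for k in range(n):
            xyz = (template @ rots[k].T + centres[k]) % box_arr
            coords.append(xyz)
            elements.extend(els)
            names.extend(ans)
            mol_ids.extend([mol_id] * len(els))
            mol_types.extend([t] * len(els))
            mol_id += 1
    config = MolecularConfiguration(
        coordinates=np.vstack(coords),
        elements=np.asarray(elements, dtype=object),
        atom_names=np.asarray(names, dtype=object),
        molecule_ids=np.asarray(mol_ids, dtype=int),
        molecule_types=np.asarray(mol_types, dtype=object),
        box=box_arr,
    )
    achieved = {
        t: counts[t] * molecule_molar_mass(t)
        / sum(counts[u] * molecule_molar_mass(u) for u in counts)
        for t in counts
    }
    truth = {
        "counts": counts,
        "target_fractions": dict(composition),
        "achieved_fractions": achieved,
        "seed": seed,
    }
    return config, truth


def make_hbond_scene(
    n_bonds: int,
    n_decoys: int,
    criteria: HBondCriteria = HBondCriteria(),
    seed: int = 0,
    margin: float = 0.10,
) -> tuple[MolecularConfiguration, dict]:
    """Scene of isolated donor-H/acceptor units with exactly ``n_bonds`` planted.

    Each unit is a donor hydroxyl (O-H, one molecule) and an acceptor O
    (separate molecule).  Planted bonds sit strictly inside both cutoffs
    with a relative ``margin``; each decoy violates exactly one criterion
    (alternating distance/angle).  Units are placed on a shuffled 1.5 nm
    grid so no inter-unit pair can satisfy the distance cutoff.
    """
    if n_bonds < 0 or n_decoys < 0:
        raise InvalidInputError("counts must be >= 0")
    n_units = n_bonds + n_decoys
    if n_units == 0:
        raise InvalidInputError("scene needs at least one unit")
    rng = np.random.default_rng(seed)
    spacing = 1.5  # nm; unit extent < 0.5 nm keeps inter-unit distances > 1.0 nm
    side = int(np.ceil(n_units ** (1.0 / 3.0)))
    cells = [(i, j, k) for i in range(side) for j in range(side) for k in range(side)]
    rng.shuffle(cells)
    box = np.full(3, side * spacing)
    d_oh = 0.098  # covalent O-H bond, nm

    elements, names, mol_ids, mol_types, coords = [], [], [], [], []
    truth_bonds = []
    mol_id = 0
    for u in range(n_units):
        centre = (np.asarray(cells[u]) + 0.5) * spacing
        rot = _random_rotations(1, rng)[0]
        u_dir = rot @ np.array([1.0, 0.0, 0.0])
        is_bond = u < n_bonds
        if is_bond:
            dist = rng.uniform(0.25, (1.0 - margin) * criteria.max_da_distance)
            ang = np.deg2rad(rng.uniform(0.0, (1.0 - margin) * criteria.max_hda_angle))
        elif (u - n_bonds) % 2 == 0:  # distance decoy
            dist = rng.uniform(
                (1.0 + margin) * criteria.max_da_distance,
                (1.0 + 3 * margin) * criteria.max_da_distance,
            )
            ang = np.deg2rad(rng.uniform(0.0, (1.0 - margin) * criteria.max_hda_angle))
        else:  # angle decoy
            dist = rng.uniform(0.25, (1.0 - margin) * criteria.max_da_distance)
            ang = np.deg2rad(
                rng.uniform((1.0 + margin) * criteria.max_hda_angle,
                            min(2.5 * criteria.max_hda_angle, 170.0))
            )
        perp = rot @ np.array([0.0, 1.0, 0.0])
        a_dir = np.cos(ang) * u_dir + np.sin(ang) * perp
        d_pos = centre
        h_pos = centre + d_oh * u_dir
        a_pos = centre + dist * a_dir
        base = len(elements)
        coords.extend([d_pos, h_pos, a_pos])
        elements.extend(["O", "H", "O"])
        names.extend(["OD", "HD", "OA"])
        mol_ids.extend([mol_id, mol_id, mol_id + 1])
        mol_types.extend(["donor", "donor", "acceptor"])
        if is_bond:
            truth_bonds.append((base, base + 1, base + 2))
        mol_id += 2
    config = MolecularConfiguration(
        coordinates=np.asarray(coords),
        elements=np.asarray(elements, dtype=object),
        atom_names=np.asarray(names, dtype=object),
        molecule_ids=np.asarray(mol_ids, dtype=int),
        molecule_types=np.asarray(mol_types, dtype=object),
        box=box,
    )
    truth = {"bonds": truth_bonds, "n_bonds": n_bonds, "n_decoys": n_decoys, "seed": seed}
    return config, truth
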