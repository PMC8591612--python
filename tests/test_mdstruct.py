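"""Structural analysis: minimum image, H-bonds, RDF, SASA, box accounting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lnpkit.constants import molar_mass
from lnpkit.errors import InvalidInputError, SelectionError
from lnpkit.mdstruct import (
    HBondCriteria,
    MolecularConfiguration,
    RdfSpec,
    box_mass_fractions,
    find_donors,
    find_hydrogen_bonds,
    hbond_timeseries,
    minimum_image_displacement,
    radial_distribution,
    select_atoms,
    solvent_accessible_area,
)
from lnpkit.synthetic import make_hbond_scene, make_solvent_box


def _brute_hbonds(config, criteria=HBondCriteria()):
    """O(N^2) reference: direct double loop over donors x acceptors."""
    donors = find_donors(config)
    acceptors = np.flatnonzero(np.isin(config.elements, ("O", "N")))
    out = []
    for heavy, h in donors:
        for a in acceptors:
            if a == heavy or config.molecule_ids[a] == config.molecule_ids[heavy]:
                continue
            v, d = minimum_image_displacement(
                config.coordinates[heavy], config.coordinates[a], config.box
            )
            if d >= criteria.max_da_distance:
                continue
            vh, _ = minimum_image_displacement(
                config.coordinates[heavy], config.coordinates[h], config.box
            )
            cos = np.dot(v, vh) / (d * np.linalg.norm(vh))
            if cos > np.cos(np.deg2rad(criteria.max_hda_angle)):
                out.append((int(heavy), int(h), int(a)))
    return sorted(out)


def _single_atom(element="O", box=10.0):
    return MolecularConfiguration(
        np.array([[box / 2] * 3]), [element], ["A1"], [0], ["x"], [box] * 3
    )


# ------------------------------------------------------------- minimum image


def test_minimum_image_zero_and_wrap():
    box = np.array([5.0, 5.0, 5.0])
    _, d = minimum_image_displacement([1, 1, 1], [1, 1, 1], box)
    assert d == 0.0
    _, d = minimum_image_displacement([0.1, 0, 0], [4.9, 0, 0], box)
    assert d == pytest.approx(0.2)


@given(st.integers(0, 10_000))
def test_minimum_image_matches_image_enumeration(seed):
    rng = np.random.default_rng(seed)
    box = rng.uniform(2.0, 8.0, 3)
    p1, p2 = rng.uniform(0, box, (2, 3))
    _, d = minimum_image_displacement(p1, p2, box)
    shifts = np.array(
        [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    )
    brute = np.min(np.linalg.norm(p2 - p1 + shifts * box, axis=1))
    assert d == pytest.approx(brute, rel=1e-10)


# ------------------------------------------------------------------- H-bonds


def _hbond_unit(d_oo, angle_deg, box=3.0):
    """Donor O-H along +x with an acceptor O at distance d and H-D-A angle."""
    ang = np.deg2rad(angle_deg)
    centre = np.array([1.5, 1.5, 1.5])
    coords = np.array(
        [
            centre,
            centre + [0.098, 0.0, 0.0],
            centre + d_oo * np.array([np.cos(ang), np.sin(ang), 0.0]),
        ]
    )
    return MolecularConfiguration(
        coords, ["O", "H", "O"], ["OD", "HD", "OA"], [0, 0, 1],
        ["donor", "donor", "acceptor"], [box] * 3,
    )


@pytest.mark.parametrize(
    "d,angle,n_expected",
    [
        (0.29, 5.0, 1),  # inside both cutoffs
        (0.36, 5.0, 0),  # distance violation
        (0.29, 35.0, 0),  # angle violation
        (0.35, 5.0, 0),  # boundary distance excluded (strict inequality)
        (0.29, 30.0, 0),  # boundary angle excluded
    ],
)
def test_hbond_geometric_criteria(d, angle, n_expected):
    assert len(find_hydrogen_bonds(_hbond_unit(d, angle))) == n_expected


@pytest.mark.parametrize("seed", range(5))
def test_cell_list_equals_brute_force_on_random_boxes(seed):
    config, _ = make_solvent_box({"water": 1.0}, box=2.8, total_molecules=250, seed=seed)
    assert find_hydrogen_bonds(config) == _brute_hbonds(config)


def test_hbond_invariant_under_box_commensurate_translation():
    config, _ = make_solvent_box({"water": 1.0}, box=3.0, total_molecules=200, seed=7)
    shifted = MolecularConfiguration(
        (config.coordinates + np.array([1.0, 2.0, 0.5])) % config.box,
        config.elements, config.atom_names, config.molecule_ids,
        config.molecule_types, config.box,
    )
    assert len(find_hydrogen_bonds(config)) == len(find_hydrogen_bonds(shifted))


def test_donor_without_hydrogen_rejected():
    config = _hbond_unit(0.29, 5.0)
    with pytest.raises(SelectionError):
        find_hydrogen_bonds(config, donors=np.array([[0, 2]]))  # atom 2 is an O


def test_hbond_timeseries_aggregation_and_permutation():
    frames = [make_solvent_box({"water": 1.0}, box=2.5, total_molecules=150, seed=s)[0]
              for s in (0, 1, 2)]
    # same topology (same counts/ordering), different coordinates
    series = hbond_timeseries(frames)
    assert len(series) == 3
    reversed_series = hbond_timeseries(frames[::-1])
    assert sorted(series["total"]) == sorted(reversed_series["total"])
    same = hbond_timeseries([frames[0], frames[0]])
    assert same["total"].std(ddof=1) == 0


def test_hbond_timeseries_topology_mismatch():
    f1, _ = make_solvent_box({"water": 1.0}, box=2.5, total_molecules=100, seed=0)
    f2, _ = make_solvent_box({"water": 1.0}, box=2.5, total_molecules=101, seed=0)
    with pytest.raises(InvalidInputError):
        hbond_timeseries([f1, f2])


# ----------------------------------------------------------------------- RDF


def test_rdf_of_ideal_gas_is_unity_within_counting_bands():
    configs = [
        make_solvent_box({"water": 1.0}, box=4.0, total_molecules=500, seed=s)[0]
        for s in range(3)
    ]
    o = select_atoms(configs[0], element="O")
    spec = RdfSpec(o, o, 0.05, 2.0)
    r, g = radial_distribution(configs, spec)
    mask = r > 0.2
    volume = 4.0**3
    rho = o.size / volume
    shell = 4 * np.pi * r[mask] ** 2 * 0.05
    expected_counts = len(configs) * o.size * rho * shell
    # identical groups double-count each unordered pair, so the effective
    # number of independent counts is half the ordered-pair expectation
    sigma = np.sqrt(2.0 / expected_counts)
    dev = np.abs(g[mask] - 1.0)
    assert np.all(dev < 4 * sigma)
    assert np.mean(dev < 3 * sigma) > 0.95


def test_rdf_two_fixed_atoms_single_bin():
    box = [5.0, 5.0, 5.0]
    d = 1.23
    config = MolecularConfiguration(
        np.array([[1.0, 1.0, 1.0], [1.0 + d, 1.0, 1.0]]),
        ["C", "C"], ["C1", "C2"], [0, 1], ["a", "b"], box,
    )
    spec = RdfSpec([0], [1], 0.02, 2.4)
    r, g = radial_distribution([config], spec)
    occupied = np.flatnonzero(g > 0)
    assert occupied.size == 1
    assert abs(r[occupied[0]] - d) <= 0.02


def test_rdf_coordination_number_conserved_under_rebinning():
    configs = [
        make_solvent_box({"water": 1.0}, box=4.0, total_molecules=400, seed=9)[0]
    ]
    o = select_atoms(configs[0], element="O")
    rho = o.size / 4.0**3
    totals = []
    for bw in (0.05, 0.10):
        r, g = radial_distribution(configs, RdfSpec(o, o, bw, 2.0))
        mask = (r > 0.5) & (r < 1.9)
        totals.append(np.sum(rho * g[mask] * 4 * np.pi * r[mask] ** 2 * bw))
    assert totals[0] == pytest.approx(totals[1], rel=0.05)


def test_rdf_rmax_beyond_half_box_rejected():
    config, _ = make_solvent_box({"water": 1.0}, box=3.0, total_molecules=50, seed=0)
    o = select_atoms(config, element="O")
    with pytest.raises(InvalidInputError):
        radial_distribution([config], RdfSpec(o, o, 0.05, 2.0))


# ---------------------------------------------------------------------- SASA


def test_sasa_single_atom_analytic():
    total, _ = solvent_accessible_area(_single_atom("O"), n_sphere_points=960)
    assert total == pytest.approx(4 * np.pi * (0.152 + 0.14) ** 2, rel=0.01)


def test_sasa_fully_overlapping_atoms_equal_one_atom():
    box = 10.0
    two = MolecularConfiguration(
        np.array([[5.0, 5, 5], [5.0, 5, 5]]), ["O", "O"], ["O1", "O2"],
        [0, 1], ["x", "x"], [box] * 3,
    )
    tot_two, _ = solvent_accessible_area(two)
    tot_one, _ = solvent_accessible_area(_single_atom("O"))
    assert tot_two == pytest.approx(tot_one, rel=1e-9)


def test_sasa_distant_atoms_additive():
    box = 10.0
    two = MolecularConfiguration(
        np.array([[2.0, 5, 5], [8.0, 5, 5]]), ["O", "O"], ["O1", "O2"],
        [0, 1], ["x", "x"], [box] * 3,
    )
    tot_two, per = solvent_accessible_area(two)
    tot_one, _ = solvent_accessible_area(_single_atom("O"))
    assert tot_two == pytest.approx(2 * tot_one, rel=1e-9)
    assert per == pytest.approx([tot_one, tot_one], rel=1e-9)


def test_sasa_point_count_convergence(rng):
    coords = 5.0 + 0.25 * rng.standard_normal((50, 3))
    cluster = MolecularConfiguration(
        coords, ["C"] * 50, [f"C{i}" for i in range(50)],
        list(range(50)), ["x"] * 50, [10.0] * 3,
    )
    coarse, _ = solvent_accessible_area(cluster, n_sphere_points=960)
    fine, _ = solvent_accessible_area(cluster, n_sphere_points=9600)
    assert coarse == pytest.approx(fine, rel=0.01)


def test_sasa_cross_checked_against_mdtraj(rng):
    """Independent oracle: mdtraj's Shrake-Rupley on the same cluster/radii."""
    mdtraj = pytest.importorskip("mdtraj")
    n = 20
    coords = 5.0 + 0.2 * rng.standard_normal((n, 3))
    cluster = MolecularConfiguration(
        coords, ["C"] * n, [f"C{i}" for i in range(n)],
        list(range(n)), ["x"] * n, [50.0] * 3,  # huge box: no PBC effects
    )
    mine, _ = solvent_accessible_area(cluster, n_sphere_points=960)
    top = mdtraj.Topology()
    chain = top.add_chain()
    for i in range(n):
        res = top.add_residue("C", chain)
        top.add_atom(f"C{i}", mdtraj.element.carbon, res)
    traj = mdtraj.Trajectory(coords[None, :, :], top)
    ref = mdtraj.shrake_rupley(traj, probe_radius=0.14, n_sphere_points=960).sum()
    assert mine == pytest.approx(float(ref), rel=0.02)


def test_sasa_missing_radius_named():
    with pytest.raises(InvalidInputError, match="O"):
        solvent_accessible_area(_single_atom("O"), atom_radii={"C": 0.17})


# ------------------------------------------------------------ box accounting


def test_box_mass_fractions_printed_compositions():
    w = box_mass_fractions({"acetone": 954, "water": 1031})
    assert round(100 * w["acetone"]) == 75
    w = box_mass_fractions(
        {"L1": 1, "acetone": 954, "water": 1031}, {"L1": molar_mass("C68H74O22")}
    )
    assert round(100 * w["L1"], 1) == 1.7


def test_box_mass_fractions_single_species_and_errors():
    assert box_mass_fractions({"water": 10}) == {"water": 1.0}
    with pytest.raises(InvalidInputError):
        box_mass_fractions({"water": 0})
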