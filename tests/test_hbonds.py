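"""Geometric H-bond detection, occupancy maps, category summaries."""

import math

import numpy as np
import pytest

from glycoccs.ensemble import AtomRecord, ConformerEnsemble, ResidueAnnotation
from glycoccs.errors import CoverageError, GeometryError
from glycoccs.hbonds import (HBondCriteria, assign_donors_hydrogens,
                             categorize_hbonds, compare_shape_hbonds,
                             detect_hbonds, hbond_occupancy_map)
from glycoccs.synthetic import make_glycan_mimic, plant_hbond

from oracles import brute_force_hbonds


def donor_acceptor_fixture(r_xy: float, theta_deg: float) -> ConformerEnsemble:
    """Donor O (res 1) with H, acceptor O (res 2) at an exact (R, θ)."""
    th = math.radians(theta_deg)
    coords = np.array([
        [0.0, 0.0, 0.0],                              # donor O
        [0.96 * math.cos(th), 0.96 * math.sin(th), 0.0],  # H at angle θ from O→Y
        [r_xy, 0.0, 0.0],                              # acceptor O
        [0.0, 8.0, 0.0],                               # spectator C, res 3
    ])
    atoms = [AtomRecord(0, "O", "O1", 1), AtomRecord(1, "H", "H1", 1),
             AtomRecord(2, "O", "O2", 2), AtomRecord(3, "C", "C1", 3)]
    return ConformerEnsemble(atoms, coords[None])


# ---------------------------------------------------------------------------
# Donor-hydrogen assignment
# ---------------------------------------------------------------------------

def test_hydroxyl_assignment():
    ens = donor_acceptor_fixture(3.0, 10.0)
    assert assign_donors_hydrogens(ens) == [(0, 1)]


def test_nearest_heavy_atom_wins():
    coords = np.array([[0.0, 0.0, 0.0],      # O at 0.97 from H
                       [0.97, 0.0, 0.0],     # H
                       [2.02, 0.0, 0.0]])    # N at 1.05 from H
    atoms = [AtomRecord(0, "O", "O", 1), AtomRecord(1, "H", "H", 1),
             AtomRecord(2, "N", "N", 2)]
    ens = ConformerEnsemble(atoms, coords[None])
    assert assign_donors_hydrogens(ens) == [(0, 1)]


def test_structure_without_hydrogens_is_error():
    atoms = [AtomRecord(0, "O", "O", 1), AtomRecord(1, "O", "O", 2),
             AtomRecord(2, "C", "C", 3)]
    ens = ConformerEnsemble(atoms, np.arange(9.0).reshape(1, 3, 3))
    with pytest.raises(CoverageError, match="no hydrogens"):
        assign_donors_hydrogens(ens)


def test_orphan_hydrogen_is_error():
    atoms = [AtomRecord(0, "O", "O", 1), AtomRecord(1, "H", "H", 1)]
    coords = np.array([[[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]]])
    with pytest.raises(GeometryError, match="orphan"):
        assign_donors_hydrogens(ConformerEnsemble(atoms, coords))


def test_carbon_bound_hydrogen_is_not_a_donor():
    atoms = [AtomRecord(0, "C", "C", 1), AtomRecord(1, "H", "H", 1),
             AtomRecord(2, "O", "O", 2)]
    coords = np.array([[[0.0, 0.0, 0.0], [1.05, 0.0, 0.0], [3.0, 0.0, 0.0]]])
    ens = ConformerEnsemble(atoms, coords)
    assert assign_donors_hydrogens(ens) == []
    assert detect_hbonds(ens) == []


# ---------------------------------------------------------------------------
# Detection against the geometric criterion
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("r,theta,expected", [
    (3.4, 20.0, True),    # inside both bounds
    (3.0, 10.0, True),
    (3.6, 10.0, False),   # distance out of bounds
    (3.4, 35.0, False),   # angle out of bounds
    (3.6, 35.0, False),
])
def test_criterion_boundaries(r, theta, expected):
    bonds = detect_hbonds(donor_acceptor_fixture(r, theta))
    assert (len(bonds) == 1) is expected
    if expected:
        assert bonds[0].distance == pytest.approx(r, abs=1e-9)
        assert bonds[0].angle == pytest.approx(theta, abs=1e-6)


def test_tightening_criteria_never_adds_bonds():
    ens, anno = make_glycan_mimic(2, 3, 3, fucose=True, seed=5)
    loose = len(detect_hbonds(ens, 0, HBondCriteria(r_max=4.5, theta_max=45.0)))
    mid = len(detect_hbonds(ens, 0, HBondCriteria(r_max=3.5, theta_max=30.0)))
    tight = len(detect_hbonds(ens, 0, HBondCriteria(r_max=2.5, theta_max=15.0)))
    assert loose >= mid >= tight


def test_detection_equals_exhaustive_triple_scan():
    """Planted bonds among a branched mimic: detector vs O(N^3) oracle."""
    ens, _ = make_glycan_mimic(3, 4, 3, fucose=True, seed=9)
    ens, _ = plant_hbond(ens, 2, 8, 3.2, 15.0)
    ens, _ = plant_hbond(ens, 4, 9, 2.9, 25.0)
    assert ens.n_atoms <= 200
    got = {(b.donor, b.hydrogen, b.acceptor) for b in detect_hbonds(ens, 0)}
    oracle = brute_force_hbonds(ens.conformer(0), list(ens.elements),
                                ens.residue_indices)
    assert got == oracle
    assert len(got) >= 2  # the planted ones are certainly there


# ---------------------------------------------------------------------------
# Occupancy maps
# ---------------------------------------------------------------------------

def make_occupancy_fixture(n_frames=50, present_in=41):
    ens, anno = make_glycan_mimic(2, 2, 2, seed=4)
    ens = ConformerEnsemble(ens.atoms, np.repeat(ens.coords, n_frames, axis=0))
    ens, planted = plant_hbond(ens, 2, 5, 3.0, 10.0, frames=list(range(present_in)))
    return ens, anno, planted


def test_occupancy_fraction():
    ens, anno, _ = make_occupancy_fixture(50, 41)
    hmap = hbond_occupancy_map(ens, annotation=anno)
    assert hmap.get(2, 5) == pytest.approx(0.82)
    assert hmap.get(5, 2) == hmap.get(2, 5)


def test_occupancy_full_and_matrix_symmetry():
    ens, anno, _ = make_occupancy_fixture(10, 10)
    hmap = hbond_occupancy_map(ens, annotation=anno)
    assert hmap.get(2, 5) == 1.0
    mat = hmap.matrix()
    assert np.array_equal(mat, mat.T)


def test_occupancy_invariant_to_rigid_transform_and_frame_order():
    ens, anno, _ = make_occupancy_fixture(10, 7)
    hmap = hbond_occupancy_map(ens, annotation=anno)
    rng = np.random.default_rng(2)
    # rotate each conformer rigidly by its own random rotation
    coords = ens.coords.copy()
    for f in range(coords.shape[0]):
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        coords[f] = coords[f] @ rot.T + rng.normal(size=3) * 5
    moved = ConformerEnsemble(ens.atoms, coords)
    hmap2 = hbond_occupancy_map(moved, annotation=anno)
    assert hmap2.occupancy.keys() == hmap.occupancy.keys()
    for k in hmap.occupancy:
        assert hmap2.occupancy[k] == pytest.approx(hmap.occupancy[k], abs=1e-12)
    shuffled = ConformerEnsemble(ens.atoms, ens.coords[::-1].copy())
    hmap3 = hbond_occupancy_map(shuffled, annotation=anno)
    assert hmap3.occupancy == hmap.occupancy


# ---------------------------------------------------------------------------
# Categories
# ---------------------------------------------------------------------------

def sparse_base(labels, n_frames=1):
    """Far-separated carbon-only residues: all detected bonds are planted ones."""
    n = len(labels)
    atoms = [AtomRecord(i, "C", "C", residue_index=i + 1) for i in range(n)]
    coords = np.column_stack([20.0 * np.arange(n), 5.0 * np.sin(np.arange(n)),
                              np.zeros(n)])
    ens = ConformerEnsemble(atoms, np.repeat(coords[None], n_frames, axis=0))
    anno = ResidueAnnotation({i + 1: lab for i, lab in enumerate(labels)})
    return ens, anno


GLYCAN_LABELS = ["PA-tag", "core-chitobiose", "core-chitobiose",
                 "alpha1-3-arm", "alpha1-3-arm", "alpha1-3-arm",
                 "alpha1-6-arm", "alpha1-6-arm", "alpha1-6-arm", "fucose"]


def test_intra_arm_only():
    ens, anno = sparse_base(GLYCAN_LABELS, n_frames=4)
    ens, _ = plant_hbond(ens, 4, 5, 3.0, 10.0)   # both residues on the α1-3 arm
    bonds = [detect_hbonds(ens, f) for f in range(4)]
    summary = categorize_hbonds(bonds, anno, ens.residue_indices)
    assert summary.percentages["intra-arm"] == 100.0
    assert sum(summary.percentages.values()) == pytest.approx(100.0)


def test_category_ratio_75_25():
    ens, anno = sparse_base(GLYCAN_LABELS, n_frames=3)
    for acceptor in (7, 8, 9):                    # three core -> α1-6 bonds
        ens, _ = plant_hbond(ens, 2, acceptor, 3.0, 10.0)
    ens, _ = plant_hbond(ens, 3, 4, 3.0, 10.0)    # one core -> α1-3 bond
    bonds = [detect_hbonds(ens, f) for f in range(3)]
    summary = categorize_hbonds(bonds, anno, ens.residue_indices)
    assert summary.percentages["core-alpha1-6"] == pytest.approx(75.0)
    assert summary.percentages["core-alpha1-3"] == pytest.approx(25.0)
    assert summary.avg_count == pytest.approx(4.0)


def test_fucose_bonds_fall_outside_categories():
    ens, anno = sparse_base(GLYCAN_LABELS)
    ens, _ = plant_hbond(ens, 2, 10, 3.0, 10.0)   # core -> fucose
    assert anno.label(10) == "fucose"
    bonds = [detect_hbonds(ens, 0)]
    summary = categorize_hbonds(bonds, anno, ens.residue_indices)
    assert summary.n_other == 1 and summary.n_categorized == 0


def test_categories_match_manual_count():
    ens, anno = make_glycan_mimic(2, 3, 2, fucose=True, seed=10)
    ens, _ = plant_hbond(ens, 2, 7, 3.1, 12.0)   # core -> α1-6
    ens, _ = plant_hbond(ens, 5, 8, 3.0, 8.0)    # α1-3 -> α1-6 (plus any incidental)
    bonds = detect_hbonds(ens, 0)
    summary = categorize_hbonds([bonds], anno, ens.residue_indices)
    manual = {c: 0 for c in summary.percentages}
    other = 0
    pair_cat = {frozenset({"core-chitobiose", "alpha1-6-arm"}): "core-alpha1-6",
                frozenset({"core-chitobiose", "alpha1-3-arm"}): "core-alpha1-3",
                frozenset({"alpha1-3-arm", "alpha1-6-arm"}): "alpha1-3-alpha1-6"}
    for b in bonds:
        ui = anno.label(int(ens.residue_indices[b.donor]))
        uj = anno.label(int(ens.residue_indices[b.acceptor]))
        ui = "core-chitobiose" if ui == "PA-tag" else ui
        uj = "core-chitobiose" if uj == "PA-tag" else uj
        if "fucose" in (ui, uj):
            other += 1
        elif ui == uj:
            manual["intra-arm"] += 1
        else:
            manual[pair_cat[frozenset({ui, uj})]] += 1
    total = sum(manual.values())
    for cat, n in manual.items():
        assert summary.percentages[cat] == pytest.approx(100.0 * n / total)
    assert summary.n_other == other


def test_compare_shape_hbonds_differences():
    ens, anno = make_glycan_mimic(2, 2, 2, seed=11)
    ens3 = ConformerEnsemble(ens.atoms, np.repeat(ens.coords, 2, axis=0))
    ga, _ = plant_hbond(ens3, 2, 4, 3.0, 10.0)
    bonds_g = [detect_hbonds(ga, f) for f in range(2)]
    summary_g = categorize_hbonds(bonds_g, anno, ga.residue_indices)
    diff0 = compare_shape_hbonds(summary_g, summary_g)
    assert all(v == 0.0 for v in diff0.values())
    rod, _ = plant_hbond(ens3, 2, 5, 3.0, 10.0)
    rod, _ = plant_hbond(rod, 3, 6, 3.0, 10.0)
    bonds_r = [detect_hbonds(rod, f) for f in range(2)]
    summary_r = categorize_hbonds(bonds_r, anno, rod.residue_indices)
    diff = compare_shape_hbonds(summary_g, summary_r)
    assert diff["avg_count"] == pytest.approx(summary_g.avg_count - summary_r.avg_count)
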