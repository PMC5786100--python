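"""Superposition, RMSD, clustering, RMSF, shape, weighted distributions."""

import math

import numpy as np
import pytest

from glycoccs.analysis import (cluster_ensemble, major_conformers, rmsd, rmsf,
                               shape_descriptor, superpose,
                               weighted_ccs_distribution)
from glycoccs.ensemble import AtomRecord, ConformerEnsemble
from glycoccs.errors import GeometryError
from glycoccs.synthetic import make_two_state_ensemble

from conftest import bead_chain
from oracles import brute_force_medoid, grid_search_min_rmsd


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


# ---------------------------------------------------------------------------
# Superposition / RMSD
# ---------------------------------------------------------------------------

def test_superpose_recovers_rigid_transform():
    ref = bead_chain(8).coords[0]
    rot = rotation_matrix([1.0, 2.0, 0.5], 1.1)
    mobile = ref @ rot.T + np.array([4.0, -2.0, 7.0])
    _, _, aligned = superpose(ref, mobile)
    assert np.sqrt(((aligned - ref) ** 2).mean()) < 1e-10


def test_superpose_identity_case():
    ref = bead_chain(5).coords[0]
    rot, trans, aligned = superpose(ref, ref)
    assert np.array_equal(rot, np.eye(3))
    assert np.array_equal(trans, np.zeros(3))
    assert np.array_equal(aligned, ref)


def test_superpose_degenerate_geometry_rejected():
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(GeometryError):
        superpose(line, line + 1.0)
    with pytest.raises(GeometryError):
        superpose(np.zeros((2, 3)), np.ones((2, 3)))


def test_superpose_matches_quaternion_grid_search_oracle():
    rng = np.random.default_rng(17)
    ref = rng.normal(size=(10, 3)) * 3.0
    mob = rng.normal(size=(10, 3)) * 3.0
    kabsch = rmsd(ref, mob, fit=True)
    oracle = grid_search_min_rmsd(ref, mob, n_grid=4000, seed=1)
    assert kabsch == pytest.approx(oracle, abs=1e-3)
    assert kabsch <= oracle + 1e-9  # Kabsch is the exact minimizer


def test_rmsd_closed_forms():
    a = bead_chain(4).coords[0]
    assert rmsd(a, a, fit=False) == 0.0
    b = a.copy()
    b[2] += np.array([0.0, 0.0, 3.0])
    assert rmsd(a, b, fit=False) == pytest.approx(1.5)  # sqrt(9/4)


def test_fitted_rmsd_never_exceeds_unfitted():
    rng = np.random.default_rng(5)
    for _ in range(100):
        a = rng.normal(size=(6, 3)) * 2
        b = rng.normal(size=(6, 3)) * 2
        assert rmsd(a, b, fit=True) <= rmsd(a, b, fit=False) + 1e-9


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def test_identical_frames_form_single_cluster():
    base = bead_chain(6)
    ens = ConformerEnsemble(base.atoms, np.repeat(base.coords, 7, axis=0))
    cs = cluster_ensemble(ens, threshold=2.5)
    assert len(cs.clusters) == 1
    assert cs.clusters[0].weight == 1.0


def test_two_state_mixture_recovers_states_and_weights():
    ens, truth = make_two_state_ensemble(n_frames=120, weight_a=0.6,
                                         rmsd_separation=10.0, noise_sigma=0.1,
                                         seed=21)
    cs = cluster_ensemble(ens, threshold=2.5)
    assert len(cs.clusters) == 2
    frac_a = truth.state_counts[0] / 120
    weights = sorted(cs.weights, reverse=True)
    expect = sorted([frac_a, 1 - frac_a], reverse=True)
    assert weights == pytest.approx(expect, abs=1e-12)  # exact label recovery
    labels = np.array(truth.state_labels)
    for c in cs.clusters:
        member_labels = labels[list(c.members)]
        assert len(set(member_labels)) == 1  # pure clusters


def test_medoids_match_exhaustive_oracle():
    rng = np.random.default_rng(3)
    base = bead_chain(5).coords[0]
    coords = np.stack([base + rng.normal(0, 1.2, base.shape) for _ in range(8)])
    atoms = [AtomRecord(i, "C", residue_index=i + 1) for i in range(5)]
    ens = ConformerEnsemble(atoms, coords)
    cs = cluster_ensemble(ens, threshold=3.0)
    # rebuild the aligned coordinates exactly as the clusterer defines them
    aligned = np.empty_like(coords)
    aligned[0] = coords[0]
    for i in range(1, 8):
        _, _, aligned[i] = superpose(coords[0], coords[i])
    for c in cs.clusters:
        oracle = brute_force_medoid(aligned, np.array(c.members),
                                    lambda x, y: rmsd(x, y, fit=True))
        assert c.medoid == oracle


def test_finer_threshold_never_gives_fewer_clusters():
    ens, _ = make_two_state_ensemble(n_frames=60, seed=2, noise_sigma=0.3)
    coarse = cluster_ensemble(ens, threshold=2.5)
    fine = cluster_ensemble(ens, threshold=0.5)
    assert len(fine.clusters) >= len(coarse.clusters)
    for cs in (coarse, fine):
        assert sum(c.weight for c in cs.clusters) == pytest.approx(1.0, abs=1e-12)


def test_cluster_radius_invariants_hold():
    ens, _ = make_two_state_ensemble(n_frames=50, seed=8, noise_sigma=0.4)
    cs = cluster_ensemble(ens, threshold=2.5)
    aligned = np.empty_like(ens.coords)
    aligned[0] = ens.coords[0]
    for i in range(1, 50):
        _, _, aligned[i] = superpose(ens.coords[0], ens.coords[i])
    for c in cs.clusters:
        mem = np.array(c.members)
        centroid = aligned[mem].mean(axis=0)
        for i in mem:
            d = np.sqrt(((aligned[i] - centroid) ** 2).sum() / centroid.shape[0])
            assert d <= cs.threshold + 1e-9
            assert rmsd(aligned[i], aligned[c.medoid], fit=False) <= 2 * cs.threshold + 1e-9


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

def test_rmsf_identical_frames_is_exactly_zero():
    base = bead_chain(5)
    ens = ConformerEnsemble(base.atoms, np.repeat(base.coords, 4, axis=0))
    profile = rmsf(ens)
    assert np.all(profile.values == 0.0)


def test_rmsf_two_frame_closed_form():
    base = bead_chain(6).coords[0]
    moved = base.copy()
    d = 1.4
    moved[3] += np.array([0.0, 0.0, d])
    atoms = [AtomRecord(i, "C", residue_index=i + 1) for i in range(6)]
    ens = ConformerEnsemble(atoms, np.stack([base, moved]))
    profile = rmsf(ens)
    # superposition redistributes a little; the displaced atom dominates
    assert profile.values.argmax() == 3
    # direct-formula oracle on pre-aligned frames: RMSF_i = d/2 for atom 3
    mean = (base + moved) / 2
    direct = np.sqrt((((np.stack([base, moved]) - mean) ** 2).sum(axis=2)).mean(axis=0))
    assert direct[3] == pytest.approx(d / 2)
    assert np.allclose(np.delete(direct, 3), 0.0)


def test_rmsf_matches_direct_formula_on_prealigned_ensemble():
    """On pre-aligned frames the iterated fit is nearly the identity.

    The superposition absorbs 6 rigid-body degrees of freedom out of 3N,
    so the fitted RMSF can undershoot the direct formula by O(6/3N);
    with N = 100 atoms that is ~2%, and the two must agree to ~10%.
    """
    rng = np.random.default_rng(9)
    base = bead_chain(100).coords[0]
    coords = np.stack([base + rng.normal(0, 0.05, base.shape) for _ in range(40)])
    atoms = [AtomRecord(i, "C", residue_index=i + 1) for i in range(100)]
    profile = rmsf(ConformerEnsemble(atoms, coords))
    mean = coords.mean(axis=0)
    direct = np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))
    # the least-squares fit can only shrink the total fluctuation
    assert (profile.values ** 2).sum() <= (direct ** 2).sum() + 1e-9
    assert np.allclose(profile.values, direct, rtol=0.10)


def test_rmsf_requires_two_frames():
    with pytest.raises(GeometryError):
        rmsf(bead_chain(5))


# ---------------------------------------------------------------------------
# Weighted CCS distribution, major conformers
# ---------------------------------------------------------------------------

def two_cluster_set(w0=0.6):
    ens, _ = make_two_state_ensemble(n_frames=10, weight_a=w0, seed=1)
    return cluster_ensemble(ens, threshold=2.5)


def test_weighted_mean_arithmetic():
    cs = two_cluster_set()
    heavy_first = cs.weights[0]
    dist = weighted_ccs_distribution(cs, {0: 400.0, 1: 450.0})
    assert dist.weighted_mean == pytest.approx(400.0 * heavy_first
                                               + 450.0 * (1 - heavy_first))
    assert dist.bin_masses.sum() == pytest.approx(1.0)


def test_single_cluster_point_mass():
    base = bead_chain(5)
    ens = ConformerEnsemble(base.atoms, np.repeat(base.coords, 3, axis=0))
    cs = cluster_ensemble(ens, threshold=2.5)
    dist = weighted_ccs_distribution(cs, {0: 425.0})
    assert dist.support == ((425.0, 1.0),)
    assert dist.weighted_mean == 425.0


def test_weighted_mean_invariant_to_relabeling():
    cs = two_cluster_set()
    d1 = weighted_ccs_distribution(cs, {0: 380.0, 1: 430.0})
    flipped = type(cs)(threshold=cs.threshold, clusters=cs.clusters[::-1],
                       n_conformers=cs.n_conformers)
    d2 = weighted_ccs_distribution(flipped, {0: 430.0, 1: 380.0})
    assert d1.weighted_mean == pytest.approx(d2.weighted_mean)


def test_major_conformers_threshold():
    cs = two_cluster_set(w0=0.9)
    majors = major_conformers(cs, min_fraction=0.10)
    weights = [w for _, w in majors]
    assert weights == sorted(weights, reverse=True)
    assert all(w > 0.10 for w in weights)
    assert major_conformers(cs, min_fraction=0.99) == []


# ---------------------------------------------------------------------------
# Shape descriptors
# ---------------------------------------------------------------------------

def test_collinear_chain_is_rod_like():
    line = np.column_stack([np.arange(6.0), np.zeros(6), np.zeros(6)])
    s = shape_descriptor(line)
    assert s.kappa_squared == pytest.approx(1.0)
    assert s.label == "rod-like"


def test_regular_tetrahedron_is_globular():
    tet = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
    s = shape_descriptor(tet)
    assert s.kappa_squared == pytest.approx(0.0, abs=1e-12)
    assert s.label == "globular"


def test_eigenvalues_match_independent_decomposition():
    rng = np.random.default_rng(12)
    pts = rng.normal(size=(20, 3)) * np.array([3.0, 1.5, 0.5])
    s = shape_descriptor(pts)
    centered = pts - pts.mean(axis=0)
    tensor = centered.T @ centered / 20
    ref = np.sort(np.linalg.eig(tensor)[0].real)[::-1]
    assert np.allclose(s.eigenvalues, ref, atol=1e-10)
    assert s.gyration_radius == pytest.approx(math.sqrt(ref.sum()))


def test_shape_invariant_under_rigid_transform():
    pts = np.random.default_rng(4).normal(size=(15, 3)) * 2
    rot = rotation_matrix([0.3, 1.0, -0.2], 0.8)
    moved = pts @ rot.T + np.array([5.0, 6.0, -7.0])
    s1, s2 = shape_descriptor(pts), shape_descriptor(moved)
    assert s1.kappa_squared == pytest.approx(s2.kappa_squared, abs=1e-12)
    assert s1.gyration_radius == pytest.approx(s2.gyration_radius, abs=1e-10)


def test_degenerate_shape_rejected():
    with pytest.raises(GeometryError):
        shape_descriptor(np.zeros((1, 3)))
    with pytest.raises(GeometryError):
        shape_descriptor(np.zeros((4, 3)))
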