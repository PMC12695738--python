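"""Superposition, subunit shifts and cofactor site matching."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

import chlorofret as cf
from chlorofret.model import Atom, Residue, StructureModel
from chlorofret.synthetic import (
    helical_chain,
    random_rotation,
    transformed_copy,
)
from helpers import make_chl


def two_chain_model(n_core=40, n_sub=20):
    residues = helical_chain("X", n_core, start=(0, 0, 0))
    residues += helical_chain("Y", n_sub, start=(25, 0, 0))
    return StructureModel("two-chain", residues)


def big_model(n=500):
    rng = np.random.default_rng(7)
    residues = [
        Residue("ALA", "X", i + 1, [Atom("CA", "C", rng.uniform(-40, 40, 3))],
                category="protein")
        for i in range(n)
    ]
    return StructureModel("cloud", residues)


def test_pair_atoms_identity_and_unpaired():
    m = two_chain_model()
    pairing = cf.pair_atoms(m, m)
    assert len(pairing) == 60 and not pairing.unpaired_a
    # drop 5 residues from B: they are reported unpaired on the A side
    m2 = StructureModel("b", [r for r in m.residues if not (r.chain_id == "X" and r.seq_id <= 5)])
    pairing2 = cf.pair_atoms(m, m2)
    assert len(pairing2) == 55
    assert len(pairing2.unpaired_a) == 5


def test_pair_atoms_seq_offset():
    m = two_chain_model()
    shifted = StructureModel(
        "off",
        [Residue(r.comp_id, r.chain_id, r.seq_id + 100, r.atoms, r.category)
         for r in m.residues if r.chain_id == "X"],
    )
    pairing = cf.pair_atoms(m, shifted, chain_map={"X": ("X", 100)})
    assert len(pairing) == 40


def test_pair_atoms_needs_three_pairs():
    m = two_chain_model()
    tiny = StructureModel("e", helical_chain("Z", 2))
    with pytest.raises(ValueError, match=">= 3"):
        cf.pair_atoms(m, tiny, chain_map={"X": "Z"})


def test_superpose_self_is_identity():
    m = two_chain_model()
    sup = cf.superpose_models(m, m)
    assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)
    assert np.allclose(sup.translation, 0.0, atol=1e-9)


def test_superpose_recovers_planted_transform(rng):
    m = two_chain_model()
    rot, t = random_rotation(rng), rng.uniform(-10, 10, 3)
    moved = transformed_copy(m, rot, t)
    sup = cf.superpose_models(m, moved)
    assert sup.rmsd < 1e-6
    # recovered transform is the inverse of the planted one
    assert np.allclose(sup.rotation, rot.T, atol=1e-8)
    back = sup.transform_model(moved)
    assert np.allclose(back.coords(), m.coords(), atol=1e-6)
    assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)


def test_superpose_noise_rmsd_expectation(rng):
    """i.i.d. Gaussian noise σ per coordinate → rmsd ≈ σ√3 at large n."""
    m = big_model(500)
    sigma = 0.2
    noisy = transformed_copy(m, noise_sigma=sigma, seed=11)
    sup = cf.superpose_models(m, noisy)
    assert sup.rmsd == pytest.approx(sigma * np.sqrt(3), rel=0.10)


def test_superpose_rejects_collinear():
    residues = [
        Residue("ALA", "X", i, [Atom("CA", "C", (float(i), 0, 0))], category="protein")
        for i in range(10)
    ]
    line = StructureModel("line", residues)
    with pytest.raises(ValueError, match="collinear"):
        cf.superpose_models(line, line)


def test_superposition_rmsd_invariant_under_pretransform(rng):
    m = big_model(200)
    noisy = transformed_copy(m, noise_sigma=0.3, seed=5)
    base = cf.superpose_models(m, noisy).rmsd
    pre = transformed_copy(noisy, random_rotation(rng), rng.uniform(-20, 20, 3))
    assert cf.superpose_models(m, pre).rmsd == pytest.approx(base, rel=1e-6)


def test_subunit_shift_planted_translation():
    m = two_chain_model()
    moved = transformed_copy(m, per_chain_offsets={"Y": np.array([3.0, 0.0, 0.0])})
    shift = cf.subunit_shift(m, moved, core_chain_map={"X": "X"}, subunit_a="Y")
    assert shift.centroid_shift == pytest.approx(3.0, abs=1e-6)
    assert shift.per_atom_rmsd == pytest.approx(3.0, abs=1e-6)
    same = cf.subunit_shift(m, m, core_chain_map={"X": "X"}, subunit_a="Y")
    assert same.centroid_shift == pytest.approx(0.0, abs=1e-9)


def test_subunit_shift_recovery_with_global_transform_and_noise(rng):
    """Planted |t| recovered exactly noise-free, and within 3σ/√n with noise."""
    m = two_chain_model(n_core=300, n_sub=100)
    rot, t = random_rotation(rng), rng.uniform(-15, 15, 3)
    clean = transformed_copy(m, rot, t, per_chain_offsets={"Y": rot @ np.array([0, 2.5, 0])})
    shift = cf.subunit_shift(m, clean, {"X": "X"}, "Y")
    assert shift.centroid_shift == pytest.approx(2.5, abs=1e-6)
    sigma = 0.2
    noisy = transformed_copy(
        m, rot, t, per_chain_offsets={"Y": rot @ np.array([0, 2.5, 0])},
        noise_sigma=sigma, seed=13,
    )
    shift_n = cf.subunit_shift(m, noisy, {"X": "X"}, "Y")
    assert shift_n.centroid_shift == pytest.approx(2.5, abs=3 * sigma / np.sqrt(100) * 3)


def test_subunit_must_not_be_in_core():
    m = two_chain_model()
    with pytest.raises(ValueError, match="excluded from the core"):
        cf.subunit_shift(m, m, {"X": "X", "Y": "Y"}, "Y")


def cofactor_model(centers, comps):
    residues = helical_chain("X", 20, start=(0, 0, -30))
    for i, (c, comp) in enumerate(zip(centers, comps)):
        cat = {"CLA": "chl_a", "KC2": "chl_c", "ALX": "carotenoid"}[comp]
        if cat in ("chl_a", "chl_c"):
            residues.append(
                Residue(comp, "P", 101 + i, [Atom("MG", "Mg", c)], category=cat)
            )
        else:
            residues.append(
                Residue(comp, "P", 101 + i, [Atom("C2", "C", c)], category=cat)
            )
    return StructureModel("cof", residues)


def test_match_sites_identity_is_perfect_regardless_of_order(rng):
    centers = [np.array([10.0 * i, 0, 0]) for i in range(6)]
    m = cofactor_model(centers, ["CLA"] * 6)
    shuffled = StructureModel("shuf", list(m.residues))
    rng.shuffle(shuffled.residues)
    table = cf.match_cofactor_sites(m, shuffled, cf.SuperpositionResult.identity())
    assert len(table.matched) == 6 and not table.only_in_a and not table.only_in_b
    assert all(mt.distance == 0.0 and mt.same_category for mt in table.matched)


def test_match_sites_deletion_and_type_change():
    centers = [np.array([10.0 * i, 0, 0]) for i in range(4)]
    m = cofactor_model(centers, ["CLA"] * 4)
    other = cofactor_model(centers[:-1], ["CLA", "KC2", "CLA"])  # one deleted, one switched
    table = cf.match_cofactor_sites(m, other, cf.SuperpositionResult.identity())
    assert [s for s, _ in table.only_in_a] == [("P", 104, "CLA")]
    changes = [mt for mt in table.matched if not mt.same_category]
    assert len(changes) == 1 and changes[0].site_a == ("P", 102, "CLA")
    assert table.n_differing() == 2


def test_greedy_matching_equals_optimal_assignment(rng):
    """On well-separated sites, greedy = Hungarian optimal assignment."""
    for _ in range(20):
        n = int(rng.integers(2, 7))
        centers = []
        while len(centers) < n:
            p = rng.uniform(-40, 40, 3)
            if all(np.linalg.norm(p - q) > 6.5 for q in centers):  # > 2×match_radius
                centers.append(p)
        jitter = [p + rng.uniform(-0.5, 0.5, 3) for p in centers]
        m = cofactor_model(centers, ["CLA"] * n)
        other = cofactor_model(jitter, ["CLA"] * n)
        table = cf.match_cofactor_sites(
            m, other, cf.SuperpositionResult.identity(), match_radius=3.0
        )
        cost = np.array([[np.linalg.norm(a - b) for b in jitter] for a in centers])
        rows, cols = linear_sum_assignment(cost)
        optimal = {(("P", 101 + i, "CLA"), ("P", 101 + j, "CLA")) for i, j in zip(rows, cols)}
        assert {(mt.site_a, mt.site_b) for mt in table.matched} == optimal
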