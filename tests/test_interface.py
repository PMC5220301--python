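"""Interface descriptors: hydrogen bonds, hydrophobic contacts, distances,
orientation, salt bridges, pi stacks, symmetry, ensemble summaries."""

import numpy as np
import pytest

from dimerscope import (
    com_distance,
    ensemble_summary,
    hydrogen_bonds,
    hydrophobic_contacts,
    pi_stacking,
    quasi_symmetry_score,
    relative_orientation,
    salt_bridges,
)
from dimerscope.structure import DimerModel, Residue, Structure, make_atom

from conftest import dimer_from_residues, single_atom_residue, toy_dimer


def _hb_fixture(d_no: float, angle_deg: float) -> DimerModel:
    """Donor N (with explicit H) on chain A, acceptor O on chain B."""
    n = make_atom(1, "N", 1, [0, 0, 0], residue_name="ALA")
    th = np.radians(angle_deg)
    h = make_atom(2, "H", 1, 0.10 * np.array([np.cos(th), np.sin(th), 0.0]))
    res_a = [Residue(1, "ALA", "A", [n, h])]
    o = make_atom(3, "O", 2, [d_no, 0, 0], residue_name="ALA")
    res_b = [Residue(2, "ALA", "B", [o])]
    return dimer_from_residues(res_a, res_b)


@pytest.mark.parametrize("d,angle,expected", [
    (0.29, 5.0, 1),     # inside both cutoffs
    (0.31, 5.0, 0),     # distance fails
    (0.29, 25.0, 0),    # angle fails
])
def test_hydrogen_bond_cutoffs(d, angle, expected):
    pairs, fallback = hydrogen_bonds(_hb_fixture(d, angle))
    assert len(pairs) == expected
    assert not fallback


def test_hydrogen_bond_heavy_atom_fallback_flagged():
    n = make_atom(1, "N", 1, [0, 0, 0], residue_name="ALA")
    o = make_atom(2, "O", 2, [0.29, 0, 0], residue_name="ALA")
    dimer = dimer_from_residues([Residue(1, "ALA", "A", [n])],
                                [Residue(2, "ALA", "B", [o])])
    pairs, fallback = hydrogen_bonds(dimer)
    assert len(pairs) == 1 and fallback


def test_hydrogen_bond_count_monotone_in_cutoff():
    dimer = toy_dimer(3, n_atoms=20, names=("N", "O"))
    counts = [len(hydrogen_bonds(dimer, d_cut=c)[0]) for c in (0.2, 0.3, 0.4)]
    assert counts == sorted(counts)


def test_hydrophobic_contact_distance_rule():
    near = dimer_from_residues(
        [single_atom_residue("C", "ALA", 1, "A", [0, 0, 0])],
        [single_atom_residue("C", "ALA", 1, "B", [0.37, 0, 0])])
    far = dimer_from_residues(
        [single_atom_residue("C", "ALA", 1, "A", [0, 0, 0])],
        [single_atom_residue("C", "ALA", 1, "B", [0.39, 0, 0])])
    assert hydrophobic_contacts(near)[0] == 1
    assert hydrophobic_contacts(far)[0] == 0


@pytest.mark.parametrize("seed", range(5))
def test_hydrophobic_contacts_match_brute_force(seed):
    dimer = toy_dimer(seed, n_atoms=25)
    xa = np.array([a.coords for a in dimer.atoms_a()])
    xb = np.array([a.coords for a in dimer.atoms_b()])
    d = np.linalg.norm(xa[:, None] - xb[None, :], axis=2)
    oracle = int((d.min(axis=1) <= 0.38).sum())
    assert hydrophobic_contacts(dimer)[0] == oracle


def test_hc_count_monotone_in_cutoff():
    dimer = toy_dimer(9)
    counts = [hydrophobic_contacts(dimer, d_cut=c)[0]
              for c in (0.3, 0.38, 0.5)]
    assert counts == sorted(counts)


def test_com_distance_cases(helix_dimer):
    dimer, ann = helix_dimer
    # identical monomers translated by the separation
    assert com_distance(dimer) == pytest.approx(ann.separation_nm, abs=0.05)
    # superposed monomers -> 0
    res_a = [single_atom_residue("C", "ALA", 1, "A", [1, 1, 1])]
    res_b = [single_atom_residue("C", "ALA", 1, "B", [1, 1, 1])]
    assert com_distance(dimer_from_residues(res_a, res_b)) == 0
    # hand-built 3-atom monomers against explicit arithmetic
    a = [single_atom_residue("C", "ALA", i, "A", xyz) for i, xyz in
         enumerate([[0, 0, 0], [1, 0, 0], [0, 1, 0]], start=1)]
    b = [single_atom_residue("C", "ALA", i, "B", xyz) for i, xyz in
         enumerate([[3, 0, 0], [4, 0, 0], [3, 1, 0]], start=1)]
    assert com_distance(dimer_from_residues(a, b)) == pytest.approx(3.0)


def _rotate_chain(dimer: DimerModel, chain: str, deg: float) -> DimerModel:
    st = dimer.structure.copy()
    atoms = st.atoms([chain])
    center = np.mean([a.coords for a in atoms], axis=0)
    th = np.radians(deg)
    c, s = np.cos(th), np.sin(th)
    R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    for a in atoms:
        a.coords = R @ (a.coords - center) + center
    return DimerModel(st, dimer.monomer_a, dimer.monomer_b)


def test_relative_orientation_zero_seventy_and_oracle(helix_dimer):
    dimer, _ = helix_dimer
    assert relative_orientation(dimer, dimer) == pytest.approx(0.0, abs=1e-4)
    rotated = _rotate_chain(dimer, "B", 70.0)
    assert relative_orientation(rotated, dimer) == pytest.approx(70.0, abs=1e-6)
    # random rotation: equals arccos((trace(R)-1)/2)
    rng = np.random.default_rng(4)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = 37.5
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    th = np.radians(ang)
    R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * K @ K
    st = dimer.structure.copy()
    atoms = st.atoms(["B"])
    center = np.mean([a.coords for a in atoms], axis=0)
    for a in atoms:
        a.coords = R @ (a.coords - center) + center
    oracle = np.degrees(np.arccos((np.trace(R) - 1) / 2))
    got = relative_orientation(DimerModel(st, ["A"], ["B"]), dimer)
    assert got == pytest.approx(oracle, abs=1e-6)


def test_salt_bridges_planted_and_pulled(helix_dimer):
    """The planted K101-E107 / E98-R97 style bridges are recovered exactly,
    and vanish when the cutoff is tightened below their planted distance."""
    dimer, ann = helix_dimer
    got = set()
    for basic, acidic, d in salt_bridges(dimer):
        got.add(frozenset({basic[1], acidic[1]}))
        assert d <= 0.4
    assert got == {frozenset(p) for p in ann.planted_salt_bridges}
    assert salt_bridges(dimer, d_cut=0.2) == []


def test_salt_bridges_match_brute_force():
    rng = np.random.default_rng(12)
    res_a, res_b = [], []
    for i in range(8):
        name = ["LYS", "GLU"][i % 2]
        atom_name = "NZ" if name == "LYS" else "OE1"
        res_a.append(single_atom_residue(atom_name, name, i + 1, "A",
                                         rng.uniform(0, 1.2, 3)))
        name_b = ["GLU", "LYS"][i % 2]
        atom_b = "OE1" if name_b == "GLU" else "NZ"
        res_b.append(single_atom_residue(atom_b, name_b, i + 1, "B",
                                         rng.uniform(0, 1.2, 3)))
    dimer = dimer_from_residues(res_a, res_b)
    got = {(b[:2], a[:2]) for b, a, _ in salt_bridges(dimer)}
    oracle = set()
    for ra in res_a + res_b:
        for rb in (res_b if ra.chain_id == "A" else res_a):
            basic, acidic = (ra, rb) if ra.name == "LYS" else (rb, ra)
            if basic.name != "LYS" or acidic.name != "GLU":
                continue
            d = np.linalg.norm(basic.atoms[0].coords - acidic.atoms[0].coords)
            if d <= 0.4:
                oracle.add(((basic.chain_id, basic.index),
                            (acidic.chain_id, acidic.index)))
    assert got == oracle


def _ring(resname, resid, chain, centroid, normal, serial0):
    from dimerscope.elements import AROMATIC_RING_ATOMS
    names = AROMATIC_RING_ATOMS[resname]
    normal = np.asarray(normal, float)
    normal /= np.linalg.norm(normal)
    ref = np.array([0, 0, 1.0]) if abs(normal[2]) < 0.9 else np.array([1.0, 0, 0])
    v1 = np.cross(normal, ref)
    v1 /= np.linalg.norm(v1)
    v2 = np.cross(normal, v1)
    atoms = []
    for k, nm in enumerate(names):
        ang = 2 * np.pi * k / len(names)
        pos = centroid + 0.12 * (np.cos(ang) * v1 + np.sin(ang) * v2)
        atoms.append(make_atom(serial0 + k, nm, resid, pos,
                               residue_name=resname))
    return Residue(resid, resname, chain, atoms)


def test_pi_stacking_geometry_classes():
    parallel = dimer_from_residues(
        [_ring("HIS", 1, "A", np.zeros(3), [0, 0, 1], 1)],
        [_ring("TYR", 2, "B", np.array([0, 0, 0.40]), [0, 0, 1], 10)])
    hits = pi_stacking(parallel)
    assert len(hits) == 1 and hits[0][4] == "parallel"
    far = dimer_from_residues(
        [_ring("HIS", 1, "A", np.zeros(3), [0, 0, 1], 1)],
        [_ring("TYR", 2, "B", np.array([0, 0, 0.70]), [0, 0, 1], 10)])
    assert pi_stacking(far) == []
    tshape = dimer_from_residues(
        [_ring("HIS", 1, "A", np.zeros(3), [0, 0, 1], 1)],
        [_ring("TYR", 2, "B", np.array([0, 0, 0.50]), [1, 0, 0], 10)])
    hits = pi_stacking(tshape)
    assert len(hits) == 1 and hits[0][4] == "t-shaped"
    assert hits[0][3] == pytest.approx(90.0, abs=1e-6)


def test_pi_stacking_incomplete_ring_skipped():
    ring = _ring("HIS", 1, "A", np.zeros(3), [0, 0, 1], 1)
    ring.atoms = ring.atoms[:-1]
    other = _ring("TYR", 2, "B", np.array([0, 0, 0.4]), [0, 0, 1], 10)
    with pytest.warns(UserWarning):
        assert pi_stacking(dimer_from_residues([ring], [other])) == []


def test_quasi_symmetry_set_arithmetic():
    from dimerscope.sasa import DeltaSasaResult, SasaResult

    def fake_dsasa(set_a, set_b):
        empty = SasaResult(np.zeros(1), {}, 0.0, 0.14, 60)
        return DeltaSasaResult(0.0, {}, sorted(set_a), sorted(set_b),
                               empty, empty, empty)

    dimer = dimer_from_residues(
        [single_atom_residue("C", "ALA", 1, "A", [0, 0, 0])],
        [single_atom_residue("C", "ALA", 1, "B", [5, 0, 0])])
    assert quasi_symmetry_score(dimer, fake_dsasa({94, 95, 101},
                                                  {94, 95, 101})) == 1.0
    assert quasi_symmetry_score(dimer, fake_dsasa({1, 2}, {3, 4})) == 0.0
    assert quasi_symmetry_score(dimer, fake_dsasa({94, 95, 101},
                                                  {94, 107})) == 0.25


def test_quasi_symmetry_rejects_heterodimer():
    dimer = dimer_from_residues(
        [single_atom_residue("C", "ALA", 1, "A", [0, 0, 0])],
        [single_atom_residue("C", "GLY", 1, "B", [5, 0, 0])])
    with pytest.raises(ValueError):
        quasi_symmetry_score(dimer)


def test_ensemble_summary_running_average_and_moments():
    const = ensemble_summary([2.0] * 10, window=3)
    np.testing.assert_allclose(const.running_average, 2.0)
    alt = ensemble_summary([0.0, 1.0] * 5, window=2)
    np.testing.assert_allclose(alt.running_average[:-1], 0.5)
    rng = np.random.default_rng(8)
    x = rng.normal(3.0, 0.5, 200)
    s = ensemble_summary(x, window=11)
    assert s.mean == pytest.approx(x.mean())
    assert s.sd == pytest.approx(x.std())
    with pytest.warns(UserWarning):
        wide = ensemble_summary([1.0, 2.0], window=10)
    np.testing.assert_allclose(wide.running_average, 1.5)


def test_metrics_invariant_under_rigid_motion(helix_dimer):
    dimer, _ = helix_dimer
    st = dimer.structure.copy()
    th = np.radians(33.0)
    c, s = np.cos(th), np.sin(th)
    R = np.array([[c, 0, s], [0, 1.0, 0], [-s, 0, c]])
    t = np.array([3.0, -2.0, 1.0])
    for a in st.atoms():
        a.coords = R @ a.coords + t
    moved = DimerModel(st, ["A"], ["B"])
    assert com_distance(moved) == pytest.approx(com_distance(dimer), abs=1e-9)
    assert hydrophobic_contacts(moved)[0] == hydrophobic_contacts(dimer)[0]
    assert len(salt_bridges(moved)) == len(salt_bridges(dimer))
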