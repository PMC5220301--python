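"""Pose RMSD, leader clustering, enrichment rule and viability filters."""

import numpy as np
import pytest

from dimerscope import (
    FixturePlan,
    apply_filters,
    cluster_poses,
    filter_effector_exposure,
    filter_interface_composition,
    filter_membrane_competence,
    pairwise_pose_rmsd,
    synth_pose_ensemble,
)
from dimerscope.posefilter import PoseEnsemble, PoseError, pose_rmsd
from dimerscope.structure import DimerModel, Structure
from dimerscope.synth import _rot, _transform_chain, build_pose_monomer

SMALL_PLAN = FixturePlan(n_poses=60, cluster_fractions=[0.2, 0.15, 0.12,
                                                        0.1, 0.09, 0.07])


@pytest.fixture(scope="module")
def small_ensemble():
    return synth_pose_ensemble(SMALL_PLAN)


@pytest.fixture(scope="module")
def clustered(small_ensemble):
    ensemble, key = small_ensemble
    matrix = pairwise_pose_rmsd(ensemble)
    return ensemble, key, matrix, cluster_poses(matrix)


def _pose(monomer, R, t):
    a = _transform_chain(monomer, np.eye(3), np.zeros(3), "A")
    b = _transform_chain(monomer, R, t, "B")
    return DimerModel(Structure({"A": a, "B": b}), ["A"], ["B"])


@pytest.fixture(scope="module")
def monomer():
    return build_pose_monomer(FixturePlan())


def test_pose_rmsd_duplicate_and_translation(monomer):
    p = _pose(monomer, np.eye(3), np.array([1.05, 0, 0]))
    q = _pose(monomer, np.eye(3), np.array([1.05, 0, 0]))
    assert pose_rmsd(p, q) == pytest.approx(0.0, abs=1e-9)
    shifted = _pose(monomer, np.eye(3), np.array([1.05, 0, 1.0]))
    assert pose_rmsd(p, shifted) == pytest.approx(1.0, abs=1e-9)


def test_pose_rmsd_label_swap_symmetric(monomer):
    p = _pose(monomer, np.eye(3), np.array([1.05, 0, 0]))
    st = p.structure
    swapped = DimerModel(st, ["B"], ["A"])
    assert pose_rmsd(p, swapped) == pytest.approx(0.0, abs=1e-6)


def test_clustering_recovers_planted_memberships(clustered):
    ensemble, key, matrix, cs = clustered
    planted = [m for m in key.memberships if m >= 0]
    agree = 0
    for cid in set(planted):
        idx = [i for i, m in enumerate(key.memberships) if m == cid]
        votes = np.bincount(cs.labels[idx])
        agree += votes.max()
    assert agree / len(planted) >= 0.95


def test_clustering_is_a_partition(clustered):
    _, _, matrix, cs = clustered
    assert (cs.labels >= 0).all()
    total = sum(len(c.members) for c in cs.clusters)
    assert total == matrix.shape[0]
    assert sum(c.enrichment for c in cs.clusters) == pytest.approx(1.0,
                                                                   abs=1e-12)


def test_all_identical_poses_single_cluster():
    m = np.zeros((5, 5))
    cs = cluster_poses(m)
    assert len(cs.clusters) == 1
    assert cs.clusters[0].enrichment == 1.0
    assert not cs.clusters[0].minor


def test_five_percent_rule_flags_small_cluster():
    # 4 tight poses among 100 -> 4% -> minor under the 5% cutoff
    n = 100
    m = np.full((n, n), 5.0)
    np.fill_diagonal(m, 0.0)
    m[:4, :4] = 0.01
    np.fill_diagonal(m[:4, :4], 0.0)
    cs = cluster_poses(m, radius=0.4, min_enrichment=0.05)
    four = next(c for c in cs.clusters if len(c.members) == 4)
    assert four.minor
    assert four.enrichment == pytest.approx(0.04)


def test_representative_minimises_intra_cluster_rmsd():
    m = np.array([[0.0, 0.1, 0.3],
                  [0.1, 0.0, 0.2],
                  [0.3, 0.2, 0.0]])
    cs = cluster_poses(m, radius=0.5)
    assert cs.clusters[0].representative == 1


def test_cluster_radius_validation():
    with pytest.raises(PoseError):
        cluster_poses(np.zeros((3, 3)), radius=0.0)
    with pytest.raises(PoseError):
        cluster_poses(np.zeros((3, 4)))


def test_tightening_radius_never_merges_clusters(clustered):
    _, _, matrix, _ = clustered
    wide = cluster_poses(matrix, radius=0.6)
    tight = cluster_poses(matrix, radius=0.2)
    assert len(tight.clusters) >= len(wide.clusters)


def test_filter_verdicts_on_designed_poses(monomer):
    plan = FixturePlan()
    hotspots = sorted({p for pair in plan.salt_bridge_pairs for p in pair})
    good = _pose(monomer, np.eye(3), np.array([1.05, 0, 0]))
    ok, reason = filter_interface_composition(good, hotspots, [],
                                              n_sphere_points=240)
    assert ok
    ok, _ = filter_effector_exposure(good, plan.loop_range,
                                     n_sphere_points=240)
    assert ok
    ok, _ = filter_membrane_competence(good, plan.anchor_residue,
                                       n_sphere_points=240)
    assert ok

    # anchors flipped to opposite faces
    zspan = (plan.helix_end - plan.helix_start) * 0.15
    flipped = _pose(monomer, _rot("x", 180.0),
                    np.array([1.05, 0, zspan + 0.6]))
    ok, reason = filter_membrane_competence(flipped, plan.anchor_residue,
                                            n_sphere_points=240)
    assert not ok and "opposite" in reason

    # loop-only contact: no reactive helix residue in the interface
    loops = _pose(monomer, _rot("z", 180.0), np.array([0.55, 3.2, 0]))
    ok, reason = filter_interface_composition(loops, hotspots, [],
                                              n_sphere_points=240)
    assert not ok


def test_loop_only_reason_when_reactive_residue_is_coil(monomer):
    plan = FixturePlan()
    loops = _pose(monomer, _rot("z", 180.0), np.array([0.55, 3.2, 0]))
    # declare the loop residues themselves reactive: composition now fails
    # purely on secondary structure
    reactive = list(range(plan.loop_range[0], plan.anchor_residue + 1))
    ok, reason = filter_interface_composition(loops, [], reactive,
                                              n_sphere_points=240)
    assert not ok and reason == "loop-only interface"


def test_apply_filters_six_to_four(clustered):
    ensemble, key, _, cs = clustered
    survivors, audit = apply_filters(
        cs, ensemble, key.hotspot_residues, [],
        effector_range=key.loop_range, anchor_residue=key.anchor_residue,
        n_sphere_points=240)
    assert len(survivors) == 4
    failed = {a.cluster_id: name for a in audit
              for name, (ok, _) in a.verdicts.items()
              if not ok and not a.minor}
    for cid, fname in key.intended_filter_failures.items():
        assert failed[cid] == fname


def test_apply_filters_empty_and_minor_promotion(small_ensemble):
    ensemble, key = small_ensemble
    empty = PoseEnsemble(poses=[])
    from dimerscope.posefilter import ClusterSet
    cs = ClusterSet(labels=np.array([], dtype=int), clusters=[], radius=0.4,
                    min_enrichment=0.05)
    survivors, audit = apply_filters(cs, empty, [], [])
    assert survivors == [] and audit == []


def test_filter_verdicts_invariant_to_pose_order(clustered):
    ensemble, key, matrix, cs = clustered
    perm = np.random.default_rng(1).permutation(len(ensemble.poses))
    shuffled = PoseEnsemble(poses=[ensemble.poses[i] for i in perm])
    m2 = matrix[np.ix_(perm, perm)]
    cs2 = cluster_poses(m2)
    s1, _ = apply_filters(cs, ensemble, key.hotspot_residues, [],
                          effector_range=key.loop_range,
                          anchor_residue=key.anchor_residue,
                          n_sphere_points=240)
    s2, _ = apply_filters(cs2, shuffled, key.hotspot_residues, [],
                          effector_range=key.loop_range,
                          anchor_residue=key.anchor_residue,
                          n_sphere_points=240)
    assert len(s1) == len(s2)


def test_all_scatter_ensemble_has_no_major_cluster():
    plan = FixturePlan(n_poses=30, cluster_fractions=[])
    ensemble, key = synth_pose_ensemble(plan)
    cs = cluster_poses(pairwise_pose_rmsd(ensemble))
    assert all(c.minor for c in cs.clusters)
    with pytest.warns(UserWarning):
        survivors, _ = apply_filters(cs, ensemble, key.hotspot_residues, [],
                                     effector_range=key.loop_range,
                                     anchor_residue=key.anchor_residue,
                                     n_sphere_points=60)
    assert survivors == []
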