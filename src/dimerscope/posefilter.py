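"""Docked-pose clustering and empirical viability filters for homodimer
models.

Poses are clustered by interface RMSD (superpose monomer A, measure
C-alpha RMSD over monomer B, minimised over the two monomer label
assignments of the homodimer) with greedy leader clustering; clusters below
an enrichment cutoff (default 5% of the ensemble) are flagged minor. The
three viability filters are: (i) the interface involves reactive or
co-evolving residues and is not made up solely of flexible loops, (ii) the
effector-binding loop of each protomer stays solvent exposed, and (iii) the
C-terminal lipid-anchor residues of both protomers point into the same
half-space and are exposed, so both anchors can insert into one membrane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import center_of_mass, kabsch_superpose
from .sasa import DeltaSasaResult, delta_sasa, relative_residue_sasa
from .structure import DimerModel


class PoseError(ValueError):
    pass


@dataclass
class PoseEnsemble:
    poses: list[DimerModel]
    scores: list[float] | None = None

    def __post_init__(self) -> None:
        if self.poses:
            n0 = len(self.poses[0].atoms_a()) + len(self.poses[0].atoms_b())
            for p in self.poses[1:]:
                if len(p.atoms_a()) + len(p.atoms_b()) != n0:
                    raise PoseError("poses differ in topology")

    def __len__(self) -> int:
        return len(self.poses)


@dataclass
class Cluster:
    members: list[int]
    representative: int
    enrichment: float
    minor: bool


@dataclass
class ClusterSet:
    labels: np.ndarray           # cluster id per pose
    clusters: list[Cluster]
    radius: float
    min_enrichment: float


def _ca_coords(pose: DimerModel) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([at.coords for at in pose.atoms_a() if at.name == "CA"])
    b = np.array([at.coords for at in pose.atoms_b() if at.name == "CA"])
    return a, b


def pose_rmsd(p: DimerModel, q: DimerModel) -> float:
    """Interface RMSD between two homodimer poses (nm).

    Monomer A of ``p`` is superposed on monomer A of ``q`` and the C-alpha
    RMSD over monomer B reported; for homodimers the minimum over the two
    monomer assignments (A->A/B->B vs A->B/B->A) is taken so label-swapped
    symmetric poses compare as identical.
    """
    pa, pb = _ca_coords(p)
    qa, qb = _ca_coords(q)
    if pa.shape != qa.shape or pb.shape != qb.shape:
        raise PoseError("pose topologies differ")

    def one(mob_a, mob_b, tgt_a, tgt_b) -> float:
        R, t, _ = kabsch_superpose(mob_a, tgt_a)
        diff = (mob_b @ R.T + t) - tgt_b
        return float(np.sqrt((diff ** 2).sum() / len(mob_b)))

    direct = one(pa, pb, qa, qb)
    if pa.shape == qb.shape and pb.shape == qa.shape:
        swapped = one(pa, pb, qb, qa)
        return min(direct, swapped)
    return direct


def pairwise_pose_rmsd(ensemble: PoseEnsemble) -> np.ndarray:
    """Symmetric matrix of pose RMSDs (nm)."""
    n = len(ensemble)
    if n < 2:
        raise PoseError("need at least 2 poses")
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pose_rmsd(ensemble.poses[i], ensemble.poses[j])
    return m


def cluster_poses(matrix: np.ndarray, radius: float = 0.4,
                  min_enrichment: float = 0.05) -> ClusterSet:
    """Greedy leader clustering of a pose RMSD matrix.

    Leaders are chosen in descending density order (number of unassigned
    poses within ``radius``); each leader claims every unassigned pose
    within the radius. The representative of a cluster is the member
    minimising the summed intra-cluster RMSD (ties -> lowest pose index);
    clusters whose enrichment (size/ensemble size) is below
    ``min_enrichment`` are flagged minor.
    """
    matrix = np.asarray(matrix, float)
    if radius <= 0:
        raise PoseError("radius must be positive")
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise PoseError("matrix must be square")
    n = matrix.shape[0]
    within = matrix <= radius
    unassigned = np.ones(n, dtype=bool)
    labels = np.full(n, -1, dtype=int)
    clusters: list[Cluster] = []
    while unassigned.any():
        density = (within & unassigned[None, :]).sum(axis=1)
        density[~unassigned] = -1
        leader = int(np.argmax(density))   # argmax is lowest index on ties
        members = np.flatnonzero(within[leader] & unassigned)
        labels[members] = len(clusters)
        unassigned[members] = False
        sub = matrix[np.ix_(members, members)]
        rep = int(members[np.argmin(sub.sum(axis=1))])
        enrichment = len(members) / n
        clusters.append(Cluster(members=[int(i) for i in members],
                                representative=rep, enrichment=enrichment,
                                minor=enrichment < min_enrichment))
    return ClusterSet(labels=labels, clusters=clusters, radius=radius,
                      min_enrichment=min_enrichment)


# ---------------------------------------------------------------------------
# viability filters
# ---------------------------------------------------------------------------

def _interface_residues(pose: DimerModel, dsasa: DeltaSasaResult | None,
                        **sasa_kwargs) -> tuple[DeltaSasaResult, set[int], set[int]]:
    if dsasa is None:
        dsasa = delta_sasa(pose, **sasa_kwargs)
    return dsasa, set(dsasa.interfacial_residues_a), set(dsasa.interfacial_residues_b)


def filter_interface_composition(pose: DimerModel, hotspots: list[int],
                                 reactive_surfaces: list[int],
                                 dsasa: DeltaSasaResult | None = None,
                                 **sasa_kwargs) -> tuple[bool, str]:
    """Filter (i): the interface must touch a co-evolving hotspot or a
    reactive-surface residue and contain at least one helix or strand
    residue (i.e. not be made up solely of flexible loops)."""
    dsasa, ifa, ifb = _interface_residues(pose, dsasa, **sasa_kwargs)
    interface = ifa | ifb
    reactive = set(hotspots) | set(reactive_surfaces)
    if not interface & reactive:
        return False, "no reactive residue in interface"
    ss = {}
    for r in pose.residues_a() + pose.residues_b():
        if r.index in interface:
            ss[(r.chain_id, r.index)] = r.secondary_structure
    if not any(v in ("helix", "strand") for v in ss.values()):
        return False, "loop-only interface"
    return True, "ok"


def filter_effector_exposure(pose: DimerModel,
                             effector_range: tuple[int, int] = (25, 40),
                             exposure_cut: float = 0.25,
                             dsasa: DeltaSasaResult | None = None,
                             **sasa_kwargs) -> tuple[bool, str]:
    """Filter (ii): mean relative SASA of the effector-binding loop, in the
    dimer, must reach ``exposure_cut`` for BOTH protomers."""
    dsasa, _, _ = _interface_residues(pose, dsasa, **sasa_kwargs)
    lo, hi = effector_range
    for label, residues in (("A", pose.residues_a()), ("B", pose.residues_b())):
        sel = [r for r in residues if lo <= r.index <= hi]
        if not sel:
            raise PoseError(f"effector range {lo}-{hi} outside protomer {label}")
        rels = [relative_residue_sasa(
            r.name, dsasa.sasa_dimer.per_residue_area.get(r.key, 0.0))
            for r in sel]
        if float(np.mean(rels)) < exposure_cut:
            return False, f"effector loop buried on protomer {label}"
    return True, "ok"


def filter_membrane_competence(pose: DimerModel, anchor_residue: int,
                               exposure_cut: float = 0.25,
                               dsasa: DeltaSasaResult | None = None,
                               **sasa_kwargs) -> tuple[bool, str]:
    """Filter (iii): the C-terminal lipid-anchor residues of both protomers
    must be able to insert into one membrane.

    Geometric test: the anchor direction of each protomer (anchor C-alpha
    minus the protomer's centre of mass) must point into the same half-space
    (positive dot product) and both anchors must be solvent exposed
    (relative SASA >= ``exposure_cut`` in the dimer)."""
    dsasa, _, _ = _interface_residues(pose, dsasa, **sasa_kwargs)
    dirs, anchors = [], []
    for residues, atoms in ((pose.residues_a(), pose.atoms_a()),
                            (pose.residues_b(), pose.atoms_b())):
        match = [r for r in residues if r.index == anchor_residue]
        if not match:
            raise PoseError(f"anchor residue {anchor_residue} missing")
        r = match[0]
        ca = r.atom("CA") or r.atoms[0]
        dirs.append(ca.coords - center_of_mass(atoms))
        anchors.append(r)
    if float(dirs[0] @ dirs[1]) <= 0:
        return False, "anchors point to opposite faces"
    for r in anchors:
        area = dsasa.sasa_dimer.per_residue_area.get(r.key, 0.0)
        if relative_residue_sasa(r.name, area) < exposure_cut:
            return False, f"anchor buried on chain {r.chain_id}"
    return True, "ok"


@dataclass
class FilterAudit:
    cluster_id: int
    enrichment: float
    minor: bool
    promoted: bool
    verdicts: dict[str, tuple[bool, str]] = field(default_factory=dict)
    survives: bool = False


def apply_filters(clusters: ClusterSet, ensemble: PoseEnsemble,
                  hotspots: list[int], reactive_surfaces: list[int],
                  effector_range: tuple[int, int] = (25, 40),
                  anchor_residue: int | None = None,
                  exposure_cut: float = 0.25,
                  promote_minor: list[int] | None = None,
                  **sasa_kwargs) -> tuple[list[int], list[FilterAudit]]:
    """Apply the three viability filters to every major-cluster
    representative pose.

    Minor clusters are excluded by the enrichment rule unless their id is in
    ``promote_minor`` (the manual-promotion override). Returns the indices
    of surviving representative poses and a full audit table with one row
    per cluster and each filter's verdict and reason.
    """
    promote = set(promote_minor or [])
    survivors: list[int] = []
    audit: list[FilterAudit] = []
    for cid, cl in enumerate(clusters.clusters):
        row = FilterAudit(cluster_id=cid, enrichment=cl.enrichment,
                          minor=cl.minor, promoted=cid in promote)
        if cl.minor and cid not in promote:
            row.verdicts["enrichment"] = (
                False, f"minor cluster ({cl.enrichment:.1%} < "
                       f"{clusters.min_enrichment:.0%})")
            audit.append(row)
            continue
        pose = ensemble.poses[cl.representative]
        dsasa = delta_sasa(pose, **sasa_kwargs)
        row.verdicts["interface_composition"] = filter_interface_composition(
            pose, hotspots, reactive_surfaces, dsasa=dsasa)
        row.verdicts["effector_exposure"] = filter_effector_exposure(
            pose, effector_range, exposure_cut, dsasa=dsasa)
        if anchor_residue is not None:
            row.verdicts["membrane_competence"] = filter_membrane_competence(
                pose, anchor_residue, exposure_cut, dsasa=dsasa)
        row.survives = all(ok for ok, _ in row.verdicts.values())
        if row.survives:
            survivors.append(cl.representative)
        audit.append(row)
    if not survivors and clusters.clusters:
        warnings.warn("no cluster survived the viability filters")
    return survivors, audit


def audit_rows(audit: list[FilterAudit]) -> list[dict]:
    """Flatten an audit into TSV-ready rows."""
    rows = []
    for a in audit:
        row = {"cluster": a.cluster_id, "enrichment": f"{a.enrichment:.4f}",
               "minor": a.minor, "promoted": a.promoted, "survives": a.survives}
        for name, (ok, reason) in a.verdicts.items():
            row[name] = "pass" if ok else f"fail: {reason}"
        rows.append(row)
    return rows
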