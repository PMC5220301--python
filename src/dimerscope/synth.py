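"""Synthetic fixtures with known ground truth for every pipeline input.

The generators build (i) ideal alpha-helical homodimers with planted
interfacial salt bridges and pi-stacks, (ii) multiple sequence alignments
with planted covarying column pairs, (iii) mean-force profiles from a
Gaussian-well PMF of known depth (hence known Kd), and (iv) docked-pose
ensembles with planted clusters, some designed to violate the viability
filters, plus clustered / completely random 2-D point patterns (via
``spatial.simulate_pattern``). Every generator is a pure function of its
plan and seed.

Helices are poly-alanine built from ideal internal coordinates
(phi = -57 deg, psi = -47 deg; 3.6 residues/turn, 0.15 nm rise) with
charged or aromatic residues planted at literature-style positions (94, 95,
97, 98, 101, 102, 107, 128, 133, 135-137) so tests read like the study
system they emulate. Planted side chains are placed geometrically (atoms
spaced along the line from the beta carbon to the planned contact point) —
they are synthetic stand-ins, not rotamer-library conformers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coevolution import MSA
from .structure import DimerModel, Residue, Structure, make_atom
from .geometry import fit_axis
from .posefilter import PoseEnsemble
from .thermo import (
    MeanForceProfile,
    PMFProfile,
    R_KCAL,
    STANDARD_VOLUME_NM3,
    dg_from_kd,
)

# default planted residue identities (position -> 3-letter code);
# everything else is alanine
DEFAULT_PLANTED_RESIDUES: dict[int, str] = {
    94: "HIS", 95: "HIS", 97: "ARG", 98: "GLU", 101: "LYS", 102: "ARG",
    107: "GLU", 128: "LYS", 133: "GLU", 135: "GLU", 136: "LYS", 137: "TYR",
}


@dataclass
class FixturePlan:
    """Parameters of the synthetic study system; fully determines every
    generated fixture given the seed."""

    seed: int = 0
    # helix dimer geometry
    helix_start: int = 87
    helix_end: int = 140
    separation_nm: float = 1.2
    crossing_angle_deg: float = 0.0
    planted_residues: dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_RESIDUES))
    salt_bridge_pairs: list[tuple[int, int]] = field(
        default_factory=lambda: [(101, 107), (98, 97)])
    pi_stack_pairs: list[tuple[int, int]] = field(
        default_factory=lambda: [(94, 95)])
    bridge_distance_nm: float = 0.32
    pi_distance_nm: float = 0.40
    clash_limit_nm: float = 0.2
    # MSA
    msa_n_sequences: int = 500
    msa_length: int = 60
    msa_covarying_pairs: list[tuple[int, int]] = field(
        default_factory=lambda: [(10, 40)])
    msa_coupling: float = 0.9
    # mean-force profile / PMF
    pmf_depth_kcal: float = 3.5
    pmf_center_nm: float = 3.6
    pmf_width_nm: float = 0.25
    pmf_grid: tuple[float, float, float] = (2.6, 5.4, 0.02)
    pmf_noise_kcal_nm: float = 0.0
    # pose ensemble
    n_poses: int = 100
    cluster_fractions: list[float] = field(
        default_factory=lambda: [0.22, 0.17, 0.13, 0.11, 0.09, 0.07])
    pose_jitter_nm: float = 0.05
    loop_range: tuple[int, int] = (141, 148)
    anchor_residue: int = 151


# ---------------------------------------------------------------------------
# backbone construction (NeRF internal-coordinate chain building)
# ---------------------------------------------------------------------------

def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float
           ) -> np.ndarray:
    """Place atom d from reference atoms a-b-c with given internal coords."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d2 = np.array([-bond * np.cos(ang),
                   bond * np.sin(ang) * np.cos(tor),
                   -bond * np.sin(ang) * np.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


_BONDS = {"N-CA": 0.1458, "CA-C": 0.1525, "C-N": 0.1329,
          "C-O": 0.1231, "CA-CB": 0.1530}


def build_backbone(residue_ids: list[int], names: list[str],
                   phi: list[float], psi: list[float],
                   chain_id: str = "A") -> list[Residue]:
    """Build a peptide backbone (N, CA, C, O, CB) from phi/psi torsions.

    ``phi[i]`` is used when placing C(i); ``psi[i]`` when placing N(i+1)
    and the carbonyl O. Terminal torsions default sensibly.
    """
    nres = len(residue_ids)
    coords: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BONDS["N-CA"], 0.0, 0.0])
    ang = np.radians(111.2)
    c0 = ca0 + _BONDS["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, nres):
        prev = coords[-1]
        n = _place(prev["N"], prev["CA"], prev["C"], _BONDS["C-N"], 116.2,
                   psi[i - 1])
        ca = _place(prev["CA"], prev["C"], n, _BONDS["N-CA"], 121.7, 180.0)
        c = _place(prev["C"], n, ca, _BONDS["CA-C"], 111.2, phi[i])
        coords.append({"N": n, "CA": ca, "C": c})
    residues: list[Residue] = []
    serial = 0
    for i, (rid, name) in enumerate(zip(residue_ids, names)):
        xyz = coords[i]
        psi_i = psi[i] if i < nres - 1 else -47.0
        xyz["O"] = _place(xyz["N"], xyz["CA"], xyz["C"], _BONDS["C-O"],
                          120.5, psi_i + 180.0)
        if name != "GLY":
            xyz["CB"] = _place(xyz["C"], xyz["N"], xyz["CA"],
                               _BONDS["CA-CB"], 110.5, -122.0)
        atoms = []
        for aname in ("N", "CA", "C", "O", "CB"):
            if aname in xyz:
                serial += 1
                atoms.append(make_atom(serial, aname, rid, xyz[aname],
                                       residue_name=name))
        residues.append(Residue(index=rid, name=name, chain_id=chain_id,
                                atoms=atoms, secondary_structure="coil"))
    return residues


def _align_helix(residues: list[Residue]) -> None:
    """Rigidly move a chain so its C-alpha principal axis is +z starting at
    z = 0 and its centroid sits on the z axis."""
    ca = np.array([r.atom("CA").coords for r in residues])
    axis = fit_axis(ca)
    target = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, target)
    s = np.linalg.norm(v)
    c = float(axis @ target)
    if s < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)
    center = ca.mean(axis=0)
    for r in residues:
        for a in r.atoms:
            a.coords = R @ (a.coords - center)
    ca = np.array([r.atom("CA").coords for r in residues])
    shift = np.array([ca[:, 0].mean(), ca[:, 1].mean(), ca[:, 2].min()])
    shift[2] = ca[:, 2].min()
    for r in residues:
        for a in r.atoms:
            a.coords = a.coords - np.array([0.0, 0.0, shift[2]])


def _rotate_about_z(residues: list[Residue], angle_rad: float) -> None:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    for r in residues:
        for a in r.atoms:
            a.coords = R @ a.coords


# ---------------------------------------------------------------------------
# side-chain planting
# ---------------------------------------------------------------------------

_CHAIN_ATOMS = {
    "LYS": ["CG", "CD", "CE", "NZ"],
    "ARG": ["CG", "CD", "NE", "CZ", "NH1"],
    "GLU": ["CG", "CD", "OE1"],
    "ASP": ["CG", "OD1"],
}
_PAIR_ATOMS = {"ARG": "NH2", "GLU": "OE2", "ASP": "OD2"}
_RING_SPECS = {
    "HIS": (["CG", "ND1", "CD2", "CE1", "NE2"], 0.115),
    "TYR": (["CG", "CD1", "CD2", "CE1", "CE2", "CZ"], 0.139),
    "PHE": (["CG", "CD1", "CD2", "CE1", "CE2", "CZ"], 0.139),
}


def _perp(u: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    v = np.cross(u, ref)
    return v / np.linalg.norm(v)


def _add_sidechain(residue: Residue, tip: np.ndarray, serial_start: int
                   ) -> int:
    """Place a minimal side chain from CB to ``tip``.

    Chain residues (Lys/Arg/Glu/Asp) put their atoms evenly spaced along the
    CB->tip segment with the terminal (charged) atom exactly at ``tip``;
    two-atom terminal groups get the partner atom 0.11 nm to the side.
    Aromatic residues put the ring centroid at ``tip`` with the ring normal
    along CB->tip.
    """
    cb = residue.atom("CB")
    if cb is None:
        raise ValueError(f"residue {residue.index} has no CB")
    u = tip - cb.coords
    dist = np.linalg.norm(u)
    u = u / dist
    serial = serial_start
    name3 = residue.name
    if name3 in _CHAIN_ATOMS:
        chain = _CHAIN_ATOMS[name3]
        for k, aname in enumerate(chain, start=1):
            pos = cb.coords + u * dist * k / len(chain)
            serial += 1
            residue.atoms.append(make_atom(serial, aname, residue.index, pos,
                                           residue_name=name3))
        if name3 in _PAIR_ATOMS:
            serial += 1
            residue.atoms.append(make_atom(
                serial, _PAIR_ATOMS[name3], residue.index,
                tip + 0.11 * _perp(u), residue_name=name3))
    elif name3 in _RING_SPECS:
        names, radius = _RING_SPECS[name3]
        v1 = _perp(u)
        v2 = np.cross(u, v1)
        for k, aname in enumerate(names):
            ang = 2 * np.pi * k / len(names)
            pos = tip + radius * (np.cos(ang) * v1 + np.sin(ang) * v2)
            serial += 1
            residue.atoms.append(make_atom(serial, aname, residue.index, pos,
                                           residue_name=name3))
        if name3 == "TYR":
            serial += 1
            residue.atoms.append(make_atom(serial, "OH", residue.index,
                                           tip + 0.28 * u, residue_name=name3))
    else:
        raise ValueError(f"no planting rule for residue type {name3}")
    return serial


def _default_tip(residue: Residue, axis_point: np.ndarray,
                 reach: float = 0.30,
                 avoid: np.ndarray | None = None) -> np.ndarray:
    """Radially outward tip for side chains not involved in a planted
    interaction; stubs pointing toward the docking partner (``avoid``
    direction) are shortened so they cannot reach into the interface."""
    cb = residue.atom("CB")
    radial = cb.coords - axis_point
    radial[2] = 0.0
    nrm = np.linalg.norm(radial)
    radial = radial / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
    if avoid is not None and float(radial @ avoid) > 0.3:
        reach = 0.10
    return cb.coords + reach * radial


@dataclass
class DimerAnnotation:
    planted_salt_bridges: list[tuple[int, int]]
    planted_pi_stacks: list[tuple[int, int]]
    secondary_structure: dict[tuple[str, int], str]
    separation_nm: float
    crossing_angle_deg: float
    helix_axes: dict[str, np.ndarray]


def _build_planted_helix(plan: FixturePlan, chain_id: str,
                         face_angle_rad: float) -> list[Residue]:
    ids = list(range(plan.helix_start, plan.helix_end + 1))
    names = [plan.planted_residues.get(i, "ALA") for i in ids]
    phi = [-57.0] * len(ids)
    psi = [-47.0] * len(ids)
    residues = build_backbone(ids, names, phi, psi, chain_id)
    _align_helix(residues)
    _rotate_about_z(residues, face_angle_rad)
    for r in residues:
        r.secondary_structure = "helix"
    return residues


def _mean_cb_angle(residues: list[Residue], ids: list[int]) -> float:
    angles = []
    for rid in ids:
        r = next(x for x in residues if x.index == rid)
        cb = r.atom("CB").coords
        angles.append(np.arctan2(cb[1], cb[0]))
    return float(np.angle(np.mean(np.exp(1j * np.array(angles)))))


def build_helix_dimer(plan: FixturePlan
                      ) -> tuple[DimerModel, DimerAnnotation]:
    """Two ideal helices (chains A, B) at the planned separation and
    crossing angle, with the planted salt bridges and pi stacks realised at
    their target contact distances. Raises on inter-monomer clashes below
    ``plan.clash_limit_nm``."""
    a_side = [p[0] for p in plan.salt_bridge_pairs] + \
        [p[0] for p in plan.pi_stack_pairs]
    b_side = [p[1] for p in plan.salt_bridge_pairs] + \
        [p[1] for p in plan.pi_stack_pairs]

    res_a = _build_planted_helix(plan, "A", 0.0)
    res_a_angle = _mean_cb_angle(res_a, a_side) if a_side else 0.0
    res_a = _build_planted_helix(plan, "A", -res_a_angle)   # face +x

    res_b = _build_planted_helix(plan, "B", 0.0)
    res_b_angle = _mean_cb_angle(res_b, b_side) if b_side else 0.0
    res_b = _build_planted_helix(plan, "B", np.pi - res_b_angle)  # face -x

    # crossing angle about the separation (x) axis, then translate
    theta = np.radians(plan.crossing_angle_deg)
    ca_b = np.array([r.atom("CA").coords for r in res_b])
    center_b = ca_b.mean(axis=0)
    c, s = np.cos(theta), np.sin(theta)
    Rx = np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])
    offset = np.array([plan.separation_nm, 0.0, 0.0])
    for r in res_b:
        for a in r.atoms:
            a.coords = Rx @ (a.coords - center_b) + center_b + offset

    # plant interacting side chains toward each other
    def resolve(residues, rid):
        return next(x for x in residues if x.index == rid)

    serial = 10000
    planted_a: set[int] = set()
    planted_b: set[int] = set()
    for (ra_id, rb_id), target in \
            [(p, plan.bridge_distance_nm) for p in plan.salt_bridge_pairs] + \
            [(p, plan.pi_distance_nm) for p in plan.pi_stack_pairs]:
        ra, rb = resolve(res_a, ra_id), resolve(res_b, rb_id)
        cba, cbb = ra.atom("CB").coords, rb.atom("CB").coords
        u = cbb - cba
        u = u / np.linalg.norm(u)
        mid = 0.5 * (cba + cbb)
        serial = _add_sidechain(ra, mid - 0.5 * target * u, serial)
        serial = _add_sidechain(rb, mid + 0.5 * target * u, serial)
        planted_a.add(ra_id)
        planted_b.add(rb_id)

    # remaining decorated residues get radially outward stubs
    axis_a = np.zeros(3)
    axis_b = offset
    for residues, planted, axis, toward in (
            (res_a, planted_a, axis_a, np.array([1.0, 0.0, 0.0])),
            (res_b, planted_b, axis_b, np.array([-1.0, 0.0, 0.0]))):
        for r in residues:
            if r.name != "ALA" and r.index not in planted:
                anchor = axis.copy()
                anchor[2] = r.atom("CB").coords[2]
                serial = _add_sidechain(
                    r, _default_tip(r, anchor, avoid=toward), serial)

    structure = Structure({"A": res_a, "B": res_b})
    dimer = DimerModel(structure, ["A"], ["B"], provenance="synthetic-helix-dimer")
    xa = structure.coords(["A"])
    xb = structure.coords(["B"])
    dmin = np.sqrt(((xa[:, None, :] - xb[None, :, :]) ** 2).sum(-1)).min()
    if dmin < plan.clash_limit_nm:
        raise ValueError(f"infeasible geometry: inter-monomer clash at "
                         f"{dmin:.3f} nm")
    ann = DimerAnnotation(
        planted_salt_bridges=list(plan.salt_bridge_pairs),
        planted_pi_stacks=list(plan.pi_stack_pairs),
        secondary_structure={(r.chain_id, r.index): "helix"
                             for r in res_a + res_b},
        separation_nm=plan.separation_nm,
        crossing_angle_deg=plan.crossing_angle_deg,
        helix_axes={"A": fit_axis(np.array([r.atom("CA").coords for r in res_a])),
                    "B": fit_axis(np.array([r.atom("CA").coords for r in res_b]))})
    return dimer, ann


# ---------------------------------------------------------------------------
# synthetic MSA
# ---------------------------------------------------------------------------

# background amino-acid frequencies (rough database composition)
_BG_AA = "ACDEFGHIKLMNPQRSTVWY"
_BG_FREQ = np.array([8.3, 1.4, 5.4, 6.7, 3.9, 7.1, 2.3, 5.9, 5.8, 9.7,
                     2.4, 4.1, 4.7, 3.9, 5.5, 6.6, 5.4, 6.9, 1.1, 2.9])
_BG_FREQ = _BG_FREQ / _BG_FREQ.sum()


def synth_msa(plan: FixturePlan) -> tuple[MSA, list[tuple[int, int]]]:
    """Alignment with i.i.d. background columns and planted covarying pairs.

    Each planted pair is a two-state coupled system: state 1 writes (K, E)
    into the pair's columns, state 2 writes (E, K). With probability
    ``msa_coupling`` the second column follows the first's state; otherwise
    it is drawn independently (so coupling 0 is background-like and
    coupling 1 is deterministic covariation). Returns the MSA and the
    0-based planted column pairs.
    """
    rng = np.random.default_rng(plan.seed)
    n, L = plan.msa_n_sequences, plan.msa_length
    mat = rng.choice(list(_BG_AA), size=(n, L), p=_BG_FREQ)
    state_letters = np.array(["K", "E"])
    for (i, j) in plan.msa_covarying_pairs:
        s_i = rng.integers(0, 2, n)
        coupled = rng.random(n) < plan.msa_coupling
        s_j = np.where(coupled, s_i, rng.integers(0, 2, n))
        mat[:, i] = state_letters[s_i]
        mat[:, j] = state_letters[1 - s_j]
    rows = ["".join(row) for row in mat]
    ids = [f"seq{k:04d}" for k in range(n)]
    return MSA(ids=ids, rows=rows), list(plan.msa_covarying_pairs)


# ---------------------------------------------------------------------------
# synthetic mean-force profile with known Kd
# ---------------------------------------------------------------------------

def gaussian_pmf(r: np.ndarray, depth: float, center: float, width: float
                 ) -> np.ndarray:
    """W(r) = -depth * exp(-(r-center)^2 / (2 width^2)) (kcal/mol)."""
    return -depth * np.exp(-((r - center) ** 2) / (2.0 * width ** 2))


def _analytic_kd(depth: float, center: float, width: float,
                 temperature: float = 300.0, r_lo: float = 2.6) -> float:
    """Kd implied by the analytic Gaussian well under the package's
    standard-state radial integral (same bound-window convention, starting
    at the profile's left edge ``r_lo``), on a fine quadrature grid."""
    rt = R_KCAL * temperature
    r = np.linspace(r_lo, center + 8 * width, 20001)
    w = gaussian_pmf(r, depth, center, width)
    # thermal bound window: out to where W rises back to -RT
    above = np.flatnonzero((r > center) & (w >= -rt))
    r_hi = r[above[0]] if above.size else r[-1]
    sel = r <= r_hi
    ka = np.trapezoid(4 * np.pi * r[sel] ** 2 * np.exp(-w[sel] / rt),
                      r[sel]) / STANDARD_VOLUME_NM3
    return 1.0 / ka


def depth_for_kd(target_kd: float, center: float, width: float,
                 temperature: float = 300.0, r_lo: float = 2.6) -> float:
    """Well depth (kcal/mol) whose Gaussian PMF yields ``target_kd`` under
    the package's Kd integral, found by bisection."""
    lo, hi = 0.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _analytic_kd(mid, center, width, temperature, r_lo) > target_kd:
            lo = mid          # too shallow -> Kd too large
        else:
            hi = mid
    return 0.5 * (lo + hi)


def synth_mean_force(plan: FixturePlan, temperature: float = 300.0
                     ) -> tuple[MeanForceProfile, float]:
    """Sampled mean-force profile of the Gaussian-well PMF plus its true Kd.

    F = -dW/dr on the plan's grid with i.i.d. Gaussian noise of sd
    ``pmf_noise_kcal_nm`` (the reported stderr). The true Kd is computed
    from the analytic W at fine quadrature, independent of the samples.
    """
    lo, hi, step = plan.pmf_grid
    r = np.arange(lo, hi + step / 2, step)
    d, c, w = plan.pmf_depth_kcal, plan.pmf_center_nm, plan.pmf_width_nm
    force = -d * (r - c) / w ** 2 * np.exp(-((r - c) ** 2) / (2 * w ** 2))
    rng = np.random.default_rng(plan.seed + 1)
    noise = plan.pmf_noise_kcal_nm
    if noise > 0:
        force = force + rng.normal(0.0, noise, r.shape)
    stderr = np.full(r.shape, noise)
    true_kd = _analytic_kd(d, c, w, temperature, r_lo=lo)
    return MeanForceProfile(r=r, force=force, stderr=stderr), true_kd


# ---------------------------------------------------------------------------
# pose-ensemble generator
# ---------------------------------------------------------------------------

def build_pose_monomer(plan: FixturePlan) -> list[Residue]:
    """Monomer for pose ensembles: the planted helix (side chains facing
    +x), an effector-loop stand-in extending +y from the helix top, and a
    C-terminal anchor tail rising +z from the loop end.

    The loop and tail are placed geometrically (not via torsions); their
    ground-truth secondary structure is coil.
    """
    res = _build_planted_helix(plan, "A", 0.0)
    face = _mean_cb_angle(res, [p[0] for p in plan.salt_bridge_pairs] or
                          [plan.helix_start])
    res = _build_planted_helix(plan, "A", -face)
    serial = 10000
    for r in res:
        if r.name != "ALA":
            # planted residues face +x (toward the docking partner)
            cb = r.atom("CB").coords
            serial = _add_sidechain(r, cb + 0.4 * np.array([1.0, 0.0, 0.0]),
                                    serial)
    z_top = max(a.coords[2] for r in res for a in r.atoms)
    lo, hi = plan.loop_range
    y = 0.35
    for k, rid in enumerate(range(lo, hi + 1)):
        jit = 0.08 * (-1) ** k
        base = np.array([jit, y, z_top + 0.25])
        atoms = []
        for off, aname in ((np.array([0.0, -0.12, 0.0]), "N"),
                           (np.zeros(3), "CA"),
                           (np.array([0.0, 0.12, 0.05]), "C"),
                           (np.array([0.10, 0.12, 0.15]), "O"),
                           (np.array([-0.05, 0.0, 0.14]), "CB")):
            serial += 1
            atoms.append(make_atom(serial, aname, rid, base + off,
                                   residue_name="ALA"))
        res.append(Residue(index=rid, name="ALA", chain_id="A", atoms=atoms,
                           secondary_structure="coil"))
        y += 0.33
    tail_base = np.array([0.0, y, z_top + 0.25])
    for k, rid in enumerate(range(hi + 1, plan.anchor_residue + 1)):
        base = tail_base + np.array([0.0, 0.0, 0.35 * (k + 1)])
        atoms = []
        for off, aname in ((np.array([0.0, 0.0, -0.12]), "N"),
                           (np.zeros(3), "CA"),
                           (np.array([0.0, 0.05, 0.12]), "C"),
                           (np.array([0.10, 0.15, 0.12]), "O"),
                           (np.array([-0.14, 0.0, 0.0]), "CB")):
            serial += 1
            atoms.append(make_atom(serial, aname, rid, base + off,
                                   residue_name="ALA"))
        res.append(Residue(index=rid, name="ALA", chain_id="A", atoms=atoms,
                           secondary_structure="coil"))
    return res


def _transform_chain(residues: list[Residue], R: np.ndarray, t: np.ndarray,
                     chain_id: str) -> list[Residue]:
    out = []
    for r in residues:
        atoms = [make_atom(a.serial, a.name, a.residue_index,
                           R @ a.coords + t, element=a.element,
                           residue_name=r.name) for a in r.atoms]
        out.append(Residue(index=r.index, name=r.name, chain_id=chain_id,
                           atoms=atoms,
                           secondary_structure=r.secondary_structure))
    return out


def _rot(axis: str, deg: float) -> np.ndarray:
    th = np.radians(deg)
    c, s = np.cos(th), np.sin(th)
    if axis == "x":
        return np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "y":
        return np.array([[c, 0, s], [0, 1.0, 0], [-s, 0, c]])
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


@dataclass
class PoseEnsembleKey:
    """Ground truth for a generated ensemble."""

    memberships: list[int]               # planted cluster id per pose, -1 scatter
    seed_transforms: list[tuple[np.ndarray, np.ndarray]]
    intended_filter_failures: dict[int, str]   # cluster id -> filter name
    secondary_structure: dict[tuple[str, int], str]
    hotspot_residues: list[int]
    loop_range: tuple[int, int]
    anchor_residue: int


def _seed_poses(plan: FixturePlan) -> tuple[list[tuple[np.ndarray, np.ndarray]],
                                            dict[int, str]]:
    """Six planted cluster seed transforms for monomer B; clusters 4 and 5
    are designed to violate the viability filters."""
    sep = 1.05
    z_span = (plan.helix_end - plan.helix_start) * 0.15
    seeds = [
        (np.eye(3), np.array([sep, 0.0, 0.0])),                 # pass
        (np.eye(3), np.array([sep, 0.0, 2.5])),                 # pass
        (_rot("z", 180.0), np.array([sep, 0.0, 0.0])),          # pass
        (_rot("z", 90.0), np.array([sep, 0.0, 0.0])),           # pass
        (_rot("x", 180.0), np.array([sep, 0.0, z_span + 0.6])), # anchors flip
        (_rot("z", 180.0), np.array([0.55, 3.2, 0.0])),         # loop-only PPI
    ]
    failures = {4: "membrane_competence", 5: "interface_composition"}
    return seeds, failures


def synth_pose_ensemble(plan: FixturePlan
                        ) -> tuple[PoseEnsemble, PoseEnsembleKey]:
    """Pose ensemble with planted clusters plus uniform scatter.

    Cluster k holds ``round(cluster_fractions[k] * n_poses)`` poses jittered
    around its seed transform with RMS displacement ``pose_jitter_nm``; the
    remaining poses place monomer B at random far (non-contacting)
    orientations. The key records intended memberships and which clusters
    violate which filter by construction.
    """
    if sum(plan.cluster_fractions) > 1.0 + 1e-9:
        raise ValueError("cluster fractions must sum to <= 1")
    rng = np.random.default_rng(plan.seed + 2)
    monomer = build_pose_monomer(plan)
    seeds, failures = _seed_poses(plan)
    sizes = [int(round(f * plan.n_poses)) for f in plan.cluster_fractions]
    if len(sizes) > len(seeds):
        raise ValueError(f"at most {len(seeds)} planted clusters supported")
    poses: list[DimerModel] = []
    memberships: list[int] = []

    def make_pose(R: np.ndarray, t: np.ndarray, tag: str) -> DimerModel:
        chain_a = _transform_chain(monomer, np.eye(3), np.zeros(3), "A")
        chain_b = _transform_chain(monomer, R, t, "B")
        st = Structure({"A": chain_a, "B": chain_b})
        return DimerModel(st, ["A"], ["B"], provenance=tag)

    for cid, size in enumerate(sizes):
        R0, t0 = seeds[cid]
        for _ in range(size):
            if plan.pose_jitter_nm > 0:
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                ang = rng.normal(0.0, 1.0)
                K = np.array([[0, -axis[2], axis[1]],
                              [axis[2], 0, -axis[0]],
                              [-axis[1], axis[0], 0]])
                th = np.radians(ang)
                Rj = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * K @ K
                tj = rng.normal(0.0, plan.pose_jitter_nm / np.sqrt(3), 3)
            else:
                Rj, tj = np.eye(3), np.zeros(3)
            poses.append(make_pose(Rj @ R0, t0 + tj, f"cluster{cid}"))
            memberships.append(cid)
    n_scatter = plan.n_poses - sum(sizes)
    for _ in range(n_scatter):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = rng.uniform(0, 360)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        th = np.radians(ang)
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * K @ K
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        t = direction * rng.uniform(3.5, 6.5)
        poses.append(make_pose(R, t, "scatter"))
        memberships.append(-1)

    hotspots = sorted(set(p for pair in plan.salt_bridge_pairs for p in pair))
    ss = {("A", r.index): r.secondary_structure for r in monomer}
    ss.update({("B", r.index): r.secondary_structure for r in monomer})
    key = PoseEnsembleKey(memberships=memberships, seed_transforms=seeds,
                          intended_filter_failures=failures,
                          secondary_structure=ss,
                          hotspot_residues=hotspots,
                          loop_range=plan.loop_range,
                          anchor_residue=plan.anchor_residue)
    return PoseEnsemble(poses=poses), key
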