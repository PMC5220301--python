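"""Interface descriptors for a dimer model.

Implements the five standard descriptors used to judge a protein-protein
interface — hydrogen-bond count, hydrophobic (carbon-carbon) contact count,
inter-monomer centre-of-mass distance, relative monomer orientation and
buried surface area — plus typed interaction detection (salt bridges,
pi-stacking) and a quasi-symmetry score for homodimers. All cutoffs default
to the conventional values: HB 0.3 nm donor-acceptor distance and 20
degree donor-H-acceptor angle, HC 0.38 nm carbon-carbon, salt bridge 0.4 nm
N-O, pi-stack 0.55 nm centroid-centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .elements import (
    AROMATIC_RING_ATOMS,
    SALT_BRIDGE_ACIDIC_ATOMS,
    SALT_BRIDGE_BASIC_ATOMS,
    SALT_BRIDGE_BASIC_ATOMS_HISP,
)
from .geometry import center_of_mass, kabsch_superpose, rotation_angle
from .sasa import DeltaSasaResult, delta_sasa
from .structure import Atom, DimerModel, Residue


@dataclass
class InterfaceReport:
    hb_count: int
    hc_count: int
    d_com: float
    delta_sasa: float
    delta_orientation: float | None
    interfacial_residues_a: list[int]
    interfacial_residues_b: list[int]
    salt_bridges: list[tuple]
    pi_stacks: list[tuple]
    quasi_symmetry: float | None
    hb_heavy_atom_fallback: bool = False
    per_frame: dict[str, list[float]] = field(default_factory=dict)


def _has_hydrogens(atoms: list[Atom]) -> bool:
    return any(a.element == "H" for a in atoms)


def _attached_hydrogens(residue: Residue, donor: Atom,
                        max_bond_nm: float = 0.13) -> list[Atom]:
    return [a for a in residue.atoms
            if a.element == "H"
            and np.linalg.norm(a.coords - donor.coords) <= max_bond_nm]


def hydrogen_bonds(dimer: DimerModel, d_cut: float = 0.30,
                   angle_cut: float = 20.0) -> tuple[list[tuple], bool]:
    """Inter-monomer hydrogen bonds.

    A bond requires donor-acceptor heavy-atom distance <= ``d_cut`` and, when
    explicit hydrogens are present, a donor-H...acceptor deviation-from-line
    angle <= ``angle_cut`` (the angle between the D->H and D->A directions).
    Without hydrogens the angle criterion is dropped (distance-only) and the
    returned flag marks the fallback. Each donor-acceptor pair counts once.
    Returns ``(pairs, heavy_atom_fallback)``; each pair is
    ``((chain, resid, donor_name), (chain, resid, acceptor_name))``.
    """
    res_a, res_b = dimer.residues_a(), dimer.residues_b()
    have_h = _has_hydrogens(dimer.atoms_a() + dimer.atoms_b())
    pairs: set[tuple] = set()

    def scan(donor_res: list[Residue], acc_res: list[Residue]) -> None:
        acceptors = [(r, a) for r in acc_res for a in r.atoms if a.is_acceptor]
        if not acceptors:
            return
        acc_xyz = np.array([a.coords for _, a in acceptors])
        tree = cKDTree(acc_xyz)
        for r in donor_res:
            for d in r.atoms:
                if not d.is_donor_heavy:
                    continue
                for j in tree.query_ball_point(d.coords, d_cut):
                    ra, a = acceptors[j]
                    ok = True
                    if have_h:
                        hs = _attached_hydrogens(r, d)
                        if hs:
                            ok = False
                            v_da = a.coords - d.coords
                            for h in hs:
                                v_dh = h.coords - d.coords
                                cosang = (v_da @ v_dh) / (
                                    np.linalg.norm(v_da) * np.linalg.norm(v_dh))
                                ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                                if ang <= angle_cut:
                                    ok = True
                                    break
                    if ok:
                        pairs.add(((r.chain_id, r.index, d.name),
                                   (ra.chain_id, ra.index, a.name)))

    scan(res_a, res_b)
    scan(res_b, res_a)
    return sorted(pairs), not have_h


def hydrophobic_contacts(dimer: DimerModel, d_cut: float = 0.38,
                         symmetric: bool = False
                         ) -> tuple[int, list[tuple]]:
    """Carbon-carbon contact count across the interface.

    Default counting follows the conventional asymmetric definition: the
    number of monomer-A carbon atoms with at least one monomer-B carbon
    within ``d_cut``. With ``symmetric=True`` carbons on either side with a
    cross-monomer partner are counted. Also returns the contacting
    atom-pair list ``((chain, resid, name), (chain, resid, name))``.
    """
    ca = [(r, a) for r in dimer.residues_a() for a in r.atoms if a.is_carbon]
    cb = [(r, a) for r in dimer.residues_b() for a in r.atoms if a.is_carbon]
    if not ca or not cb:
        return 0, []
    xyz_b = np.array([a.coords for _, a in cb])
    tree = cKDTree(xyz_b)
    pairs = []
    count_a = 0
    touched_b: set[int] = set()
    for r, a in ca:
        idx = tree.query_ball_point(a.coords, d_cut)
        if idx:
            count_a += 1
            touched_b.update(idx)
            for j in idx:
                rb, b = cb[j]
                pairs.append(((r.chain_id, r.index, a.name),
                              (rb.chain_id, rb.index, b.name)))
    count = count_a + len(touched_b) if symmetric else count_a
    return count, pairs


def com_distance(dimer: DimerModel) -> float:
    """Mass-weighted inter-monomer centre-of-mass distance (nm)."""
    com_a = center_of_mass(dimer.atoms_a())
    com_b = center_of_mass(dimer.atoms_b())
    return float(np.linalg.norm(com_a - com_b))


def relative_orientation(dimer: DimerModel, reference: DimerModel) -> float:
    """Orientation deviation (degrees) of monomer B relative to monomer A,
    versus a reference arrangement.

    Monomer A of the dimer is superposed onto monomer A of the reference;
    the residual rotation taking reference B onto the superposed B is
    reported as its axis-angle magnitude, so the value is 0 for the
    reference itself and equals the applied angle when B is rigidly rotated.
    """
    a = np.array([at.coords for at in dimer.atoms_a()])
    b = np.array([at.coords for at in dimer.atoms_b()])
    ra = np.array([at.coords for at in reference.atoms_a()])
    rb = np.array([at.coords for at in reference.atoms_b()])
    if a.shape != ra.shape or b.shape != rb.shape:
        raise ValueError("dimer and reference topologies differ")
    R, t, _ = kabsch_superpose(a, ra)
    b_aligned = b @ R.T + t
    R_b, _, _ = kabsch_superpose(rb, b_aligned)
    return rotation_angle(R_b)


def salt_bridges(dimer: DimerModel, d_cut: float = 0.40,
                 his_protonated: bool = False) -> list[tuple]:
    """Inter-monomer salt bridges: any basic-group nitrogen within ``d_cut``
    of an acidic-group oxygen. Histidine counts as basic only when flagged
    protonated. Pairs are ``(basic (chain, resid, resname),
    acidic (chain, resid, resname), min_distance_nm)``.
    """
    def group_atoms(residues: list[Residue], role: str) -> list[tuple]:
        out = []
        for r in residues:
            if role == "basic":
                names = SALT_BRIDGE_BASIC_ATOMS.get(r.name, set())
                if his_protonated and r.name == "HIS":
                    names = names | SALT_BRIDGE_BASIC_ATOMS_HISP
            else:
                names = SALT_BRIDGE_ACIDIC_ATOMS.get(r.name, set())
            for a in r.atoms:
                if a.name in names:
                    out.append((r, a))
        return out

    bridges = {}
    for basic_side, acidic_side in ((dimer.residues_a(), dimer.residues_b()),
                                    (dimer.residues_b(), dimer.residues_a())):
        basics = group_atoms(basic_side, "basic")
        acidics = group_atoms(acidic_side, "acidic")
        for rb, ab in basics:
            for ra, aa in acidics:
                d = float(np.linalg.norm(ab.coords - aa.coords))
                if d <= d_cut:
                    key = ((rb.chain_id, rb.index, rb.name),
                           (ra.chain_id, ra.index, ra.name))
                    if key not in bridges or d < bridges[key]:
                        bridges[key] = d
    return sorted((b, a, d) for (b, a), d in bridges.items())


def _ring_geometry(residue: Residue) -> tuple[np.ndarray, np.ndarray] | None:
    names = AROMATIC_RING_ATOMS.get(residue.name)
    if names is None:
        return None
    atoms = [residue.atom(n) for n in names]
    if any(a is None for a in atoms):
        warnings.warn(f"incomplete ring in {residue.chain_id}:{residue.index}; "
                      "skipped")
        return None
    xyz = np.array([a.coords for a in atoms])
    centroid = xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(xyz - centroid)
    return centroid, vt[2]


def pi_stacking(dimer: DimerModel, centroid_cut: float = 0.55,
                parallel_max_deg: float = 30.0) -> list[tuple]:
    """Inter-monomer aromatic stacking by ring-centroid distance.

    Ring-plane angle (folded into [0, 90]) classifies the geometry:
    ``parallel`` if <= ``parallel_max_deg``, else ``t-shaped``. Pairs are
    ``((chain, resid, resname), (chain, resid, resname), distance_nm,
    angle_deg, class)``.
    """
    rings_a = [(r, g) for r in dimer.residues_a()
               if (g := _ring_geometry(r)) is not None]
    rings_b = [(r, g) for r in dimer.residues_b()
               if (g := _ring_geometry(r)) is not None]
    out = []
    for ra, (ca, na) in rings_a:
        for rb, (cb, nb) in rings_b:
            d = float(np.linalg.norm(ca - cb))
            if d > centroid_cut:
                continue
            cosang = abs(float(na @ nb))
            ang = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
            cls = "parallel" if ang <= parallel_max_deg else "t-shaped"
            out.append(((ra.chain_id, ra.index, ra.name),
                        (rb.chain_id, rb.index, rb.name), d, ang, cls))
    return sorted(out)


def quasi_symmetry_score(dimer: DimerModel,
                         dsasa: DeltaSasaResult | None = None,
                         **sasa_kwargs) -> float:
    """Jaccard overlap of the interfacial residue-index sets contributed by
    the two monomers of a homodimer; 1 means a perfectly symmetric (C2)
    interface, 0 disjoint contributions."""
    if not dimer.is_homodimer():
        raise ValueError("quasi-symmetry is defined for homodimers only")
    if dsasa is None:
        dsasa = delta_sasa(dimer, **sasa_kwargs)
    sa = set(dsasa.interfacial_residues_a)
    sb = set(dsasa.interfacial_residues_b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


@dataclass
class EnsembleSummary:
    series: np.ndarray
    running_average: np.ndarray
    mean: float
    sd: float
    window: int


def ensemble_summary(series, window: int = 1) -> EnsembleSummary:
    """Per-frame series with a centred running average and mean +/- sd.

    The running average at frame i averages the frames in a centred window
    of ``window`` frames (truncated at the ends). A window longer than the
    series falls back to the global mean with a warning.
    """
    x = np.asarray(list(series), dtype=float)
    if x.size == 0:
        raise ValueError("need at least one frame")
    if window > x.size:
        warnings.warn("running-average window exceeds series length; "
                      "using global mean")
        run = np.full_like(x, x.mean())
    else:
        half_lo = (window - 1) // 2
        half_hi = window // 2
        run = np.array([x[max(0, i - half_lo): i + half_hi + 1].mean()
                        for i in range(x.size)])
    return EnsembleSummary(series=x, running_average=run,
                           mean=float(x.mean()),
                           sd=float(x.std(ddof=0)), window=window)


def characterize(dimer: DimerModel, reference: DimerModel | None = None,
                 probe_radius: float = 0.14, n_sphere_points: int = 960,
                 hb_d_cut: float = 0.30, hb_angle_cut: float = 20.0,
                 hc_d_cut: float = 0.38, sb_d_cut: float = 0.40,
                 pi_cut: float = 0.55) -> InterfaceReport:
    """Full single-conformer interface report (the five descriptors plus
    typed interactions). For multi-frame structures use
    ``characterize_ensemble``."""
    hbs, fallback = hydrogen_bonds(dimer, hb_d_cut, hb_angle_cut)
    hc, _ = hydrophobic_contacts(dimer, hc_d_cut)
    dsasa = delta_sasa(dimer, probe_radius, n_sphere_points)
    delta = relative_orientation(dimer, reference) if reference else None
    qsym = quasi_symmetry_score(dimer, dsasa) if dimer.is_homodimer() else None
    return InterfaceReport(
        hb_count=len(hbs), hc_count=hc, d_com=com_distance(dimer),
        delta_sasa=dsasa.total, delta_orientation=delta,
        interfacial_residues_a=dsasa.interfacial_residues_a,
        interfacial_residues_b=dsasa.interfacial_residues_b,
        salt_bridges=salt_bridges(dimer, sb_d_cut),
        pi_stacks=pi_stacking(dimer, pi_cut),
        quasi_symmetry=qsym, hb_heavy_atom_fallback=fallback)
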