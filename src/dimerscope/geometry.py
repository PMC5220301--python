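"""Rigid-body geometry: superposition, centres of mass, dihedral angles and
backbone-dihedral secondary-structure assignment."""

from __future__ import annotations

import warnings

import numpy as np

from .structure import Atom, Residue, Structure, atom_mass


class GeometryError(ValueError):
    pass


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(R, t, rmsd)`` such that ``mobile @ R.T + t`` best matches
    ``target``; ``R`` is a proper rotation (det +1) and ``rmsd`` is the
    minimised root-mean-square deviation in nm.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError("point sets must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError("need at least 3 points for superposition")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    P = mobile - mc
    Q = target - tc
    if np.linalg.matrix_rank(np.vstack([P, Q]), tol=1e-10) < 2:
        raise GeometryError("degenerate (collinear) point configuration")
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    diff = (mobile @ R.T + t) - target
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return R, t, rmsd


def rotation_angle(R: np.ndarray) -> float:
    """Axis-angle magnitude of a rotation matrix, in degrees."""
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def center_of_mass(atoms: list[Atom], weighting: str = "mass") -> np.ndarray:
    """Centre of mass (element masses) or geometric centre of a selection."""
    if not atoms:
        raise GeometryError("empty selection")
    coords = np.array([a.coords for a in atoms])
    if weighting == "geometric":
        return coords.mean(axis=0)
    if weighting != "mass":
        raise ValueError("weighting must be 'mass' or 'geometric'")
    w = np.array([atom_mass(a) for a in atoms])
    return (coords * w[:, None]).sum(axis=0) / w.sum()


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
             ) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    return float(np.degrees(np.arctan2(y, x)))


# phi/psi windows (degrees). The helix window brackets the ideal alpha helix
# (-57, -47); the strand window the fully extended chain (+/-180, +/-180).
_HELIX_PHI = (-100.0, -30.0)
_HELIX_PSI = (-80.0, -5.0)
_MIN_HELIX_RUN = 4
_MIN_STRAND_RUN = 3


def _in_window(v: float, lo: float, hi: float) -> bool:
    return lo <= v <= hi


def _is_strand(phi: float, psi: float) -> bool:
    phi = phi - 360.0 if phi > 175.0 else phi    # +180 == -180
    return (-180.0 <= phi <= -90.0) and (psi >= 90.0 or psi <= -160.0)


def assign_secondary_structure(structure: Structure,
                               overrides: dict[tuple[str, int], str] | None = None
                               ) -> dict[tuple[str, int], str]:
    """Assign helix/strand/coil per residue from backbone dihedrals.

    A residue is helix-compatible if (phi, psi) fall in the alpha window and
    helices require runs of >= 4 such residues; strands require runs of >= 3
    extended residues. Chain termini (undefined phi or psi) and residues with
    missing backbone atoms are coil. ``overrides`` maps ``(chain, resid)`` to
    an assignment and wins over the dihedral rule. Assignments are also
    stored on each residue's ``secondary_structure``.
    """
    overrides = overrides or {}
    result: dict[tuple[str, int], str] = {}
    for cid, residues in structure.chains.items():
        labels = ["coil"] * len(residues)
        raw = []
        for i, r in enumerate(residues):
            n, ca, c = r.atom("N"), r.atom("CA"), r.atom("C")
            if n is None or ca is None or c is None:
                warnings.warn(f"residue {cid}:{r.index} missing backbone; coil")
                raw.append(None)
                continue
            phi = psi = None
            if i > 0:
                prev_c = residues[i - 1].atom("C")
                if prev_c is not None:
                    phi = dihedral(prev_c.coords, n.coords, ca.coords, c.coords)
            if i < len(residues) - 1:
                next_n = residues[i + 1].atom("N")
                if next_n is not None:
                    psi = dihedral(n.coords, ca.coords, c.coords, next_n.coords)
            raw.append((phi, psi))
        # classify candidates, then enforce minimum run lengths
        cand = []
        for entry in raw:
            if entry is None or entry[0] is None or entry[1] is None:
                cand.append("coil")
                continue
            phi, psi = entry
            if _in_window(phi, *_HELIX_PHI) and _in_window(psi, *_HELIX_PSI):
                cand.append("helix")
            elif _is_strand(phi, psi):
                cand.append("strand")
            else:
                cand.append("coil")
        i = 0
        while i < len(cand):
            j = i
            while j < len(cand) and cand[j] == cand[i]:
                j += 1
            run, length = cand[i], j - i
            if run == "helix" and length >= _MIN_HELIX_RUN:
                labels[i:j] = ["helix"] * length
            elif run == "strand" and length >= _MIN_STRAND_RUN:
                labels[i:j] = ["strand"] * length
            i = j
        for r, lab in zip(residues, labels):
            lab = overrides.get((cid, r.index), lab)
            r.secondary_structure = lab
            result[(cid, r.index)] = lab
    return result


def fit_axis(coords: np.ndarray) -> np.ndarray:
    """Principal axis (unit vector) of a point cloud, e.g. a helix axis."""
    coords = np.asarray(coords, float)
    c = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    axis = vt[0]
    # orient along increasing point order for reproducibility
    if (coords[-1] - coords[0]) @ axis < 0:
        axis = -axis
    return axis
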