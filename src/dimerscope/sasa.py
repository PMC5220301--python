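"""Shrake-Rupley solvent-accessible surface area and interface buried area.

Each atom is expanded by the probe radius (default 0.14 nm, a water probe)
and covered with a deterministic golden-section spiral lattice of test
points; the accessible area is the exposed fraction of points times the
expanded-sphere area. The deterministic lattice makes results bit
reproducible and guarantees that adding occluding atoms can only reduce the
area, so buried areas (dSASA) are non-negative by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .elements import MAX_SASA_NM2
from .structure import Atom, DimerModel, Residue, Structure

DEFAULT_PROBE_NM = 0.14
DEFAULT_N_POINTS = 960

# Per-residue buried area above this is counted as interfacial (noise floor
# of the point sampling).
INTERFACIAL_DSASA_NM2 = 0.01


class SasaError(ValueError):
    pass


@dataclass
class SasaResult:
    per_atom_area: np.ndarray          # nm^2, order follows input atoms
    per_residue_area: dict[tuple[str, int], float]
    total: float
    probe_radius: float
    n_sphere_points: int


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral lattice on the unit sphere."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _resolve_atoms(obj) -> tuple[list[Atom], list[tuple[str, int]]]:
    """Return atoms plus a (chain, resid) key per atom."""
    if isinstance(obj, Structure):
        atoms, keys = [], []
        for r in obj.residues():
            for a in r.atoms:
                atoms.append(a)
                keys.append(r.key)
        return atoms, keys
    if isinstance(obj, Residue):
        return list(obj.atoms), [obj.key] * len(obj.atoms)
    atoms = list(obj)
    if atoms and isinstance(atoms[0], Residue):
        flat, keys = [], []
        for r in atoms:
            for a in r.atoms:
                flat.append(a)
                keys.append(r.key)
        return flat, keys
    return atoms, [("", a.residue_index) for a in atoms]


def shrake_rupley(obj, probe_radius: float = DEFAULT_PROBE_NM,
                  n_sphere_points: int = DEFAULT_N_POINTS) -> SasaResult:
    """Accessible surface area of a Structure, residue list or atom list.

    ``per_atom_area[i] = exposed_points/total_points * 4*pi*(r_i+probe)^2``.
    """
    if n_sphere_points < 60:
        raise SasaError("n_sphere_points must be >= 60")
    atoms, keys = _resolve_atoms(obj)
    if not atoms:
        raise SasaError("empty selection")
    centers = np.array([a.coords for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms]) + probe_radius
    unit = sphere_points(n_sphere_points)
    tree = cKDTree(centers)
    max_r = radii.max()
    per_atom = np.zeros(len(atoms))
    for i, (c, r) in enumerate(zip(centers, radii)):
        pts = c + r * unit
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j in tree.query_ball_point(c, r + max_r):
            if j == i:
                continue
            d2 = ((pts - centers[j]) ** 2).sum(axis=1)
            exposed &= d2 > radii[j] ** 2
        per_atom[i] = exposed.sum() / n_sphere_points * 4.0 * np.pi * r * r
    per_res: dict[tuple[str, int], float] = {}
    for key, area in zip(keys, per_atom):
        per_res[key] = per_res.get(key, 0.0) + float(area)
    return SasaResult(per_atom_area=per_atom, per_residue_area=per_res,
                      total=float(per_atom.sum()), probe_radius=probe_radius,
                      n_sphere_points=n_sphere_points)


@dataclass
class DeltaSasaResult:
    total: float                          # nm^2 buried on complex formation
    per_residue: dict[tuple[str, int], float]
    interfacial_residues_a: list[int]
    interfacial_residues_b: list[int]
    sasa_a: SasaResult
    sasa_b: SasaResult
    sasa_dimer: SasaResult


def delta_sasa(dimer: DimerModel, probe_radius: float = DEFAULT_PROBE_NM,
               n_sphere_points: int = DEFAULT_N_POINTS,
               interfacial_cut: float = INTERFACIAL_DSASA_NM2
               ) -> DeltaSasaResult:
    """Buried interface area: SASA(A) + SASA(B) - SASA(AB).

    Per-residue contributions are the per-residue differences between the
    isolated-monomer and in-dimer areas; residues burying more than
    ``interfacial_cut`` nm^2 are flagged interfacial.
    """
    res_a = dimer.residues_a()
    res_b = dimer.residues_b()
    sasa_a = shrake_rupley(res_a, probe_radius, n_sphere_points)
    sasa_b = shrake_rupley(res_b, probe_radius, n_sphere_points)
    sasa_ab = shrake_rupley(res_a + res_b, probe_radius, n_sphere_points)
    per_res: dict[tuple[str, int], float] = {}
    for key, area in {**sasa_a.per_residue_area, **sasa_b.per_residue_area}.items():
        per_res[key] = area - sasa_ab.per_residue_area.get(key, 0.0)
    chains_a = set(dimer.monomer_a)
    ifa = sorted(idx for (cid, idx), v in per_res.items()
                 if cid in chains_a and v > interfacial_cut)
    ifb = sorted(idx for (cid, idx), v in per_res.items()
                 if cid not in chains_a and v > interfacial_cut)
    total = sasa_a.total + sasa_b.total - sasa_ab.total
    return DeltaSasaResult(total=float(total), per_residue=per_res,
                           interfacial_residues_a=ifa,
                           interfacial_residues_b=ifb,
                           sasa_a=sasa_a, sasa_b=sasa_b, sasa_dimer=sasa_ab)


def relative_residue_sasa(residue_name: str, area_nm2: float) -> float:
    """Observed area over the Gly-X-Gly theoretical maximum for the residue."""
    try:
        ref = MAX_SASA_NM2[residue_name]
    except KeyError:
        raise SasaError(f"no reference maximum area for residue {residue_name!r}")
    return area_nm2 / ref


def is_exposed(residue_name: str, area_nm2: float,
               threshold: float = 0.25) -> bool:
    """Exposure classification; the threshold is inclusive (ratio == cut
    counts as exposed)."""
    return relative_residue_sasa(residue_name, area_nm2) >= threshold


def residue_sasa_table(structure: Structure, sasa: SasaResult,
                       threshold: float = 0.25) -> list[dict]:
    """Per-residue TSV-ready rows: id, chain, area, relative area, exposed."""
    rows = []
    for r in structure.residues():
        area = sasa.per_residue_area.get(r.key, 0.0)
        rel = relative_residue_sasa(r.name, area) if r.name in MAX_SASA_NM2 \
            else float("nan")
        rows.append({"resid": r.index, "chain": r.chain_id, "name": r.name,
                     "area_nm2": area, "relative_area": rel,
                     "exposed": bool(rel >= threshold)})
    return rows
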