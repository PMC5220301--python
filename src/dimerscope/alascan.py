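"""Computational alanine scanning of interfacial residues.

Each scanned residue is truncated to alanine (side chain removed beyond the
beta carbon, backbone untouched) and the loss of pairwise inter-monomer
interaction energy, ddE = E_mut - E_wt, is reported; since favourable
interactions are negative, positive ddE marks residues whose side chain
stabilises the dimer. The energy is a transparent fixed-
parameter pairwise sum: Coulomb between formal side-chain charges (+/-1 e
spread over the terminal group atoms) with a distance-dependent dielectric
eps = 4r, plus a 12-6 Lennard-Jones term from the element tables, evaluated
over inter-monomer pairs within 1.2 nm with switching beyond 1.0 nm. The
scan is rigid: no relaxation after mutation, so the ranking (not the
absolute energies) is the deliverable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .elements import (
    CHARGED_GROUP_ATOMS,
    CHARGED_GROUP_ATOMS_HISP,
    LJ_EPS_KCAL,
)
from .structure import DimerModel, Residue, Structure

COULOMB_KCAL_A = 332.0637    # kcal/mol * Angstrom / e^2
CUTOFF_NM = 1.2
SWITCH_ON_NM = 1.0
_SIDECHAIN_KEEP = {"N", "CA", "C", "O", "OXT", "CB"}


class ScanError(ValueError):
    pass


@dataclass
class ScanResult:
    chain_id: str
    residue_index: int
    residue_name: str
    dde: float                  # kcal/mol, E_mut - E_wt
    dde_coulomb: float
    dde_lj: float
    contact_partners: list[tuple[str, int]]
    rank: int = 0
    skipped: str | None = None


def mutate_to_alanine(structure: Structure, chain_id: str, residue_index: int
                      ) -> tuple[Structure, str | None]:
    """Truncate one residue's side chain to alanine on a copy.

    Gly and Pro are skipped (no Cb / backbone-coupled ring); an Ala input is
    a no-op. Returns ``(structure_copy, skip_reason_or_None)``.
    """
    residue = structure.residue(chain_id, residue_index)
    if residue.name == "GLY":
        return structure, "glycine has no side chain to truncate"
    if residue.name == "PRO":
        return structure, "proline side chain is backbone-coupled"
    if residue.name == "ALA":
        return structure, "already alanine"
    if residue.atom("CB") is None:
        raise ScanError(f"residue {chain_id}:{residue_index} has no CB atom")
    out = structure.copy()
    res = out.residue(chain_id, residue_index)
    res.atoms = [a for a in res.atoms
                 if a.name in _SIDECHAIN_KEEP or a.element == "H"
                 and a.name in ("H", "HA")]
    res.name = "ALA"
    return out, None


def _charges(residue: Residue, his_protonated: bool) -> dict[str, float]:
    table = CHARGED_GROUP_ATOMS.get(residue.name, {})
    if his_protonated and residue.name == "HIS":
        table = CHARGED_GROUP_ATOMS_HISP
    return table


def _switch(r: np.ndarray) -> np.ndarray:
    """CHARMM-style switching function, 1 below SWITCH_ON, 0 beyond CUTOFF."""
    r2, on2, off2 = r ** 2, SWITCH_ON_NM ** 2, CUTOFF_NM ** 2
    s = np.ones_like(r)
    mid = (r > SWITCH_ON_NM) & (r <= CUTOFF_NM)
    s[mid] = ((off2 - r2[mid]) ** 2 * (off2 + 2 * r2[mid] - 3 * on2)
              / (off2 - on2) ** 3)
    s[r > CUTOFF_NM] = 0.0
    return s


def inter_monomer_energy(dimer: DimerModel, his_protonated: bool = False
                         ) -> tuple[float, float, float]:
    """Pairwise inter-monomer energy; returns (total, coulomb, lj) kcal/mol.

    Coulomb uses the distance-dependent dielectric eps = 4r (r in Angstrom),
    i.e. E = 332 q_i q_j / (4 r_A^2); LJ minima sit at the sum of the vdW
    radii with geometric-mean well depths.
    """
    def annotate(residues):
        atoms, charges = [], []
        for r in residues:
            table = _charges(r, his_protonated)
            for a in r.atoms:
                atoms.append(a)
                charges.append(table.get(a.name, 0.0))
        return atoms, np.array(charges)

    atoms_a, q_a = annotate(dimer.residues_a())
    atoms_b, q_b = annotate(dimer.residues_b())
    if not atoms_a or not atoms_b:
        return 0.0, 0.0, 0.0
    xyz_a = np.array([a.coords for a in atoms_a])
    xyz_b = np.array([a.coords for a in atoms_b])
    eps_a = np.array([LJ_EPS_KCAL[a.element] for a in atoms_a])
    eps_b = np.array([LJ_EPS_KCAL[a.element] for a in atoms_b])
    rmin_a = np.array([a.vdw_radius for a in atoms_a])
    rmin_b = np.array([a.vdw_radius for a in atoms_b])

    tree = cKDTree(xyz_b)
    e_coul = e_lj = 0.0
    for i, xa in enumerate(xyz_a):
        idx = tree.query_ball_point(xa, CUTOFF_NM)
        if not idx:
            continue
        idx = np.asarray(idx)
        d = np.linalg.norm(xyz_b[idx] - xa, axis=1)
        d = np.maximum(d, 1e-3)
        sw = _switch(d)
        qq = q_a[i] * q_b[idx]
        nz = qq != 0
        if np.any(nz):
            d_ang = d[nz] * 10.0
            e_coul += float(np.sum(sw[nz] * COULOMB_KCAL_A * qq[nz]
                                   / (4.0 * d_ang ** 2)))
        rm = rmin_a[i] + rmin_b[idx]
        eps = np.sqrt(eps_a[i] * eps_b[idx])
        x6 = (rm / d) ** 6
        e_lj += float(np.sum(sw * eps * (x6 ** 2 - 2.0 * x6)))
    return e_coul + e_lj, e_coul, e_lj


def scan_interface(dimer: DimerModel,
                   interfacial: list[tuple[str, int]],
                   his_protonated: bool = False) -> list[ScanResult]:
    """Alanine-scan the given interfacial residues, ranked by ddE descending.

    ddE = E_mut - E_wt, so residues whose side chain stabilises the dimer
    score positive. Gly/Ala/Pro entries appear in the output with a skip
    reason and ddE = 0.
    """
    e_wt, c_wt, l_wt = inter_monomer_energy(dimer, his_protonated)
    chains_a = set(dimer.monomer_a)
    results: list[ScanResult] = []
    for chain_id, resid in interfacial:
        residue = dimer.structure.residue(chain_id, resid)
        mut, skip = mutate_to_alanine(dimer.structure, chain_id, resid)
        if skip is not None:
            results.append(ScanResult(chain_id, resid, residue.name, 0.0,
                                      0.0, 0.0, [], skipped=skip))
            continue
        mdim = DimerModel(mut, list(dimer.monomer_a), list(dimer.monomer_b),
                          provenance=f"{dimer.provenance}|{chain_id}{resid}A")
        e_mut, c_mut, l_mut = inter_monomer_energy(mdim, his_protonated)
        partner_res = mdim.residues_b() if chain_id in chains_a \
            else mdim.residues_a()
        partners = _contact_partners(residue, partner_res)
        results.append(ScanResult(chain_id, resid, residue.name,
                                  dde=e_mut - e_wt, dde_coulomb=c_mut - c_wt,
                                  dde_lj=l_mut - l_wt,
                                  contact_partners=partners))
    results.sort(key=lambda s: s.dde, reverse=True)
    for rank, s in enumerate(results, start=1):
        s.rank = rank
    return results


def _contact_partners(residue: Residue, others: list[Residue],
                      d_cut: float = 0.5) -> list[tuple[str, int]]:
    xyz = np.array([a.coords for a in residue.atoms])
    out = []
    for r in others:
        oxyz = np.array([a.coords for a in r.atoms])
        d = np.linalg.norm(xyz[:, None, :] - oxyz[None, :, :], axis=2)
        if d.min() <= d_cut:
            out.append((r.chain_id, r.index))
    return out
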