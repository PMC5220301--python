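"""Hierarchical coordinate model and PDB input/output.

The internal length unit is the nanometre throughout the package; PDB files
(which are in Angstrom) are converted on read and write. Residues keep the
author (PDB) numbering so that literature residue identifiers map directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Atom import DisorderedAtom

from .elements import (
    BACKBONE_ATOMS,
    MASSES,
    SIDECHAIN_ACCEPTOR_ATOMS,
    SIDECHAIN_DONOR_ATOMS,
    VDW_RADIUS_NM,
    element_from_name,
)

A_TO_NM = 0.1
NM_TO_A = 10.0


class StructureError(ValueError):
    """Raised for malformed or empty structure input."""


@dataclass
class Atom:
    """A single atom with coordinates in nm."""

    serial: int
    name: str
    element: str
    residue_index: int
    coords: np.ndarray
    vdw_radius: float
    is_carbon: bool = False
    is_donor_heavy: bool = False
    is_acceptor: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"non-finite coordinates for atom {self.name}")
        if self.vdw_radius <= 0:
            raise StructureError(f"non-positive vdW radius for atom {self.name}")


@dataclass
class Residue:
    index: int
    name: str
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)
    secondary_structure: str = "coil"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.index)


class Structure:
    """Ordered chains of residues, optionally with multiple coordinate frames.

    ``frames`` holds one ``(n_atoms, 3)`` array per model; ``set_frame`` copies
    a frame into the live atom coordinates. All frames share one topology.
    """

    def __init__(self, chains: dict[str, list[Residue]],
                 frames: list[np.ndarray] | None = None) -> None:
        self.chains = chains
        self.frames = frames
        self._active_frame = 0
        for cid, residues in chains.items():
            seen = set()
            for r in residues:
                if r.index in seen:
                    raise StructureError(
                        f"duplicate residue index {r.index} in chain {cid}")
                seen.add(r.index)

    # -- iteration helpers -------------------------------------------------
    def residues(self, chain_ids: list[str] | None = None) -> list[Residue]:
        out = []
        for cid, residues in self.chains.items():
            if chain_ids is None or cid in chain_ids:
                out.extend(residues)
        return out

    def atoms(self, chain_ids: list[str] | None = None) -> list[Atom]:
        return [a for r in self.residues(chain_ids) for a in r.atoms]

    def coords(self, chain_ids: list[str] | None = None) -> np.ndarray:
        atoms = self.atoms(chain_ids)
        if not atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in atoms])

    @property
    def n_frames(self) -> int:
        return 1 if self.frames is None else len(self.frames)

    def set_frame(self, k: int) -> None:
        if self.frames is None:
            if k != 0:
                raise StructureError("structure has a single frame")
            return
        frame = self.frames[k]
        for atom, xyz in zip(self.atoms(), frame):
            atom.coords = np.array(xyz, dtype=float)
        self._active_frame = k

    def residue(self, chain_id: str, index: int) -> Residue:
        for r in self.chains[chain_id]:
            if r.index == index:
                return r
        raise KeyError(f"residue {index} not in chain {chain_id}")

    def sequence(self, chain_id: str) -> str:
        from .elements import AA_3TO1
        return "".join(AA_3TO1.get(r.name, "X") for r in self.chains[chain_id])

    # -- selection ---------------------------------------------------------
    def select(self, expression: str) -> list[Atom]:
        """Evaluate a selection expression.

        The mini-language supports clauses joined by ``and``:
        ``chain A``, ``resid 87-104`` (inclusive; comma lists allowed),
        ``name CA`` (comma lists allowed). Example:
        ``"chain A and resid 87-104 and name CA"``.
        """
        chain_ids: set[str] | None = None
        resids: set[int] | None = None
        names: set[str] | None = None
        for clause in expression.split(" and "):
            parts = clause.strip().split()
            if len(parts) < 2:
                raise ValueError(f"bad selection clause: {clause!r}")
            kw, args = parts[0].lower(), " ".join(parts[1:])
            if kw == "chain":
                chain_ids = set(args.replace(",", " ").split())
            elif kw == "resid":
                resids = set()
                for token in args.replace(",", " ").split():
                    if "-" in token[1:]:
                        lo, hi = token.rsplit("-", 1)
                        resids.update(range(int(lo), int(hi) + 1))
                    else:
                        resids.add(int(token))
            elif kw == "name":
                names = set(args.replace(",", " ").split())
            else:
                raise ValueError(f"unknown selection keyword {kw!r}")
        out = []
        for cid, residues in self.chains.items():
            if chain_ids is not None and cid not in chain_ids:
                continue
            for r in residues:
                if resids is not None and r.index not in resids:
                    continue
                for a in r.atoms:
                    if names is not None and a.name not in names:
                        continue
                    out.append(a)
        return out

    def copy(self) -> "Structure":
        chains = {}
        for cid, residues in self.chains.items():
            chains[cid] = [
                Residue(r.index, r.name, r.chain_id,
                        [Atom(a.serial, a.name, a.element, a.residue_index,
                              a.coords.copy(), a.vdw_radius, a.is_carbon,
                              a.is_donor_heavy, a.is_acceptor)
                         for a in r.atoms],
                        r.secondary_structure)
                for r in residues
            ]
        frames = None if self.frames is None else [f.copy() for f in self.frames]
        return Structure(chains, frames)


@dataclass
class DimerModel:
    """Two disjoint monomer selections (by chain) within one structure."""

    structure: Structure
    monomer_a: list[str]
    monomer_b: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.monomer_a, str):
            self.monomer_a = [self.monomer_a]
        if isinstance(self.monomer_b, str):
            self.monomer_b = [self.monomer_b]
        if not self.monomer_a or not self.monomer_b:
            raise StructureError("monomer selections must be non-empty")
        if set(self.monomer_a) & set(self.monomer_b):
            raise StructureError("monomer selections must be disjoint")

    def atoms_a(self) -> list[Atom]:
        return self.structure.atoms(self.monomer_a)

    def atoms_b(self) -> list[Atom]:
        return self.structure.atoms(self.monomer_b)

    def residues_a(self) -> list[Residue]:
        return self.structure.residues(self.monomer_a)

    def residues_b(self) -> list[Residue]:
        return self.structure.residues(self.monomer_b)

    def is_homodimer(self) -> bool:
        sa = "".join(self.structure.sequence(c) for c in self.monomer_a)
        sb = "".join(self.structure.sequence(c) for c in self.monomer_b)
        return sa == sb


def make_atom(serial: int, name: str, residue_index: int, coords,
              element: str | None = None, residue_name: str = "") -> Atom:
    """Build an Atom, inferring element, radius and hydrogen-bond roles."""
    el = element or element_from_name(name)
    if el not in VDW_RADIUS_NM:
        raise StructureError(f"no vdW radius for element {el!r} (atom {name})")
    donor = (name == "N" and residue_name != "PRO") or \
        name in SIDECHAIN_DONOR_ATOMS.get(residue_name, set())
    acceptor = (name in ("O", "OXT")) or \
        name in SIDECHAIN_ACCEPTOR_ATOMS.get(residue_name, set())
    return Atom(serial=serial, name=name, element=el,
                residue_index=residue_index, coords=np.asarray(coords, float),
                vdw_radius=VDW_RADIUS_NM[el], is_carbon=(el == "C"),
                is_donor_heavy=donor, is_acceptor=acceptor)


def _pick_altloc(bio_atom):
    if isinstance(bio_atom, DisorderedAtom):
        children = list(bio_atom.disordered_get_list())
        return max(children, key=lambda a: (a.get_occupancy() or 0.0))
    return bio_atom


def read_structure(path: str | Path, frame_policy: str = "first",
                   include_het: bool = False) -> Structure:
    """Read a PDB file into a Structure with coordinates in nm.

    Alternate locations are resolved to the highest-occupancy conformer;
    waters and hetero groups are excluded unless ``include_het``. With
    ``frame_policy="all"`` every MODEL becomes a coordinate frame (all
    models must share one topology); ``"first"`` keeps only the first.
    """
    if frame_policy not in ("first", "all"):
        raise ValueError("frame_policy must be 'first' or 'all'")
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        bio = parser.get_structure("s", str(path))
    except Exception as exc:  # Bio.PDB raises assorted exception types
        raise StructureError(f"failed to parse PDB {path}: {exc}") from exc

    models = list(bio.get_models())
    if not models:
        raise StructureError(f"no models in {path}")

    def build(model) -> tuple[dict[str, list[Residue]], np.ndarray]:
        chains: dict[str, list[Residue]] = {}
        xyz = []
        serial = 0
        for ch in model:
            residues: list[Residue] = []
            for res in ch:
                hetflag = res.id[0]
                if hetflag != " " and not include_het:
                    continue
                if res.get_resname() in ("HOH", "WAT"):
                    continue
                atoms: list[Atom] = []
                for ba in res:
                    ba = _pick_altloc(ba)
                    serial += 1
                    name = ba.get_name()
                    el = (ba.element or "").strip().upper() or None
                    coords = np.asarray(ba.get_coord(), float) * A_TO_NM
                    atoms.append(make_atom(serial, name, res.id[1], coords,
                                           element=el,
                                           residue_name=res.get_resname()))
                    xyz.append(coords)
                if atoms:
                    residues.append(Residue(index=res.id[1],
                                            name=res.get_resname(),
                                            chain_id=ch.id, atoms=atoms))
            if residues:
                chains[ch.id] = residues
        return chains, np.array(xyz)

    chains, xyz0 = build(models[0])
    n_atoms = sum(len(r.atoms) for rs in chains.values() for r in rs)
    if n_atoms == 0:
        raise StructureError(f"no ATOM records in {path}")

    frames = None
    if frame_policy == "all" and len(models) > 1:
        frames = [xyz0]
        topo = [(a.name, a.residue_index) for a in Structure(chains).atoms()]
        for m in models[1:]:
            ch_m, xyz_m = build(m)
            topo_m = [(a.name, a.residue_index) for a in Structure(ch_m).atoms()]
            if topo_m != topo:
                raise StructureError("MODEL frames differ in topology")
            frames.append(xyz_m)
    return Structure(chains, frames)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure to PDB (nm -> Angstrom), one MODEL per frame."""
    path = Path(path)
    lines: list[str] = []

    def emit(frame_atoms_coords):
        serial = 0
        it = iter(frame_atoms_coords)
        for cid, residues in structure.chains.items():
            for r in residues:
                for a in r.atoms:
                    serial += 1
                    x, y, z = next(it) * NM_TO_A
                    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                    lines.append(
                        f"ATOM  {serial:5d} {name:<4s}{r.name:>4s} {cid:1s}"
                        f"{r.index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                        f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}")
            lines.append("TER")

    if structure.n_frames > 1:
        for k, frame in enumerate(structure.frames, start=1):
            lines.append(f"MODEL     {k:4d}")
            emit(frame)
            lines.append("ENDMDL")
    else:
        emit([a.coords for a in structure.atoms()])
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def backbone_complete(residue: Residue) -> bool:
    names = {a.name for a in residue.atoms}
    return {"N", "CA", "C"} <= names


def is_backbone(atom: Atom) -> bool:
    return atom.name in BACKBONE_ATOMS


def atom_mass(atom: Atom) -> float:
    try:
        return MASSES[atom.element]
    except KeyError:
        raise StructureError(f"no mass for element {atom.element!r}")
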