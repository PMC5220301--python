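import numpy as np
import pytest

from dimerscope import FixturePlan, build_helix_dimer
from dimerscope.structure import Atom, DimerModel, Residue, Structure, make_atom


@pytest.fixture(scope="session")
def helix_dimer():
    """Default synthetic helix homodimer with planted bridges and a stack."""
    return build_helix_dimer(FixturePlan())


def toy_dimer(seed: int, n_atoms: int = 25, box: float = 1.5,
              names=("C",)) -> DimerModel:
    """Random two-chain atom cloud for brute-force detector comparisons."""
    rng = np.random.default_rng(seed)
    chains = {}
    for cid, offset in (("A", 0.0), ("B", 0.6)):
        residues = []
        for i in range(n_atoms):
            name = names[i % len(names)]
            xyz = rng.uniform(0, box, 3) + np.array([offset, 0, 0])
            atom = make_atom(i + 1, name, i + 1, xyz, residue_name="ALA")
            residues.append(Residue(index=i + 1, name="ALA", chain_id=cid,
                                    atoms=[atom]))
        chains[cid] = residues
    return DimerModel(Structure(chains), ["A"], ["B"], provenance=f"toy{seed}")


def single_atom_residue(name: str, resname: str, resid: int, chain: str,
                        coords) -> Residue:
    atom = make_atom(resid, name, resid, coords, residue_name=resname)
    return Residue(index=resid, name=resname, chain_id=chain, atoms=[atom])


def dimer_from_residues(res_a: list[Residue], res_b: list[Residue]
                        ) -> DimerModel:
    return DimerModel(Structure({"A": res_a, "B": res_b}), ["A"], ["B"])
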