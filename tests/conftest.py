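import numpy as np
import pytest

from tomodock.structures import Atom, Structure
from tomodock.toysystems import ToyPocketSpec, make_toy_ligands, make_toy_pocket


def make_atoms(coords, chain="A", resseq=1, resname="GLY", element="C",
               name_prefix="C", hetero=False):
    return [
        Atom(serial=i + 1, name=f"{name_prefix}{i + 1}", element=element,
             residue_name=resname, residue_seq=resseq, chain=chain,
             coords=tuple(float(v) for v in xyz), is_hetero=hetero)
        for i, xyz in enumerate(np.atleast_2d(coords))
    ]


def random_structure(rng, n_atoms=20, n_residues=4, chain="A"):
    atoms = []
    for i in range(n_atoms):
        atoms.append(
            Atom(
                serial=i + 1,
                name=f"C{i + 1}",
                element=rng.choice(["C", "N", "O"]),
                residue_name="GLY",
                residue_seq=1 + i % n_residues,
                chain=chain,
                coords=tuple(rng.uniform(-10, 10, 3)),
            )
        )
    return Structure(atoms, id="random")


@pytest.fixture(scope="session")
def toy_system():
    spec = ToyPocketSpec(seed=0)
    receptor, pocket, niche, filter_refs, truth = make_toy_pocket(spec)
    passing, blocked = make_toy_ligands(spec)
    return {
        "spec": spec,
        "receptor": receptor,
        "pocket": pocket,
        "niche": niche,
        "filter_refs": filter_refs,
        "truth": truth,
        "passing": passing,
        "blocked": blocked,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
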