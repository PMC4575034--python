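import numpy as np
import pytest

from pdnakit.structure import AtomRecord, ComplexStructure, ResidueRecord
from pdnakit._elements import element_mass, element_vdw_radius


def make_atom(name, x, y, z, element=None, serial=1, mass=None, radius=None, charge=0.0):
    element = element or name[0]
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        coords=np.array([x, y, z], dtype=float),
        mass=mass if mass is not None else element_mass(element),
        vdw_radius=radius if radius is not None else element_vdw_radius(element),
        partial_charge=charge,
    )


def make_residue(name, atoms, chain_id="A", seq_number=1, polymer_class="auto"):
    return ResidueRecord(
        name=name, chain_id=chain_id, seq_number=seq_number,
        atoms=atoms, polymer_class=polymer_class,
    )


def make_structure(residues, structure_id="test"):
    chains: dict[str, list] = {}
    for res in residues:
        chains.setdefault(res.chain_id, []).append(res)
    return ComplexStructure(id=structure_id, chains=chains)


@pytest.fixture
def gly_pdb_text():
    return (
        "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N\n"
        "ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C\n"
        "ATOM      3  C   GLY A   1       2.003   1.420   0.000  1.00  0.00           C\n"
        "ATOM      4  O   GLY A   1       1.246   2.390   0.000  1.00  0.00           O\n"
        "END\n"
    )


@pytest.fixture
def duplex():
    from pdnakit.synthetic import build_bdna

    return build_bdna("GCATGCAT")


# 38-bp model duplex used in the dendrimer–DNA worked examples
SEQUENCE_38BP = "GCCGCGAGGTGTCAGGGATTGCAGCCAGCATCTCGTCG"
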