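"""Shared fixtures: hand-written coordinate files and synthetic complexes."""

import numpy as np
import pytest

from structint import SyntheticComplexSpec, make_complex
from structint.structure import Atom, Chain, Residue, Structure

# Minimal hand-written two-residue, Cα-only model; B-factor column carries plDDT.
TINY_PDB = """\
HEADER    TEST FIXTURE
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 85.30           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00 42.10           C
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(TINY_PDB)
    return path


@pytest.fixture
def ring5():
    """Deterministic 5-chain ring complex with its dimer decomposition."""
    return make_complex(SyntheticComplexSpec(n_chains=5, geometry="ring", seed=11))


def make_point_chain(chain_id, ca_positions, plddts=None, aa="ALA", start_seq=1):
    """A Cα-only chain from explicit coordinates (test helper)."""
    ca_positions = np.asarray(ca_positions, dtype=float)
    if plddts is None:
        plddts = [90.0] * len(ca_positions)
    residues = [
        Residue(
            seq_id=start_seq + i,
            aa_code=aa,
            atoms=[Atom("CA", "C", pos)],
            plddt=float(plddts[i]),
        )
        for i, pos in enumerate(ca_positions)
    ]
    return Chain(chain_id=chain_id, residues=residues)


def random_chain(rng, chain_id, n_res, atoms_per_res=3, scale=20.0):
    """A random multi-atom chain for oracle-equivalence property tests."""
    residues = []
    for i in range(n_res):
        center = rng.uniform(-scale, scale, size=3)
        atom_names = ["CA", "CB", "NZ"][:atoms_per_res]
        atoms = [
            Atom(name, "C" if name != "NZ" else "N",
                 center + rng.normal(0, 1.0, size=3))
            for name in atom_names
        ]
        residues.append(
            Residue(seq_id=i + 1, aa_code="LYS", atoms=atoms,
                    plddt=float(rng.uniform(30, 100)))
        )
    return Chain(chain_id=chain_id, residues=residues)


def two_chain_structure(chain_a, chain_b, structure_id="pair"):
    return Structure(id=structure_id, chains=[chain_a, chain_b])
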