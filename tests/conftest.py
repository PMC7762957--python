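"""Shared fixtures: tiny hand-written PDB files and synthetic models."""

from __future__ import annotations

import numpy as np
import pytest

from phytomotion.rigid_geometry import RigidTransform, apply
from phytomotion.structure_io import (
    AtomRecord,
    Residue,
    ResidueRef,
    StructureModel,
    read_structure,
)

# a minimal, hand-written three-atom PDB (wwPDB v3.3 columns)
THREE_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 20.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 20.00           C
ATOM      3  C   ALA A   1      12.759   7.092  -4.973  1.00 20.00           C
END
"""

# one serine with a two-copy side chain (altlocs A occ 0.60 / B occ 0.40)
ALTLOC_PDB = """\
ATOM      1  N   SER A  10       0.000   0.000   0.000  1.00 15.00           N
ATOM      2  CA  SER A  10       1.458   0.000   0.000  1.00 15.00           C
ATOM      3  C   SER A  10       2.009   1.420   0.000  1.00 15.00           C
ATOM      4  O   SER A  10       1.251   2.390   0.000  1.00 15.00           O
ATOM      5  CB ASER A  10       1.980  -0.773   1.215  0.60 18.00           C
ATOM      6  CB BSER A  10       1.966  -0.805  -1.190  0.40 18.00           C
ATOM      7  OG ASER A  10       3.390  -0.850   1.190  0.60 22.00           O
ATOM      8  OG BSER A  10       3.375  -0.900  -1.150  0.40 22.00           O
END
"""


@pytest.fixture
def three_atom_model(tmp_path):
    path = tmp_path / "three_atom.pdb"
    path.write_text(THREE_ATOM_PDB)
    return read_structure(path)


@pytest.fixture
def altloc_model(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return read_structure(path)


def build_ca_chain(n_residues: int, chain_id: str = "A") -> StructureModel:
    """A synthetic chain of Ca-only residues numbered from 1."""
    residues = []
    for i in range(n_residues):
        ref = ResidueRef(chain_id, i + 1, "", "GLY")
        atom = AtomRecord(
            serial=i + 1,
            name="CA",
            element="C",
            altloc="",
            occupancy=1.0,
            bfactor=20.0,
            coords=np.array([3.8 * i, 0.0, 0.0]),
        )
        residues.append(Residue(ref=ref, atoms=[atom]))
    return StructureModel(id="ca_chain", chains={chain_id: residues})


def random_transform(rng: np.random.Generator) -> RigidTransform:
    """A uniformly random proper rotation plus a random translation."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    return RigidTransform(R, rng.standard_normal(3) * 20)


def transform_model(model: StructureModel, t: RigidTransform) -> StructureModel:
    """Apply a rigid transform to every atom of a model (new object)."""
    chains = {}
    for cid, residues in model.chains.items():
        new_res = []
        for res in residues:
            atoms = [
                AtomRecord(
                    serial=a.serial,
                    name=a.name,
                    element=a.element,
                    altloc=a.altloc,
                    occupancy=a.occupancy,
                    bfactor=a.bfactor,
                    coords=apply(t, a.coords[None, :])[0],
                )
                for a in res.atoms
            ]
            new_res.append(Residue(ref=res.ref, atoms=atoms, is_het=res.is_het))
        chains[cid] = new_res
    return StructureModel(id=model.id + "_moved", chains=chains)
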