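"""Shared fixtures: hand-built residues, toy complexes and PDB writers."""

from __future__ import annotations

import numpy as np
import pytest

from pepiface.chemistry import VDW_RADII, element_from_atom_name
from pepiface.structures import AtomRecord, ComplexSpec, ResidueRecord, StructureModel
from pepiface.synthetic import ToyComplexParams, make_toy_complex


def make_atom(name: str, coords, serial: int = 1, occupancy: float = 1.0) -> AtomRecord:
    element = element_from_atom_name(name)
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        alt_loc="",
        coords=np.asarray(coords, dtype=float),
        occupancy=occupancy,
        vdw_radius=VDW_RADII.get(element, 1.7),
    )


def make_residue(chain_id, res_seq, res_name, atom_specs) -> ResidueRecord:
    """``atom_specs`` is a list of (atom_name, (x, y, z))."""
    return ResidueRecord(
        chain_id=chain_id,
        res_seq=res_seq,
        icode="",
        res_name=res_name,
        atoms=[make_atom(n, c, serial=i + 1) for i, (n, c) in enumerate(atom_specs)],
    )


def single_chain_model(residues, chain_id="A", source_id="test") -> StructureModel:
    return StructureModel(chains={chain_id: list(residues)}, source_id=source_id)


@pytest.fixture
def leu_residue() -> ResidueRecord:
    """A leucine with its 8 heavy atoms at plausible coordinates."""
    return make_residue(
        "A",
        1,
        "LEU",
        [
            ("N", (0.0, 0.0, 0.0)),
            ("CA", (1.46, 0.0, 0.0)),
            ("C", (2.0, 1.4, 0.0)),
            ("O", (1.4, 2.4, 0.4)),
            ("CB", (2.0, -0.8, -1.2)),
            ("CG", (1.6, -2.3, -1.3)),
            ("CD1", (2.3, -3.0, -2.4)),
            ("CD2", (1.9, -3.0, 0.0)),
        ],
    )


@pytest.fixture(scope="session")
def toy_complex():
    """18-mer helix over a slab, gap 3 A, with ground-truth contacts."""
    params = ToyComplexParams("LSIEETNEIREKLGMKPI", gap=3.0, seed=0)
    model, contacts = make_toy_complex(params)
    return model, contacts


@pytest.fixture(scope="session")
def toy_spec() -> ComplexSpec:
    return ComplexSpec(frozenset({"A"}), frozenset({"C"}))


def random_rigid_transform(rng):
    """A seeded random proper rotation matrix and translation vector."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return rot.as_matrix(), rng.uniform(-20, 20, size=3)


def brute_force_residue_contacts(model, spec, cutoff):
    """O(n^2) all-pairs heavy-atom residue contact scan (test oracle)."""
    out = set()
    rec_res = list(model.iter_residues(set(spec.receptor_chains)))
    lig_res = list(model.iter_residues(set(spec.ligand_chains)))
    for rr in rec_res:
        for lr in lig_res:
            hit = False
            for ra in rr.heavy_atoms():
                for la in lr.heavy_atoms():
                    if np.linalg.norm(ra.coords - la.coords) <= cutoff:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                out.add((rr.key, lr.key))
    return out
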