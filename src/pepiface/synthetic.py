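"""Synthetic test-data generators.

Three generators make every downstream stage testable without external
structure downloads:

* :func:`make_toy_complex` — an ideal poly-peptide alpha helix docked
  against a rigid residue slab, with the heavy-atom contact list known
  by construction;
* :func:`make_decoy` — rigid-body perturbed copies of a reference
  complex with closed-form RMSD oracles;
* :func:`synth_interaction_table` — seeded random per-residue count
  matrices shaped like a truncation-scan interaction table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .chemistry import (
    AA_ONE_TO_THREE,
    SIDECHAIN_PSEUDO_ATOM,
    SIDECHAIN_REACH,
    VDW_RADII,
    element_from_atom_name,
)
from .network import InteractionTable
from .structures import AtomRecord, ComplexSpec, ResidueRecord, StructureModel

__all__ = [
    "ToyComplexParams",
    "DecoySpec",
    "make_toy_complex",
    "make_decoy",
    "synth_interaction_table",
]

# Ideal alpha-helix dihedrals (degrees).
PHI_HELIX = -57.0
PSI_HELIX = -47.0
OMEGA_TRANS = 180.0

# Standard backbone geometry: bond lengths (A) and angles (degrees).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O = 120.8
_A_C_CA_CB, _T_N_C_CA_CB = 110.1, 122.55


@dataclass(frozen=True)
class ToyComplexParams:
    peptide_sequence: str
    receptor_size: int = 48
    gap: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.peptide_sequence) < 1:
            raise ValueError("peptide sequence must be non-empty")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")


@dataclass(frozen=True)
class DecoySpec:
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    rotation_angle: float = 0.0
    seed: int = 0

    @staticmethod
    def random(seed: int, max_translation: float = 5.0, max_angle: float = 30.0) -> "DecoySpec":
        rng = np.random.default_rng(seed)
        t = rng.uniform(-max_translation, max_translation, size=3)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(0.0, max_angle)
        return DecoySpec(tuple(t), tuple(axis), float(angle), seed)


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom d from atoms a-b-c."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_ideal_helix(
    sequence: str,
    chain_id: str = "C",
    phi: float = PHI_HELIX,
    psi: float = PSI_HELIX,
) -> StructureModel:
    """Build an ideal alpha helix with N/CA/C/O backbone, CB, and one
    side-chain centroid pseudo-atom per residue."""
    res_names = []
    for letter in sequence:
        if letter not in AA_ONE_TO_THREE:
            raise ValueError(f"unknown residue letter {letter!r}")
        res_names.append(AA_ONE_TO_THREE[letter])

    n_atoms: list[np.ndarray] = []
    ca_atoms: list[np.ndarray] = []
    c_atoms: list[np.ndarray] = []
    for i in range(len(res_names)):
        if i == 0:
            n = np.zeros(3)
            ca = np.array([_B_N_CA, 0.0, 0.0])
            ang = math.radians(_A_N_CA_C)
            c = ca + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
        else:
            n = _place_atom(n_atoms[-1], ca_atoms[-1], c_atoms[-1], _B_C_N, _A_CA_C_N, psi)
            ca = _place_atom(ca_atoms[-1], c_atoms[-1], n, _B_N_CA, _A_C_N_CA, OMEGA_TRANS)
            c = _place_atom(c_atoms[-1], n, ca, _B_CA_C, _A_N_CA_C, phi)
        n_atoms.append(n)
        ca_atoms.append(ca)
        c_atoms.append(c)

    residues: list[ResidueRecord] = []
    serial = 0

    def add(res: ResidueRecord, name: str, pos: np.ndarray) -> None:
        nonlocal serial
        serial += 1
        element = element_from_atom_name(name)
        res.atoms.append(
            AtomRecord(
                serial=serial,
                name=name,
                element=element,
                alt_loc="",
                coords=pos,
                vdw_radius=VDW_RADII.get(element, VDW_RADII["C"]),
            )
        )

    for i, res_name in enumerate(res_names):
        res = ResidueRecord(chain_id=chain_id, res_seq=i + 1, icode="", res_name=res_name)
        n, ca, c = n_atoms[i], ca_atoms[i], c_atoms[i]
        add(res, "N", n)
        add(res, "CA", ca)
        add(res, "C", c)
        add(res, "O", _place_atom(n, ca, c, _B_C_O, _A_CA_C_O, psi + 180.0))
        if res_name != "GLY":
            cb = _place_atom(n, c, ca, _B_CA_CB, _A_C_CA_CB, _T_N_C_CA_CB)
            add(res, "CB", cb)
            reach = SIDECHAIN_REACH[res_name]
            pseudo_name = SIDECHAIN_PSEUDO_ATOM[res_name]
            if reach > _B_CA_CB and pseudo_name != "CB":
                direction = cb - ca
                direction /= np.linalg.norm(direction)
                add(res, pseudo_name, ca + reach * direction)
        residues.append(res)

    return StructureModel(chains={chain_id: residues}, source_id=f"helix:{sequence}")


def _residue_contacts(
    model: StructureModel, spec: ComplexSpec, cutoff: float
) -> list[tuple[tuple[str, int, str], tuple[str, int, str]]]:
    """Brute-force-equivalent residue-pair contact scan (KD-tree backed)."""
    rec = [(res.key, a.coords) for res, a in model.iter_atoms(set(spec.receptor_chains)) if not a.is_hydrogen]
    lig = [(res.key, a.coords) for res, a in model.iter_atoms(set(spec.ligand_chains)) if not a.is_hydrogen]
    if not rec or not lig:
        return []
    rec_xyz = np.array([c for _, c in rec])
    lig_xyz = np.array([c for _, c in lig])
    pairs = cKDTree(rec_xyz).query_ball_tree(cKDTree(lig_xyz), r=cutoff)
    found: set[tuple] = set()
    for ri, lig_idx in enumerate(pairs):
        for li in lig_idx:
            found.add((rec[ri][0], lig[li][0]))
    return sorted(found)


def make_toy_complex(
    params: ToyComplexParams, contact_cutoff: float = 5.0
) -> tuple[StructureModel, list[tuple[tuple[str, int, str], tuple[str, int, str]]]]:
    """Build helix-over-slab toy complex plus its ground-truth contact list.

    The peptide (chain ``C``) is an ideal alpha helix; the receptor
    (chain ``A``) is a rigid planar slab of alternating Gly/Ala residues
    positioned so the closest heavy-atom approach equals ``params.gap``.
    Returns the structure and the exact list of cross-interface residue
    pairs with any heavy-atom distance <= ``contact_cutoff``.
    """
    helix = build_ideal_helix(params.peptide_sequence, chain_id="C")
    pep_xyz = np.array([a.coords for _, a in helix.iter_atoms()])
    lo, hi = pep_xyz.min(axis=0), pep_xyz.max(axis=0)

    spacing = 4.0
    margin = 6.0
    nx = max(2, int(math.ceil((hi[0] - lo[0] + 2 * margin) / spacing)))
    ny = max(2, int(math.ceil((hi[1] - lo[1] + 2 * margin) / spacing)))
    n_res = min(params.receptor_size, nx * ny)

    slab_residues: list[ResidueRecord] = []
    serial = 10000
    positions = []
    for j in range(ny):
        for i in range(nx):
            positions.append((lo[0] - margin + i * spacing, lo[1] - margin + j * spacing))
    positions = positions[:n_res]

    slab_z = 0.0  # placed later via rigid shift
    for idx, (x, y) in enumerate(positions):
        res_name = "ALA" if idx % 2 == 0 else "GLY"
        res = ResidueRecord(chain_id="A", res_seq=idx + 1, icode="", res_name=res_name)
        base = np.array([x, y, slab_z])
        offsets = {
            "N": np.array([-1.2, -0.4, -0.6]),
            "CA": np.array([0.0, 0.0, -0.8]),
            "C": np.array([1.2, 0.4, -0.6]),
            "O": np.array([1.6, 1.2, -1.4]),
        }
        if res_name == "ALA":
            offsets["CB"] = np.array([0.0, -0.4, 0.0])  # slab-top atom
        for name, off in offsets.items():
            serial += 1
            element = element_from_atom_name(name)
            res.atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=element,
                    alt_loc="",
                    coords=base + off,
                    vdw_radius=VDW_RADII[element],
                )
            )
        slab_residues.append(res)

    slab = StructureModel(chains={"A": slab_residues}, source_id="slab")
    slab_xyz = np.array([a.coords for _, a in slab.iter_atoms()])

    # Slide the slab along z until the closest heavy-atom approach equals
    # the requested gap exactly; min-distance is continuous in dz, so a
    # bracketed root search converges to machine precision.
    tree = cKDTree(pep_xyz)

    def min_dist(dz: float) -> float:
        d, _ = tree.query(slab_xyz + np.array([0.0, 0.0, dz]))
        return float(d.min())

    target = max(params.gap, 1e-6)
    z_near = float(lo[2] - slab_xyz[:, 2].max())  # slab top touching helix bottom
    if min_dist(z_near) - target > 0:
        # already beyond the gap at contact height: move upward into range
        z_hi = z_near + 100.0
        dz = brentq(lambda z: min_dist(z) - target, z_near, z_hi, xtol=1e-10)
    else:
        z_far = z_near - max(200.0, 2 * target)
        dz = brentq(lambda z: min_dist(z) - target, z_far, z_near, xtol=1e-10)
    shift = np.array([0.0, 0.0, dz])
    for res in slab.chains["A"]:
        for atom in res.atoms:
            atom.coords = atom.coords + shift

    combined = StructureModel(
        chains={"A": slab.chains["A"], "C": helix.chains["C"]},
        source_id=f"toy:{params.peptide_sequence}:gap={params.gap}",
    )
    spec = ComplexSpec(frozenset({"A"}), frozenset({"C"}))
    contacts = _residue_contacts(combined, spec, contact_cutoff)
    return combined, contacts


def make_decoy(
    reference: StructureModel, spec: DecoySpec, complex_spec: ComplexSpec
) -> StructureModel:
    """Rigid-body perturb the ligand chains of ``reference``.

    The ligand is rotated about its own centroid by ``rotation_angle``
    degrees around ``rotation_axis``, then translated; the receptor is
    untouched.  A pure translation by ``t`` therefore yields a ligand
    RMSD of exactly ``|t|``.
    """
    missing = set(complex_spec.ligand_chains) - set(reference.chains)
    if missing:
        raise KeyError(f"ligand chains not in reference: {sorted(missing)}")
    axis = np.asarray(spec.rotation_axis, dtype=float)
    norm = np.linalg.norm(axis)
    if spec.rotation_angle != 0.0 and norm == 0.0:
        raise ValueError("rotation axis must be a non-zero vector")
    if norm > 0:
        axis = axis / norm
    rot = Rotation.from_rotvec(np.radians(spec.rotation_angle) * axis).as_matrix()

    lig_xyz = np.array(
        [a.coords for _, a in reference.iter_atoms(set(complex_spec.ligand_chains))]
    )
    centroid = lig_xyz.mean(axis=0)
    return reference.transformed(
        rotation=rot,
        translation=np.asarray(spec.translation, dtype=float),
        chains=set(complex_spec.ligand_chains),
        center=centroid,
    )


_COUNT_LAWS = ("poisson", "uniform", "zero")


def synth_interaction_table(
    n_peptides: int,
    n_residues: int,
    count_law: tuple[str, dict] = ("poisson", {"lam": 3.0}),
    seed: int = 0,
) -> InteractionTable:
    """Generate a seeded random interaction count matrix.

    ``count_law`` is ``(name, params)`` with name one of ``poisson``
    (param ``lam``), ``uniform`` (params ``low``/``high``, integer
    inclusive) or ``zero``.
    """
    if n_peptides < 1 or n_residues < 1:
        raise ValueError("n_peptides and n_residues must be >= 1")
    name, params = count_law
    rng = np.random.default_rng(seed)
    if name == "poisson":
        counts = rng.poisson(params.get("lam", 3.0), size=(n_peptides, n_residues))
    elif name == "uniform":
        counts = rng.integers(
            params.get("low", 0), params.get("high", 5) + 1, size=(n_peptides, n_residues)
        )
    elif name == "zero":
        counts = np.zeros((n_peptides, n_residues), dtype=int)
    else:
        raise ValueError(f"unsupported count law {name!r}; known: {_COUNT_LAWS}")
    scores = np.clip(rng.normal(5.0, 2.0, size=n_peptides), 0.0, None)
    return InteractionTable(
        residue_labels=[f"RES-{i + 1}" for i in range(n_residues)],
        peptide_ids=[f"Peptide-{i + 1}" for i in range(n_peptides)],
        counts=counts.astype(int),
        coop_scores=list(np.round(scores, 2)),
    )
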