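"""Structural data model and fixed-column PDB input/output.

The hierarchy is deliberately small: a :class:`StructureModel` maps chain
identifiers to ordered lists of :class:`ResidueRecord`, each holding its
:class:`AtomRecord` objects.  All downstream geometry keys on
``(chain_id, res_seq, icode)`` and PDB residue numbering is preserved
verbatim.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .chemistry import (
    BACKBONE_ATOMS,
    DEFAULT_VDW_RADIUS,
    STANDARD_RESIDUES,
    VDW_RADII,
    element_from_atom_name,
)

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "StructureModel",
    "ComplexSpec",
    "PDBFormatError",
    "read_pdb",
    "write_pdb",
    "select_atoms",
]


class PDBFormatError(ValueError):
    """Raised for malformed or empty PDB input and unwritable models."""


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    alt_loc: str
    coords: np.ndarray
    occupancy: float = 1.0
    vdw_radius: float = DEFAULT_VDW_RADIUS

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.name!r}: vdw_radius must be positive")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class ResidueRecord:
    chain_id: str
    res_seq: int
    icode: str
    res_name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.icode)

    @property
    def is_standard(self) -> bool:
        return self.res_name in STANDARD_RESIDUES

    @property
    def label(self) -> str:
        """Normalised ``RES-SEQ`` label, e.g. ``VAL-30``."""
        return f"{self.res_name.upper()}-{self.res_seq}"

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def sidechain_heavy_atoms(self) -> list[AtomRecord]:
        return [
            a
            for a in self.atoms
            if not a.is_hydrogen and a.name not in BACKBONE_ATOMS and a.name != "OXT"
        ]


@dataclass
class StructureModel:
    """Ordered chain -> residue -> atom hierarchy with coordinates in Angstrom."""

    chains: dict[str, list[ResidueRecord]] = field(default_factory=dict)
    source_id: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for chain_id, residues in self.chains.items():
            for res in residues:
                if res.chain_id != chain_id:
                    raise ValueError(
                        f"residue {res.key} filed under chain {chain_id!r}"
                    )
                if res.key in seen:
                    raise ValueError(f"duplicate residue identifier {res.key}")
                seen.add(res.key)

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def iter_residues(self, chains: set[str] | None = None):
        for chain_id, residues in self.chains.items():
            if chains is None or chain_id in chains:
                yield from residues

    def iter_atoms(self, chains: set[str] | None = None):
        for res in self.iter_residues(chains):
            for atom in res.atoms:
                yield res, atom

    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def residue(self, chain_id: str, res_seq: int, icode: str = "") -> ResidueRecord:
        for res in self.chains.get(chain_id, []):
            if res.res_seq == res_seq and res.icode == icode:
                return res
        raise KeyError(f"residue ({chain_id!r}, {res_seq}, {icode!r}) not found")

    def subset(self, chains: set[str]) -> "StructureModel":
        missing = set(chains) - set(self.chains)
        if missing:
            raise KeyError(f"chains not in model: {sorted(missing)}")
        return StructureModel(
            chains={c: [_copy_residue(r) for r in self.chains[c]] for c in self.chains if c in chains},
            source_id=self.source_id,
        )

    def copy(self) -> "StructureModel":
        return self.subset(set(self.chains))

    def transformed(
        self,
        rotation: np.ndarray | None = None,
        translation: np.ndarray | None = None,
        chains: set[str] | None = None,
        center: np.ndarray | None = None,
    ) -> "StructureModel":
        """Return a copy with ``x -> R @ (x - center) + center + t`` applied
        to the selected chains (all chains when ``chains`` is None)."""
        rot = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        trans = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        ctr = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        out = self.copy()
        for chain_id, residues in out.chains.items():
            if chains is not None and chain_id not in chains:
                continue
            for res in residues:
                for atom in res.atoms:
                    atom.coords = rot @ (atom.coords - ctr) + ctr + trans
        return out


def _copy_residue(res: ResidueRecord) -> ResidueRecord:
    return ResidueRecord(
        chain_id=res.chain_id,
        res_seq=res.res_seq,
        icode=res.icode,
        res_name=res.res_name,
        atoms=[replace(a, coords=a.coords.copy()) for a in res.atoms],
    )


@dataclass(frozen=True)
class ComplexSpec:
    """Receptor/ligand chain partition of a complex."""

    receptor_chains: frozenset[str]
    ligand_chains: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "receptor_chains", frozenset(self.receptor_chains))
        object.__setattr__(self, "ligand_chains", frozenset(self.ligand_chains))
        if not self.receptor_chains or not self.ligand_chains:
            raise ValueError("receptor and ligand chain sets must be non-empty")
        if self.receptor_chains & self.ligand_chains:
            raise ValueError(
                "receptor and ligand chain sets overlap: "
                f"{sorted(self.receptor_chains & self.ligand_chains)}"
            )

    @property
    def all_chains(self) -> frozenset[str]:
        return self.receptor_chains | self.ligand_chains


# --- PDB reading -----------------------------------------------------------

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def read_pdb(
    path,
    keep_hydrogens: bool = False,
    keep_het: bool = False,
    radii: dict[str, float] | None = None,
) -> StructureModel:
    """Parse fixed-column ATOM/HETATM records into a :class:`StructureModel`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties break to the first record).  Waters are always dropped; other
    HETATM records are dropped unless ``keep_het``.  Elements are taken
    from columns 77-78 when present, otherwise inferred from the atom
    name; van der Waals radii come from the packaged table, with a
    warning and :data:`DEFAULT_VDW_RADIUS` for unknown elements.
    """
    radius_table = VDW_RADII if radii is None else radii
    try:
        with open(path) as handle:
            lines = handle.readlines()
    except OSError as exc:
        raise OSError(f"cannot read PDB file {path!r}: {exc}") from exc

    # (chain, res_seq, icode) -> residue; within residue, atom name -> best altloc
    chains: dict[str, list[ResidueRecord]] = {}
    residues: dict[tuple[str, int, str], ResidueRecord] = {}
    best: dict[tuple[str, int, str, str], float] = {}
    n_atom_records = 0

    for line in lines:
        rectype = line[:6]
        if rectype not in ("ATOM  ", "HETATM"):
            continue
        res_name = line[17:20].strip()
        if rectype == "HETATM":
            if res_name in _WATER_NAMES or not keep_het:
                continue
        elif res_name in _WATER_NAMES:
            continue
        n_atom_records += 1

        name = line[12:16].strip()
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
        if not element:
            element = element_from_atom_name(line[12:16])
        if element == "H" and not keep_hydrogens:
            continue

        try:
            serial = int(line[6:11])
        except ValueError:
            serial = n_atom_records
        alt_loc = line[16].strip()
        chain_id = line[21].strip() or " "
        res_seq = int(line[22:26])
        icode = line[26].strip()
        coords = np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        )
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0

        if element in radius_table:
            radius = radius_table[element]
        else:
            warnings.warn(
                f"atom {serial} ({name}): no vdW radius for element "
                f"{element!r}, using default {DEFAULT_VDW_RADIUS} A",
                stacklevel=2,
            )
            radius = DEFAULT_VDW_RADIUS

        key = (chain_id, res_seq, icode)
        if key not in residues:
            res = ResidueRecord(chain_id=chain_id, res_seq=res_seq, icode=icode, res_name=res_name)
            residues[key] = res
            chains.setdefault(chain_id, []).append(res)
        res = residues[key]

        atom = AtomRecord(
            serial=serial,
            name=name,
            element=element,
            alt_loc=alt_loc,
            coords=coords,
            occupancy=occupancy,
            vdw_radius=radius,
        )
        akey = key + (name,)
        existing = res.atom(name)
        if existing is None:
            res.atoms.append(atom)
            best[akey] = occupancy
        elif occupancy > best[akey]:
            res.atoms[res.atoms.index(existing)] = atom
            best[akey] = occupancy

    if n_atom_records == 0:
        raise PDBFormatError(f"{path!r}: no ATOM records found")
    return StructureModel(chains=chains, source_id=str(path))


# --- PDB writing -----------------------------------------------------------

def write_pdb(model: StructureModel, path) -> None:
    """Write standard fixed-column ATOM records with TER between chains."""
    if not model.chains or model.n_atoms() == 0:
        raise ValueError("cannot write an empty model")
    lines: list[str] = []
    serial = 0
    for chain_id, chain_residues in model.chains.items():
        last = None
        for res in chain_residues:
            for atom in res.atoms:
                serial += 1
                x, y, z = atom.coords
                if any(abs(v) >= 10000 or not math.isfinite(v) for v in (x, y, z)):
                    raise PDBFormatError(
                        f"atom {atom.name} in {res.key}: coordinate exceeds PDB field width"
                    )
                # 4-char atom-name field: names of 1-letter elements start
                # at column 14 unless the name itself is 4 characters.
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s} "
                    f"{res.res_name:>3s} {chain_id:1s}{res.res_seq:4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
                last = res
        if last is not None:
            serial += 1
            lines.append(
                f"TER   {serial:5d}      {last.res_name:>3s} "
                f"{chain_id:1s}{last.res_seq:4d}{last.icode or ' ':1s}"
            )
    lines.append("END")
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")


# --- selections ------------------------------------------------------------

def select_atoms(
    model: StructureModel,
    chains: set[str] | None = None,
    atom_names="heavy",
) -> tuple[np.ndarray, list[tuple[str, int, str, str]]]:
    """Select atoms as an ``(n, 3)`` coordinate matrix plus an index map.

    ``atom_names`` may be ``"heavy"`` (all non-hydrogen), ``"backbone"``
    (N, CA, C, O), ``"all"``, or an explicit set of atom names.  The
    index map records ``(chain_id, res_seq, icode, atom_name)`` per row.
    """
    if chains is not None:
        missing = set(chains) - set(model.chains)
        if missing:
            raise KeyError(f"chains not in model: {sorted(missing)}")

    if isinstance(atom_names, str):
        selector = atom_names
        if selector == "backbone":
            wanted = BACKBONE_ATOMS
        elif selector in ("heavy", "all"):
            wanted = None
        else:
            raise ValueError(f"unknown selector {atom_names!r}")
    else:
        selector = "named"
        wanted = frozenset(atom_names)

    coords: list[np.ndarray] = []
    index: list[tuple[str, int, str, str]] = []
    for res, atom in model.iter_atoms(chains):
        if selector != "all" and atom.is_hydrogen:
            continue
        if wanted is not None and atom.name not in wanted:
            continue
        coords.append(atom.coords)
        index.append((res.chain_id, res.res_seq, res.icode, atom.name))
    if not coords:
        raise ValueError(
            f"selection {selector!r} on chains "
            f"{sorted(chains) if chains else 'ALL'} matched no atoms"
        )
    return np.asarray(coords, dtype=float), index
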