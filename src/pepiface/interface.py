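"""Interface characterization: SASA, buried surface area, solvation gain
and polar-bond detection.

SASA uses the Shrake-Rupley algorithm with a deterministic
generalized-spiral quadrature sphere so that every run of the same
structure yields bitwise-identical areas.  The interface criterion is
per-residue buried surface area (isolated-chain ASA minus in-complex
ASA) above a small floor that suppresses quadrature noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .chemistry import (
    ANION_ATOMS,
    CATION_ATOMS,
    SIDECHAIN_ACCEPTORS,
    SIDECHAIN_DONORS,
    SOLVATION_SIGMA,
)
from .network import AtomRef
from .structures import ComplexSpec, StructureModel

__all__ = [
    "PolarBond",
    "ResidueInterfaceRow",
    "ChainTotals",
    "InterfaceReport",
    "sphere_points",
    "compute_sasa",
    "interface_report",
    "solvation_gain",
    "detect_polar_bonds",
]

AtomKey = tuple[str, int, str, str]  # chain, res_seq, icode, atom_name

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960
DEFAULT_BSA_FLOOR = 0.01


def sphere_points(n: int) -> np.ndarray:
    """Deterministic generalized-spiral (golden-angle) unit-sphere points."""
    if n < 32:
        raise ValueError(f"quadrature too coarse: n_points={n} < 32")
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    theta = np.pi * (1.0 + 5.0**0.5) * k
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def compute_sasa(
    model: StructureModel,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> dict[AtomKey, float]:
    """Per-atom solvent-accessible surface area (Shrake-Rupley).

    Hydrogens are ignored.  Each heavy atom's probe-expanded sphere is
    sampled at ``n_points`` deterministic quadrature points; the ASA is
    the unoccluded fraction times the expanded-sphere area.
    """
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    unit = sphere_points(n_points)

    keys: list[AtomKey] = []
    coords: list[np.ndarray] = []
    radii: list[float] = []
    for res, atom in model.iter_atoms():
        if atom.is_hydrogen:
            continue
        keys.append((res.chain_id, res.res_seq, res.icode, atom.name))
        coords.append(atom.coords)
        radii.append(atom.vdw_radius + probe)
    if not coords:
        return {}
    xyz = np.asarray(coords)
    expanded = np.asarray(radii)

    tree = cKDTree(xyz)
    max_r = expanded.max()
    areas: dict[AtomKey, float] = {}
    for i, key in enumerate(keys):
        ri = expanded[i]
        neighbor_idx = [
            j
            for j in tree.query_ball_point(xyz[i], ri + max_r)
            if j != i and np.linalg.norm(xyz[j] - xyz[i]) < ri + expanded[j]
        ]
        pts = xyz[i] + ri * unit
        if neighbor_idx:
            nb_xyz = xyz[neighbor_idx]
            nb_r = expanded[neighbor_idx]
            d2 = ((pts[:, None, :] - nb_xyz[None, :, :]) ** 2).sum(axis=-1)
            buried = (d2 < (nb_r**2)[None, :]).any(axis=1)
            n_free = int((~buried).sum())
        else:
            n_free = n_points
        areas[key] = 4.0 * np.pi * ri * ri * n_free / n_points
    return areas


@dataclass
class ResidueInterfaceRow:
    chain_id: str
    res_seq: int
    icode: str
    res_name: str
    asa_isolated: float
    asa_complex: float
    bsa: float
    is_interface: bool
    delta_i_g: float = 0.0

    @property
    def label(self) -> str:
        return f"{self.res_name.upper()}-{self.res_seq}"


@dataclass
class ChainTotals:
    chain_ids: tuple[str, ...]
    n_interface_atoms: int
    n_surface_atoms: int
    n_total_atoms: int
    n_interface_residues: int
    n_surface_residues: int
    n_total_residues: int
    interface_area: float
    total_area: float
    solvation_isolated: float
    solvation_gain: float

    @property
    def pct_interface_residues(self) -> float:
        return 100.0 * self.n_interface_residues / max(self.n_total_residues, 1)


@dataclass
class InterfaceReport:
    per_residue: list[ResidueInterfaceRow]
    receptor_totals: ChainTotals
    ligand_totals: ChainTotals
    probe: float
    bsa_floor: float

    def rows_for(self, side: str) -> list[ResidueInterfaceRow]:
        chains = (
            self.receptor_totals.chain_ids if side == "receptor" else self.ligand_totals.chain_ids
        )
        return [r for r in self.per_residue if r.chain_id in chains]

    def interface_residues(self, side: str) -> list[ResidueInterfaceRow]:
        return [r for r in self.rows_for(side) if r.is_interface]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chain": r.chain_id,
                    "res_seq": r.res_seq,
                    "icode": r.icode,
                    "res_name": r.res_name,
                    "asa_isolated": round(r.asa_isolated, 3),
                    "asa_complex": round(r.asa_complex, 3),
                    "bsa": round(r.bsa, 3),
                    "is_interface": r.is_interface,
                    "delta_i_g": round(r.delta_i_g, 4),
                }
                for r in self.per_residue
            ]
        )

    def totals_frame(self) -> pd.DataFrame:
        rows = []
        for side, tot in (("receptor", self.receptor_totals), ("ligand", self.ligand_totals)):
            rows.append(
                {
                    "side": side,
                    "chains": "".join(tot.chain_ids),
                    "n_interface_atoms": tot.n_interface_atoms,
                    "n_surface_atoms": tot.n_surface_atoms,
                    "n_total_atoms": tot.n_total_atoms,
                    "n_interface_residues": tot.n_interface_residues,
                    "n_surface_residues": tot.n_surface_residues,
                    "n_total_residues": tot.n_total_residues,
                    "interface_area": round(tot.interface_area, 2),
                    "total_area": round(tot.total_area, 2),
                    "solvation_isolated": round(tot.solvation_isolated, 3),
                    "solvation_gain": round(tot.solvation_gain, 3),
                }
            )
        return pd.DataFrame(rows)


def _side_totals(
    chains: tuple[str, ...],
    model: StructureModel,
    rows: list[ResidueInterfaceRow],
    atom_asa_isolated: dict[AtomKey, float],
    atom_delta: dict[AtomKey, float],
) -> ChainTotals:
    chain_set = set(chains)
    side_rows = [r for r in rows if r.chain_id in chain_set]
    n_total_atoms = sum(
        1 for res, a in model.iter_atoms(chain_set) if not a.is_hydrogen
    )
    n_surface_atoms = 0
    n_interface_atoms = 0
    for res, atom in model.iter_atoms(chain_set):
        if atom.is_hydrogen:
            continue
        key = (res.chain_id, res.res_seq, res.icode, atom.name)
        if atom_asa_isolated.get(key, 0.0) > 1e-12:
            n_surface_atoms += 1
        if atom_delta.get(key, 0.0) > 1e-12:
            n_interface_atoms += 1
    return ChainTotals(
        chain_ids=chains,
        n_interface_atoms=n_interface_atoms,
        n_surface_atoms=n_surface_atoms,
        n_total_atoms=n_total_atoms,
        n_interface_residues=sum(1 for r in side_rows if r.is_interface),
        n_surface_residues=sum(1 for r in side_rows if r.asa_isolated > 1e-12),
        n_total_residues=len(side_rows),
        interface_area=sum(r.bsa for r in side_rows if r.bsa > 0),
        total_area=sum(r.asa_isolated for r in side_rows),
        solvation_isolated=0.0,
        solvation_gain=0.0,
    )


def interface_report(
    model: StructureModel,
    spec: ComplexSpec,
    probe: float = DEFAULT_PROBE,
    bsa_floor: float = DEFAULT_BSA_FLOOR,
    n_points: int = DEFAULT_N_POINTS,
    asp_table: dict[str, float] | None = None,
) -> InterfaceReport:
    """Characterize the receptor/ligand interface of a complex.

    ASA is computed for each side in isolation and in the complex;
    a residue is an interface residue iff its buried area exceeds
    ``bsa_floor``; an atom is an interface atom iff its own ASA drops on
    complexation.  Solvation gains use the packaged atomic solvation
    parameters (see :func:`solvation_gain`).
    """
    missing = set(spec.all_chains) - set(model.chains)
    if missing:
        raise KeyError(f"chains not in model: {sorted(missing)}")

    receptor = model.subset(set(spec.receptor_chains))
    ligand = model.subset(set(spec.ligand_chains))
    both = model.subset(set(spec.all_chains))

    asa_rec = compute_sasa(receptor, probe, n_points)
    asa_lig = compute_sasa(ligand, probe, n_points)
    asa_iso = {**asa_rec, **asa_lig}
    asa_cpx = compute_sasa(both, probe, n_points)
    atom_delta = {k: asa_iso[k] - asa_cpx.get(k, 0.0) for k in asa_iso}

    rows: list[ResidueInterfaceRow] = []
    for res in both.iter_residues():
        iso = cpx = 0.0
        for atom in res.heavy_atoms():
            key = (res.chain_id, res.res_seq, res.icode, atom.name)
            iso += asa_iso.get(key, 0.0)
            cpx += asa_cpx.get(key, 0.0)
        bsa = iso - cpx
        rows.append(
            ResidueInterfaceRow(
                chain_id=res.chain_id,
                res_seq=res.res_seq,
                icode=res.icode,
                res_name=res.res_name,
                asa_isolated=iso,
                asa_complex=cpx,
                bsa=bsa,
                is_interface=bsa > bsa_floor,
            )
        )

    rec_totals = _side_totals(
        tuple(sorted(spec.receptor_chains)), both, rows, asa_iso, atom_delta
    )
    lig_totals = _side_totals(
        tuple(sorted(spec.ligand_chains)), both, rows, asa_iso, atom_delta
    )
    report = InterfaceReport(
        per_residue=rows,
        receptor_totals=rec_totals,
        ligand_totals=lig_totals,
        probe=probe,
        bsa_floor=bsa_floor,
    )
    solvation_gain(report, model, asa_iso, atom_delta, asp_table=asp_table)
    return report


def solvation_gain(
    report: InterfaceReport,
    model: StructureModel,
    atom_asa_isolated: dict[AtomKey, float],
    atom_delta: dict[AtomKey, float],
    asp_table: dict[str, float] | None = None,
) -> InterfaceReport:
    """Fill per-residue and per-chain solvation free-energy terms in place.

    ``gain(residue) = sum_atoms sigma(element) * dASA(atom)``; apolar
    elements carry negative sigma so burying hydrophobic area yields a
    negative (favourable) gain.  Atoms whose element has no entry in the
    table contribute zero (with a warning).  The isolated-structure
    solvation term is ``sum sigma * ASA_isolated`` per side.
    """
    import warnings

    sigma = SOLVATION_SIGMA if asp_table is None else asp_table
    per_res_gain: dict[tuple[str, int, str], float] = {}
    per_key_iso: dict[tuple[str, int, str], float] = {}
    warned: set[str] = set()
    for res, atom in model.iter_atoms():
        if atom.is_hydrogen:
            continue
        key = (res.chain_id, res.res_seq, res.icode, atom.name)
        if key not in atom_asa_isolated:
            continue
        if atom.element not in sigma:
            if atom.element not in warned:
                warnings.warn(
                    f"no solvation parameter for element {atom.element!r}; "
                    "contribution set to zero",
                    stacklevel=2,
                )
                warned.add(atom.element)
            continue
        s = sigma[atom.element]
        rkey = (res.chain_id, res.res_seq, res.icode)
        per_res_gain[rkey] = per_res_gain.get(rkey, 0.0) + s * atom_delta.get(key, 0.0)
        per_key_iso[rkey] = per_key_iso.get(rkey, 0.0) + s * atom_asa_isolated[key]

    for row in report.per_residue:
        row.delta_i_g = per_res_gain.get((row.chain_id, row.res_seq, row.icode), 0.0)
    for totals in (report.receptor_totals, report.ligand_totals):
        chain_set = set(totals.chain_ids)
        rows = [r for r in report.per_residue if r.chain_id in chain_set]
        totals.solvation_gain = sum(r.delta_i_g for r in rows)
        totals.solvation_isolated = sum(
            per_key_iso.get((r.chain_id, r.res_seq, r.icode), 0.0) for r in rows
        )
    return report


# --- polar bonds -----------------------------------------------------------

@dataclass(frozen=True)
class PolarBond:
    kind: str  # hydrogen_bond | salt_bridge
    receptor_atom: AtomRef
    ligand_atom: AtomRef
    donor_side: str  # "receptor" | "ligand" (cation side for salt bridges)
    distance: float
    angle: float | None = None  # antecedent-donor-acceptor, degrees


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _polar_atoms(model: StructureModel, chains: frozenset[str]):
    """Collect donor (with antecedent), acceptor, cation and anion atoms."""
    donors, acceptors, cations, anions = [], [], [], []
    for res in model.iter_residues(set(chains)):
        donor_map = dict(SIDECHAIN_DONORS.get(res.res_name, {}))
        if res.res_name != "PRO":
            donor_map["N"] = "CA"
        acceptor_set = set(SIDECHAIN_ACCEPTORS.get(res.res_name, frozenset())) | {"O", "OXT"}
        cation_set = CATION_ATOMS.get(res.res_name, frozenset())
        anion_set = ANION_ATOMS.get(res.res_name, frozenset())
        for atom in res.atoms:
            if atom.is_hydrogen:
                continue
            ref = AtomRef(
                res.chain_id, res.res_seq, res.icode, res.res_name,
                atom.name, tuple(atom.coords),
            )
            if atom.name in donor_map:
                antecedent = res.atom(donor_map[atom.name])
                donors.append((ref, None if antecedent is None else antecedent.coords))
            if atom.name in acceptor_set:
                acceptors.append(ref)
            if atom.name in cation_set and atom.element == "N":
                cations.append(ref)
            if atom.name in anion_set:
                anions.append(ref)
    return donors, acceptors, cations, anions


def detect_polar_bonds(
    model: StructureModel,
    spec: ComplexSpec,
    hb_dist: float = 3.5,
    hb_angle: float = 90.0,
    sb_dist: float = 4.0,
) -> list[PolarBond]:
    """Detect cross-interface hydrogen bonds and salt bridges (heavy atoms).

    A hydrogen bond is a donor-heavy to acceptor distance <= ``hb_dist``
    whose antecedent-donor-acceptor angle is >= ``hb_angle`` when the
    donor's antecedent atom is resolvable (the angle test is skipped
    otherwise).  A salt bridge pairs an Arg/Lys/His side-chain nitrogen
    with an Asp/Glu side-chain oxygen at <= ``sb_dist``.
    """
    rec = _polar_atoms(model, spec.receptor_chains)
    lig = _polar_atoms(model, spec.ligand_chains)
    bonds: list[PolarBond] = []

    def scan_hb(donors, acceptors, donor_side: str):
        for donor_ref, antecedent in donors:
            d_xyz = np.array(donor_ref.coords)
            for acc_ref in acceptors:
                a_xyz = np.array(acc_ref.coords)
                dist = float(np.linalg.norm(d_xyz - a_xyz))
                if dist > hb_dist or dist < 1e-6:
                    continue
                angle = None
                if antecedent is not None:
                    angle = _angle_deg(np.asarray(antecedent), d_xyz, a_xyz)
                    if angle < hb_angle:
                        continue
                receptor_atom = donor_ref if donor_side == "receptor" else acc_ref
                ligand_atom = acc_ref if donor_side == "receptor" else donor_ref
                bonds.append(
                    PolarBond("hydrogen_bond", receptor_atom, ligand_atom, donor_side, dist, angle)
                )

    scan_hb(rec[0], lig[1], "receptor")
    scan_hb(lig[0], rec[1], "ligand")

    def scan_sb(cations, anions, cation_side: str):
        for cat in cations:
            c_xyz = np.array(cat.coords)
            for an in anions:
                dist = float(np.linalg.norm(c_xyz - np.array(an.coords)))
                if dist <= sb_dist:
                    receptor_atom = cat if cation_side == "receptor" else an
                    ligand_atom = an if cation_side == "receptor" else cat
                    bonds.append(
                        PolarBond("salt_bridge", receptor_atom, ligand_atom, cation_side, dist)
                    )

    scan_sb(rec[2], lig[3], "receptor")
    scan_sb(lig[2], rec[3], "ligand")
    return bonds
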