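"""Cross-interface contact typing, per-residue counting and hot-spot ranking."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemistry import APOLAR_ATOMS
from .structures import ComplexSpec, StructureModel

__all__ = [
    "AtomRef",
    "ContactRecord",
    "InteractionTable",
    "HotspotRanking",
    "type_contacts",
    "count_per_residue",
    "cooperativity_score",
    "rank_hotspots",
    "aggregate_scores",
    "round_half_up",
]

CONTACT_WEIGHTS = {"hydrophobic": 0.5, "hydrogen_bond": 1.0, "salt_bridge": 1.5}


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (0.5 -> 1), unlike banker's rounding."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class AtomRef:
    chain_id: str
    res_seq: int
    icode: str
    res_name: str
    atom_name: str
    coords: tuple[float, float, float]

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.icode)

    @property
    def residue_label(self) -> str:
        return f"{self.res_name.upper()}-{self.res_seq}"


@dataclass(frozen=True)
class ContactRecord:
    receptor: AtomRef
    ligand: AtomRef
    distance: float
    kind: str  # hydrophobic | hydrogen_bond | salt_bridge

    def __post_init__(self) -> None:
        if self.kind not in CONTACT_WEIGHTS:
            raise ValueError(f"unknown contact kind {self.kind!r}")


@dataclass
class InteractionTable:
    """Peptides x receptor-residues integer count matrix with per-peptide scores."""

    residue_labels: list[str]
    peptide_ids: list[str]
    counts: np.ndarray
    coop_scores: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.peptide_ids), len(self.residue_labels)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.peptide_ids)} peptides x {len(self.residue_labels)} residues"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def column_totals(self) -> dict[str, int]:
        return dict(zip(self.residue_labels, self.counts.sum(axis=0).tolist()))

    def row_totals(self) -> dict[str, int]:
        return dict(zip(self.peptide_ids, self.counts.sum(axis=1).tolist()))

    def grand_total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.counts, index=self.peptide_ids, columns=self.residue_labels)
        if self.coop_scores:
            frame["CooperativityScore"] = self.coop_scores
        frame.index.name = "ID"
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "InteractionTable":
        scores = []
        if "CooperativityScore" in frame.columns:
            scores = frame["CooperativityScore"].astype(float).tolist()
            frame = frame.drop(columns=["CooperativityScore"])
        return cls(
            residue_labels=list(frame.columns),
            peptide_ids=list(frame.index),
            counts=frame.to_numpy(dtype=int),
            coop_scores=scores,
        )


@dataclass
class HotspotRanking:
    residue_labels: list[str]  # non-increasing by total count
    totals: list[int]
    k: int
    top_k_fraction: int | None  # whole percent; None when grand total is 0

    @property
    def top_residues(self) -> list[str]:
        return self.residue_labels[: self.k]

    @property
    def fraction_defined(self) -> bool:
        return self.top_k_fraction is not None


# --- contact typing --------------------------------------------------------

def _apolar_atom_refs(model: StructureModel, chains: frozenset[str]) -> list[AtomRef]:
    refs = []
    for res in model.iter_residues(set(chains)):
        apolar = APOLAR_ATOMS.get(res.res_name, frozenset())
        for atom in res.atoms:
            if atom.name in apolar and not atom.is_hydrogen:
                refs.append(
                    AtomRef(
                        res.chain_id, res.res_seq, res.icode, res.res_name,
                        atom.name, tuple(atom.coords),
                    )
                )
    return refs


def type_contacts(
    model: StructureModel,
    spec: ComplexSpec,
    hydrophobic_cutoff: float = 4.5,
    hb_dist: float = 3.5,
    hb_angle: float = 90.0,
    sb_dist: float = 4.0,
) -> list[ContactRecord]:
    """Type all cross-interface contacts of a complex.

    Hydrophobic contacts pair apolar atoms (per the packaged residue
    polarity table) across the interface at <= ``hydrophobic_cutoff``;
    hydrogen bonds and salt bridges are delegated to
    :func:`pepiface.interface.detect_polar_bonds` and merged in.
    """
    from .interface import detect_polar_bonds  # deferred: avoids import cycle

    missing = set(spec.all_chains) - set(model.chains)
    if missing:
        raise KeyError(f"chains not in model: {sorted(missing)}")

    contacts: list[ContactRecord] = []
    rec_refs = _apolar_atom_refs(model, spec.receptor_chains)
    lig_refs = _apolar_atom_refs(model, spec.ligand_chains)
    for r in rec_refs:
        rx = np.array(r.coords)
        for l in lig_refs:
            d = float(np.linalg.norm(rx - np.array(l.coords)))
            if d <= hydrophobic_cutoff:
                contacts.append(ContactRecord(r, l, d, "hydrophobic"))

    for bond in detect_polar_bonds(model, spec, hb_dist=hb_dist, hb_angle=hb_angle, sb_dist=sb_dist):
        contacts.append(
            ContactRecord(bond.receptor_atom, bond.ligand_atom, bond.distance, bond.kind)
        )
    return contacts


def count_per_residue(
    contacts: list[ContactRecord],
    peptide_id: str,
    residue_labels: list[str] | None = None,
) -> tuple[str, dict[str, int]]:
    """Count contacts per receptor residue for one peptide complex.

    Returns ``(peptide_id, {residue_label: count})``.  When
    ``residue_labels`` is given the result covers exactly those labels
    (zero-filled); otherwise labels are taken from the contacts.
    """
    counts: dict[str, int] = {}
    if residue_labels is not None:
        counts = {label: 0 for label in residue_labels}
    for c in contacts:
        label = c.receptor.residue_label
        if residue_labels is not None and label not in counts:
            continue
        counts[label] = counts.get(label, 0) + 1
    return peptide_id, counts


def rows_to_table(
    rows: list[tuple[str, dict[str, int]]],
    coop_scores: list[float] | None = None,
) -> InteractionTable:
    """Assemble :func:`count_per_residue` rows into an :class:`InteractionTable`."""
    labels = sorted({label for _, counts in rows for label in counts}, key=_label_sort_key)
    matrix = np.array(
        [[counts.get(label, 0) for label in labels] for _, counts in rows], dtype=int
    )
    return InteractionTable(
        residue_labels=labels,
        peptide_ids=[pid for pid, _ in rows],
        counts=matrix,
        coop_scores=coop_scores or [],
    )


def _label_sort_key(label: str) -> tuple[int, str]:
    try:
        return (int(label.rsplit("-", 1)[1]), label)
    except (IndexError, ValueError):
        return (10**9, label)


def cooperativity_score(
    contacts: list[ContactRecord],
    neighbor_radius: float = 6.0,
    bonus: float = 0.1,
) -> float:
    """Network-style interface score in which clustered contacts reinforce.

    ``score = sum_c w(kind_c) * (1 + bonus * deg(c))`` where ``deg(c)``
    counts the other contacts whose receptor atoms lie within
    ``neighbor_radius`` of c's receptor atom.  This is a documented
    surrogate for proprietary interaction-network scores: only ordering
    properties are contractual, not absolute values.
    """
    if not contacts:
        return 0.0
    xyz = np.array([c.receptor.coords for c in contacts])
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    degree = (dist <= neighbor_radius).sum(axis=1) - 1  # exclude self
    weights = np.array([CONTACT_WEIGHTS[c.kind] for c in contacts])
    return float(np.sum(weights * (1.0 + bonus * degree)))


def rank_hotspots(table: InteractionTable, k: int = 5) -> HotspotRanking:
    """Rank receptor residues by total interaction count.

    Ties break toward the lower residue number.  ``top_k_fraction`` is
    the top-k share of the grand total as a whole percent (half-up);
    it is ``None`` (undefined) when the table is all zero.
    """
    if not table.residue_labels:
        raise ValueError("interaction table has no residue columns")
    totals = table.column_totals()
    ordered = sorted(
        totals.items(), key=lambda item: (-item[1],) + _label_sort_key(item[0])
    )
    labels = [label for label, _ in ordered]
    counts = [count for _, count in ordered]
    grand = sum(counts)
    if grand == 0:
        fraction = None
    else:
        fraction = int(round_half_up(100.0 * sum(counts[:k]) / grand))
    return HotspotRanking(residue_labels=labels, totals=counts, k=k, top_k_fraction=fraction)


def aggregate_scores(
    table: InteractionTable, peptide_filter=None
) -> dict[str, float | int | None]:
    """Mean and sample SD of cooperativity scores over filtered peptides.

    ``peptide_filter`` is a predicate on the peptide id (None keeps all).
    With a single surviving peptide the SD is undefined and reported as
    ``None``.
    """
    if not table.coop_scores:
        raise ValueError("interaction table carries no cooperativity scores")
    pairs = [
        (pid, score)
        for pid, score in zip(table.peptide_ids, table.coop_scores)
        if peptide_filter is None or peptide_filter(pid)
    ]
    if not pairs:
        raise ValueError("peptide filter matched no peptides")
    values = np.array([s for _, s in pairs], dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else None
    return {"mean": mean, "sd": sd, "n": len(values)}
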