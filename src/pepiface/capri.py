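"""CAPRI-style docked-model quality assessment.

Implements least-squares (Kabsch) superposition and the three standard
metrics: Fnat (fraction of native cross-interface residue contacts),
LRMS (ligand backbone RMSD after receptor superposition) and IRMS
(backbone RMSD over reference-defined interface residues).  The quality
classes follow the threshold grid:

========== ======== ======== ======
quality    LRMS (A) IRMS (A) Fnat
========== ======== ======== ======
High       <1.0     <0.5     >0.8
Medium     <2.0     <1.0     >0.5
Acceptable <5.0     <2.0     >0.2
========== ======== ======== ======

A model must satisfy ALL THREE conditions of a row to earn its class;
per-criterion pass flags are returned so callers can apply looser rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .network import round_half_up
from .structures import ComplexSpec, StructureModel, select_atoms

__all__ = [
    "CapriResult",
    "CohortSummary",
    "kabsch_superpose",
    "fnat",
    "native_contacts",
    "lrms",
    "irms",
    "classify_quality",
    "evaluate",
    "summarize_cohort",
]

QUALITY_THRESHOLDS = {
    # quality: (lrms <, irms <, fnat >)
    "High": (1.0, 0.5, 0.8),
    "Medium": (2.0, 1.0, 0.5),
    "Acceptable": (5.0, 2.0, 0.2),
}
QUALITY_ORDER = ["Incorrect", "Acceptable", "Medium", "High"]


@dataclass
class CapriResult:
    fnat: float | None  # None when reference has no native contacts or CA-only input
    lrms: float
    irms: float
    quality: str
    atoms_used: str  # "backbone" or "CA-only"
    fnat_low_confidence: bool = False
    criterion_flags: dict | None = None


@dataclass
class CohortSummary:
    label: str
    values: list[float]
    threshold: float
    fraction_below: int  # whole percent, half-up

    @property
    def n_below(self) -> int:
        return sum(1 for v in self.values if v < self.threshold)


def kabsch_superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD to
    ``target``; the rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must be matching (n, 3) matrices")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 corresponding points, got {n}")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    p, q = mobile - mc, target - tc
    if np.linalg.matrix_rank(p, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set: rotation is underdetermined")
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = tc - rotation @ mc
    moved = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(((moved - target) ** 2).sum(axis=1).mean()))
    return rotation, translation, rmsd


# --- contacts and Fnat -----------------------------------------------------

def native_contacts(
    model: StructureModel, spec: ComplexSpec, cutoff: float = 5.0
) -> set[tuple[tuple[str, int, str], tuple[str, int, str]]]:
    """Cross-interface residue pairs with any heavy-atom distance <= cutoff."""
    rec = [
        (res.key, a.coords)
        for res, a in model.iter_atoms(set(spec.receptor_chains))
        if not a.is_hydrogen
    ]
    lig = [
        (res.key, a.coords)
        for res, a in model.iter_atoms(set(spec.ligand_chains))
        if not a.is_hydrogen
    ]
    if not rec or not lig:
        return set()
    rec_xyz = np.array([c for _, c in rec])
    lig_xyz = np.array([c for _, c in lig])
    pairs = cKDTree(rec_xyz).query_ball_tree(cKDTree(lig_xyz), r=cutoff)
    out: set[tuple] = set()
    for ri, lig_idx in enumerate(pairs):
        for li in lig_idx:
            out.add((rec[ri][0], lig[li][0]))
    return out


def fnat(
    model: StructureModel,
    reference: StructureModel,
    spec: ComplexSpec,
    contact_cutoff: float = 5.0,
) -> float | None:
    """Fraction of reference contacts preserved in the model.

    No superposition is involved.  Returns ``None`` (undefined, not 0)
    when the reference has no cross-interface contacts at the cutoff.
    """
    ref_contacts = native_contacts(reference, spec, contact_cutoff)
    if not ref_contacts:
        return None
    model_contacts = native_contacts(model, spec, contact_cutoff)
    return len(ref_contacts & model_contacts) / len(ref_contacts)


# --- RMS metrics -----------------------------------------------------------

def _paired_coords(
    model: StructureModel,
    reference: StructureModel,
    chains: set[str],
    residue_keys: set[tuple[str, int, str]] | None = None,
    max_missing_fraction: float = 0.10,
) -> tuple[np.ndarray, np.ndarray, str]:
    """Matched backbone coordinate matrices (model, reference).

    Uses backbone atoms shared by both structures.  When the model turns
    out to carry only CA atoms, the comparison silently degrades to
    CA-only (reported in the descriptor); otherwise more than
    ``max_missing_fraction`` missing backbone atoms is an error.
    """
    ref_xyz, ref_idx = select_atoms(reference, chains, "backbone")
    ref_map = dict(zip(ref_idx, ref_xyz))
    mod_xyz, mod_idx = select_atoms(model, chains, "backbone")
    mod_map = dict(zip(mod_idx, mod_xyz))

    if residue_keys is not None:
        ref_map = {k: v for k, v in ref_map.items() if k[:3] in residue_keys}
        mod_map = {k: v for k, v in mod_map.items() if k[:3] in residue_keys}

    ca_only = all(k[3] == "CA" for k in mod_map)
    if ca_only:
        ref_map = {k: v for k, v in ref_map.items() if k[3] == "CA"}
    shared = sorted(set(ref_map) & set(mod_map))
    if not shared:
        raise ValueError("no shared backbone atoms between model and reference")
    missing = 1.0 - len(shared) / len(ref_map)
    if not ca_only and missing > max_missing_fraction:
        raise ValueError(
            f"{missing:.0%} of reference backbone atoms missing from the model "
            f"(limit {max_missing_fraction:.0%})"
        )
    return (
        np.array([mod_map[k] for k in shared]),
        np.array([ref_map[k] for k in shared]),
        "CA-only" if ca_only else "backbone",
    )


def lrms(
    model: StructureModel, reference: StructureModel, spec: ComplexSpec
) -> float:
    """Ligand backbone RMSD after superposing on the receptor backbone."""
    value, _ = _lrms_with_descriptor(model, reference, spec)
    return value


def _lrms_with_descriptor(model, reference, spec) -> tuple[float, str]:
    rec_mod, rec_ref, used_r = _paired_coords(model, reference, set(spec.receptor_chains))
    rotation, translation, _ = kabsch_superpose(rec_mod, rec_ref)
    lig_mod, lig_ref, used_l = _paired_coords(model, reference, set(spec.ligand_chains))
    moved = lig_mod @ rotation.T + translation
    value = float(np.sqrt(((moved - lig_ref) ** 2).sum(axis=1).mean()))
    used = "CA-only" if "CA-only" in (used_r, used_l) else "backbone"
    return value, used


def interface_residue_keys(
    reference: StructureModel, spec: ComplexSpec, interface_cutoff: float = 10.0
) -> set[tuple[str, int, str]]:
    """Residues (both sides) with any heavy atom within the cutoff of the
    partner side, evaluated on the reference."""
    pairs = native_contacts(reference, spec, interface_cutoff)
    keys: set[tuple[str, int, str]] = set()
    for rk, lk in pairs:
        keys.add(rk)
        keys.add(lk)
    return keys


def irms(
    model: StructureModel,
    reference: StructureModel,
    spec: ComplexSpec,
    interface_cutoff: float = 10.0,
) -> float:
    """Backbone RMSD over reference-defined interface residues after
    superposing on exactly those atoms."""
    value, _ = _irms_with_descriptor(model, reference, spec, interface_cutoff)
    return value


def _irms_with_descriptor(model, reference, spec, interface_cutoff=10.0):
    keys = interface_residue_keys(reference, spec, interface_cutoff)
    if not keys:
        raise ValueError(
            f"reference has no interface residues at {interface_cutoff} A"
        )
    mod, ref, used = _paired_coords(
        model, reference, set(spec.all_chains), residue_keys=keys
    )
    _, _, rmsd = kabsch_superpose(mod, ref)
    return rmsd, used


# --- classification --------------------------------------------------------

def classify_quality(
    fnat_value: float | None, lrms_value: float, irms_value: float
) -> tuple[str, dict]:
    """Classify a model against the threshold grid.

    Returns ``(quality, flags)`` where ``flags[quality][criterion]``
    records each individual comparison.  When ``fnat_value`` is None
    (undefined) the class is computed from the RMS criteria only and
    flagged ``fnat_ignored``.
    """
    if lrms_value < 0 or irms_value < 0 or (fnat_value is not None and fnat_value < 0):
        raise ValueError("metrics must be non-negative")
    flags: dict = {"fnat_ignored": fnat_value is None}
    best = "Incorrect"
    for quality in ("Acceptable", "Medium", "High"):
        lrms_max, irms_max, fnat_min = QUALITY_THRESHOLDS[quality]
        checks = {
            "lrms": lrms_value < lrms_max,
            "irms": irms_value < irms_max,
            "fnat": True if fnat_value is None else fnat_value > fnat_min,
        }
        flags[quality] = checks
        if all(checks.values()):
            best = quality
    return best, flags


def evaluate(
    model: StructureModel,
    reference: StructureModel,
    spec: ComplexSpec,
    contact_cutoff: float = 5.0,
    interface_cutoff: float = 10.0,
) -> CapriResult:
    """Compute Fnat/LRMS/IRMS and the quality class for one model."""
    lrms_value, used_l = _lrms_with_descriptor(model, reference, spec)
    irms_value, used_i = _irms_with_descriptor(model, reference, spec, interface_cutoff)
    atoms_used = "CA-only" if "CA-only" in (used_l, used_i) else "backbone"
    fnat_value = fnat(model, reference, spec, contact_cutoff)
    low_confidence = atoms_used == "CA-only" and fnat_value is not None
    quality, flags = classify_quality(fnat_value, lrms_value, irms_value)
    return CapriResult(
        fnat=fnat_value,
        lrms=lrms_value,
        irms=irms_value,
        quality=quality,
        atoms_used=atoms_used,
        fnat_low_confidence=low_confidence,
        criterion_flags=flags,
    )


def summarize_cohort(
    values: list[float], threshold: float, label: str = ""
) -> CohortSummary:
    """Fraction of values strictly below a threshold, as a whole percent
    (rounded half-up)."""
    if not values:
        raise ValueError("cohort is empty")
    n_below = sum(1 for v in values if v < threshold)
    fraction = int(round_half_up(100.0 * n_below / len(values)))
    return CohortSummary(
        label=label, values=list(values), threshold=threshold, fraction_below=fraction
    )
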