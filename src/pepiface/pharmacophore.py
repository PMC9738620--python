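"""Typed-feature pharmacophore extraction from anchor residues.

A feature is the centroid of a residue's relevant heavy atoms:
hydrophobic features average all side-chain heavy atoms (CB onward);
positive-ionisable features average the charged-group atoms (Arg
guanidinium, Lys NZ, His imidazole nitrogens).  The model carries the
full symmetric pairwise centroid distance matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemistry import CATION_ATOMS
from .structures import StructureModel

__all__ = [
    "PharmacophoreFeature",
    "PharmacophoreModel",
    "derive_features",
    "export_model",
    "import_model",
]

FEATURE_KINDS = ("hydrophobic", "positive_ionic")


@dataclass(frozen=True)
class PharmacophoreFeature:
    kind: str
    chain_id: str
    res_seq: int
    res_name: str
    centroid: tuple[float, float, float]
    n_atoms: int

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.n_atoms < 1:
            raise ValueError("feature must be built from at least one atom")

    @property
    def label(self) -> str:
        return f"{self.kind}:{self.chain_id}:{self.res_name}-{self.res_seq}"


@dataclass
class PharmacophoreModel:
    features: list[PharmacophoreFeature]
    distance_matrix: np.ndarray

    def __post_init__(self) -> None:
        self.distance_matrix = np.asarray(self.distance_matrix, dtype=float)
        n = len(self.features)
        if self.distance_matrix.shape != (n, n):
            raise ValueError("distance matrix shape must match the feature count")
        if not np.allclose(self.distance_matrix, self.distance_matrix.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.distance_matrix), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal must be zero")

    def kind_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for f in self.features:
            out[f.kind] = out.get(f.kind, 0) + 1
        return out

    def pairwise_distances(self) -> list[tuple[str, str, float]]:
        out = []
        for i in range(len(self.features)):
            for j in range(i + 1, len(self.features)):
                out.append(
                    (
                        self.features[i].label,
                        self.features[j].label,
                        float(self.distance_matrix[i, j]),
                    )
                )
        return out


def derive_features(
    model: StructureModel,
    anchors: list[tuple[str, int, str]],
) -> PharmacophoreModel:
    """Build a pharmacophore from ``(chain_id, res_seq, kind)`` anchors.

    Hydrophobic centroids are the unweighted mean of the residue's
    side-chain heavy atoms; positive-ionic centroids average the
    charged-group atoms.  Gly cannot anchor a hydrophobic feature.
    """
    if not anchors:
        raise ValueError("at least one anchor is required")
    features: list[PharmacophoreFeature] = []
    centroids: list[np.ndarray] = []
    for chain_id, res_seq, kind in anchors:
        if kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {kind!r} for anchor "
                             f"{chain_id}:{res_seq}")
        res = model.residue(chain_id, res_seq)
        if kind == "hydrophobic":
            atoms = res.sidechain_heavy_atoms()
            if not atoms:
                raise ValueError(
                    f"anchor {chain_id}:{res_seq} ({res.res_name}) has no "
                    "side-chain heavy atoms for a hydrophobic feature"
                )
        else:
            group = CATION_ATOMS.get(res.res_name)
            if not group:
                raise ValueError(
                    f"anchor {chain_id}:{res_seq} ({res.res_name}) carries no "
                    "positive-ionisable group"
                )
            atoms = [a for a in res.atoms if a.name in group]
            if not atoms:
                raise ValueError(
                    f"anchor {chain_id}:{res_seq}: charged-group atoms "
                    f"{sorted(group)} absent from the structure"
                )
        centroid = np.mean([a.coords for a in atoms], axis=0)
        centroids.append(centroid)
        features.append(
            PharmacophoreFeature(
                kind=kind,
                chain_id=chain_id,
                res_seq=res_seq,
                res_name=res.res_name,
                centroid=tuple(float(x) for x in centroid),
                n_atoms=len(atoms),
            )
        )
    xyz = np.asarray(centroids)
    diff = xyz[:, None, :] - xyz[None, :, :]
    matrix = np.sqrt((diff**2).sum(axis=-1))
    return PharmacophoreModel(features=features, distance_matrix=matrix)


def export_model(model: PharmacophoreModel, path, fmt: str = "json") -> None:
    """Write the model as JSON or TSV (centroids to 3 decimals)."""
    if not model.features:
        raise ValueError("cannot export an empty pharmacophore model")
    if fmt == "json":
        payload = {
            "features": [
                {
                    "kind": f.kind,
                    "chain": f.chain_id,
                    "res_seq": f.res_seq,
                    "res_name": f.res_name,
                    "centroid": [round(x, 3) for x in f.centroid],
                    "n_atoms": f.n_atoms,
                }
                for f in model.features
            ],
            "distance_matrix": np.round(model.distance_matrix, 3).tolist(),
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=2)
    elif fmt == "tsv":
        rows = [
            {
                "kind": f.kind,
                "chain": f.chain_id,
                "res_seq": f.res_seq,
                "res_name": f.res_name,
                "x": round(f.centroid[0], 3),
                "y": round(f.centroid[1], 3),
                "z": round(f.centroid[2], 3),
                "n_atoms": f.n_atoms,
            }
            for f in model.features
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r} (use 'json' or 'tsv')")


def import_model(path) -> PharmacophoreModel:
    """Re-load a JSON export written by :func:`export_model`."""
    with open(path) as handle:
        payload = json.load(handle)
    features = [
        PharmacophoreFeature(
            kind=f["kind"],
            chain_id=f["chain"],
            res_seq=f["res_seq"],
            res_name=f["res_name"],
            centroid=tuple(f["centroid"]),
            n_atoms=f["n_atoms"],
        )
        for f in payload["features"]
    ]
    return PharmacophoreModel(
        features=features, distance_matrix=np.asarray(payload["distance_matrix"])
    )
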