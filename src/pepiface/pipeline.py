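"""End-to-end pipeline driver: interface -> contacts -> hot spots ->
pharmacophore on a reference complex, with a reproducible run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .interface import interface_report
from .network import (
    cooperativity_score,
    count_per_residue,
    rank_hotspots,
    rows_to_table,
    type_contacts,
)
from .pharmacophore import derive_features, export_model
from .structures import ComplexSpec, read_pdb

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

log = logging.getLogger("pepiface.pipeline")


@dataclass
class PipelineConfig:
    complex_pdb: str
    receptor_chains: tuple[str, ...]
    ligand_chains: tuple[str, ...]
    out_dir: str = "pepiface_run"
    probe: float = 1.4
    contact_cutoff: float = 5.0
    interface_cutoff: float = 10.0
    hydrophobic_cutoff: float = 4.5
    bsa_floor: float = 0.01
    n_points: int = 960
    hotspot_k: int = 5
    anchors: list[tuple[str, int, str]] = field(default_factory=list)
    seed: int = 0
    force: bool = False

    def validate(self) -> None:
        for name in ("probe", "contact_cutoff", "interface_cutoff", "hydrophobic_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cutoff {name} must be positive")
        # raises on overlap / empty sets
        ComplexSpec(frozenset(self.receptor_chains), frozenset(self.ligand_chains))
        if not Path(self.complex_pdb).exists():
            raise FileNotFoundError(self.complex_pdb)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        data["receptor_chains"] = tuple(data["receptor_chains"])
        data["ligand_chains"] = tuple(data["ligand_chains"])
        data["anchors"] = [tuple(a) for a in data.get("anchors", [])]
        return cls(**data)


@dataclass
class RunManifest:
    version: str
    config: dict
    stages: dict
    checksums: dict

    def write(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=2, default=str)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run interface -> network -> hotspots (-> pharmacophore) on a complex.

    Each stage writes TSV/JSON under ``config.out_dir``; completed
    stages are skipped on re-runs unless ``config.force``.  Any stage
    error aborts the run, leaving a partial manifest on disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, str] = {}
    checksums: dict[str, str] = {}
    manifest = RunManifest(
        version=__version__, config=asdict(config), stages=stages, checksums=checksums
    )
    manifest_path = out / "manifest.json"

    spec = ComplexSpec(frozenset(config.receptor_chains), frozenset(config.ligand_chains))
    log.info(
        "pipeline start: %s receptor=%s ligand=%s probe=%.2f contact=%.2f "
        "interface=%.2f hydrophobic=%.2f bsa_floor=%g",
        config.complex_pdb, config.receptor_chains, config.ligand_chains,
        config.probe, config.contact_cutoff, config.interface_cutoff,
        config.hydrophobic_cutoff, config.bsa_floor,
    )

    def stage(name: str, outputs: list[Path], fn) -> None:
        t0 = time.time()
        if all(p.exists() for p in outputs) and not config.force:
            stages[name] = "skipped (outputs exist)"
        else:
            try:
                fn()
            except Exception as exc:
                stages[name] = f"error: {exc}"
                manifest.write(manifest_path)
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            stages[name] = "ok"
        for p in outputs:
            checksums[p.name] = _sha256(p)
        log.info("stage %s: %s (%.2fs)", name, stages[name], time.time() - t0)
        manifest.write(manifest_path)

    model = read_pdb(config.complex_pdb)
    state: dict = {}

    def do_interface() -> None:
        report = interface_report(
            model, spec,
            probe=config.probe, bsa_floor=config.bsa_floor, n_points=config.n_points,
        )
        report.to_frame().to_csv(out / "interface_residues.tsv", sep="\t", index=False)
        report.totals_frame().to_csv(out / "interface_totals.tsv", sep="\t", index=False)
        state["report"] = report

    stage(
        "interface",
        [out / "interface_residues.tsv", out / "interface_totals.tsv"],
        do_interface,
    )

    def do_network() -> None:
        contacts = type_contacts(model, spec, hydrophobic_cutoff=config.hydrophobic_cutoff)
        score = cooperativity_score(contacts)
        pid = Path(config.complex_pdb).stem
        table = rows_to_table([count_per_residue(contacts, pid)], coop_scores=[score])
        table.to_frame().to_csv(out / "interaction_counts.tsv", sep="\t")
        state["table"] = table

    stage("network", [out / "interaction_counts.tsv"], do_network)

    def do_hotspots() -> None:
        if "table" not in state:
            from .network import InteractionTable  # re-load after a skip
            import pandas as pd

            state["table"] = InteractionTable.from_frame(
                pd.read_csv(out / "interaction_counts.tsv", sep="\t", index_col="ID")
            )
        ranking = rank_hotspots(state["table"], k=config.hotspot_k)
        payload = {
            "residues": ranking.residue_labels,
            "totals": ranking.totals,
            "k": ranking.k,
            "top_k_fraction": ranking.top_k_fraction,
        }
        (out / "hotspots.json").write_text(json.dumps(payload, indent=2))

    stage("hotspots", [out / "hotspots.json"], do_hotspots)

    if config.anchors:
        def do_pharmacophore() -> None:
            pharm = derive_features(model, list(config.anchors))
            export_model(pharm, out / "pharmacophore.json", fmt="json")

        stage("pharmacophore", [out / "pharmacophore.json"], do_pharmacophore)

    manifest.write(manifest_path)
    return manifest
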