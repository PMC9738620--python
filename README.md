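# pepiface

Protein–peptide interface analysis toolkit: buried-surface interface
characterization, cross-interface contact typing with hot-spot ranking,
CAPRI-style grading of docked peptide models, truncation-library design,
and typed-feature pharmacophore extraction — plus synthetic-data
generators so the whole pipeline is testable without downloading any
structures.

## Modules

| module                  | what it does |
|-------------------------|--------------|
| `pepiface.structures`   | chain → residue → atom data model, fixed-column PDB read/write, atom selections (`heavy`/`backbone`/`all`) |
| `pepiface.interface`    | Shrake–Rupley SASA (deterministic spiral quadrature), per-residue BSA interface reports, solvation-gain surrogate, hydrogen-bond/salt-bridge detection |
| `pepiface.network`      | hydrophobic/polar contact typing, per-receptor-residue interaction counts, cooperativity-score surrogate, hot-spot ranking with top-k fraction |
| `pepiface.capri`        | Kabsch superposition, Fnat / LRMS / IRMS, High/Medium/Acceptable/Incorrect classification, cohort summaries |
| `pepiface.design`       | three-phase truncation-scan peptide libraries (N-terminal, C-terminal, double) |
| `pepiface.pharmacophore`| hydrophobic / positive-ionisable feature centroids with full distance matrices |
| `pepiface.synthetic`    | ideal-helix-over-slab toy complexes with exact contact ground truth, rigid-body decoys with closed-form RMSD, seeded synthetic count tables |
| `pepiface.fixtures`     | packaged reference tables (peptide library, IRMS cohorts, interaction counts) |
| `pepiface.pipeline` / `pepiface.cli` | end-to-end driver with run manifest, and the `pepiface` command |

## CLI

```bash
# interface report (per-residue ASA/BSA plus per-side totals)
pepiface interface complex.pdb --receptor A --ligand C --probe 1.4 --out report.tsv

# contact typing + per-residue counts, then hot-spot ranking
pepiface network complex.pdb --receptor A --ligand C --out counts.tsv
pepiface hotspots counts.tsv -k 5
pepiface hotspots --fixture table5 -k 5          # packaged count matrix

# CAPRI-style grading and cohort summaries
pepiface capri --model model.pdb --reference ref.pdb --receptor A --ligand C
pepiface capri-cohort --fixture table4 --threshold 1.0

# truncation library (default scheme: N-del to 10, C-del to 5, double 5,3)
pepiface design --sequence LSIEETNEIREKLGMKPI --fasta library.fasta

# pharmacophore from anchor residues
pepiface pharmacophore complex.pdb --anchor C:15:hydrophobic --anchor C:16:positive

# synthetic data
pepiface synth toy --sequence LSIEETNEIREKLGMKPI --gap 3.0 --out toy.pdb
pepiface synth decoy --reference toy.pdb --receptor A --ligand C --translate 3,0,0 --out decoy.pdb
pepiface synth table --n-peptides 15 --n-residues 10 --seed 1 --out table.tsv

# full pipeline with manifest
pepiface run --complex toy.pdb --receptor A --ligand C --out-dir run/
```

Exit codes: 0 success, 2 validation error, 3 runtime failure.

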