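"""Packaged fixture tables and typed loaders.

Three reference tables ship with the package as plain TSV:

* ``table2`` — the truncation peptide library (ID/Sequence/Length);
* ``table4`` — IRMS values per peptide for the CA- and all-atom
  representation model groups (medoid/filtered/lowest);
* ``table5`` — per-receptor-residue interaction counts per peptide plus
  a per-peptide cooperativity score.

The printed cooperativity scores come from an external proprietary
scoring tool; they ship as data for the aggregation operations and are
never recomputed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .network import InteractionTable

__all__ = ["FIXTURE_NAMES", "load_fixture", "table5_interaction_table"]

FIXTURE_NAMES = ("table2", "table4", "table5")

# Expected column totals of the table5 count matrix, used as a
# load-time integrity check against silent fixture corruption.
_TABLE5_TOTALS = {
    "MET-1": 20, "ASP-26": 42, "LEU-19": 26, "VAL-30": 44, "LYS-29": 30,
    "ASP-22": 39, "LEU-33": 32, "LYS-17": 13, "CYS-18": 19, "GLU-21": 10,
}


def _read(name: str, **kwargs) -> pd.DataFrame:
    ref = resources.files("pepiface.data") / f"{name}.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", **kwargs)


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture table by name (``table2``/``table4``/``table5``)."""
    if name not in FIXTURE_NAMES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    if name == "table2":
        frame = _read(name, dtype={"ID": str, "Sequence": str, "Length": int})
    elif name == "table4":
        frame = _read(name)
        for col in frame.columns[2:]:
            frame[col] = frame[col].astype(float)
    else:
        frame = _read(name, index_col="ID")
        count_cols = [c for c in frame.columns if c != "CooperativityScore"]
        frame[count_cols] = frame[count_cols].astype(int)
        totals = frame[count_cols].sum()
        mismatch = {
            col: int(totals[col])
            for col in count_cols
            if int(totals[col]) != _TABLE5_TOTALS[col]
        }
        if mismatch:
            raise ValueError(f"table5 fixture corrupted; bad column totals: {mismatch}")
    return frame


def table5_interaction_table() -> InteractionTable:
    """The table5 fixture as a typed :class:`InteractionTable`."""
    return InteractionTable.from_frame(load_fixture("table5"))
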