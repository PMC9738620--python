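"""Truncation-scan peptide library design.

From a parent sequence, build a deletion series in three phases:

1. stepwise single N-terminal deletions down to a stop length;
2. from the last phase-1 peptide, stepwise single C-terminal deletions
   down to a second stop length;
3. one double-truncation peptide removing a fixed number of residues
   from both ends of the parent at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .chemistry import AA_ONE_TO_THREE

__all__ = ["PeptideEntry", "PeptideLibrary", "truncation_library", "library_report"]


@dataclass(frozen=True)
class PeptideEntry:
    id: str
    sequence: str
    scheme: str  # parent | N-del | C-del | double

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PeptideLibrary:
    parent: str
    entries: list[PeptideEntry]  # entry 0 is the parent

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("peptide ids must be unique")
        for e in self.entries:
            if e.sequence not in self.parent:
                raise ValueError(
                    f"{e.id}: {e.sequence!r} is not a contiguous substring of the parent"
                )

    @property
    def peptides(self) -> list[PeptideEntry]:
        """Generated peptides, excluding the parent entry."""
        return [e for e in self.entries if e.scheme != "parent"]

    def sequences(self) -> list[str]:
        return [e.sequence for e in self.entries]


def _validate_sequence(sequence: str) -> None:
    bad = sorted({ch for ch in sequence if ch not in AA_ONE_TO_THREE})
    if bad:
        raise ValueError(f"non-standard residue letters in sequence: {bad}")


def truncation_library(
    parent: str,
    n_del_to_length: int = 10,
    c_del_to_length: int = 5,
    double_spec: tuple[int, int] | None = (5, 3),
    parent_id: str = "parent",
) -> PeptideLibrary:
    """Build the three-phase truncation library of a parent peptide.

    Phase 1 deletes one N-terminal residue at a time from
    ``len(parent) - 1`` down to ``n_del_to_length``; phase 2 continues
    from the last phase-1 peptide with single C-terminal deletions down
    to ``c_del_to_length``; phase 3 (optional) removes
    ``double_spec = (n_cut, c_cut)`` residues from both ends of the
    parent in one step.  Peptides are labelled ``Peptide-1`` ...
    ``Peptide-N`` in generation order; the parent is entry 0.
    """
    _validate_sequence(parent)
    if not (len(parent) > n_del_to_length >= c_del_to_length >= 1):
        raise ValueError(
            "stop lengths must satisfy len(parent) > n_del_to_length "
            ">= c_del_to_length >= 1"
        )

    entries = [PeptideEntry(id=parent_id, sequence=parent, scheme="parent")]
    counter = 0

    for cut in range(1, len(parent) - n_del_to_length + 1):
        counter += 1
        entries.append(
            PeptideEntry(id=f"Peptide-{counter}", sequence=parent[cut:], scheme="N-del")
        )

    phase1_final = entries[-1].sequence if counter else parent
    for cut in range(1, len(phase1_final) - c_del_to_length + 1):
        counter += 1
        entries.append(
            PeptideEntry(
                id=f"Peptide-{counter}", sequence=phase1_final[:-cut], scheme="C-del"
            )
        )

    if double_spec is not None:
        n_cut, c_cut = double_spec
        if n_cut < 0 or c_cut < 0 or n_cut + c_cut >= len(parent):
            raise ValueError(f"infeasible double truncation {double_spec} "
                             f"for a {len(parent)}-mer parent")
        counter += 1
        entries.append(
            PeptideEntry(
                id=f"Peptide-{counter}",
                sequence=parent[n_cut : len(parent) - c_cut],
                scheme="double",
            )
        )
    return PeptideLibrary(parent=parent, entries=entries)


def library_report(lib: PeptideLibrary, parent_label: str = "Snu66 peptide") -> pd.DataFrame:
    """ID/Sequence/Length table of the library, parent row first."""
    if not lib.entries:
        raise ValueError("library is empty")
    rows = []
    for entry in lib.entries:
        rows.append(
            {
                "ID": parent_label if entry.scheme == "parent" else entry.id,
                "Sequence": entry.sequence,
                "Length": entry.length,
            }
        )
    return pd.DataFrame(rows)
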