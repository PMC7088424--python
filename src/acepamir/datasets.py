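"""Bundled reference dataset: the 14 reported onion (Allium cepa) miRNAs.

Ships the curated precursor and mature sequences, the published
per-precursor statistics (MFOLD-derived free energies, composition,
arm, mismatch counts), psRNATarget-style target alignments and GO
annotations of the predicted targets.  Used by the worked examples,
the test suite and the reproduction script; also convenient as a small
realistic reference set for the scanner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .homology import ReferenceMature


@dataclass(frozen=True)
class ReportedMirna:
    """One reported onion miRNA with its published statistics."""

    name: str
    homolog_id: str
    homolog_sequence: str
    subject_id: str
    subject_length: int
    mature: str
    precursor: str
    precursor_length: int
    mature_length: int
    arm: str
    strand: str
    mismatches: int
    pct_gc: float
    mfe: float
    amfe: float
    mfei: float


@dataclass(frozen=True)
class ReportedTarget:
    """One reported miRNA:target alignment row."""

    mirna: str
    target_id: str
    fragment: str
    description: str
    expectation: float
    upe: float
    inhibition: str


@lru_cache(maxsize=1)
def _raw() -> dict:
    text = resources.files("acepamir.data").joinpath("ace_mirnas.json").read_text()
    return json.loads(text)


def load_reported_mirnas() -> list[ReportedMirna]:
    """The 14 reported onion miRNAs with sequences and published statistics."""
    out = []
    for row in _raw()["mirnas"]:
        rep = row["reported"]
        out.append(
            ReportedMirna(
                name=row["name"],
                homolog_id=row["homolog_id"],
                homolog_sequence=row["homolog_sequence"],
                subject_id=row["subject_id"],
                subject_length=row["subject_length"],
                mature=row["mature"],
                precursor=row["precursor"],
                precursor_length=rep["precursor_length"],
                mature_length=rep["mature_length"],
                arm=rep["arm"],
                strand=rep["strand"],
                mismatches=rep["mismatches"],
                pct_gc=rep["pct_gc"],
                mfe=rep["mfe"],
                amfe=rep["amfe"],
                mfei=rep["mfei"],
            )
        )
    return out


def load_reported_targets() -> list[ReportedTarget]:
    """The reported target alignments (aligned fragments 5'->3')."""
    return [ReportedTarget(**row) for row in _raw()["targets"]]


def load_go_annotations() -> list[dict]:
    """GO term rows: go_id, category, description, evalue, genes."""
    return [dict(row) for row in _raw()["go_annotations"]]


def reference_matures() -> list[ReferenceMature]:
    """The homolog mature miRNAs as a scanner reference set."""
    seen = {}
    for row in load_reported_mirnas():
        if row.homolog_id not in seen:
            seen[row.homolog_id] = ReferenceMature(
                id=row.homolog_id, sequence=row.homolog_sequence
            )
    return list(seen.values())


def get_mirna(name: str) -> ReportedMirna:
    """Look up one reported miRNA by name (e.g. ``ace-miR162``)."""
    for row in load_reported_mirnas():
        if row.name == name:
            return row
    raise KeyError(name)
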