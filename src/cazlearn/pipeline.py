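"""End-to-end two-stage annotation: gate, then family assignment.

Every query embedding is scored by the binary gate; only gate-positives
(score >= tau) are passed to the family network.  Each input id appears in
the output exactly once, in input order, so downstream joins are trivial.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .curation import FamilyLabel
from .embeddings import EmbeddingSet
from .family import FamilyModel, family_predict
from .gate import GateModel, gate_scores


class PipelineError(ValueError):
    """Raised on inconsistent pipeline inputs."""


PREDICTIONS_COLUMNS = ["id", "gate_score", "is_cazyme", "family", "family_probability"]
PREDICTIONS_FORMAT_VERSION = "1"


@dataclass(frozen=True)
class PredictionRecord:
    """One protein's annotation: gate score plus family call when gated in."""

    id: str
    gate_score: float
    is_cazyme: bool
    family: FamilyLabel | None = None
    family_probability: float | None = None

    def __post_init__(self) -> None:
        if self.is_cazyme != (self.family is not None):
            raise PipelineError(
                f"{self.id}: family fields must be present iff is_cazyme"
            )
        if (self.family is None) != (self.family_probability is None):
            raise PipelineError(f"{self.id}: family and probability must co-occur")


def annotate(
    query: EmbeddingSet,
    gate: GateModel,
    family: FamilyModel,
    gate_threshold: float = 0.5,
    families_only: bool = False,
) -> list[PredictionRecord]:
    """Run the two-stage classification over a query embedding set.

    ``families_only`` bypasses the gate for pre-vetted inputs: every record
    is treated as a CAZyme (gate score reported as 1.0).
    """
    if query.dim != gate.dim:
        raise PipelineError(f"query dim {query.dim} != gate dim {gate.dim}")
    if query.dim != family.input_dim:
        raise PipelineError(
            f"query dim {query.dim} != family model dim {family.input_dim}"
        )
    if len(query) == 0:
        return []

    if families_only:
        scores = {pid: 1.0 for pid in query.ids}
        positives = list(query.ids)
    else:
        gs = gate_scores(gate, query, threshold=gate_threshold)
        scores = {s.id: s.score for s in gs}
        positives = [s.id for s in gs if s.decision]

    fam_by_id = {}
    if positives:
        preds = family_predict(family, query.subset(positives))
        fam_by_id = {p.id: p for p in preds}

    out: list[PredictionRecord] = []
    for pid in query.ids:
        fam = fam_by_id.get(pid)
        if fam is None:
            out.append(
                PredictionRecord(id=pid, gate_score=scores[pid], is_cazyme=False)
            )
        else:
            out.append(
                PredictionRecord(
                    id=pid,
                    gate_score=scores[pid],
                    is_cazyme=True,
                    family=fam.label,
                    family_probability=fam.probability,
                )
            )
    return out


def write_predictions_tsv(records: Sequence[PredictionRecord], path: str | Path) -> None:
    """Fixed, versioned TSV: id, gate_score, is_cazyme, family, family_probability."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# predictions_format_version={PREDICTIONS_FORMAT_VERSION}\n")
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(PREDICTIONS_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.id,
                    f"{r.gate_score:.6f}",
                    int(r.is_cazyme),
                    str(r.family) if r.family is not None else "",
                    f"{r.family_probability:.6f}" if r.family_probability is not None else "",
                ]
            )


def read_predictions_tsv(path: str | Path) -> list[PredictionRecord]:
    path = Path(path)
    if not path.exists():
        raise PipelineError(f"no such predictions file: {path}")
    out: list[PredictionRecord] = []
    with open(path, newline="") as fh:
        rows = [r for r in fh if not r.startswith("#")]
    reader = csv.DictReader(rows, delimiter="\t")
    if reader.fieldnames != PREDICTIONS_COLUMNS:
        raise PipelineError(
            f"unexpected predictions columns in {path}: {reader.fieldnames}"
        )
    for row in reader:
        is_caz = bool(int(row["is_cazyme"]))
        out.append(
            PredictionRecord(
                id=row["id"],
                gate_score=float(row["gate_score"]),
                is_cazyme=is_caz,
                family=FamilyLabel.parse(row["family"]) if is_caz else None,
                family_probability=float(row["family_probability"]) if is_caz else None,
            )
        )
    return out
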