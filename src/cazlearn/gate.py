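"""Binary CAZyme / non-CAZyme gate over embedding vectors.

A random forest (200 trees, fixed random state) separates CAZymes from
non-CAZymes in embedding space.  The gate score of a query is the fraction
of trees voting CAZyme, a probability-like value in [0, 1] suitable both for
thresholding (default tau = 0.5) and for ROC / precision-recall curve
construction.  Training is deterministic: identical inputs and seed yield
byte-identical score vectors.
"""

from __future__ import annotations

import hashlib
import io
import json
import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .embeddings import EmbeddingSet


class GateError(ValueError):
    """Raised on invalid gate-training or scoring inputs."""


@dataclass(frozen=True)
class GateScore:
    id: str
    score: float
    decision: bool


@dataclass
class GateModel:
    """A fitted gate with its training provenance manifest."""

    forest: RandomForestClassifier
    dim: int
    n_trees: int
    seed: int
    training_checksum: str

    def save(self, path: str | Path) -> None:
        payload = {
            "manifest": {
                "kind": "gate",
                "n_trees": self.n_trees,
                "seed": self.seed,
                "dim": self.dim,
                "training_checksum": self.training_checksum,
            },
            "forest": pickle.dumps(self.forest),
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "GateModel":
        path = Path(path)
        if not path.exists():
            raise GateError(f"no such model file: {path}")
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        man = payload["manifest"]
        if man.get("kind") != "gate":
            raise GateError(f"{path} is not a gate model archive")
        return cls(
            forest=pickle.loads(payload["forest"]),
            dim=man["dim"],
            n_trees=man["n_trees"],
            seed=man["seed"],
            training_checksum=man["training_checksum"],
        )


def _checksum(pos: EmbeddingSet, neg: EmbeddingSet) -> str:
    h = hashlib.sha256()
    for es in (pos, neg):
        h.update(json.dumps(es.ids).encode())
        h.update(np.ascontiguousarray(es.matrix).tobytes())
    return h.hexdigest()[:16]


def train_gate(
    pos: EmbeddingSet,
    neg: EmbeddingSet,
    n_trees: int = 200,
    seed: int = 0,
    balance_classes: bool = False,
) -> GateModel:
    """Fit the binary gate forest on positive (CAZyme) and negative embeddings.

    ``balance_classes`` switches on per-class sample weighting
    (class_weight='balanced') for imbalanced gate training; off by default.
    """
    if len(pos) < 2 or len(neg) < 2:
        raise GateError("need at least 2 examples per class to train the gate")
    if pos.dim != neg.dim:
        raise GateError(f"dimension mismatch: pos dim {pos.dim}, neg dim {neg.dim}")
    overlap = set(pos.ids) & set(neg.ids)
    if overlap:
        raise GateError(f"positive and negative sets share ids: {sorted(overlap)[:5]}")
    X = np.vstack([pos.matrix, neg.matrix]).astype(np.float64)
    y = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        random_state=seed,
        class_weight="balanced" if balance_classes else None,
        n_jobs=1,
    )
    forest.fit(X, y)
    return GateModel(
        forest=forest,
        dim=pos.dim,
        n_trees=n_trees,
        seed=seed,
        training_checksum=_checksum(pos, neg),
    )


def gate_scores(
    model: GateModel, query: EmbeddingSet, threshold: float = 0.5
) -> list[GateScore]:
    """Score every query vector; score = fraction of trees voting CAZyme.

    Output order follows input order; decision = (score >= threshold).
    """
    if len(query) == 0:
        return []
    if query.dim != model.dim:
        raise GateError(f"query dim {query.dim} != model dim {model.dim}")
    proba = model.forest.predict_proba(query.matrix.astype(np.float64))
    pos_col = list(model.forest.classes_).index(1)
    scores = proba[:, pos_col]
    return [
        GateScore(id=pid, score=float(s), decision=bool(s >= threshold))
        for pid, s in zip(query.ids, scores)
    ]


def write_scores_tsv(scores: Sequence[GateScore], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tscore\tdecision\n")
        for s in scores:
            fh.write(f"{s.id}\t{s.score:.6f}\t{int(s.decision)}\n")
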