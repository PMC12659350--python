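"""Multiclass CAZyme family assignment: a feedforward network over embeddings.

The second classification stage maps a D-dimensional per-protein embedding
(D = 1024 for the reference pLM) through two hidden layers — 256 then 512
units by default — to a softmax over the K family/subfamily labels of a
:class:`~cazlearn.curation.FamilyOntology`.  K is always taken from the
data, never fixed.

Family sizes in CAZy-style catalogues are wildly imbalanced (carbohydrate
esterases are ~4% of sequences), so training minimises a *weighted*
cross-entropy in which the penalty for misclassifying family c is
proportional to 1 / n_c, the inverse of its training count: mislabelling a
rare family costs more than mislabelling an abundant one.  Weights are
normalised to mean 1 so loss magnitudes stay comparable across ontologies.

Hyperparameters (hidden sizes, batch size, learning rate) are chosen by
random search over 20 candidates with a synchronous successive-halving
schedule: all candidates train to the first rung, the worst half (by
validation loss) is pruned at every rung, and survivors continue to the
epoch budget.  The whole search is reproducible from a single seed.

The network itself is implemented directly in numpy (ReLU activations,
softmax output, Adam optimiser): at the scale of fixed-length embedding
vectors a hand-written MLP is fast, dependency-light and exactly
reproducible across platforms.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .curation import CurationError, FamilyLabel, FamilyOntology
from .embeddings import EmbeddingSet


class FamilyError(ValueError):
    """Raised on invalid family-classifier inputs."""


# ---------------------------------------------------------------------------
# Class weights and weighted cross-entropy
# ---------------------------------------------------------------------------

@dataclass
class ClassWeights:
    """Per-class loss weights, proportional to inverse training counts."""

    w: np.ndarray  # length K, positive, mean 1

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.w.ndim != 1 or np.any(self.w <= 0):
            raise FamilyError("class weights must be a 1-D positive vector")

    @property
    def K(self) -> int:
        return len(self.w)


def class_weights(ontology: FamilyOntology) -> ClassWeights:
    """w_c proportional to 1 / n_c, normalised to mean 1.

    A zero training count is an error (the label is not trainable).
    """
    counts = np.asarray(ontology.counts, dtype=np.float64)
    for lab, n in zip(ontology.labels, ontology.counts):
        if n < 1:
            raise FamilyError(f"label {lab} has zero training sequences")
    inv = 1.0 / counts
    return ClassWeights(w=inv / inv.mean())


def weighted_cross_entropy(
    probabilities: np.ndarray,
    label: int | np.ndarray,
    weights: ClassWeights,
    eps: float = 1e-12,
    reduction: str = "weighted_mean",
) -> float:
    """Weighted cross-entropy loss.

    For a single probability vector p and class index y the loss is
    ``-w_y * log p_y``.  For a batch (2-D probabilities, label array) the
    declared reduction applies: ``weighted_mean`` (default) divides the
    weighted sum by the sum of the sample weights, ``mean`` averages the
    per-sample weighted losses, ``sum`` adds them.  Zero probabilities are
    clamped at ``eps`` rather than producing an infinite loss.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    if p.ndim == 1:
        y = int(label)
        if not 0 <= y < weights.K:
            raise FamilyError(f"label index {y} outside [0, {weights.K})")
        return float(-weights.w[y] * np.log(max(p[y], eps)))
    if p.ndim != 2:
        raise FamilyError("probabilities must be a vector or a batch matrix")
    y = np.asarray(label, dtype=int)
    if y.shape != (p.shape[0],):
        raise FamilyError("batch labels must align with probability rows")
    w = weights.w[y]
    losses = -w * np.log(np.clip(p[np.arange(len(y)), y], eps, None))
    if reduction == "weighted_mean":
        return float(losses.sum() / w.sum())
    if reduction == "mean":
        return float(losses.mean())
    if reduction == "sum":
        return float(losses.sum())
    raise FamilyError(f"unknown reduction {reduction!r}")


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------

def _init_params(dims: tuple[int, int, int, int], rng: np.random.Generator) -> dict:
    D, h1, h2, K = dims
    # He initialisation for the ReLU layers
    return {
        "W1": rng.normal(0.0, np.sqrt(2.0 / D), size=(D, h1)),
        "b1": np.zeros(h1),
        "W2": rng.normal(0.0, np.sqrt(2.0 / h1), size=(h1, h2)),
        "b2": np.zeros(h2),
        "W3": rng.normal(0.0, np.sqrt(2.0 / h2), size=(h2, K)),
        "b3": np.zeros(K),
    }


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(params: dict, X: np.ndarray) -> tuple[np.ndarray, dict]:
    a1 = np.maximum(X @ params["W1"] + params["b1"], 0.0)
    a2 = np.maximum(a1 @ params["W2"] + params["b2"], 0.0)
    probs = _softmax(a2 @ params["W3"] + params["b3"])
    return probs, {"a1": a1, "a2": a2}


def _backward(
    params: dict, X: np.ndarray, probs: np.ndarray, cache: dict,
    y: np.ndarray, sample_w: np.ndarray,
) -> dict:
    # gradient of the weighted-mean cross-entropy w.r.t. logits
    n = X.shape[0]
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (sample_w / sample_w.sum())[:, None]
    a1, a2 = cache["a1"], cache["a2"]
    grads = {"W3": a2.T @ dlogits, "b3": dlogits.sum(axis=0)}
    da2 = dlogits @ params["W3"].T
    da2[a2 <= 0] = 0.0
    grads["W2"] = a1.T @ da2
    grads["b2"] = da2.sum(axis=0)
    da1 = da2 @ params["W2"].T
    da1[a1 <= 0] = 0.0
    grads["W1"] = X.T @ da1
    grads["b1"] = da1.sum(axis=0)
    return grads


class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k in params:
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * grads[k]
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * grads[k] ** 2
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class FamilyModel:
    """A trained family classifier with its manifest."""

    params: dict
    labels: list[FamilyLabel]
    dims: tuple[int, int, int, int]
    manifest: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return self.dims[3]

    @property
    def input_dim(self) -> int:
        return self.dims[0]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise FamilyError(
                f"query matrix must be (n, {self.input_dim}); got {X.shape}"
            )
        probs, _ = _forward(self.params, X)
        return probs

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(
                {
                    "manifest": {"kind": "family", **self.manifest},
                    "dims": self.dims,
                    "labels": [str(lab) for lab in self.labels],
                    "params": self.params,
                },
                fh,
            )

    @classmethod
    def load(cls, path: str | Path) -> "FamilyModel":
        path = Path(path)
        if not path.exists():
            raise FamilyError(f"no such model file: {path}")
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload["manifest"].get("kind") != "family":
            raise FamilyError(f"{path} is not a family model archive")
        return cls(
            params=payload["params"],
            labels=[FamilyLabel.parse(s) for s in payload["labels"]],
            dims=tuple(payload["dims"]),
            manifest=payload["manifest"],
        )


# ---------------------------------------------------------------------------
# Random search + successive halving
# ---------------------------------------------------------------------------

@dataclass
class SearchSpec:
    """Random-search configuration for the family-network tuner.

    Defaults follow the reference training recipe: 20 candidates with
    randomly sampled hyperparameters, a 100-epoch budget, and halving
    (reduction factor 2) at geometrically spaced rungs starting at
    ``grace_period`` epochs.
    """

    n_candidates: int = 20
    max_epochs: int = 100
    reduction_factor: int = 2
    grace_period: int = 5
    hidden_range: tuple[int, int] = (128, 1024)
    batch_range: tuple[int, int] = (32, 512)
    lr_range: tuple[float, float] = (1e-4, 1e-2)

    def __post_init__(self) -> None:
        if self.n_candidates < 1 or self.max_epochs < 1:
            raise FamilyError("need at least one candidate and one epoch")
        if self.reduction_factor < 2:
            raise FamilyError("reduction factor must be >= 2")
        if self.grace_period < 1 or self.grace_period > self.max_epochs:
            raise FamilyError("grace period must lie in [1, max_epochs]")


def rung_schedule(spec: SearchSpec) -> list[tuple[int, int]]:
    """Successive-halving bookkeeping: (epoch budget, candidates trained)
    at each rung.

    Rung epochs grow geometrically from the grace period by the reduction
    factor, capped at ``max_epochs``; the candidate count is divided by the
    reduction factor at every rung (never below one).
    """
    epochs: list[int] = []
    e = spec.grace_period
    while e < spec.max_epochs:
        epochs.append(e)
        e *= spec.reduction_factor
    epochs.append(spec.max_epochs)
    counts: list[int] = []
    n = spec.n_candidates
    for _ in epochs:
        counts.append(n)
        n = max(1, n // spec.reduction_factor)
    return list(zip(epochs, counts))


def sample_candidates(spec: SearchSpec, seed: int) -> list[dict]:
    """Draw the candidate hyperparameter configurations (reproducible)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EA2C4]))
    cands = []
    for i in range(spec.n_candidates):
        h_lo, h_hi = spec.hidden_range
        b_lo, b_hi = spec.batch_range
        cands.append(
            {
                "candidate": i,
                "h1": int(np.exp(rng.uniform(np.log(h_lo), np.log(h_hi)))),
                "h2": int(np.exp(rng.uniform(np.log(h_lo), np.log(h_hi)))),
                "batch_size": int(np.exp(rng.uniform(np.log(b_lo), np.log(b_hi)))),
                "lr": float(np.exp(rng.uniform(np.log(spec.lr_range[0]), np.log(spec.lr_range[1])))),
            }
        )
    return cands


@dataclass
class SearchReport:
    """Per-candidate outcome of the random search."""

    candidates: list[dict]  # hyperparameters + epochs_trained, val_loss, val_acc, rungs_survived
    rungs: list[tuple[int, int]]
    best_candidate: int


class _CandidateState:
    def __init__(self, hp: dict, dims_in_out: tuple[int, int], weights: ClassWeights, seed: int):
        self.hp = hp
        D, K = dims_in_out
        self.dims = (D, hp["h1"], hp["h2"], K)
        self.rng = np.random.default_rng(np.random.SeedSequence([seed, hp["candidate"]]))
        self.params = _init_params(self.dims, self.rng)
        self.opt = _Adam(self.params, lr=hp["lr"])
        self.weights = weights
        self.epochs_trained = 0
        self.val_loss = np.inf
        self.val_acc = 0.0
        self.rungs_survived = 0

    def train_to(self, target_epoch: int, X: np.ndarray, y: np.ndarray) -> None:
        n = X.shape[0]
        bs = min(self.hp["batch_size"], n)
        w_all = self.weights.w
        while self.epochs_trained < target_epoch:
            order = self.rng.permutation(n)
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                Xb, yb = X[idx], y[idx]
                probs, cache = _forward(self.params, Xb)
                grads = _backward(self.params, Xb, probs, cache, yb, w_all[yb])
                self.opt.step(self.params, grads)
            self.epochs_trained += 1

    def evaluate(self, Xv: np.ndarray, yv: np.ndarray) -> None:
        probs, _ = _forward(self.params, Xv)
        self.val_loss = weighted_cross_entropy(probs, yv, self.weights)
        self.val_acc = float((probs.argmax(axis=1) == yv).mean())


def _labelled_arrays(
    embeddings: EmbeddingSet, labels: Mapping[str, FamilyLabel | str], ontology: FamilyOntology
) -> tuple[np.ndarray, np.ndarray]:
    ids = [pid for pid in embeddings.ids if pid in labels]
    missing = set(embeddings.ids) - set(ids)
    if missing:
        raise FamilyError(f"no label for embedding id(s): {sorted(missing)[:5]}")
    X = embeddings.matrix.astype(np.float64)
    y = np.empty(len(ids), dtype=int)
    for i, pid in enumerate(ids):
        lab = labels[pid]
        if isinstance(lab, str):
            lab = FamilyLabel.parse(lab)
        y[i] = ontology.index_of(lab)
    return X, y


def train_family(
    train: EmbeddingSet,
    train_labels: Mapping[str, FamilyLabel | str],
    val: EmbeddingSet,
    val_labels: Mapping[str, FamilyLabel | str],
    spec: SearchSpec | None = None,
    seed: int = 0,
    ontology: FamilyOntology | None = None,
    class_weighting: str = "inverse",
) -> tuple[FamilyModel, SearchReport]:
    """Random search with successive halving over the family network.

    All candidates train to the first rung; at every rung the surviving pool
    is ranked by validation loss and cut by the reduction factor; survivors
    of the last rung finish the epoch budget.  The returned model is the
    candidate with the best final validation accuracy.  The whole procedure
    — candidate sampling, initialisation, minibatch order — is a pure
    function of the seed and the inputs.

    ``class_weighting='inverse'`` (default) trains with the
    inverse-frequency weighted loss; ``'uniform'`` gives every class weight
    1, i.e. plain cross-entropy — the baseline for paired imbalance
    experiments.
    """
    spec = spec or SearchSpec()
    if len(val) == 0:
        raise FamilyError("validation set must be non-empty")
    if set(train.ids) & set(val.ids):
        raise FamilyError("train and validation ids must be disjoint")
    if train.dim != val.dim:
        raise FamilyError(f"dim mismatch: train {train.dim}, val {val.dim}")

    if ontology is None:
        from collections import Counter

        cnt: Counter[FamilyLabel] = Counter()
        for pid in train.ids:
            lab = train_labels[pid] if pid in train_labels else None
            if lab is None:
                raise FamilyError(f"no label for training id {pid!r}")
            if isinstance(lab, str):
                lab = FamilyLabel.parse(lab)
            cnt[lab] += 1
        ontology = FamilyOntology(labels=sorted(cnt), counts=[cnt[k] for k in sorted(cnt)])
    else:
        seen = set()
        for pid in train.ids:
            lab = train_labels[pid]
            seen.add(FamilyLabel.parse(lab) if isinstance(lab, str) else lab)
        absent = set(ontology.labels) - seen
        if absent:
            raise FamilyError(
                f"ontology label(s) absent from training data: "
                f"{', '.join(str(l) for l in sorted(absent)[:5])}"
            )

    if class_weighting == "inverse":
        weights = class_weights(ontology)
    elif class_weighting == "uniform":
        weights = ClassWeights(w=np.ones(ontology.K))
    else:
        raise FamilyError(f"unknown class_weighting {class_weighting!r}")
    X, y = _labelled_arrays(train, train_labels, ontology)
    try:
        Xv, yv = _labelled_arrays(val, val_labels, ontology)
    except CurationError as exc:
        raise FamilyError(str(exc)) from exc

    cands = [
        _CandidateState(hp, (train.dim, ontology.K), weights, seed)
        for hp in sample_candidates(spec, seed)
    ]
    rungs = rung_schedule(spec)
    alive = list(cands)
    for rung_i, (epoch_budget, n_expected) in enumerate(rungs):
        # the schedule is the source of truth for how many candidates train here
        alive = alive[:n_expected]
        for cand in alive:
            cand.train_to(epoch_budget, X, y)
            cand.evaluate(Xv, yv)
            cand.rungs_survived = rung_i + 1
        # rank by validation loss; deterministic tie-break by candidate index
        alive.sort(key=lambda c: (c.val_loss, c.hp["candidate"]))

    best = max(alive, key=lambda c: (c.val_acc, -c.hp["candidate"]))
    model = FamilyModel(
        params=best.params,
        labels=list(ontology.labels),
        dims=best.dims,
        manifest={
            "seed": seed,
            "activation": "relu",
            "optimizer": "adam",
            "hyperparameters": best.hp,
            "epochs_trained": best.epochs_trained,
            "val_accuracy": best.val_acc,
            "val_loss": best.val_loss,
            "K": ontology.K,
        },
    )
    report = SearchReport(
        candidates=[
            {
                **c.hp,
                "epochs_trained": c.epochs_trained,
                "rungs_survived": c.rungs_survived,
                "val_loss": c.val_loss,
                "val_acc": c.val_acc,
            }
            for c in cands
        ],
        rungs=rungs,
        best_candidate=best.hp["candidate"],
    )
    return model, report


@dataclass(frozen=True)
class FamilyPrediction:
    id: str
    label: FamilyLabel
    probability: float
    probabilities: np.ndarray


def family_predict(model: FamilyModel, query: EmbeddingSet) -> list[FamilyPrediction]:
    """Assign each query its argmax family (ties -> lowest class index)."""
    if len(query) == 0:
        return []
    if query.dim != model.input_dim:
        raise FamilyError(f"query dim {query.dim} != model input dim {model.input_dim}")
    probs = model.predict_proba(query.matrix)
    out = []
    for i, pid in enumerate(query.ids):
        j = int(probs[i].argmax())  # argmax returns the first (lowest) index on ties
        out.append(
            FamilyPrediction(
                id=pid,
                label=model.labels[j],
                probability=float(probs[i, j]),
                probabilities=probs[i],
            )
        )
    return out


def write_search_report_tsv(report: SearchReport, path: str | Path) -> None:
    cols = ["candidate", "h1", "h2", "batch_size", "lr",
            "epochs_trained", "rungs_survived", "val_loss", "val_acc"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in report.candidates:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
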