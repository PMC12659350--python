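"""Embedding-space interpretability probes.

Two tools for asking *why* the classifier calls a protein what it does:

* exact Euclidean nearest-neighbor search of query embeddings against a
  reference embedding database (e.g. the non-redundant training set), which
  surfaces the closest catalogued CAZyme and its family; and

* an in-silico mutagenesis probe: slide a window (10 residues by default)
  along the sequence, replace every residue in the window by its most
  distant substitution under BLOSUM62 (the row-minimum scoring amino acid),
  re-embed the mutant, and record the model's probability for a target
  family.  Windows whose perturbation collapses that probability mark the
  sequence segments the embedding — and hence the classification — depends
  on (signal peptides, catalytic motifs, ...).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.spatial.distance import cdist

from .curation import CANONICAL_RESIDUES, FamilyLabel, ProteinRecord
from .embeddings import Embedder, EmbeddingSet, pool_residue_embeddings
from .family import FamilyModel


class LatentError(ValueError):
    """Raised on invalid probe or neighbor-search inputs."""


AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def load_blosum62() -> dict[tuple[str, str], int]:
    """BLOSUM62 over the 20 canonical residues, symmetry checked at load."""
    table = substitution_matrices.load("BLOSUM62")
    scores: dict[tuple[str, str], int] = {}
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            scores[(a, b)] = int(table[a, b])
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            assert scores[(a, b)] == scores[(b, a)], "BLOSUM62 must be symmetric"
        assert all(
            scores[(a, a)] >= scores[(a, b)] for b in AMINO_ACIDS if b != a
        ), "diagonal must dominate its row"
    return scores


# ---------------------------------------------------------------------------
# Nearest neighbors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeighborHit:
    query_id: str
    neighbor_id: str
    distance: float
    neighbor_family: FamilyLabel | None = None


def nearest_neighbors(
    query: EmbeddingSet,
    reference: EmbeddingSet,
    k: int = 1,
    exclude_self: bool = False,
    reference_labels: Mapping[str, FamilyLabel] | None = None,
) -> list[NeighborHit]:
    """Exact k-nearest-neighbor search under Euclidean distance.

    No approximate index is involved: all pairwise distances are computed.
    Ties are broken by reference-id order (the order of ``reference.ids``);
    ``exclude_self`` drops a reference sharing the query's id.
    """
    if len(reference) == 0:
        raise LatentError("reference set is empty")
    if query.dim != reference.dim:
        raise LatentError(f"dim mismatch: query {query.dim}, reference {reference.dim}")
    max_k = len(reference) - (1 if exclude_self else 0)
    if k < 1 or k > max_k:
        raise LatentError(f"k={k} out of range for {len(reference)} references")

    dists = cdist(query.matrix.astype(np.float64), reference.matrix.astype(np.float64))
    hits: list[NeighborHit] = []
    ref_pos = np.arange(len(reference))
    for qi, qid in enumerate(query.ids):
        row = dists[qi].copy()
        if exclude_self and qid in reference:
            row[reference.ids.index(qid)] = np.inf
        # sort by (distance, reference order) for deterministic ties
        order = np.lexsort((ref_pos, row))[:k]
        for j in order:
            rid = reference.ids[j]
            hits.append(
                NeighborHit(
                    query_id=qid,
                    neighbor_id=rid,
                    distance=float(row[j]),
                    neighbor_family=(
                        reference_labels.get(rid) if reference_labels else None
                    ),
                )
            )
    return hits


def write_neighbors_tsv(hits: Sequence[NeighborHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query\tneighbor\tdistance\tneighbor_family\n")
        for h in hits:
            fam = str(h.neighbor_family) if h.neighbor_family is not None else ""
            fh.write(f"{h.query_id}\t{h.neighbor_id}\t{h.distance:.6f}\t{fam}\n")


# ---------------------------------------------------------------------------
# BLOSUM62 sliding-window substitution probe
# ---------------------------------------------------------------------------

def most_distant_substitution(
    residue: str, matrix: Mapping[tuple[str, str], int] | None = None
) -> str:
    """The amino acid most distant from ``residue`` under the matrix.

    Distance is operationalised as the minimum substitution score in the
    residue's matrix row, excluding the residue itself; score ties are
    broken alphabetically.  Non-canonical residues are an error here —
    callers decide whether to skip or remap them.
    """
    if residue not in CANONICAL_RESIDUES:
        raise LatentError(f"non-canonical residue {residue!r}")
    if matrix is None:
        matrix = load_blosum62()
    best = min((matrix[(residue, b)], b) for b in AMINO_ACIDS if b != residue)
    return best[1]


@dataclass
class ProbeTrace:
    """Per-window target-class probabilities from the substitution probe.

    Windows are 0-based half-open [start, start + window); ``baseline`` is
    the unmutated sequence's probability for the target class.
    """

    starts: list[int]
    window: int
    probabilities: list[float]
    baseline: float
    skipped: list[int]

    @property
    def deltas(self) -> list[float]:
        return [self.baseline - p for p in self.probabilities]


def sliding_window_probe(
    record: ProteinRecord,
    embedder: Embedder,
    family_model: FamilyModel,
    target_class: FamilyLabel,
    window: int = 10,
    step: int = 1,
    substitution: str = "most_distant",
    nonstandard: str = "skip",
    seed: int = 0,
) -> ProbeTrace:
    """Track the target family's probability as each window is perturbed.

    For every window position, each residue in the window is replaced
    (``substitution='most_distant'``: the BLOSUM62 row-minimum substitution;
    ``'sampled'``: a residue drawn inversely proportional to its BLOSUM62
    similarity; ``'identity'``: no change — a no-op control that must trace
    flat at the baseline).  Each mutant is re-embedded and scored by the
    family model.

    Windows containing non-canonical residues are skipped (recorded in
    ``skipped``) or those residues are mapped to a random canonical
    substitution when ``nonstandard='substitute'``.
    """
    L = len(record)
    if window < 1 or L < window:
        raise LatentError(f"sequence length {L} shorter than window {window}")
    if step < 1:
        raise LatentError("step must be >= 1")
    try:
        target_idx = family_model.labels.index(target_class)
    except ValueError:
        raise LatentError(f"target class {target_class} not in the model ontology") from None
    if substitution not in ("most_distant", "sampled", "identity"):
        raise LatentError(f"unknown substitution mode {substitution!r}")

    matrix = load_blosum62()
    rng = np.random.default_rng(seed)

    def embed_one(seq: str) -> np.ndarray:
        out = np.asarray(embedder(seq))
        if out.ndim == 2:
            out = pool_residue_embeddings(out)
        return out

    def prob(seq: str, context: str) -> float:
        try:
            vec = embed_one(seq)
        except Exception as exc:
            raise LatentError(f"embedder failed at {context}: {exc}") from exc
        p = family_model.predict_proba(vec[None, :])[0]
        return float(p[target_idx])

    def substitute(res: str) -> str:
        if substitution == "identity":
            return res
        if substitution == "most_distant":
            return most_distant_substitution(res, matrix)
        # sampled mode: weight inversely with similarity (shift row to >= 1)
        scores = np.array([matrix[(res, b)] for b in AMINO_ACIDS], dtype=float)
        others = np.array([b != res for b in AMINO_ACIDS])
        w = (scores.max() + 1.0) - scores
        w[~others] = 0.0
        w /= w.sum()
        return AMINO_ACIDS[rng.choice(len(AMINO_ACIDS), p=w)]

    baseline = prob(record.sequence, "baseline")
    starts: list[int] = []
    probs: list[float] = []
    skipped: list[int] = []
    seq = record.sequence
    for start in range(0, L - window + 1, step):
        segment = seq[start : start + window]
        noncanon = [c for c in segment if c not in CANONICAL_RESIDUES]
        if noncanon and nonstandard == "skip" and substitution != "identity":
            skipped.append(start)
            continue
        mutated = "".join(
            substitute(c)
            if c in CANONICAL_RESIDUES
            else (AMINO_ACIDS[rng.integers(20)] if substitution != "identity" else c)
            for c in segment
        )
        mutant = seq[:start] + mutated + seq[start + window :]
        starts.append(start)
        probs.append(prob(mutant, f"window {start}"))
    return ProbeTrace(
        starts=starts,
        window=window,
        probabilities=probs,
        baseline=baseline,
        skipped=skipped,
    )


def write_probe_tsv(trace: ProbeTrace, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("window_start\twindow_end\tprobability\tdelta_from_baseline\n")
        for start, p in zip(trace.starts, trace.probabilities):
            fh.write(
                f"{start}\t{start + trace.window}\t{p:.6f}\t{trace.baseline - p:.6f}\n"
            )
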