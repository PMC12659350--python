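"""Deterministic synthetic data for every pipeline input.

Three generators stand in for the real-world inputs at desk scale:

* **Embedding clusters** — per-family isotropic Gaussian clouds in a
  D-dimensional embedding space, class means placed on a sphere scaled so
  every pairwise mean distance is at least ``separation`` within-class
  standard deviations.  This is the minimal geometry under which both the
  gate forest and the family network should succeed, and its separation
  knob calibrates chance-level and separable regimes.

* **Random protein sequences** — i.i.d. uniform residues, with helpers for
  mutated copies (to exercise identity clustering), planted shared segments
  (homology purge) and chimeras.

* **Count matrices** — negative-binomial baselines with per-sample depth
  factors, a planted multiplicative disease effect on a chosen gene
  fraction, optional covariate effects and prevalence controls; a lognormal
  mode plants effects of an exact standardized size on the log2 scale.
  Every planted effect is recorded in a truth table so downstream recovery
  tests never re-derive ground truth.

All generators are pure functions of their seed: the same spec yields
byte-identical output at float32/float64 precision across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .curation import FamilyLabel, FamilyOntology, ProteinRecord
from .diffabund import CountMatrix
from .embeddings import EmbeddingSet


class FixtureError(ValueError):
    """Raised on infeasible fixture specifications."""


AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Embedding clusters
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingFixture:
    embeddings: EmbeddingSet
    labels: dict[str, FamilyLabel]
    ontology: FamilyOntology
    class_means: np.ndarray

    def split(
        self, test_fraction: float = 0.25, seed: int = 0
    ) -> tuple[EmbeddingSet, dict[str, FamilyLabel], EmbeddingSet, dict[str, FamilyLabel]]:
        """Stratified train/test split, deterministic from the seed."""
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x51737]))
        by_class: dict[FamilyLabel, list[str]] = {}
        for pid in self.embeddings.ids:
            by_class.setdefault(self.labels[pid], []).append(pid)
        train_ids: list[str] = []
        test_ids: list[str] = []
        for lab in sorted(by_class):
            ids = by_class[lab]
            n_test = max(1, int(round(test_fraction * len(ids))))
            perm = rng.permutation(len(ids))
            test_ids.extend(ids[i] for i in perm[:n_test])
            train_ids.extend(ids[i] for i in perm[n_test:])
        train_ids.sort()
        test_ids.sort()
        return (
            self.embeddings.subset(train_ids),
            {i: self.labels[i] for i in train_ids},
            self.embeddings.subset(test_ids),
            {i: self.labels[i] for i in test_ids},
        )


def simulate_embeddings(
    n_classes: int,
    n_per_class: int | Sequence[int],
    dim: int,
    separation: float,
    seed: int = 0,
    sigma: float = 1.0,
    heavy_tailed: bool = False,
    id_prefix: str = "p",
) -> EmbeddingFixture:
    """Per-family Gaussian clusters with controlled mean separation.

    Class means are drawn as random directions on a sphere of radius
    ``separation * sigma``; if two directions happen to fall closer than
    that, the sphere is inflated so every pairwise mean distance is at
    least ``separation * sigma`` (zero separation collapses all means onto
    the origin).  Points are i.i.d. isotropic Gaussian (Student-t with 3 df
    when ``heavy_tailed``) around their class mean.  Classes are labelled
    GH1 .. GHn.
    """
    if n_classes < 1:
        raise FixtureError("need at least one class")
    if dim < 2:
        raise FixtureError("embedding dimension must be >= 2")
    if separation < 0:
        raise FixtureError("separation must be non-negative")
    counts = (
        [int(n_per_class)] * n_classes
        if np.isscalar(n_per_class)
        else [int(x) for x in n_per_class]
    )
    if len(counts) != n_classes or min(counts) < 1:
        raise FixtureError("n_per_class must give a positive count per class")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE3B]))
    if n_classes == 1 or separation == 0:
        means = np.zeros((n_classes, dim))
    else:
        directions = rng.normal(size=(n_classes, dim))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        d2 = np.linalg.norm(directions[:, None, :] - directions[None, :, :], axis=2)
        np.fill_diagonal(d2, np.inf)
        d_min = d2.min()
        if d_min < 1e-3:
            raise FixtureError(
                f"cannot separate {n_classes} classes in dimension {dim}: "
                "two class directions nearly coincide"
            )
        radius = separation * sigma
        if radius * d_min < separation * sigma:
            radius = separation * sigma / d_min
        means = directions * radius

    labels_space = [FamilyLabel("GH", c + 1) for c in range(n_classes)]
    ids: list[str] = []
    rows: list[np.ndarray] = []
    labels: dict[str, FamilyLabel] = {}
    for c in range(n_classes):
        if heavy_tailed:
            noise = rng.standard_t(df=3, size=(counts[c], dim)) * sigma
        else:
            noise = rng.normal(scale=sigma, size=(counts[c], dim))
        for j in range(counts[c]):
            pid = f"{id_prefix}{c + 1:02d}_{j:04d}"
            ids.append(pid)
            rows.append(means[c] + noise[j])
            labels[pid] = labels_space[c]
    emb = EmbeddingSet(ids=ids, matrix=np.stack(rows), provenance=f"simulated(seed={seed})")
    ontology = FamilyOntology(labels=labels_space, counts=counts)
    return EmbeddingFixture(embeddings=emb, labels=labels, ontology=ontology, class_means=means)


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def simulate_sequences(
    n: int, length: int, seed: int = 0, id_prefix: str = "seq"
) -> list[ProteinRecord]:
    """n i.i.d. uniform-residue sequences of the given length."""
    if length < 10:
        raise FixtureError("sequence length must be >= 10")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E0]))
    return [
        ProteinRecord(id=f"{id_prefix}{i:04d}", sequence=_random_sequence(rng, length))
        for i in range(n)
    ]


def mutated_copies(
    parent: ProteinRecord,
    n_copies: int,
    mutation_rate: float,
    seed: int = 0,
    id_prefix: str | None = None,
) -> list[ProteinRecord]:
    """Point-substitution copies of a parent (expected identity ~ 1 - rate)."""
    if not 0 <= mutation_rate < 1:
        raise FixtureError("mutation rate must lie in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x3C0]))
    prefix = id_prefix or f"{parent.id}_m"
    out: list[ProteinRecord] = []
    for i in range(n_copies):
        chars = list(parent.sequence)
        for pos in range(len(chars)):
            if rng.random() < mutation_rate:
                alternatives = [a for a in AMINO_ACIDS if a != chars[pos]]
                chars[pos] = alternatives[rng.integers(len(alternatives))]
        out.append(
            ProteinRecord(id=f"{prefix}{i:03d}", sequence="".join(chars), labels=parent.labels)
        )
    return out


def plant_segment(record: ProteinRecord, segment: str, position: int) -> ProteinRecord:
    """Overwrite the record's residues at [position, position + len(segment))."""
    if len(segment) > len(record):
        raise FixtureError("planted segment longer than the sequence")
    if position < 0 or position + len(segment) > len(record):
        raise FixtureError("planted segment does not fit at that position")
    seq = record.sequence[:position] + segment + record.sequence[position + len(segment):]
    return ProteinRecord(id=record.id, sequence=seq, labels=record.labels)


@dataclass
class HomologyFixture:
    """Negatives with planted positive-derived chimeras, plus the truth."""

    negatives: list[ProteinRecord]
    positives: list[ProteinRecord]
    chimera_ids: set[str]


def simulate_homology_fixture(
    n_negatives: int,
    n_chimeras: int,
    n_positives: int = 5,
    negative_length: int = 80,
    positive_length: int = 120,
    segment_length: int = 40,
    seed: int = 0,
) -> HomologyFixture:
    """Random negatives, ``n_chimeras`` of which carry an exact segment
    copied from a positive sequence (the planted homology)."""
    if n_chimeras > n_negatives:
        raise FixtureError("more chimeras than negatives")
    if segment_length > min(negative_length, positive_length):
        raise FixtureError("segment longer than the sequences")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC41]))
    positives = [
        ProteinRecord(id=f"pos{i:03d}", sequence=_random_sequence(rng, positive_length))
        for i in range(n_positives)
    ]
    negatives = [
        ProteinRecord(id=f"neg{i:03d}", sequence=_random_sequence(rng, negative_length))
        for i in range(n_negatives)
    ]
    chimera_idx = rng.choice(n_negatives, size=n_chimeras, replace=False)
    chimera_ids: set[str] = set()
    for idx in chimera_idx:
        donor = positives[rng.integers(n_positives)]
        start = int(rng.integers(0, positive_length - segment_length + 1))
        segment = donor.sequence[start : start + segment_length]
        pos = int(rng.integers(0, negative_length - segment_length + 1))
        negatives[idx] = plant_segment(negatives[idx], segment, pos)
        chimera_ids.add(negatives[idx].id)
    return HomologyFixture(negatives=negatives, positives=positives, chimera_ids=chimera_ids)


# ---------------------------------------------------------------------------
# Mock embedders
# ---------------------------------------------------------------------------

class HashEmbedder:
    """Deterministic mock pLM: each residue letter maps to a fixed random
    vector, the per-residue matrix is their stack.

    Pooled embeddings therefore reflect residue composition; any point
    mutation moves the embedding.  Useful wherever a cheap, reproducible
    embedder contract is needed.
    """

    def __init__(self, dim: int = 32, seed: int = 0, name: str = "hash-embedder"):
        self.dim = dim
        self.name = name
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x4A5]))
        letters = AMINO_ACIDS + "BZXUO"
        self._table = {c: rng.normal(size=dim) for c in letters}

    def __call__(self, sequence: str) -> np.ndarray:
        try:
            return np.stack([self._table[c] for c in sequence])
        except KeyError as exc:
            raise ValueError(f"unknown residue {exc.args[0]!r}") from exc


class SpanSensitiveEmbedder:
    """Mock pLM sensitive *only* to the residues inside one span.

    Residues inside [start, stop) contribute their hashed vectors; every
    other position contributes a constant row.  Mutations outside the span
    therefore leave the embedding bit-identical — the control needed to
    show that the sliding-window probe localizes signal correctly.
    """

    def __init__(self, start: int, stop: int, dim: int = 32, seed: int = 0):
        if stop <= start:
            raise FixtureError("span must be non-empty")
        self.start = start
        self.stop = stop
        self.dim = dim
        self.name = f"span-embedder[{start}:{stop}]"
        self._inner = HashEmbedder(dim=dim, seed=seed)
        self._blank = np.zeros(dim)

    def __call__(self, sequence: str) -> np.ndarray:
        rows = [
            self._inner._table[c] if self.start <= i < self.stop else self._blank
            for i, c in enumerate(sequence)
        ]
        return np.stack(rows)


class FailingEmbedder:
    """Mock that fails on listed ids' sequences — for --allow-partial paths."""

    def __init__(self, inner, fail_sequences: set[str]):
        self._inner = inner
        self._fail = set(fail_sequences)
        self.dim = inner.dim
        self.name = f"failing({inner.name})"

    def __call__(self, sequence: str) -> np.ndarray:
        if sequence in self._fail:
            raise RuntimeError("simulated embedder failure")
        return self._inner(sequence)


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

@dataclass
class CountFixture:
    matrix: CountMatrix
    truth: pd.DataFrame  # per gene: is_diff, planted_log2fc, low_prevalence, cov_effect


def simulate_counts(
    n_genes: int,
    n_disease: int,
    n_control: int,
    seed: int = 0,
    frac_diff: float = 0.0,
    log2fc: float = 2.0,
    family: str = "nb",
    dispersion: float = 0.3,
    base_log2_mean: float = 5.0,
    base_log2_sd: float = 1.0,
    noise_log2_sd: float = 1.0,
    depth_log_sd: float = 0.2,
    frac_low_prevalence: float = 0.0,
    low_prevalence: float = 0.05,
    covariate_effect_log2fc: float = 0.0,
    frac_cov_affected: float = 0.0,
) -> CountFixture:
    """Gene x sample counts with planted disease effects and a truth table.

    ``family='nb'`` draws negative-binomial counts (variance mu + dispersion
    * mu^2) around lognormal per-gene baselines with per-sample depth
    factors; the disease effect multiplies the mean by 2**log2fc for a
    ``frac_diff`` fraction of genes.  ``family='lognormal'`` generates
    counts as 2**N(m_g, noise_log2_sd) so the planted shift ``log2fc`` is an
    exact effect in log2 units (log2fc / noise_log2_sd standard deviations).
    A binary covariate 'cov1' and a numeric 'age' column are always present
    in the metadata; 'cov1' carries a multiplicative effect on a
    ``frac_cov_affected`` fraction of genes.  A ``frac_low_prevalence``
    fraction of genes is thinned to ``low_prevalence`` nonzero samples so
    the prevalence filter has work to do.
    """
    if n_genes < 2 or (n_disease + n_control) < 2:
        raise FixtureError("need at least 2 genes and 2 samples")
    if family not in ("nb", "lognormal"):
        raise FixtureError(f"unknown count family {family!r}")
    if dispersion <= 0:
        raise FixtureError("dispersion must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0117]))
    n_samples = n_disease + n_control
    samples = [f"s{i:03d}" for i in range(n_samples)]
    disease = np.array([1] * n_disease + [0] * n_control)
    age = rng.normal(45.0, 12.0, size=n_samples)
    cov1 = rng.integers(0, 2, size=n_samples)
    depth = np.exp(rng.normal(0.0, depth_log_sd, size=n_samples))

    genes = [f"g{i:05d}" for i in range(n_genes)]
    n_diff = int(round(frac_diff * n_genes))
    diff_idx = rng.choice(n_genes, size=n_diff, replace=False) if n_diff else np.array([], dtype=int)
    is_diff = np.zeros(n_genes, dtype=bool)
    is_diff[diff_idx] = True
    planted = np.where(is_diff, log2fc, 0.0)

    n_cov = int(round(frac_cov_affected * n_genes))
    cov_idx = rng.choice(n_genes, size=n_cov, replace=False) if n_cov else np.array([], dtype=int)
    cov_eff = np.zeros(n_genes)
    cov_eff[cov_idx] = covariate_effect_log2fc

    base = rng.normal(base_log2_mean, base_log2_sd, size=n_genes)
    # per-gene, per-sample mean on the log2 scale
    log2_mu = (
        base[:, None]
        + planted[:, None] * disease[None, :]
        + cov_eff[:, None] * cov1[None, :]
        + np.log2(depth)[None, :]
    )
    if family == "nb":
        mu = 2.0 ** log2_mu
        r = 1.0 / dispersion
        counts = rng.negative_binomial(n=r, p=r / (r + mu)).astype(float)
    else:
        counts = 2.0 ** (log2_mu + rng.normal(0.0, noise_log2_sd, size=(n_genes, n_samples)))
        counts = np.round(counts, 3)

    low_prev = np.zeros(n_genes, dtype=bool)
    n_low = int(round(frac_low_prevalence * n_genes))
    if n_low:
        low_idx = rng.choice(n_genes, size=n_low, replace=False)
        low_prev[low_idx] = True
        keep_n = max(1, int(np.floor(low_prevalence * n_samples)))
        for gi in low_idx:
            keep = rng.choice(n_samples, size=keep_n, replace=False)
            mask = np.ones(n_samples, dtype=bool)
            mask[keep] = False
            counts[gi, mask] = 0.0
            if (counts[gi] == 0).all():
                counts[gi, keep[0]] = 1.0

    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        metadata=pd.DataFrame(
            {"disease": disease, "age": age, "cov1": cov1}, index=samples
        ),
    )
    truth = pd.DataFrame(
        {
            "is_diff": is_diff,
            "planted_log2fc": planted,
            "low_prevalence": low_prev,
            "cov_effect_log2fc": cov_eff,
        },
        index=genes,
    )
    return CountFixture(matrix=matrix, truth=truth)
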