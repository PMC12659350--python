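"""Fixed-length per-protein embedding vectors and their HDF5 storage.

A protein language model (pLM) turns an amino-acid sequence of length L into
an L x D matrix of per-residue vectors; a per-protein embedding is obtained
by pooling over residues (mean by default).  The classifiers downstream
consume only the pooled vectors, so the embedder itself is a pluggable
contract: any callable mapping a sequence to either an (L, D) matrix or a
(D,) vector, with a declared dimension, can stand behind the pipeline —
a transformer served elsewhere, or a deterministic mock in tests.

Embeddings are stored in HDF5 with one float32 dataset per protein keyed by
its id at the file root (the dialect of common embedding toolkits); a single
(n, D) matrix layout with an id column is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Protocol, Sequence, runtime_checkable

import h5py
import numpy as np

from .curation import ProteinRecord


class EmbeddingError(ValueError):
    """Raised on invalid embedding sets or files."""


@dataclass
class EmbeddingSet:
    """An ordered id -> vector map with a single declared dimension.

    Vectors are held as one float32 matrix of shape (n, dim), row i belonging
    to ``ids[i]``.  All values must be finite and ids unique.
    """

    ids: list[str]
    matrix: np.ndarray
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float32)
        if self.matrix.ndim != 2:
            raise EmbeddingError("embedding matrix must be 2-D (n, dim)")
        if len(self.ids) != self.matrix.shape[0]:
            raise EmbeddingError(
                f"{len(self.ids)} ids but {self.matrix.shape[0]} vectors"
            )
        if len(set(self.ids)) != len(self.ids):
            raise EmbeddingError("embedding ids must be unique")
        if self.matrix.size and not np.all(np.isfinite(self.matrix)):
            raise EmbeddingError("embedding vectors must be finite")
        self._row = {pid: i for i, pid in enumerate(self.ids)}

    @property
    def dim(self) -> int:
        return int(self.matrix.shape[1])

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, pid: str) -> bool:
        return pid in self._row

    def vector(self, pid: str) -> np.ndarray:
        try:
            return self.matrix[self._row[pid]]
        except KeyError:
            raise EmbeddingError(f"no embedding for id {pid!r}") from None

    def items(self) -> Iterator[tuple[str, np.ndarray]]:
        for pid in self.ids:
            yield pid, self.matrix[self._row[pid]]

    def subset(self, ids: Sequence[str]) -> "EmbeddingSet":
        rows = [self._row[pid] for pid in ids]
        return EmbeddingSet(list(ids), self.matrix[rows], self.provenance)

    @classmethod
    def from_dict(
        cls, vectors: dict[str, np.ndarray], provenance: str = "unknown"
    ) -> "EmbeddingSet":
        ids = list(vectors)
        if not ids:
            return cls(ids=[], matrix=np.zeros((0, 0), dtype=np.float32), provenance=provenance)
        dims = {np.asarray(v).shape for v in vectors.values()}
        if len(dims) > 1 or any(len(s) != 1 for s in dims):
            offender = next(
                pid for pid, v in vectors.items()
                if np.asarray(v).ndim != 1 or np.asarray(v).shape != np.asarray(vectors[ids[0]]).shape
            )
            raise EmbeddingError(f"inconsistent vector shape at id {offender!r}")
        return cls(ids=ids, matrix=np.stack([vectors[i] for i in ids]), provenance=provenance)


# ---------------------------------------------------------------------------
# HDF5 round trip
# ---------------------------------------------------------------------------

def write_h5(
    embeddings: EmbeddingSet, path: str | Path, layout: str = "per_protein"
) -> None:
    """Write an :class:`EmbeddingSet` to HDF5.

    ``layout='per_protein'`` stores one dataset per id at the file root;
    ``layout='matrix'`` stores a single (n, dim) dataset plus an id table.
    """
    if layout not in ("per_protein", "matrix"):
        raise EmbeddingError(f"unknown HDF5 layout {layout!r}")
    with h5py.File(path, "w") as f:
        f.attrs["provenance"] = embeddings.provenance
        f.attrs["layout"] = layout
        if layout == "per_protein":
            for pid, vec in embeddings.items():
                f.create_dataset(pid, data=vec.astype(np.float32))
        else:
            f.create_dataset("embeddings", data=embeddings.matrix)
            f.create_dataset(
                "ids", data=np.array(embeddings.ids, dtype=h5py.string_dtype())
            )


def read_h5(path: str | Path) -> EmbeddingSet:
    """Read an embedding file in either layout; dimension checked across ids."""
    path = Path(path)
    if not path.exists():
        raise EmbeddingError(f"no such file: {path}")
    with h5py.File(path, "r") as f:
        provenance = str(f.attrs.get("provenance", "unknown"))
        if "embeddings" in f and "ids" in f:
            ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["ids"][()]]
            return EmbeddingSet(ids=ids, matrix=f["embeddings"][()], provenance=provenance)
        ids = sorted(f.keys())
        vectors: dict[str, np.ndarray] = {}
        dim: int | None = None
        for pid in ids:
            vec = np.asarray(f[pid][()], dtype=np.float32)
            if vec.ndim != 1:
                raise EmbeddingError(f"dataset {pid!r} is not a 1-D vector")
            if dim is None:
                dim = vec.shape[0]
            elif vec.shape[0] != dim:
                raise EmbeddingError(
                    f"dimension mismatch at id {pid!r}: {vec.shape[0]} != {dim}"
                )
            vectors[pid] = vec
        return EmbeddingSet.from_dict(vectors, provenance=provenance)


# ---------------------------------------------------------------------------
# Pooling and the embedder contract
# ---------------------------------------------------------------------------

def pool_residue_embeddings(matrix: np.ndarray, mode: str = "mean") -> np.ndarray:
    """Reduce an (L, dim) per-residue matrix to a single (dim,) vector."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[0] < 1:
        raise EmbeddingError("per-residue matrix must be (L, dim) with L >= 1")
    if mode == "mean":
        return matrix.mean(axis=0)
    if mode == "sum":
        return matrix.sum(axis=0)
    if mode == "max":
        return matrix.max(axis=0)
    raise EmbeddingError(f"unknown pooling mode {mode!r}")


@runtime_checkable
class Embedder(Protocol):
    """Pluggable pLM contract: sequence -> (L, dim) matrix or (dim,) vector.

    Implementations must be deterministic for a fixed sequence and declare
    their output dimension and a name for provenance tracking.
    """

    dim: int
    name: str

    def __call__(self, sequence: str) -> np.ndarray: ...


@dataclass
class EmbeddingRun:
    """Result of embedding a record set: vectors plus per-id failures."""

    embeddings: EmbeddingSet
    failures: dict[str, str] = field(default_factory=dict)


def embed_records(
    records: Iterable[ProteinRecord],
    embedder: Embedder,
    pooling: str = "mean",
    max_len: int = 5000,
    allow_partial: bool = False,
) -> EmbeddingRun:
    """Embed every record through the pluggable embedder, pooling per-residue
    outputs to per-protein vectors.

    Sequences longer than ``max_len`` are rejected (they are also excluded
    from training by curation, so scoring them would be out of distribution).
    An embedder exception is recorded per id; unless ``allow_partial`` the
    whole run fails so records are never silently skipped.
    """
    vectors: dict[str, np.ndarray] = {}
    failures: dict[str, str] = {}
    for rec in records:
        if len(rec) > max_len:
            failures[rec.id] = f"sequence length {len(rec)} exceeds cap {max_len}"
            continue
        try:
            out = np.asarray(embedder(rec.sequence))
            if out.ndim == 2:
                out = pool_residue_embeddings(out, mode=pooling)
            elif out.ndim != 1:
                raise EmbeddingError(f"embedder output has ndim {out.ndim}")
            if out.shape[0] != embedder.dim:
                raise EmbeddingError(
                    f"embedder returned dim {out.shape[0]}, declared {embedder.dim}"
                )
            vectors[rec.id] = out.astype(np.float32)
        except Exception as exc:
            failures[rec.id] = str(exc)
    if failures and not allow_partial:
        sample = "; ".join(f"{k}: {v}" for k, v in list(failures.items())[:3])
        raise EmbeddingError(
            f"embedding failed for {len(failures)} record(s) ({sample}); "
            "pass allow_partial=True to keep the successful subset"
        )
    emb = EmbeddingSet.from_dict(vectors, provenance=getattr(embedder, "name", "unknown"))
    return EmbeddingRun(embeddings=emb, failures=failures)


def export_tsv(embeddings: EmbeddingSet, path: str | Path, first_k: int = 5) -> None:
    """Spot-check export: id, dim, and the first k vector components."""
    with open(path, "w") as fh:
        cols = "\t".join(f"v{i}" for i in range(first_k))
        fh.write(f"id\tdim\t{cols}\n")
        for pid, vec in embeddings.items():
            head = "\t".join(f"{x:.6g}" for x in vec[:first_k])
            fh.write(f"{pid}\t{embeddings.dim}\t{head}\n")
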