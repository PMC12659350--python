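"""Training-set curation for CAZyme classifiers.

CAZymes (carbohydrate-active enzymes) are catalogued into four main classes
— glycoside hydrolases (GH), glycosyltransferases (GT), carbohydrate
esterases (CE) and polysaccharide lyases (PL) — subdivided into numbered
families and subfamilies (e.g. ``GH43_18``).  Building a training set from
such a catalogue requires: parsing family labels out of FASTA headers,
dropping overlong sequences, removing exact duplicates, clustering the
positive set at a sequence-identity threshold to strip redundancy, and
purging the negative (non-CAZyme) set of anything homologous to a positive.

The identity clustering mirrors the greedy longest-first strategy of
CD-HIT-style tools; an external clusterer can be plugged in through
``identity_fn`` / the ``HomologySearch`` callable, and a built-in
alignment-based fallback is provided for desk-scale work.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import edlib

CAZY_CLASSES = ("GH", "GT", "CE", "PL")

# letters outside the 20 canonical amino acids that may appear in inputs
AMBIGUOUS_RESIDUES = frozenset("BZXUO")
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

_LABEL_RE = re.compile(r"^(GH|GT|CE|PL)(\d+)(?:_(\d+))?$")


class CurationError(ValueError):
    """Raised on malformed inputs during training-set curation."""


@dataclass(frozen=True, order=True)
class FamilyLabel:
    """A CAZy family/subfamily label such as ``GH43`` or ``GH43_18``."""

    cazy_class: str
    family: int
    subfamily: int | None = None

    def __post_init__(self) -> None:
        if self.cazy_class not in CAZY_CLASSES:
            raise CurationError(f"unknown CAZy class {self.cazy_class!r}")
        if self.family < 1:
            raise CurationError("family number must be a positive integer")
        if self.subfamily is not None and self.subfamily < 1:
            raise CurationError("subfamily number must be a positive integer")

    @classmethod
    def parse(cls, token: str) -> "FamilyLabel":
        m = _LABEL_RE.match(token.strip())
        if m is None:
            raise CurationError(f"not a CAZy family label: {token!r}")
        sub = int(m.group(3)) if m.group(3) is not None else None
        return cls(m.group(1), int(m.group(2)), sub)

    @classmethod
    def try_parse(cls, token: str) -> "FamilyLabel | None":
        try:
            return cls.parse(token)
        except CurationError:
            return None

    def __str__(self) -> str:
        base = f"{self.cazy_class}{self.family}"
        return base if self.subfamily is None else f"{base}_{self.subfamily}"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an identifier and optional family labels."""

    id: str
    sequence: str
    labels: tuple[FamilyLabel, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise CurationError("protein record id must be non-empty")
        if not self.sequence:
            raise CurationError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_ambiguous(self) -> bool:
        return any(c not in CANONICAL_RESIDUES for c in self.sequence)


@dataclass
class FamilyOntology:
    """Ordered label space of the multiclass stage.

    The number of classes K is driven by the labels present in the training
    data, never fixed ahead of time; ``counts`` holds the number of training
    sequences behind each label.
    """

    labels: list[FamilyLabel]
    counts: list[int]

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise CurationError("ontology labels must be distinct")
        if len(self.counts) != len(self.labels):
            raise CurationError("counts and labels must align")
        for lab, n in zip(self.labels, self.counts):
            if n < 1:
                raise CurationError(f"label {lab} has no training sequences")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def K(self) -> int:
        return len(self.labels)

    def index_of(self, label: FamilyLabel) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise CurationError(f"label {label} not in ontology") from None

    @classmethod
    def from_records(cls, records: Iterable[ProteinRecord]) -> "FamilyOntology":
        counter: Counter[FamilyLabel] = Counter()
        for rec in records:
            for lab in rec.labels:
                counter[lab] += 1
        labels = sorted(counter)
        return cls(labels=labels, counts=[counter[lab] for lab in labels])


# ---------------------------------------------------------------------------
# FASTA parsing
# ---------------------------------------------------------------------------

def parse_labeled_fasta(path: str | Path, delimiters: str = "| \t") -> list[ProteinRecord]:
    """Parse a FASTA file whose headers may carry CAZy family labels.

    Header tokens (split on ``delimiters``) matching the family-label grammar
    become labels; the first token is the record id.  Records whose headers
    carry no parsable label get an empty label tuple.

    Raises :class:`CurationError` with a line number on malformed input and
    lists offenders when ids are duplicated.
    """
    path = Path(path)
    if not path.exists():
        raise CurationError(f"no such file: {path}")
    split_re = re.compile("[" + re.escape(delimiters) + "]+")
    records: list[ProteinRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        tokens = [t for t in split_re.split(header) if t]
        if not tokens:
            raise CurationError(f"{path}:{header_line}: empty FASTA header")
        labels = tuple(
            lab for t in tokens[1:] if (lab := FamilyLabel.try_parse(t)) is not None
        )
        seq = "".join(chunks).upper()
        if not seq:
            raise CurationError(
                f"{path}:{header_line}: record {tokens[0]!r} has no sequence"
            )
        records.append(ProteinRecord(id=tokens[0], sequence=seq, labels=labels))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise CurationError(
                        f"{path}:{lineno}: sequence data before any FASTA header"
                    )
                chunks.append(line)
        flush()

    seen: Counter[str] = Counter(r.id for r in records)
    dups = sorted(i for i, n in seen.items() if n > 1)
    if dups:
        raise CurationError(f"duplicate record ids in {path}: {', '.join(dups)}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records back out; labels re-join the header pipe-delimited."""
    with open(path, "w") as fh:
        for rec in records:
            head = rec.id
            if rec.labels:
                head += "|" + "|".join(str(lab) for lab in rec.labels)
            fh.write(f">{head}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Filtering and deduplication
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    kept: int = 0
    removed_overlength: int = 0
    removed_dropped_class: int = 0


def filter_records(
    records: Iterable[ProteinRecord],
    max_len: int = 5000,
    drop_classes: Iterable[str] = (),
    require_label: bool = False,
) -> tuple[list[ProteinRecord], FilterReport]:
    """Drop overlong sequences and (optionally) records without a usable label.

    Sequences strictly longer than ``max_len`` residues are removed — the
    boundary length is retained.  In positive-set mode (``require_label``),
    a record must keep at least one label whose CAZy class is outside
    ``drop_classes``; its label tuple is restricted to those classes.
    """
    if max_len < 1:
        raise CurationError("max_len must be >= 1")
    dropped = set(drop_classes)
    report = FilterReport()
    kept: list[ProteinRecord] = []
    for rec in records:
        if len(rec) > max_len:
            report.removed_overlength += 1
            continue
        labels = tuple(lab for lab in rec.labels if lab.cazy_class not in dropped)
        if require_label and not labels:
            report.removed_dropped_class += 1
            continue
        if labels != rec.labels:
            rec = ProteinRecord(rec.id, rec.sequence, labels)
        kept.append(rec)
        report.kept += 1
    return kept, report


def deduplicate(records: Iterable[ProteinRecord]) -> list[ProteinRecord]:
    """Keep one representative per identical sequence (100% identity).

    The representative is the record with the lexicographically smallest id;
    labels of all duplicates are merged onto it so no family evidence is lost.
    """
    by_seq: dict[str, list[ProteinRecord]] = defaultdict(list)
    for rec in records:
        by_seq[rec.sequence].append(rec)
    out: list[ProteinRecord] = []
    for seq, group in by_seq.items():
        rep = min(group, key=lambda r: r.id)
        merged = tuple(sorted({lab for r in group for lab in r.labels}))
        out.append(ProteinRecord(rep.id, seq, merged))
    out.sort(key=lambda r: r.id)
    return out


# ---------------------------------------------------------------------------
# Pairwise identity and greedy clustering
# ---------------------------------------------------------------------------

def _canonicalize(seq: str) -> str:
    """Map ambiguity letters (B, Z, X, U, O, anything non-canonical) to X."""
    return "".join(c if c in CANONICAL_RESIDUES else "X" for c in seq.upper())


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment length.

    Uses a Needleman–Wunsch alignment (edlib, unit costs); identity is the
    fraction of match columns over all alignment columns including gaps.
    """
    if not a or not b:
        raise CurationError("cannot align empty sequences")
    res = edlib.align(_canonicalize(a), _canonicalize(b), mode="NW", task="path")
    matches = 0
    length = 0
    for count, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        n = int(count)
        length += n
        if op == "=":
            matches += n
    return matches / length


@dataclass
class ClusterResult:
    """Greedy identity-clustering output: representative -> member ids."""

    clusters: dict[str, list[str]]
    representatives: list[ProteinRecord]
    identities: dict[str, float] = field(default_factory=dict)  # member -> identity to rep

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def cluster_identity(
    records: Sequence[ProteinRecord],
    threshold: float = 0.60,
    identity_fn: Callable[[str, str], float] = pairwise_identity,
) -> ClusterResult:
    """Greedy longest-first single-representative clustering.

    Sequences are visited longest first (ties by id); each joins the first
    existing representative it exceeds ``threshold`` identity with, otherwise
    it seeds a new cluster.  In the result no member of one cluster has
    identity above the threshold with any other cluster's representative
    checked in seeding order, mirroring CD-HIT's strategy.
    """
    if not 0 < threshold < 1:
        raise CurationError("identity threshold must lie in (0, 1)")
    order = sorted(records, key=lambda r: (-len(r), r.id))
    reps: list[ProteinRecord] = []
    clusters: dict[str, list[str]] = {}
    identities: dict[str, float] = {}
    for rec in order:
        assigned = False
        for rep in reps:
            try:
                ident = identity_fn(rec.sequence, rep.sequence)
            except Exception as exc:  # propagate with context, never swallow
                raise CurationError(
                    f"identity computation failed for {rec.id} vs {rep.id}: {exc}"
                ) from exc
            if ident > threshold:
                clusters[rep.id].append(rec.id)
                identities[rec.id] = ident
                assigned = True
                break
        if not assigned:
            reps.append(rec)
            clusters[rec.id] = [rec.id]
            identities[rec.id] = 1.0
    return ClusterResult(clusters=clusters, representatives=reps, identities=identities)


def write_cluster_tsv(result: ClusterResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("member_id\trepresentative_id\tidentity\n")
        for rep_id, members in result.clusters.items():
            for member in members:
                fh.write(f"{member}\t{rep_id}\t{result.identities[member]:.4f}\n")


# ---------------------------------------------------------------------------
# Negative-set homolog purge
# ---------------------------------------------------------------------------

HomologySearch = Callable[[Sequence[ProteinRecord], Sequence[ProteinRecord]], set[str]]
"""Contract for the homology search used by :func:`purge_homologs`.

A callable taking (query set, reference set) and returning the set of query
ids with at least one hit.  Must be deterministic for fixed inputs.  An
external search tool (e.g. a DIAMOND subprocess adapter) satisfies the same
contract as the built-in k-mer + alignment fallback.
"""


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def kmer_alignment_search(
    queries: Sequence[ProteinRecord],
    references: Sequence[ProteinRecord],
    k: int = 8,
    min_identity: float = 0.30,
    min_coverage: float = 0.50,
) -> set[str]:
    """Desk-scale homology screen: exact shared k-mers, then local alignment.

    A query registers a hit against a reference when they share at least one
    exact k-mer and the best local alignment between them reaches
    ``min_identity`` over at least ``min_coverage`` of the query length.
    A random pair of unrelated proteins essentially never shares an 8-mer
    (20^-8 per position pair), so the screen is conservative.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner(mode="local")
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1

    ref_index: dict[str, list[int]] = defaultdict(list)
    for j, ref in enumerate(references):
        for kmer in _kmers(_canonicalize(ref.sequence), k):
            ref_index[kmer].append(j)

    hits: set[str] = set()
    for rec in queries:
        q = _canonicalize(rec.sequence)
        candidates = sorted({j for kmer in _kmers(q, k) for j in ref_index.get(kmer, ())})
        for j in candidates:
            r = _canonicalize(references[j].sequence)
            try:
                aln = aligner.align(q, r)[0]
            except Exception as exc:
                raise CurationError(
                    f"alignment failed for {rec.id} vs {references[j].id}: {exc}"
                ) from exc
            matches = 0
            cols = 0
            q_covered = 0
            for (qs, qe), (rs, re_) in zip(*aln.aligned):
                q_covered += qe - qs
                cols += qe - qs
                matches += sum(1 for x, y in zip(q[qs:qe], r[rs:re_]) if x == y)
            if cols == 0:
                continue
            if matches / cols >= min_identity and q_covered / len(q) >= min_coverage:
                hits.add(rec.id)
                break
    return hits


def purge_homologs(
    negatives: Sequence[ProteinRecord],
    positives: Sequence[ProteinRecord],
    search: HomologySearch | None = None,
) -> list[ProteinRecord]:
    """Remove from the negative set every record the homology search flags.

    Any negative that registers a hit against the positive set is dropped.
    A failing search aborts the purge — unpurged negatives are never kept
    silently.
    """
    neg_ids = {r.id for r in negatives}
    pos_ids = {r.id for r in positives}
    overlap = neg_ids & pos_ids
    if overlap:
        raise CurationError(
            f"negative and positive sets share ids: {sorted(overlap)[:5]}"
        )
    if search is None:
        search = kmer_alignment_search
    try:
        flagged = search(negatives, positives)
    except CurationError:
        raise
    except Exception as exc:
        raise CurationError(f"homology search failed: {exc}") from exc
    unknown = flagged - neg_ids
    if unknown:
        raise CurationError(f"search returned unknown ids: {sorted(unknown)[:5]}")
    return [r for r in negatives if r.id not in flagged]
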