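"""Training-set curation: label grammar, filtering, dedup, clustering, purge."""

import numpy as np
import pytest

from cazlearn import (
    CurationError,
    FamilyLabel,
    FamilyOntology,
    ProteinRecord,
    cluster_identity,
    deduplicate,
    filter_records,
    kmer_alignment_search,
    pairwise_identity,
    parse_labeled_fasta,
    purge_homologs,
    write_fasta,
)
from cazlearn.simulate import (
    mutated_copies,
    simulate_homology_fixture,
    simulate_sequences,
)


class TestFamilyLabel:
    @pytest.mark.parametrize(
        "text,cls,fam,sub",
        [("GH43_18", "GH", 43, 18), ("GT2", "GT", 2, None),
         ("CE17", "CE", 17, None), ("PL9_1", "PL", 9, 1)],
    )
    def test_parse_roundtrip(self, text, cls, fam, sub):
        lab = FamilyLabel.parse(text)
        assert (lab.cazy_class, lab.family, lab.subfamily) == (cls, fam, sub)
        assert str(lab) == text
        assert FamilyLabel.parse(str(lab)) == lab

    @pytest.mark.parametrize("bad", ["GH", "XX1", "GH0", "GH1_0", "gh43", "GH43_18_2"])
    def test_rejects_bad_grammar(self, bad):
        with pytest.raises(CurationError):
            FamilyLabel.parse(bad)


class TestParseFasta:
    def test_header_with_label(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">seq1|GH43_18\nMKV\n")
        (rec,) = parse_labeled_fasta(p)
        assert rec.id == "seq1"
        assert rec.labels == (FamilyLabel("GH", 43, 18),)
        assert rec.sequence == "MKV"

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.fasta"
        p.write_text("")
        assert parse_labeled_fasta(p) == []

    def test_synthetic_catalogue_label_counts(self, tmp_path):
        # 100 entries, 3 of which carry two labels; count by independent scan
        records = simulate_sequences(100, 50, seed=3)
        labelled = []
        for i, rec in enumerate(records):
            labels = (FamilyLabel("GH", 1 + i % 7),)
            if i in (5, 40, 77):
                labels += (FamilyLabel("CE", 2),)
            labelled.append(ProteinRecord(rec.id, rec.sequence, labels))
        path = tmp_path / "cat.fasta"
        write_fasta(labelled, path)

        expected_multi = sum(
            1 for line in path.read_text().splitlines()
            if line.startswith(">") and line.count("|") > 1
        )
        parsed = parse_labeled_fasta(path)
        assert len(parsed) == 100
        assert sum(1 for r in parsed if len(r.labels) > 1) == expected_multi == 3

    def test_malformed_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text("MKVNOTAHEADER\n>seq1\nMKV\n")
        with pytest.raises(CurationError, match=":1:"):
            parse_labeled_fasta(p)

    def test_duplicate_ids_listed(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">a\nMK\n>a\nMV\n")
        with pytest.raises(CurationError, match="duplicate.*a"):
            parse_labeled_fasta(p)


class TestFilter:
    def test_strict_length_boundary(self):
        at = ProteinRecord("at", "A" * 5000)
        over = ProteinRecord("over", "A" * 5001)
        kept, report = filter_records([at, over])
        assert [r.id for r in kept] == ["at"]
        assert report.removed_overlength == 1

    def test_empty_input(self):
        kept, report = filter_records([])
        assert kept == [] and report.kept == 0

    def test_overlength_count(self):
        records = simulate_sequences(187, 100, seed=4)
        long = [ProteinRecord(f"L{i}", "A" * 201) for i in range(13)]
        kept, report = filter_records(records + long, max_len=200)
        assert len(kept) == 187
        assert report.removed_overlength == 13

    def test_drop_classes_positive_mode(self):
        recs = [
            ProteinRecord("a", "MKV", (FamilyLabel("GH", 1),)),
            ProteinRecord("b", "MKL", (FamilyLabel("CE", 1),)),
            ProteinRecord("c", "MKI", (FamilyLabel("CE", 1), FamilyLabel("GT", 3))),
        ]
        kept, report = filter_records(recs, drop_classes={"CE"}, require_label=True)
        assert [r.id for r in kept] == ["a", "c"]
        assert kept[1].labels == (FamilyLabel("GT", 3),)
        assert report.removed_dropped_class == 1


class TestDeduplicate:
    def test_identical_pair_keeps_smallest_id(self):
        out = deduplicate([ProteinRecord("b", "MKV"), ProteinRecord("a", "MKV")])
        assert [r.id for r in out] == ["a"]

    def test_distinct_unchanged_and_idempotent(self):
        recs = simulate_sequences(20, 40, seed=5)
        once = deduplicate(recs)
        assert sorted(r.id for r in once) == sorted(r.id for r in recs)
        assert deduplicate(once) == once

    def test_planted_duplicates(self):
        base = simulate_sequences(40, 60, seed=6)
        dups = [ProteinRecord(f"dup{i}", base[i].sequence) for i in range(10)]
        out = deduplicate(base + dups)
        # hash-count oracle
        assert len(out) == len({r.sequence for r in base + dups}) == 40


class TestIdentity:
    def test_identical(self):
        assert pairwise_identity("MKVLAT", "MKVLAT") == 1.0

    def test_known_substitution_count(self):
        # k substitutions, no indels: identity must be (L - k) / L exactly
        parent = simulate_sequences(1, 100, seed=8)[0]
        child = list(parent.sequence)
        for pos in (3, 17, 44, 90):
            child[pos] = "W" if child[pos] != "W" else "Y"
        assert pairwise_identity(parent.sequence, "".join(child)) == pytest.approx(0.96)

    def test_ambiguity_mapped_to_x(self):
        # B and Z both map to X, so they count as matches with each other
        assert pairwise_identity("MBKV", "MZKV") == 1.0


class TestClusterIdentity:
    def test_identical_pair_one_cluster(self):
        recs = [ProteinRecord("a", "MKVLATGH" * 5), ProteinRecord("b", "MKVLATGH" * 5)]
        assert cluster_identity(recs).n_clusters == 1

    def test_random_pair_two_clusters(self):
        a, b = simulate_sequences(2, 100, seed=9)
        # independent check: random sequences over 20 letters sit far below 60%
        assert pairwise_identity(a.sequence, b.sequence) < 0.5
        assert cluster_identity([a, b], threshold=0.60).n_clusters == 2

    def test_three_mutated_groups(self):
        seeds = simulate_sequences(3, 120, seed=10)
        records = []
        for i, s in enumerate(seeds):
            records.extend(mutated_copies(s, 10, mutation_rate=0.15, seed=20 + i,
                                          id_prefix=f"g{i}_"))
        result = cluster_identity(records, threshold=0.60)
        assert result.n_clusters == 3
        # post-hoc verification by brute-force pairwise alignment
        reps = result.representatives
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                assert pairwise_identity(reps[i].sequence, reps[j].sequence) <= 0.60

    def test_members_exceed_threshold_to_representative(self):
        seeds = simulate_sequences(1, 100, seed=12)[0]
        records = [seeds] + mutated_copies(seeds, 5, 0.1, seed=13)
        result = cluster_identity(records, threshold=0.60)
        rep_by_id = {r.id: r for r in records}
        for rep_id, members in result.clusters.items():
            for m in members:
                if m != rep_id:
                    ident = pairwise_identity(
                        rep_by_id[m].sequence, rep_by_id[rep_id].sequence
                    )
                    assert ident > 0.60

    def test_threshold_validation(self):
        with pytest.raises(CurationError):
            cluster_identity([], threshold=1.5)

    def test_identity_fn_failure_propagates(self):
        def broken(a, b):
            raise RuntimeError("boom")

        recs = simulate_sequences(2, 50, seed=14)
        with pytest.raises(CurationError, match="boom"):
            cluster_identity(recs, identity_fn=broken)


class TestPurgeHomologs:
    def test_identical_negative_removed(self):
        pos = simulate_sequences(3, 80, seed=15, id_prefix="pos")
        neg = simulate_sequences(3, 80, seed=16, id_prefix="neg")
        neg[0] = ProteinRecord("neg0000", pos[0].sequence)
        kept = purge_homologs(neg, pos)
        assert {r.id for r in kept} == {"neg0001", "neg0002"}

    def test_unrelated_negatives_unchanged(self):
        pos = simulate_sequences(5, 100, seed=17, id_prefix="pos")
        neg = simulate_sequences(5, 100, seed=18, id_prefix="neg")
        # independent confirmation: no shared exact 8-mers
        pos_kmers = {
            p.sequence[i:i + 8] for p in pos for i in range(len(p.sequence) - 7)
        }
        for n in neg:
            assert not any(
                n.sequence[i:i + 8] in pos_kmers for i in range(len(n.sequence) - 7)
            )
        assert len(purge_homologs(neg, pos)) == 5

    def test_planted_chimeras_removed(self):
        fx = simulate_homology_fixture(
            n_negatives=100, n_chimeras=15, seed=19,
            negative_length=80, segment_length=40,
        )
        kept = purge_homologs(fx.negatives, fx.positives)
        assert len(kept) == 85
        assert {r.id for r in kept} == {
            r.id for r in fx.negatives if r.id not in fx.chimera_ids
        }

    def test_never_removes_zero_hit_records(self):
        # brute-force all-pairs oracle at the same cutoff on a small instance
        fx = simulate_homology_fixture(n_negatives=12, n_chimeras=4, seed=21,
                                       negative_length=80, segment_length=40)
        flagged = kmer_alignment_search(fx.negatives, fx.positives)
        kept = purge_homologs(fx.negatives, fx.positives)
        assert {r.id for r in fx.negatives} - flagged == {r.id for r in kept}

    def test_overlapping_ids_rejected(self):
        rec = simulate_sequences(1, 50, seed=22)[0]
        with pytest.raises(CurationError, match="share ids"):
            purge_homologs([rec], [rec])

    def test_search_failure_aborts(self):
        def broken(q, r):
            raise RuntimeError("search died")

        neg = simulate_sequences(2, 50, seed=23, id_prefix="n")
        pos = simulate_sequences(2, 50, seed=24, id_prefix="p")
        with pytest.raises(CurationError, match="search died"):
            purge_homologs(neg, pos, search=broken)


class TestOntology:
    def test_data_driven_label_space(self):
        recs = [
            ProteinRecord("a", "MK", (FamilyLabel("GH", 2),)),
            ProteinRecord("b", "MV", (FamilyLabel("GH", 2), FamilyLabel("CE", 1))),
            ProteinRecord("c", "ML", (FamilyLabel("PL", 9, 1),)),
        ]
        ont = FamilyOntology.from_records(recs)
        assert ont.K == 3
        assert dict(zip(map(str, ont.labels), ont.counts)) == {
            "CE1": 1, "GH2": 2, "PL9_1": 1
        }
        for i, lab in enumerate(ont.labels):
            assert ont.index_of(lab) == i

    def test_zero_count_rejected(self):
        with pytest.raises(CurationError):
            FamilyOntology(labels=[FamilyLabel("GH", 1)], counts=[0])
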