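"""Manifest, VCF extraction, PHYLIP and Newick round trips."""

from __future__ import annotations

import numpy as np
import pytest

from snvclust import (
    CohortManifest,
    DistanceMatrix,
    ExtractionOptions,
    SnvKey,
    extract_snv_sets,
    read_distance_matrix,
    read_manifest,
    read_newick,
    to_newick,
    write_distance_matrix,
    write_newick,
)
from snvclust.variant_io import normalize_chrom

from conftest import random_additive_tree, write_manifest_tsv, write_vcf


class TestManifest:
    def test_reads_rows_and_preserves_ids(self, tmp_path):
        path = write_manifest_tsv(
            tmp_path / "m.tsv",
            [("s1", "case", "MA", "Female", 35),
             ("s2", "control", "AU", "Male", 44)],
        )
        manifest = read_manifest(path)
        assert manifest.ids == ["s1", "s2"]
        assert manifest.label_of("s2", "population") == "AU"

    def test_empty_manifest_is_allowed(self, tmp_path):
        path = write_manifest_tsv(tmp_path / "m.tsv", [])
        assert read_manifest(path).ids == []

    def test_duplicate_id_rejected_by_name(self, tmp_path):
        path = write_manifest_tsv(
            tmp_path / "m.tsv",
            [("MA-Control-1", "control", "MA", "Female", 50)] * 2,
        )
        with pytest.raises(ValueError, match="MA-Control-1"):
            read_manifest(path)

    def test_missing_column_rejected_by_name(self, tmp_path):
        (tmp_path / "m.tsv").write_text("id\tgroup\tsex\tage\ns1\tcase\tF\t3\n")
        with pytest.raises(ValueError, match="population"):
            read_manifest(tmp_path / "m.tsv")


class TestChromNormalization:
    @pytest.mark.parametrize(
        "raw,expected",
        [("chr1", "1"), ("1", "1"), ("chrX", "X"), ("x", "X"),
         ("chrM", "MT"), ("M", "MT"), ("MT", "MT"), ("chr22", "22")],
    )
    def test_prefix_and_aliases_unify(self, raw, expected):
        assert normalize_chrom(raw) == expected

    def test_idempotent_on_canonical_labels(self):
        labels = [str(i) for i in range(1, 23)] + ["X", "Y", "MT"]
        for label in labels:
            assert normalize_chrom(normalize_chrom("chr" + label)) == \
                normalize_chrom(label) == label


class TestExtraction:
    def _manifest(self, tmp_path, ids=("A", "B")):
        return read_manifest(write_manifest_tsv(
            tmp_path / "m.tsv",
            [(i, "case", "MA", "Female", 30) for i in ids],
        ))

    def test_snv_filter_and_genotype_rules(self, tmp_path):
        # one SNV alt in both, one SNV alt only in A, one 2-bp deletion
        vcf = write_vcf(tmp_path / "t.vcf", ["A", "B"], [
            ("1", 100, "A", ["G"], ["0/1", "1/1"]),
            ("1", 200, "C", ["T"], ["0/1", "0/0"]),
            ("1", 300, "TA", ["T"], ["1/1", "0/1"]),
        ])
        coll = extract_snv_sets([vcf], self._manifest(tmp_path))
        assert coll.get("A", "1") == {SnvKey("1", 100), SnvKey("1", 200)}
        assert coll.get("B", "1") == {SnvKey("1", 100)}

    def test_missing_genotype_counts_as_absent(self, tmp_path):
        vcf = write_vcf(tmp_path / "t.vcf", ["A", "B"], [
            ("1", 100, "A", ["G"], ["./.", "0/1"]),
        ])
        coll = extract_snv_sets([vcf], self._manifest(tmp_path))
        assert coll.get("A", "1") == set()
        assert coll.get("B", "1") == {SnvKey("1", 100)}

    def test_multiallelic_decomposition(self, tmp_path):
        vcf = write_vcf(tmp_path / "t.vcf", ["A", "B"], [
            ("1", 500, "A", ["C", "T"], ["1/2", "0/0"]),
        ])
        pos_only = extract_snv_sets([vcf], self._manifest(tmp_path))
        assert pos_only.get("A", "1") == {SnvKey("1", 500)}
        aware = extract_snv_sets(
            [vcf], self._manifest(tmp_path),
            ExtractionOptions(allele_aware=True),
        )
        assert aware.get("A", "1") == {
            SnvKey("1", 500, "A", "C"), SnvKey("1", 500, "A", "T")
        }

    def test_mixed_snv_indel_alts_keep_only_snv_carriers(self, tmp_path):
        # B carries only the indel alt: position must not enter B's set
        vcf = write_vcf(tmp_path / "t.vcf", ["A", "B"], [
            ("1", 700, "A", ["G", "AT"], ["0/1", "0/2"]),
        ])
        coll = extract_snv_sets([vcf], self._manifest(tmp_path))
        assert coll.get("A", "1") == {SnvKey("1", 700)}
        assert coll.get("B", "1") == set()

    def test_position_only_is_projection_of_allele_aware(self, tmp_path, rng):
        records = []
        for pos in rng.choice(10_000, size=60, replace=False):
            ref, alt = [["A", "C"], ["G", "T"], ["C", "A"]][int(pos) % 3]
            gts = [rng.choice(["0/0", "0/1", "1/1", "./."]) for _ in range(2)]
            records.append(("1", int(pos) + 1, ref, [alt], gts))
        records.sort(key=lambda r: r[1])
        vcf = write_vcf(tmp_path / "t.vcf", ["A", "B"], records)
        manifest = self._manifest(tmp_path)
        aware = extract_snv_sets([vcf], manifest,
                                 ExtractionOptions(allele_aware=True))
        pos_only = extract_snv_sets([vcf], manifest)
        for subj in ("A", "B"):
            projected = {k.drop_alleles() for k in aware.get(subj, "1")}
            assert pos_only.get(subj, "1") == projected
            assert len(pos_only.get(subj, "1")) <= len(aware.get(subj, "1"))

    def test_subject_absent_from_all_vcfs_is_an_error(self, tmp_path):
        vcf = write_vcf(tmp_path / "t.vcf", ["A"], [
            ("1", 100, "A", ["G"], ["0/1"]),
        ])
        with pytest.raises(ValueError, match="B"):
            extract_snv_sets([vcf], self._manifest(tmp_path, ids=("A", "B")))

    def test_chr_prefix_unifies_with_bare_labels(self, tmp_path):
        vcf = write_vcf(tmp_path / "t.vcf", ["A"], [
            ("chr1", 100, "A", ["G"], ["0/1"]),
        ], contigs=("chr1",))
        coll = extract_snv_sets([vcf], self._manifest(tmp_path, ids=("A",)))
        assert coll.get("A", "1") == {SnvKey("1", 100)}
        assert coll.get("A", "chr1") == {SnvKey("1", 100)}


class TestPhylipRoundTrip:
    def test_round_trip_identity(self, tmp_path, rng):
        n = 9
        values = rng.random((n, n))
        values = (values + values.T) / 2
        np.fill_diagonal(values, 0.0)
        dm = DistanceMatrix([f"s{i}" for i in range(n)], values)
        write_distance_matrix(dm, tmp_path / "d.phy")
        back = read_distance_matrix(tmp_path / "d.phy")
        assert back.labels == dm.labels
        np.testing.assert_allclose(back.values, dm.values, rtol=1e-12, atol=0)
        header = (tmp_path / "d.phy").read_text().splitlines()[0]
        assert header == str(n)

    def test_nonzero_diagonal_rejected(self, tmp_path):
        (tmp_path / "d.phy").write_text("2\nA\t0.1\t0.5\nB\t0.5\t0\n")
        with pytest.raises(ValueError, match="diagonal"):
            read_distance_matrix(tmp_path / "d.phy")

    def test_asymmetry_rejected_naming_pair(self, tmp_path):
        (tmp_path / "d.phy").write_text("2\nA\t0\t0.5\nB\t0.4\t0\n")
        with pytest.raises(ValueError, match="'A'.*'B'|'B'.*'A'"):
            read_distance_matrix(tmp_path / "d.phy")


class TestNewick:
    def test_two_leaf_edge_split_evenly(self):
        from snvclust.nj import ClusterTree
        tree = ClusterTree({0: {1: 0.4}, 1: {0: 0.4}}, {0: "A", 1: "B"})
        assert to_newick(tree) == "(A:0.200000,B:0.200000);"

    def test_label_quoting(self):
        from snvclust.nj import ClusterTree
        tree = ClusterTree({0: {1: 0.4}, 1: {0: 0.4}},
                           {0: "s 1", 1: "s(2)"})
        text = to_newick(tree)
        assert "'s 1'" in text and "'s(2)'" in text

    def test_unrooted_serialization_is_trifurcating(self, rng):
        tree = random_additive_tree(rng, [f"t{i}" for i in range(6)])
        text = to_newick(tree)
        # top level of the Newick string must have exactly 3 children
        depth, top_commas = 0, 0
        for ch in text:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
            elif ch == "," and depth == 1:
                top_commas += 1
        assert top_commas == 2

    @pytest.mark.parametrize("n", [2, 3, 5, 12])
    def test_round_trip_through_dendropy(self, tmp_path, rng, n):
        """An independent Newick parser must see the same leaves and the
        same pairwise path lengths as the tree that was written (branch
        lengths quantized to the serialized 6-decimal precision)."""
        import dendropy

        from snvclust.nj import ClusterTree, tree_path_distances

        tree = random_additive_tree(rng, [f"t{i}" for i in range(n)])
        write_newick(tree, tmp_path / "t.nwk")
        dtree = dendropy.Tree.get(path=str(tmp_path / "t.nwk"),
                                  schema="newick")
        pdm = dtree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in dtree.taxon_namespace}
        assert set(taxa) == set(tree.leaf_names.values())
        quantized = ClusterTree(
            {a: {b: round(l, 6) for b, l in nbrs.items()}
             for a, nbrs in tree.adjacency.items()},
            dict(tree.leaf_names),
        )
        ours = tree_path_distances(quantized)
        for i, a in enumerate(ours.labels):
            for b in ours.labels[i + 1:]:
                assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                    ours.get(a, b), abs=1e-6
                )

    @pytest.mark.parametrize("n", [2, 4, 8])
    def test_own_reader_inverts_writer(self, tmp_path, rng, n):
        from snvclust.nj import tree_path_distances

        tree = random_additive_tree(rng, [f"t{i}" for i in range(n)])
        write_newick(tree, tmp_path / "t.nwk")
        back = read_newick(tmp_path / "t.nwk")
        ours, theirs = tree_path_distances(tree), tree_path_distances(back)
        assert ours.labels == theirs.labels
        # serialized branch lengths carry 6 decimals; a path of k edges can
        # drift by k * 5e-7 relative to the in-memory tree
        n_edges = sum(1 for _ in tree.edges()) + 1
        np.testing.assert_allclose(ours.values, theirs.values,
                                   atol=n_edges * 5e-7)
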