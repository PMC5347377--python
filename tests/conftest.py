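from __future__ import annotations

import numpy as np
import pytest

from snvclust.nj import ClusterTree


def write_vcf(path, samples, records, contigs=("1", "2")):
    """Write a minimal VCF 4.2 file.

    ``records`` is a list of (chrom, pos, ref, alts, genotypes) where
    ``alts`` is a list of ALT allele strings and ``genotypes`` one GT
    string (e.g. "0/1") per sample.
    """
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c},length=100000>" for c in contigs]
    lines.append(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    )
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if samples:
        header += "\tFORMAT\t" + "\t".join(samples)
    lines.append(header)
    for chrom, pos, ref, alts, gts in records:
        row = f"{chrom}\t{pos}\t.\t{ref}\t{','.join(alts)}\t.\t.\t."
        if samples:
            row += "\tGT\t" + "\t".join(gts)
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")
    return path


def write_manifest_tsv(path, rows):
    """rows: list of (id, group, population, sex, age)."""
    lines = ["id\tgroup\tpopulation\tsex\tage"]
    lines += ["\t".join(str(x) for x in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


def random_additive_tree(rng: np.random.Generator, labels) -> ClusterTree:
    """Random unrooted binary tree with positive branch lengths, built by
    attaching each leaf to a uniformly chosen existing edge."""
    labels = list(labels)
    assert len(labels) >= 2

    def length() -> float:
        return float(rng.uniform(0.05, 1.0))

    adjacency: dict[int, dict[int, float]] = {0: {}, 1: {}}
    leaf_names = {0: labels[0], 1: labels[1]}
    l0 = length()
    adjacency[0][1] = l0
    adjacency[1][0] = l0
    next_id = 2
    for label in labels[2:]:
        edges = [(a, b) for a in adjacency for b in adjacency[a] if a < b]
        a, b = edges[rng.integers(len(edges))]
        old = adjacency[a].pop(b)
        adjacency[b].pop(a)
        mid, leaf = next_id, next_id + 1
        next_id += 2
        split = float(rng.uniform(0.2, 0.8))
        adjacency[mid] = {}
        adjacency[leaf] = {}
        for u, v, l in (
            (a, mid, old * split),
            (mid, b, old * (1 - split)),
            (mid, leaf, length()),
        ):
            adjacency[u][v] = l
            adjacency[v][u] = l
        leaf_names[leaf] = label
    return ClusterTree(adjacency, leaf_names)


def normalized_splits(tree: ClusterTree) -> set[frozenset[str]]:
    """Edge bipartitions in a side-independent normal form (the
    lexicographically smaller side of each edge)."""
    leaves = frozenset(tree.leaf_names.values())
    return {
        min(side, leaves - side, key=lambda s: (len(s), sorted(s)))
        for side in tree.bipartitions()
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
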