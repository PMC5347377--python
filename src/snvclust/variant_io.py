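"""Input/output layer: manifests, VCF extraction, distance matrices, trees.

Subjects are represented by their per-chromosome sets of single-nucleotide
variants (SNVs).  An SNV is identified by its chromosome and 1-based
position; optionally (allele-aware mode) also by its REF and ALT alleles.
The default, position-only identity reflects the working hypothesis that
sharing *same-position* SNVs is what makes two genomes similar.

File formats handled here are all plain text: TSV manifests, VCF 4.x
(plain or bgzipped, via cyvcf2), PHYLIP square distance matrices, and
Newick trees.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_NUCLEOTIDES = frozenset("ACGT")

#: canonical chromosome labels accepted by :func:`normalize_chrom`
_CANONICAL_CHROMS = frozenset([str(i) for i in range(1, 23)] + ["X", "Y", "MT"])

_MANIFEST_COLUMNS = ("id", "group", "population", "sex", "age")


class SnvKey(NamedTuple):
    """Identity of one single-nucleotide variant.

    ``ref``/``alt`` are ``None`` in position-only mode; in allele-aware
    mode they are single nucleotides with ``ref != alt``.
    """

    chrom: str
    pos: int
    ref: str | None = None
    alt: str | None = None

    def drop_alleles(self) -> "SnvKey":
        return SnvKey(self.chrom, self.pos)


def normalize_chrom(label: str) -> str:
    """Normalize a chromosome label: strip a ``chr`` prefix, uppercase
    X/Y/MT, and map ``M`` to ``MT``.

    Idempotent; ``chr1`` and ``1`` unify, as do ``chrM``, ``M`` and ``MT``.
    """
    if not label:
        raise ValueError("empty chromosome label")
    s = label.strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() in {"M", "MT"}:
        return "MT"
    if s.upper() in {"X", "Y"}:
        return s.upper()
    return s


@dataclass(frozen=True)
class CohortManifest:
    """Per-subject metadata: group label (e.g. case/control), population
    label (e.g. MA/AU), sex, and age in years."""

    table: pd.DataFrame  # columns: id, group, population, sex, age

    def __post_init__(self) -> None:
        missing = [c for c in _MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing column(s): {', '.join(missing)}")
        dup = self.table["id"][self.table["id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate subject id in manifest: {dup.iloc[0]!r}")
        if (self.table["age"] < 0).any():
            bad = self.table.loc[self.table["age"] < 0, "id"].iloc[0]
            raise ValueError(f"negative age for subject {bad!r}")

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    def subjects_where(self, **labels: str) -> list[str]:
        """Subject ids matching all given column=value constraints,
        e.g. ``subjects_where(population="MA", group="case")``."""
        mask = pd.Series(True, index=self.table.index)
        for col, val in labels.items():
            if col not in self.table.columns:
                raise KeyError(f"manifest has no column {col!r}")
            mask &= self.table[col] == val
        return list(self.table.loc[mask, "id"])

    def label_of(self, subject: str, column: str) -> str:
        row = self.table[self.table["id"] == subject]
        if row.empty:
            raise KeyError(f"unknown subject id {subject!r}")
        return row[column].iloc[0]


def read_manifest(path: str | Path) -> CohortManifest:
    """Read a tab-separated manifest with header columns
    ``id, group, population, sex, age``."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"manifest {path} missing column(s): {', '.join(missing)}"
        )
    if df.empty:
        logger.warning("manifest %s contains a header but no subjects", path)
    return CohortManifest(df[list(_MANIFEST_COLUMNS)].copy())


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    manifest.table.to_csv(path, sep="\t", index=False)


@dataclass
class SnvSetCollection:
    """Mapping subject -> chromosome -> set of :class:`SnvKey`.

    These are the objects the Jaccard metric compares: the SNV set of one
    subject on one chromosome (or, unioned, on the whole genome).
    """

    subjects: list[str]
    sets: dict[str, dict[str, set[SnvKey]]]
    mode: str = "position-only"  # or "allele-aware"

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for per_chrom in self.sets.values():
            for c in per_chrom:
                seen.setdefault(c)
        return sorted(seen, key=_chrom_sort_key)

    def get(self, subject: str, scope: str) -> set[SnvKey]:
        """SNV set for ``subject`` on a chromosome, or genome-wide when
        ``scope == "genome"`` (keys carry the chromosome, so the union over
        chromosomes is disjoint-safe)."""
        if subject not in self.sets:
            raise KeyError(f"unknown subject id {subject!r}")
        per_chrom = self.sets[subject]
        if scope == "genome":
            out: set[SnvKey] = set()
            for s in per_chrom.values():
                out |= s
            return out
        chrom = normalize_chrom(scope)
        if chrom not in self.chromosomes():
            raise KeyError(
                f"unknown chromosome scope {scope!r}; available: "
                f"{', '.join(self.chromosomes())}"
            )
        return per_chrom.get(chrom, set())

    def drop_alleles(self) -> "SnvSetCollection":
        """Project an allele-aware collection onto position-only keys."""
        sets = {
            subj: {c: {k.drop_alleles() for k in s} for c, s in per.items()}
            for subj, per in self.sets.items()
        }
        return SnvSetCollection(list(self.subjects), sets, "position-only")


def _chrom_sort_key(label: str) -> tuple[int, int | str]:
    return (0, int(label)) if label.isdigit() else (1, label)


@dataclass(frozen=True)
class ExtractionOptions:
    """Extraction policy.

    allele_aware
        Keep REF/ALT in the key; a multi-allelic record then contributes
        one key per single-nucleotide ALT the subject carries.
    pass_only
        Keep only records whose FILTER is PASS/unset (default accepts all,
        mirroring an unfiltered upstream calling pipeline).
    """

    allele_aware: bool = False
    pass_only: bool = False


def extract_snv_sets(
    vcf_paths: Sequence[str | Path],
    manifest: CohortManifest,
    options: ExtractionOptions | None = None,
) -> SnvSetCollection:
    """Read VCFs into per-subject, per-chromosome SNV sets.

    A subject possesses an SNV iff it has at least one called ALT allele
    there (het or hom-alt); missing genotypes (``./.``) count as absent.
    INDELs and other non-SNV alleles are excluded.  Every manifest subject
    must appear as a sample in exactly one of the given VCFs.
    """
    from cyvcf2 import VCF

    options = options or ExtractionOptions()
    wanted = set(manifest.ids)
    sets: dict[str, dict[str, set[SnvKey]]] = {s: {} for s in manifest.ids}
    found: set[str] = set()

    for path in vcf_paths:
        vcf = VCF(str(path))
        samples = [s for s in vcf.samples if s in wanted]
        if not samples:
            continue
        overlap = found.intersection(samples)
        if overlap:
            raise ValueError(
                f"subject(s) {sorted(overlap)} appear in more than one VCF"
            )
        found.update(samples)
        idx = [vcf.samples.index(s) for s in samples]
        per_subject = [sets[s] for s in samples]
        for record in vcf:
            if options.pass_only and record.FILTER is not None:
                continue
            ref = record.REF.upper()
            if len(ref) != 1 or ref not in _NUCLEOTIDES:
                continue
            chrom = normalize_chrom(record.CHROM)
            pos = record.POS
            # genotypes: array of allele indices per sample, -1 = missing
            gts = record.genotype.array()
            for alt_index, alt in enumerate(record.ALT, start=1):
                alt = alt.upper()
                if len(alt) != 1 or alt not in _NUCLEOTIDES or alt == ref:
                    continue
                key = (
                    SnvKey(chrom, pos, ref, alt)
                    if options.allele_aware
                    else SnvKey(chrom, pos)
                )
                for j, store in zip(idx, per_subject):
                    if (gts[j][:-1] == alt_index).any():
                        store.setdefault(chrom, set()).add(key)

    absent = wanted - found
    if absent:
        raise ValueError(
            f"manifest subject(s) not found in any VCF: {sorted(absent)}"
        )
    mode = "allele-aware" if options.allele_aware else "position-only"
    return SnvSetCollection(list(manifest.ids), sets, mode)


def write_snv_sets(collection: SnvSetCollection, path: str | Path) -> None:
    """Serialize a collection as TSV (one row per subject/variant)."""
    with open(path, "w") as fh:
        fh.write(f"#mode={collection.mode}\n")
        fh.write("subject\tchrom\tpos\tref\talt\n")
        for subject in collection.subjects:
            per = collection.sets.get(subject, {})
            if not per:
                fh.write(f"{subject}\t.\t0\t.\t.\n")  # subject with no variants
            for chrom in sorted(per, key=_chrom_sort_key):
                for key in sorted(per[chrom]):
                    fh.write(
                        f"{subject}\t{key.chrom}\t{key.pos}"
                        f"\t{key.ref or '.'}\t{key.alt or '.'}\n"
                    )


def read_snv_sets(path: str | Path) -> SnvSetCollection:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#mode="):
            raise ValueError(f"{path}: missing '#mode=' header line")
        mode = header.split("=", 1)[1]
        fh.readline()  # column header
        subjects: list[str] = []
        sets: dict[str, dict[str, set[SnvKey]]] = {}
        for line in fh:
            subject, chrom, pos, ref, alt = line.rstrip("\n").split("\t")
            if subject not in sets:
                subjects.append(subject)
                sets[subject] = {}
            if chrom == ".":
                continue
            key = SnvKey(
                chrom,
                int(pos),
                None if ref == "." else ref,
                None if alt == "." else alt,
            )
            sets[subject].setdefault(chrom, set()).add(key)
    return SnvSetCollection(subjects, sets, mode)


# ---------------------------------------------------------------------------
# PHYLIP square distance matrices


def write_distance_matrix(dm, path: str | Path) -> None:
    """Write a labeled distance matrix in PHYLIP square format.

    First line is the subject count; each following line is a label and its
    full row at 12+ significant digits (round-trip safe).
    """
    with open(path, "w") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for label, row in zip(dm.labels, dm.values):
            cells = "\t".join(format(v, ".17g") for v in row)
            fh.write(f"{label}\t{cells}\n")


def read_distance_matrix(path: str | Path, scope: str = "genome"):
    from .jaccard_core import DistanceMatrix

    with open(path) as fh:
        n = int(fh.readline().strip())
        labels: list[str] = []
        rows: list[list[float]] = []
        for _ in range(n):
            parts = fh.readline().split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    values = np.asarray(rows, dtype=float)
    if values.shape != (n, n):
        raise ValueError(f"{path}: expected a {n}x{n} matrix")
    for i in range(n):
        if values[i, i] != 0.0:
            raise ValueError(
                f"{path}: nonzero diagonal for {labels[i]!r}: {values[i, i]}"
            )
        for j in range(i):
            if not np.isclose(values[i, j], values[j, i], rtol=0, atol=1e-12):
                raise ValueError(
                    f"{path}: matrix not symmetric for pair "
                    f"({labels[i]!r}, {labels[j]!r})"
                )
    return DistanceMatrix(labels, values, scope=scope)


# ---------------------------------------------------------------------------
# Newick trees

_NEEDS_QUOTE = re.compile(r"[\s()\[\]{}:;,']")


def _quote_label(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")


def to_newick(tree) -> str:
    """Serialize a :class:`~snvclust.nj.ClusterTree` as Newick.

    Unrooted trees are written from an internal (trifurcating) node; a
    2-leaf tree has its single edge split evenly across a synthetic root.
    Branch lengths are written with 6 decimal places.
    """
    leaves = tree.leaf_nodes()
    if len(leaves) == 1:
        (node,) = leaves
        return f"{_quote_label(tree.leaf_names[node])};"
    if len(leaves) == 2:
        a, b = sorted(leaves)
        half = tree.adjacency[a][b] / 2.0
        return (
            f"({_quote_label(tree.leaf_names[a])}:{half:.6f},"
            f"{_quote_label(tree.leaf_names[b])}:{half:.6f});"
        )
    root = min(n for n in tree.adjacency if n not in tree.leaf_names)

    def render(node: int, parent: int) -> str:
        children = sorted(k for k in tree.adjacency[node] if k != parent)
        if node in tree.leaf_names:
            return _quote_label(tree.leaf_names[node])
        inner = ",".join(
            f"{render(c, node)}:{tree.adjacency[node][c]:.6f}" for c in children
        )
        return f"({inner})"

    return render(root, -1) + ";"


def _tokenize_newick(text: str) -> Iterable[str]:
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
        elif c in "(),:;":
            yield c
            i += 1
        elif c == "'":
            j = i + 1
            buf = []
            while j < n:
                if text[j] == "'" and j + 1 < n and text[j + 1] == "'":
                    buf.append("'")
                    j += 2
                elif text[j] == "'":
                    j += 1
                    break
                else:
                    buf.append(text[j])
                    j += 1
            yield "'" + "".join(buf)
            i = j
        else:
            j = i
            while j < n and text[j] not in "(),:;" and not text[j].isspace():
                j += 1
            yield text[i:j]
            i = j


def read_newick(path: str | Path):
    """Parse a Newick file into a :class:`~snvclust.nj.ClusterTree`.

    Rooted binary representations collapse their degree-2 root so that the
    result is the corresponding unrooted tree.
    """
    from .nj import ClusterTree

    text = Path(path).read_text()
    tokens = list(_tokenize_newick(text))
    adjacency: dict[int, dict[int, float]] = {}
    leaf_names: dict[int, str] = {}
    next_id = 0

    def new_node() -> int:
        nonlocal next_id
        adjacency[next_id] = {}
        next_id += 1
        return next_id - 1

    def connect(a: int, b: int, length: float) -> None:
        adjacency[a][b] = length
        adjacency[b][a] = length

    pos = 0

    def parse_clade() -> tuple[int, float]:
        nonlocal pos
        if tokens[pos] == "(":
            node = new_node()
            pos += 1
            while True:
                child, length = parse_clade()
                connect(node, child, length)
                if tokens[pos] == ",":
                    pos += 1
                    continue
                break
            if tokens[pos] != ")":
                raise ValueError("malformed Newick: expected ')'")
            pos += 1
            if tokens[pos] not in "(),:;":  # internal label, ignored
                pos += 1
        else:
            node = new_node()
            label = tokens[pos]
            leaf_names[node] = label[1:] if label.startswith("'") else label
            pos += 1
        length = 0.0
        if pos < len(tokens) and tokens[pos] == ":":
            length = float(tokens[pos + 1])
            pos += 2
        return node, length

    root, _ = parse_clade()
    if tokens[pos] != ";":
        raise ValueError("malformed Newick: expected ';'")
    # suppress a degree-2 root (rooted representation of an unrooted tree)
    if len(adjacency[root]) == 2 and root not in leaf_names:
        (a, la), (b, lb) = adjacency[root].items()
        del adjacency[a][root], adjacency[b][root], adjacency[root]
        connect(a, b, la + lb)
    return ClusterTree(adjacency, leaf_names)
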