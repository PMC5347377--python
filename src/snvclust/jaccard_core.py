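"""Jaccard distance between subjects' SNV sets.

For two SNV sets ``S1`` and ``S2`` on the same chromosome (or the whole
genome), the Jaccard distance is

    J(S1, S2) = 1 - |S1 n S2| / |S1 u S2|

It is 0 for identical sets, 1 for disjoint non-empty sets, and a true
metric: it satisfies the triangle inequality, which distance-based tree
methods rely on.  Sharing many same-position SNVs makes two subjects
close; a population with a largely disjoint variant pool sits near
distance 1 from everyone outside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .variant_io import SnvKey, SnvSetCollection


class JaccardCounts(NamedTuple):
    """Diagnostic breakdown of one pairwise comparison."""

    intersection: int
    size_1: int
    size_2: int

    @property
    def union(self) -> int:
        return self.size_1 + self.size_2 - self.intersection

    @property
    def distance(self) -> float:
        if self.union == 0:
            return 0.0  # both empty: equal sets by convention
        return 1.0 - self.intersection / self.union


def jaccard_counts(s1: Iterable[SnvKey], s2: Iterable[SnvKey]) -> JaccardCounts:
    """Exact |S1 n S2|, |S1|, |S2| for two SNV sets."""
    if not isinstance(s1, (set, frozenset)):
        s1 = set(s1)
    if not isinstance(s2, (set, frozenset)):
        s2 = set(s2)
    return JaccardCounts(len(s1 & s2), len(s1), len(s2))


def jaccard_distance(s1: Iterable[SnvKey], s2: Iterable[SnvKey]) -> float:
    """Jaccard distance ``1 - |S1 n S2| / |S1 u S2|`` in [0, 1].

    Two empty sets are equal, so ``J(set(), set()) == 0.0``.
    """
    return jaccard_counts(s1, s2).distance


@dataclass
class DistanceMatrix:
    """Labeled symmetric distance matrix with zero diagonal, entries in [0,1]
    for Jaccard distances (arbitrary non-negative values are tolerated so the
    same container can hold tree path-length matrices)."""

    labels: list[str]
    values: np.ndarray
    scope: str = "genome"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} labels"
            )

    def validate(self, atol: float = 1e-12) -> None:
        if not np.allclose(self.values, self.values.T, rtol=0, atol=atol):
            i, j = np.unravel_index(
                np.argmax(np.abs(self.values - self.values.T)),
                self.values.shape,
            )
            raise ValueError(
                f"matrix not symmetric at ({self.labels[i]!r}, "
                f"{self.labels[j]!r})"
            )
        if np.abs(np.diag(self.values)).max(initial=0.0) > atol:
            raise ValueError("matrix diagonal is not zero")
        if (self.values < -atol).any():
            raise ValueError("negative distances")

    def get(self, a: str, b: str) -> float:
        return self.values[self.labels.index(a), self.labels.index(b)]

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            list(labels), self.values[np.ix_(idx, idx)], scope=self.scope
        )


def distance_matrix(
    collection: SnvSetCollection, scope: str = "genome"
) -> DistanceMatrix:
    """Pairwise Jaccard distances between all subjects on one chromosome,
    or genome-wide (``scope="genome"``, per-chromosome sets unioned).

    Subjects appear in manifest (collection) order.
    """
    subjects = collection.subjects
    sets = [frozenset(collection.get(s, scope)) for s in subjects]
    n = len(subjects)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = jaccard_counts(
                sets[i], sets[j]
            ).distance
    return DistanceMatrix(list(subjects), values, scope=scope)
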