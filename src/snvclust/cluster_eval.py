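"""Does a labeled group "cluster together" in an unrooted tree?

The visual reading "the cases grouped together in a cluster" is formalized
as monophyly in the unrooted sense: a leaf subset clusters together iff
some edge of the tree separates exactly that subset from all other leaves
(an edge bipartition).  When the group is not a clade, the number of
"misplaced" subjects is the minimum number of leaves whose removal makes
the remaining group a clade — an exact quantity obtained by scanning edge
bipartitions (removing the symmetric difference between the group and one
side of an edge always works, and no smaller removal can).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

from .nj import ClusterTree
from .variant_io import CohortManifest


@dataclass
class GroupResult:
    """Clade status of one labeled group of subjects."""

    label: str
    subjects: list[str]
    is_clade: bool
    misplaced: int
    misplaced_subjects: list[str]


@dataclass
class SeparationReport:
    """Per-population and per-group clade evaluation of one tree."""

    scope: str
    n_leaves: int
    outgroup: str | None
    populations: dict[str, GroupResult]
    within_population_groups: dict[str, dict[str, GroupResult]]

    def all_clades_hold(self) -> bool:
        results = list(self.populations.values())
        for per_group in self.within_population_groups.values():
            results.extend(per_group.values())
        return all(r.is_clade for r in results)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent)


def is_clade(tree: ClusterTree, leaf_subset: set[str]) -> bool:
    """True iff ``leaf_subset`` is one side of some edge bipartition.

    Groups of size 1 or n-1 are always clades (every pendant edge is a
    bipartition).  The subset must be a non-empty proper subset of the
    leaves.
    """
    subset = frozenset(leaf_subset)
    leaves = frozenset(tree.leaf_names.values())
    unknown = subset - leaves
    if unknown:
        raise KeyError(f"unknown subject id(s): {sorted(unknown)}")
    if not subset or subset == leaves:
        raise ValueError("subset must be a non-empty proper subset of leaves")
    complement = leaves - subset
    for side in tree.bipartitions():
        if side == subset or side == complement:
            return True
    return False


def misplaced_subjects(tree: ClusterTree, leaf_subset: set[str]) -> list[str]:
    """A minimum set of leaves whose removal makes the group a clade.

    For each edge with sides (A, B), removing the leaves in the symmetric
    difference A ^ group leaves exactly group & A on one side of that edge,
    so the cost of "fixing" the group at that edge is |A ^ group|; any
    valid removal set must contain such a symmetric difference, hence the
    minimum over edges and sides is exact.  Empty iff the group already is
    a clade.
    """
    subset = frozenset(leaf_subset)
    leaves = frozenset(tree.leaf_names.values())
    unknown = subset - leaves
    if unknown:
        raise KeyError(f"unknown subject id(s): {sorted(unknown)}")
    if not subset or subset == leaves:
        raise ValueError("subset must be a non-empty proper subset of leaves")
    best: frozenset[str] | None = None
    for side in tree.bipartitions():
        for candidate in (side, leaves - side):
            removal = candidate ^ subset
            if candidate & subset and (best is None or len(removal) < len(best)):
                best = removal
    assert best is not None
    return sorted(best)


def _evaluate_group(tree: ClusterTree, label: str, members: list[str]) -> GroupResult:
    leaves = set(tree.leaf_names.values())
    subset = set(members)
    if not subset or subset == leaves:
        # size 0 handled upstream; size n is trivially "together"
        return GroupResult(label, sorted(members), True, 0, [])
    removal = misplaced_subjects(tree, subset)
    return GroupResult(label, sorted(members), not removal, len(removal), removal)


def separation_report(
    tree: ClusterTree,
    manifest: CohortManifest,
    outgroup_population: str | None = None,
) -> SeparationReport:
    """Evaluate population- and group-level clustering of a tree.

    Each population is tested as a clade of the full tree.  Within each
    population, the tree is first restricted to that population's leaves
    (pruning the rest and suppressing degree-2 nodes) and each group label
    (e.g. case/control) is then tested as a clade of the restricted tree.
    """
    leaves = set(tree.leaf_names.values())
    covered = set(manifest.ids)
    if not leaves <= covered:
        raise ValueError(
            f"manifest does not cover leaf/leaves: {sorted(leaves - covered)}"
        )
    sub = manifest.table[manifest.table["id"].isin(leaves)]
    populations = sorted(sub["population"].unique())
    if outgroup_population is not None and outgroup_population not in populations:
        raise ValueError(
            f"outgroup population {outgroup_population!r} matches no leaves; "
            f"populations present: {populations}"
        )

    pop_results: dict[str, GroupResult] = {}
    within: dict[str, dict[str, GroupResult]] = {}
    for pop in populations:
        members = list(sub.loc[sub["population"] == pop, "id"])
        pop_results[pop] = _evaluate_group(tree, pop, members)
        if pop == outgroup_population:
            continue
        restricted = tree.restrict(set(members))
        per_group: dict[str, GroupResult] = {}
        pop_rows = sub[sub["population"] == pop]
        for group in sorted(pop_rows["group"].unique()):
            group_members = list(pop_rows.loc[pop_rows["group"] == group, "id"])
            per_group[group] = _evaluate_group(restricted, group, group_members)
        within[pop] = per_group

    return SeparationReport(
        scope="tree",
        n_leaves=len(leaves),
        outgroup=outgroup_population,
        populations=pop_results,
        within_population_groups=within,
    )
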