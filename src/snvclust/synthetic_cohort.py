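"""Synthetic VCF cohorts with known population and case/control structure.

The generative model mirrors the structure the clustering method assumes:

* each population shares a pool of common variant positions, and every
  subject carries each pooled variant independently with a fixed
  probability — population pools are disjoint, so cross-population SNV
  sets overlap only by (rare) coincidence of private variants;
* within a focal population, cases additionally draw from a case-enriched
  pool that controls carry at a much lower rate — the "shared
  same-position SNVs" signal the Jaccard metric is meant to pick up;
* every subject also carries private variants scattered uniformly along
  each chromosome at a small per-base rate.

There is deliberately no linkage, mutation-rate or coalescent structure:
the Jaccard metric sees only set membership, so none of that would be
exercised.  Output is a sorted multi-sample VCF 4.2 (genotypes 0/1) plus
a truth manifest; a fixed seed gives byte-identical output.

The default configuration reproduces the shape of the reference cohort at
roughly 1/1000 scale: one population of 15 subjects averaging ~7.7k SNVs
(10 cases, 5 controls) and an outgroup of 10 subjects averaging ~3.9k.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np

from .variant_io import CohortManifest, SnvKey, SnvSetCollection

_NUCS = np.array(list("ACGT"))


@dataclass(frozen=True)
class PopulationSpec:
    """One population's piece of the generative model.

    pool_size
        Number of shared variant positions (split across chromosomes in
        proportion to length).
    carriage_prob
        Probability that a subject carries each pooled variant.
    private_rate
        Per-base probability of a private variant per subject.
    case_pool_size / case_carriage_cases / case_carriage_controls
        The case-enrichment pool: extra shared positions carried with
        probability ``case_carriage_cases`` by cases and
        ``case_carriage_controls`` by controls.  Set size 0 for a
        population with no case/control signal.
    """

    name: str
    n_cases: int
    n_controls: int
    pool_size: int
    carriage_prob: float
    private_rate: float
    case_pool_size: int = 0
    case_carriage_cases: float = 0.0
    case_carriage_controls: float = 0.0

    def __post_init__(self) -> None:
        for p in (
            self.carriage_prob,
            self.private_rate,
            self.case_carriage_cases,
            self.case_carriage_controls,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if min(self.n_cases, self.n_controls, self.pool_size,
               self.case_pool_size) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    chromosomes: dict[str, int]  # label -> length in bp
    populations: tuple[PopulationSpec, ...]

    def total_length(self) -> int:
        return sum(self.chromosomes.values())

    def total_pooled(self) -> int:
        return sum(p.pool_size + p.case_pool_size for p in self.populations)

    def validate(self) -> None:
        if self.total_pooled() > self.total_length():
            raise ValueError(
                f"pool sites ({self.total_pooled()}) exceed genome length "
                f"({self.total_length()})"
            )
        for label, length in self.chromosomes.items():
            if length < 1:
                raise ValueError(f"chromosome {label!r} has length {length}")

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent)


def default_config(seed: int = 0) -> SimulationConfig:
    """Desk-scale analogue of the reference cohort (~1/1000 burden scale)."""
    return SimulationConfig(
        seed=seed,
        chromosomes={"1": 150_000, "2": 100_000},
        populations=(
            PopulationSpec(
                name="MA",
                n_cases=10,
                n_controls=5,
                pool_size=8400,
                carriage_prob=0.85,
                private_rate=2.0e-3,
                case_pool_size=400,
                case_carriage_cases=0.9,
                case_carriage_controls=0.1,
            ),
            PopulationSpec(
                name="AU",
                n_cases=5,
                n_controls=5,
                pool_size=4400,
                carriage_prob=0.85,
                private_rate=6.0e-4,
            ),
        ),
    )


def _split_by_length(total: int, lengths: list[int]) -> list[int]:
    """Deterministically apportion `total` sites across chromosomes in
    proportion to length (largest-remainder rounding)."""
    weights = np.asarray(lengths, dtype=float)
    exact = total * weights / weights.sum()
    base = np.floor(exact).astype(int)
    remainder = total - int(base.sum())
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:remainder]] += 1
    return [int(x) for x in base]


@dataclass
class _Site:
    chrom: str
    pos: int
    ref: str
    alt: str


def _draw_sites(
    rng: np.random.Generator, config: SimulationConfig
) -> tuple[dict[str, list[_Site]], dict[str, np.ndarray]]:
    """Draw all pool sites (disjoint, without replacement) per population,
    and the per-chromosome free-position arrays left for private variants."""
    chroms = list(config.chromosomes)
    lengths = [config.chromosomes[c] for c in chroms]
    used: dict[str, set[int]] = {c: set() for c in chroms}
    pools: dict[str, list[_Site]] = {}

    def draw_pool(size: int) -> list[_Site]:
        per_chrom = _split_by_length(size, lengths)
        sites: list[_Site] = []
        for chrom, length, k in zip(chroms, lengths, per_chrom):
            taken = used[chrom]
            positions: set[int] = set()
            while len(positions) < k:
                batch = rng.integers(1, length + 1, size=k - len(positions))
                for pos in batch:
                    p = int(pos)
                    if p not in taken and p not in positions:
                        positions.add(p)
            taken.update(positions)
            for pos in sorted(positions):
                ref, alt = rng.choice(4, size=2, replace=False)
                sites.append(_Site(chrom, pos, _NUCS[ref], _NUCS[alt]))
        return sites

    for pop in config.populations:
        pools[pop.name] = draw_pool(pop.pool_size)
        pools[f"{pop.name}:case"] = draw_pool(pop.case_pool_size)
    free = {
        c: np.setdiff1d(
            np.arange(1, config.chromosomes[c] + 1), sorted(used[c])
        )
        for c in chroms
    }
    return pools, free


def _subject_roster(config: SimulationConfig) -> list[tuple[str, str, str]]:
    """(subject id, population, group) in deterministic order."""
    roster = []
    for pop in config.populations:
        for i in range(pop.n_cases):
            roster.append((f"{pop.name}-Case-{i + 1}", pop.name, "case"))
        for i in range(pop.n_controls):
            roster.append((f"{pop.name}-Control-{i + 1}", pop.name, "control"))
    return roster


def simulate_collection(
    config: SimulationConfig,
) -> tuple[SnvSetCollection, CohortManifest, dict]:
    """Draw a cohort in memory.

    Returns the position-only SNV set collection, the truth manifest, and
    the site catalogue (used by :func:`simulate_cohort` to emit VCF).
    """
    import pandas as pd

    config.validate()
    rng = np.random.default_rng(config.seed)
    pools, free = _draw_sites(rng, config)
    roster = _subject_roster(config)

    carriers: dict[tuple[str, int], set[int]] = {}
    site_alleles: dict[tuple[str, int], tuple[str, str]] = {}
    sets: dict[str, dict[str, set[SnvKey]]] = {}

    for subj_idx, (subject, pop_name, group) in enumerate(roster):
        pop = next(p for p in config.populations if p.name == pop_name)
        per_chrom: dict[str, set[SnvKey]] = {
            c: set() for c in config.chromosomes
        }

        def carry(sites: list[_Site], prob: float) -> None:
            if not sites or prob == 0.0:
                return
            mask = rng.random(len(sites)) < prob
            for site, hit in zip(sites, mask):
                if hit:
                    locus = (site.chrom, site.pos)
                    carriers.setdefault(locus, set()).add(subj_idx)
                    site_alleles.setdefault(locus, (site.ref, site.alt))
                    per_chrom[site.chrom].add(SnvKey(site.chrom, site.pos))

        carry(pools[pop_name], pop.carriage_prob)
        carry(
            pools[f"{pop_name}:case"],
            pop.case_carriage_cases if group == "case"
            else pop.case_carriage_controls,
        )
        # private variants: uniform over positions outside every pool
        for chrom in config.chromosomes:
            pool_free = free[chrom]
            k = rng.binomial(len(pool_free), pop.private_rate)
            if k == 0:
                continue
            for pos in pool_free[
                rng.choice(len(pool_free), size=k, replace=False)
            ]:
                locus = (chrom, int(pos))
                carriers.setdefault(locus, set()).add(subj_idx)
                if locus not in site_alleles:
                    ref, alt = rng.choice(4, size=2, replace=False)
                    site_alleles[locus] = (_NUCS[ref], _NUCS[alt])
                per_chrom[chrom].add(SnvKey(chrom, int(pos)))
        sets[subject] = per_chrom

    rows = []
    for subject, pop_name, group in roster:
        rows.append(
            {
                "id": subject,
                "group": group,
                "population": pop_name,
                "sex": "Female",
                "age": int(rng.integers(18, 61)),
            }
        )
    manifest = CohortManifest(
        pd.DataFrame(rows, columns=["id", "group", "population", "sex", "age"])
    )
    collection = SnvSetCollection(
        [r[0] for r in roster], sets, "position-only"
    )
    catalogue = {"carriers": carriers, "alleles": site_alleles,
                 "roster": roster}
    return collection, manifest, catalogue


def simulate_cohort(
    config: SimulationConfig,
    vcf_path: str | Path,
    manifest_path: str | Path,
) -> CohortManifest:
    """Simulate a cohort and write it as a multi-sample VCF 4.2 plus a
    TSV truth manifest.  Deterministic given the config (incl. its seed)."""
    from .variant_io import write_manifest

    _, manifest, catalogue = simulate_collection(config)
    roster = catalogue["roster"]
    samples = [r[0] for r in roster]
    carriers = catalogue["carriers"]
    alleles = catalogue["alleles"]

    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=snvclust-simulate\n")
        for chrom, length in config.chromosomes.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        columns = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        if samples:
            columns += "\tFORMAT\t" + "\t".join(samples)
        fh.write(columns + "\n")
        for chrom in config.chromosomes:
            loci = sorted(p for c, p in carriers if c == chrom)
            for pos in loci:
                ref, alt = alleles[(chrom, pos)]
                cs = carriers[(chrom, pos)]
                gts = "\t".join(
                    "0/1" if i in cs else "0/0" for i in range(len(samples))
                )
                row = f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t."
                if samples:
                    row += f"\tGT\t{gts}"
                fh.write(row + "\n")
    write_manifest(manifest, manifest_path)
    return manifest


def expected_snv_count(config: SimulationConfig, population: str,
                       group: str) -> float:
    """Closed-form expected per-subject SNV count for a role."""
    pop = next(p for p in config.populations if p.name == population)
    free_len = config.total_length() - config.total_pooled()
    case_p = (
        pop.case_carriage_cases if group == "case"
        else pop.case_carriage_controls
    )
    return (
        pop.pool_size * pop.carriage_prob
        + pop.case_pool_size * case_p
        + free_len * pop.private_rate
    )


def expected_jaccard(
    config: SimulationConfig,
    role_a: tuple[str, str],
    role_b: tuple[str, str],
) -> float:
    """Ratio-of-expectations approximation of E[J] between two subjects.

    Summing per-site inclusion probabilities p_i, q_i over the pools gives
    E|S1 n S2| = sum p_i q_i and E|S1 u S2| = sum (p_i + q_i - p_i q_i);
    private variants contribute to the union only (two subjects sharing a
    private position has probability ~rate^2 per base, neglected).  The
    returned 1 - E|n| / E|u| approximates E[J] well when the union is
    large; the small-sample bias is documented and checked empirically in
    the test suite, not corrected here.
    """
    config.validate()
    free_len = config.total_length() - config.total_pooled()

    def inclusion(role: tuple[str, str]) -> dict[str, float]:
        pop_name, group = role
        pop = next(p for p in config.populations if p.name == pop_name)
        probs: dict[str, float] = {}
        for other in config.populations:
            probs[other.name] = (
                pop.carriage_prob if other.name == pop_name else 0.0
            )
            if other.name == pop_name:
                probs[f"{other.name}:case"] = (
                    pop.case_carriage_cases if group == "case"
                    else pop.case_carriage_controls
                )
            else:
                probs[f"{other.name}:case"] = 0.0
        probs["__private__"] = pop.private_rate
        return probs

    pa, pb = inclusion(role_a), inclusion(role_b)
    e_inter = 0.0
    e_union = 0.0
    for pop in config.populations:
        for key, size in (
            (pop.name, pop.pool_size),
            (f"{pop.name}:case", pop.case_pool_size),
        ):
            p, q = pa[key], pb[key]
            e_inter += size * p * q
            e_union += size * (p + q - p * q)
    e_union += free_len * (pa["__private__"] + pb["__private__"])
    if e_union == 0.0:
        return 0.0
    return 1.0 - e_inter / e_union
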