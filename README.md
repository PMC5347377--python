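# snvclust

Cluster human subjects by the entirety of their whole-genome single
nucleotide variants (SNVs).

Genotyping-based association studies compare cases and controls one
variant at a time. `snvclust` implements a complementary, model-free
strategy: treat each subject's whole-genome SNV profile — every position
where they carry at least one non-reference allele — as a *set*, measure
dissimilarity between subjects with the Jaccard distance, and build
distance-based cluster trees. If sharing many same-position SNVs tracks
shared phenotype, subjects with the same diagnosis should cluster
together, and a genetically distant population should attach as an
outgroup. The intended users are statistical-genetics researchers with
per-subject VCFs and a case/control manifest.

## The method

For SNV sets $S_1, S_2$ of two subjects on one chromosome (or the whole
genome), the distance is the Jaccard metric

$$J(S_1, S_2) = 1 - \frac{|S_1 \cap S_2|}{|S_1 \cup S_2|} \in [0, 1],$$

which is 0 for identical sets, 1 for disjoint sets, and satisfies the
triangle inequality — a true metric, unlike many alignment-based
genomic distances. The pairwise distance matrix is fed to
neighbor joining (Saitou–Nei): repeatedly join the pair $(i,j)$
minimizing $Q(i,j) = (n-2)\,d(i,j) - \sum_k d(i,k) - \sum_k d(j,k)$,
with the canonical branch-length and matrix-reduction formulas. NJ
assumes no molecular clock and is exact on additive matrices. Whether a
labeled group "clusters together" is decided formally: the group forms a
clade iff some edge of the unrooted tree separates exactly that group
from all other leaves.

The package contains six parts:

| module | contents |
| --- | --- |
| `snvclust.variant_io` | VCF → per-subject/per-chromosome SNV sets (via cyvcf2), TSV manifests, PHYLIP matrices, Newick trees |
| `snvclust.jaccard_core` | Jaccard distance and pairwise distance matrices |
| `snvclust.nj` | neighbor joining, from scratch, with deterministic tie-breaking |
| `snvclust.cluster_eval` | clade tests, misplaced-subject counts, separation reports |
| `snvclust.cohort_stats` | count tables, group summaries, Welch's t-test, boxplot five-number summaries |
| `snvclust.synthetic_cohort` | VCF cohort simulator with known population / case-control structure |

## Worked example

Simulate a 25-subject cohort with the bundled default configuration —
population "MA" (15 subjects, 10 cases with an enriched pool of shared
case variants, 5 controls) versus outgroup population "AU" (10
subjects), with MA carrying roughly twice AU's variant burden — then run
the pipeline:

```
snvclust simulate -o demo --seed 42
snvclust dist demo/cohort.vcf -m demo/manifest.tsv --genome -o demo
snvclust tree demo/dist_genome.phy -o demo
snvclust eval demo/tree_genome.nwk -m demo/manifest.tsv \
    --outgroup AU --assert-clade MA:case
```

The evaluation report (abridged) prints:

```json
{
  "populations": {
    "AU": {"is_clade": true, "misplaced": 0},
    "MA": {"is_clade": true, "misplaced": 0}
  },
  "within_population_groups": {
    "MA": {
      "case":    {"is_clade": true, "misplaced": 0},
      "control": {"is_clade": true, "misplaced": 0}
    }
  }
}
```

Both populations form clades (AU behaves as an outgroup), and within MA
the 10 simulated cases cluster together with no misplaced subjects — the
tree recovers the planted case/control structure from the VCF alone.
`misplaced` is the minimum number of leaves whose removal would make the
group a clade, so 0 means perfect separation. `snvclust summary` adds the
burden statistics: with this seed, mean total SNVs 7864.1 (MA, n=15)
versus 3883.3 (AU, n=10), Welch p = 1.24e-21 — the simulated analogue,
at 1/1000 scale, of a two-population burden difference.

The bundled reference table (`snvclust.datasets.reference_cohort`)
carries the published per-subject totals and demographics of a real
25-subject cohort; from it the package reproduces mean burdens of
3,901,078 (AU) and 7,729,021.3 (MA), Welch p = 2.09e-15, and the
case/control age balance (38.8 ± 8.15 vs 39.6 years).

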