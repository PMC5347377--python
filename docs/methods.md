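# Methods

## The clustering model

A subject's genomic state is reduced to a family of finite sets: for
each chromosome, the set of positions (1-based, VCF native) at which the
subject carries at least one called non-reference single-nucleotide
allele. All downstream quantities are functions of these sets only —
no allele frequencies, no genotype dosages, no linkage, no statistical
model. The working hypothesis is that two subjects who share many
same-position SNVs are phenotypically closer than two who do not; the
Jaccard distance operationalizes "share" as set intersection, normalized
by the union so the value is comparable across subjects with very
different burdens.

Two identity notions for an SNV are supported:

* **position-only** (default): `(chromosome, position)`. This matches
  the same-position hypothesis and makes a multi-allelic site one key.
* **allele-aware** (option): `(chromosome, position, REF, ALT)`, one key
  per single-nucleotide ALT the subject carries. Strictly finer: the
  position-only set is the image of the allele-aware set under dropping
  alleles. Offered for sensitivity analysis.

Inclusion is zygosity-blind — het and hom-alt both count, missing
(`./.`) counts as absent — because the set formalism has no natural
place for dosage. FILTER is ignored by default (`--pass-only` restricts
to passing records); whether upstream calling was joint or per-sample
does not change the metric.

`J(∅, ∅) = 0` by convention (equal sets; avoids 0/0). This arises only
for degenerate inputs, e.g. a chromosome scope where neither subject
has calls.

## Neighbor joining

Implemented directly from the Q-criterion with running row sums, O(n³)
overall — n is a cohort size (tens), so no sub-cubic refinement is
warranted. Two policies are fixed where the literature leaves freedom:

* **Tie-breaking**: among equal-Q pairs, the lexicographically smallest
  (row, column) in the current working order is joined. Arbitrary but
  deterministic; repeated runs are byte-identical through to Newick.
* **Negative branch lengths** (possible on non-additive input) are kept
  by default, as the algebra produces them; `clamp_negative` zeroes a
  negative length and transfers the deficit to its sibling edge so the
  path length between the joined pair is preserved.

On additive input NJ is exact; the suite verifies topology and
path-length recovery to 1e-12 on random trees up to 50 leaves, and
cross-checks bipartitions against scikit-bio's independent NJ on noisy
matrices.

## Clade evaluation

"The group clusters together" is formalized as an unrooted bipartition:
some edge separates exactly the group from everything else. This is the
sharpest criterion consistent with reading a drawn tree, and it is
outgroup-free (rooting with an outgroup that is itself a clade yields
the same verdict). Groups of size 1 and n−1 are trivially clades.

When the group fails, the **misplaced-subject count** is the minimum
number of leaves whose removal makes the remaining group a clade. It is
computed exactly in polynomial time: for an edge with sides (A, B),
removing the symmetric difference A △ G leaves G ∩ A as one full side of
that edge, and conversely any fixing removal must contain such a
symmetric difference, so the minimum over edges and sides is the
optimum. (No branch-and-bound is needed; the scan is O(n) per edge.)

Within-population group evaluation first restricts the tree to that
population's leaves (pruning and suppressing degree-2 nodes, summing
the merged edge lengths), so a population-level split cannot mask
case/control structure. Restriction can only preserve or create clades,
never destroy one — verified property-based.

## Welch's t-test and descriptive statistics

The two-population burden comparison uses Welch's unequal-variance
statistic with Welch–Satterthwaite degrees of freedom, not the pooled
test: in the bundled reference cohort the group SDs differ by an order
of magnitude (≈37k vs ≈413k), exactly the regime the pooled test
mishandles. The implementation reproduces the cohort's published
p-value of 2.09e-15 to three significant figures; the pooled variant is
implemented for comparison and gives a clearly different value.
`log10_p` is reported alongside `p` so extreme results survive floating
underflow. With zero variance in both groups the test degenerates to
p = 1 (equal means) or p = 0 with log10_p = −inf (different means).

Age summaries report the population SD (divisor n) first — that
convention reproduces the reference cohort's printed 8.15 (cases) and
7.36 (controls) — with the sample SD (n−1) always emitted alongside.
Boxplot cells use Tukey hinges (medians of inclusive halves); the
reference figures print no quartile values, so the rule is fixed here by
convention and oracle-tested against an independent computation.

## Synthetic cohorts

The generator emulates the *statistical shape* the method assumes,
nothing more:

* per population, a pool of shared variant positions (drawn without
  replacement, pools mutually disjoint) carried independently with
  probability `carriage_prob` per subject;
* within the focal population, a case-enrichment pool carried at
  `case_carriage_cases` by cases vs `case_carriage_controls` by
  controls;
* per subject, private variants at a small per-base rate on positions
  outside every pool.

Genotypes are emitted as `0/1` — zygosity is invisible to position-set
extraction, so simulating it would add nothing testable. Likewise there
is no linkage, coalescent or mutation-rate structure: the Jaccard
metric sees only set membership. Consequences for interpretation:
passing end-to-end tests show the pipeline recovers planted
*set-overlap* structure from valid VCFs; they do not show that real MDD
cohorts contain such structure, nor address confounding by relatedness,
ancestry admixture or age — which in real data must be controlled by
design.

Default configuration (the package's study conditions): 15 focal
subjects (10 cases, 5 controls) and 10 outgroup subjects — the reference
cohort's composition — on two chromosomes of 150 kb and 100 kb, with
pool sizes and carriage chosen so expected burdens are ≈7.7k (focal) vs
≈3.9k (outgroup), i.e. the reference cohort's burdens at 1/1000 scale,
with carriage 0.85 for population pools and 0.9/0.1 case/control
carriage of a 400-site enrichment pool. The end-to-end studies use the
same shape at a further-reduced 50 kb genome (pools 1500/300/900),
which keeps 200 full pipeline replicates (simulate → VCF → extract →
Jaccard → NJ → evaluate) around a minute while leaving the planted
signal far from the noise floor.

`expected_jaccard` is a ratio-of-expectations approximation: it sums
per-site inclusion probabilities into E|∩| and E|∪| and returns
1 − E|∩|/E|∪|, neglecting both the covariance correction for the ratio
and private-variant collisions (probability ~rate² per base). The Monte
Carlo agreement test bounds the combined error empirically (within 3
standard errors plus 0.01 at desk scale).

## Numerical and format choices

* Chromosome labels normalize by stripping `chr`, uppercasing X/Y/MT,
  mapping `M` → `MT`; idempotent and bijective on the canonical labels.
* PHYLIP square matrices are written at 17 significant digits —
  round-trip exact for doubles; the reader rejects asymmetry and
  nonzero diagonals, naming the offending pair.
* Newick branch lengths are written with 6 decimal places; an unrooted
  tree is serialized from an internal trifurcating node, and a 2-leaf
  tree's single edge is split evenly across a synthetic root
  (documented, arbitrary). Round-trip fidelity (leaf sets, path lengths
  to 1e-6) is asserted against the tree *as written*, i.e. with lengths
  quantized to the serialized precision — over multi-edge paths the
  quantization itself can accumulate beyond 1e-6 relative to the
  in-memory tree, which is a property of the fixed-precision format,
  not of the parsers.
* The trees have no bootstrap support values: the method performs no
  resampling.

## Limitations

* Jaccard distances say nothing about *which* variants drive
  similarity; the method is a global screen, not a mapping tool.
* The misplaced-subject count is a tree statistic without an attached
  null distribution; label-permutation significance testing would be
  the natural extension and is not implemented.
* Mitochondrial scope is handled like any chromosome; real mtDNA
  (haploid, high copy number, different calling error profile) may
  behave differently in ways the simulator does not emulate.
* The reference table's INDEL and dbSNP-membership columns are out of
  scope: they require upstream annotation and an external database.
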