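# Methods

This note records the models, conventions and design decisions behind
`germcore`, in the order a user meets them: the data model, the diversity
measures, the samplers, the two-step pipeline, the evaluation battery and
the synthetic-bank generator.

## Data model and missing data

Genotypes are unordered diploid pairs of opaque allele labels at each of
*L* multiallelic co-dominant loci; no fragment-length semantics are
attached. The tokens `NA`, the empty string and `0/0` parse as missing
calls. Every pairwise quantity (difference counts, chord distance,
simple matching, kinship, LD) uses **pairwise deletion**: loci missing in
either member of a pair are skipped and locus averages run over the
jointly observed loci. This is the field default; results on data with
heavy, non-random missingness should be read with that in mind.

Deduplication treats "difference ≤ t" as a single-linkage relation:
accessions are clustered transitively and the first-listed member of each
cluster is retained. This makes the retained panel well defined even
though the underlying relation is not transitive; the outcome depends on
accession order only through which representative is kept, never through
which clusters form. `t = 0` collapses exact duplicates; `t = 3`
reproduces the conventional "more than three dissimilar alleles" panel
used before kinship and LD analysis of clonal collections.

## Diversity measures

- **Cv** — count (and fraction) of the bank's allele universe present in a
  subset. Row subsets keep the parent table's alphabets, so cores are
  always scored against the bank they came from.
- **He** — mean over loci of 1 − Σ p²; loci with no data in the subset are
  excluded from the mean with a warning.
- **Sh** — Shannon entropy (natural log) of the pooled, locus-weighted
  allele distribution q = p / L′. This is the definition under which a
  bank-scale collection scores ≈ 4.5 with 17 loci and ~280 alleles; a
  per-locus mean would sit near 2 and the unweighted pooled count near
  ln 280. Note one consequence: a panel of clones scores 0 only at a
  single locus; over L monomorphic loci the pooled index is ln L (the
  locus-weighting spreads mass evenly across loci).
- **D_CE** — chord distance without the 2/π constant and with the locus
  average under the square root, so the range is exactly [0, 1]; the
  printed bank-scale means (~0.75) fill most of that range, which is how
  the variant was pinned down. The exact variant used by legacy programs
  is not documented; this one is self-consistent and bounded.
- **Simple matching dissimilarity** — 1 − (shared alleles)/(2 L″); used
  for the diversity tree (MLST) and the PCoA.

## Samplers

`sample_random` is the uniform baseline. The two optimizing samplers are
the package's core algorithmic contribution and are implemented from
scratch:

**M-method** (`sample_m_method`): greedy seeding by marginal category gain
(alleles, optionally plus trait classes), kernel first, random tie-breaks;
then up to `iterations` single-swap improvement sweeps. The pooled Shannon
index acts as a tie-break among equally improving swaps and as the ranking
criterion between replicates — not as a secondary objective optimized to
exhaustion, which would collapse all independent runs onto one subset and
destroy the family structure the pipeline exists for. When a sweep finds
no improving swap, one random coverage-neutral swap is applied (a plateau
kick, at most 15 without improvement) and the best subset seen is
returned; this escapes the swap-local optima that tight covering instances
produce. "100 iterations" is interpreted as 100 improvement sweeps.

**ASLS** (`sample_asls`): fixed-size subset search by simulated annealing
(geometric cooling from T₀ = 0.01 to 10⁻⁵, single-swap moves, Metropolis
acceptance) followed by a best-improvement polish, over the objective
Σ w<sub>m</sub>·norm<sub>m</sub>(S). Normalization bounds are exact:
coverage and He are natively fractions, Sh is divided by ln(total
alleles), D_CE is already in [0, 1]. The replica-exchange metaheuristic of
the legacy program is not reproduced — only objective values matter to the
pipeline — and on every exhaustively searchable instance tested the
annealer reaches the true optimum. The best of `replicas` independent
replicas is returned. Defaults (8 replicas × 2500 steps) solve bank-scale
instances in a few seconds.

**MLST** (`sample_mlst`): neighbor-joining tree on the simple-matching
dissimilarity; repeatedly the cherry with the globally shortest external
edge loses its shorter-edged leaf and the tree is recomputed from the
remaining accessions. Ties break lexicographically on accession id, so
the procedure is fully deterministic. Recomputing the tree after each
removal is quadratic-cubic and intended for the moderate sizes where MLST
is competitive.

`redundancy_minimum_size` locates the smallest size whose best M-run
captures every category by bisection between the kernel size and the
greedy-cover upper bound; the best attainable coverage is monotone in
subset size, so bisection is equivalent to a linear scan and much cheaper.
Because the located size is *exactly* minimal, a single stochastic run at
that size can occasionally land one category short; family generation
therefore retries a failed run with fresh derived seeds (at most 4
attempts) before raising the hard error that guards the construction's
defining full-coverage property.

## Two-step pipeline

`build_kernel` draws the primary core at `primary_fraction` (default 8%)
with weights {Sh: 1}, then adds, for each plastid haplotype missing from
it, the carrier with the highest marginal allele gain (ties by id), and
finally every reference variety not already selected; an accession
qualifying on both grounds is counted once. `generate_core_family` runs
the kernel-constrained M-method `n_runs` times at the minimal
full-coverage size, decomposes the family into common set (selection
frequency 1) and complement panel, and exposes the presence/absence
matrix. The "arbitrarily chosen" family member is implemented as the
highest-Sh run — reproducible rather than arbitrary. Run seeds derive
from the master seed through a counter and are recorded in provenance.

`compare_objective_spaces` builds one family over alleles+traits and one
over alleles only. Objective nesting guarantees the markers-only minimal
size cannot exceed the joint one; if the two stochastic searches estimate
otherwise, the markers-only family is rebuilt at the joint size (which is
feasible by construction).

## Evaluation battery

- **Loiselle kinship**: ratio-of-sums multilocus estimator with the
  p(1−p)/(n<sub>l</sub>−1) small-sample bias term; negative pair values
  (less related than random) truncated to 0. Reference allele frequencies
  are computed **within the evaluated panel**, since the question the
  coefficient answers — is this pair more related than a random pair of
  the panel? — is panel-relative. The histogram bins pairs at 0.05 width
  with an open final bin at 0.45.
- **LD**: alleles rarer than 0.05 are removed first (a genotype left with
  no retained allele at a locus becomes missing there; loci with fewer
  than two retained alleles are dropped). Per locus pair the statistic is
  the allele-frequency-weighted mean over retained allele pairs of the
  squared dosage correlation — the composite genotypic disequilibrium,
  needing no phase information. A duplicated biallelic locus scores
  exactly r² = 1; for a duplicated locus with k > 2 alleles the weighted
  mean sits below 1 because cross-allele correlations are bounded by the
  within-locus frequency structure (a known property of averaged
  multiallelic r²). Significance: permutation of accession labels at one
  locus with the add-one correction p = (1 + #{r²* ≥ r²})/(B + 1), so
  p ∈ [1/(B+1), 1]; B = 1000 by default, reducible for tests.
- **PCoA**: classical metric scaling (double-centering +
  eigendecomposition), coordinates on positive-eigenvalue axes, explained
  variance as each eigenvalue's share of the positive spectrum;
  cross-checked against scikit-bio's implementation in the tests.
- **ΔK**: |mean L(K+1) − 2 mean L(K) + mean L(K−1)| / sd(L(K)) with
  sample SD; zero spread yields NaN with a warning. The clustering itself
  is consumed, never computed: ancestry matrices and log-likelihoods are
  external inputs, and the admixture report counts accessions whose
  maximal membership falls below 0.80.
- **Certification tests**: Mann–Whitney (exact null when the pooled
  sample is ≤ 12 and tie-free, tie-corrected normal approximation
  otherwise) on per-locus richness and gene diversity; the "t-test on the
  Shannon index" is realized as a paired t-test over per-locus Shannon
  components of core vs bank, the only construction that yields more than
  a single scalar per collection; zero-variance differences report p = 1
  with a warning.

## Synthetic-bank generator

The generator emulates a Mediterranean-style clonal bank: by default 502
accessions × 17 loci with ~280 alleles (16.4/locus), three gene pools in
West/Center/East proportions 0.28/0.54/0.18 with the central pool as a
hybrid zone (stronger admixture), pool differentiation set by a drift
parameter (Dirichlet resampling of a common base spectrum, Fst ≈
divergence), 12 plastid haplotypes with one dominant at 0.832, 72 traits
in 213 pool-dependent classes with 25% missingness, 45 planted near-clone
pairs (1–3 allele edits), and 19% of alleles forced to single carriers.

Calibration choices, fixed once: the base allele spectrum uses a
Dirichlet concentration of 0.35, which reproduces bank-scale He ≈ 0.73,
Sh ≈ 4.5 and mean D_CE ≈ 0.75; common-allele frequencies are floored at
~3.5 expected copies so that the "observed once" class stays governed by
the singleton dial while a 2–4-copy class survives — those few-carrier
alleles are what give core families genuinely interchangeable complement
slots; and singletons are injected into a pool of 30 candidate carriers,
mimicking the empirical clustering of rare alleles on few unusual
genotypes that keeps the family's common set well below the family size.
Clone-pair members are excluded from singleton injection so the planted
pairs are exactly the pairs within 3 allele differences.

What the generator does **not** emulate: stepwise-mutation allele-size
structure, genuine pedigree relatedness (all non-clone accessions are
unrelated draws), linkage between loci (all LD in the synthetic bank is
structure-driven), geography beyond the three-pool zone labels, and
reference varieties that are systematically more diverse than average
(references are random accessions, so more of them tend to fall outside
the primary core than in a real bank where references are prominent,
widely genotyped varieties). Passing tests therefore demonstrate the
machinery's correctness and the direction of structure-driven effects,
not quantitative agreement with any particular real collection.

## Problem sizes used in tests and the acceptance script

Statistical tests run either at full bank scale (502 × 17: calibration,
size trend, family structure, pool recovery) or at a reduced scale
(150–220 accessions, 12–14 loci: strategy dominance over 20 generator
seeds, LD contrast over 10 seeds) chosen to keep the whole suite in a few
minutes while leaving the tested contrasts heavily powered. Families are
generated with 25–50 runs rather than 200; the decomposition stabilizes
well before that. Permutation counts are 199 in tests and 499 in the
acceptance script (1000 remains the library default).

## Known limitations

- The optimizing samplers are stochastic; minimal sizes from the
  redundancy curve are best-effort estimates (exact on all exhaustively
  checkable instances tested, and reported with the evaluated curve).
- MLST recomputes a neighbor-joining tree per pruning step; use it for
  moderate collection sizes.
- The composite-LD aggregate is conservative for multiallelic perfect
  association (see above); comparisons between panels use the same
  statistic, so contrasts are unaffected.
- Trait classes are treated as unordered categories; ordinal structure in
  real descriptor scales is ignored.
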