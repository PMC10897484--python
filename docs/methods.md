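# Methods

This note documents the statistical models, estimator conventions and design
decisions behind `cnpop`, in enough detail to re-derive every number the
package produces.

## Genotype model

Copy states are integers 0–6 with CN=2 the normal diploid state. The
four-allele system assigns haploid alleles carrying 0, 1, 2 or 3 segment
copies; a diploid copy state is the sum of its two allele copy values, giving
the fixed, unique decomposition

| CN | 0 | 1 | 2 | 3 | 4 | 5 | 6 |
|----|---|---|---|---|---|---|---|
| genotype | 0/0 | 0/1 | 1/1 | 1/2 | 2/2 | 2/3 | 3/3 |

This mapping is a bijection, so allele frequencies, heterozygosity and all
downstream estimators are well defined directly from copy states. Missing
calls are the sentinel −1 and are excluded locus- and pairwise throughout;
they never silently become CN=2.

Locus architecture classes from the observed copy-state set: *deletion*
(only ≤2 with some <2), *duplication* (only ≥2 with some >2), *mixed* (both),
*non-allelic* (only 2). Carrier frequency is the fraction of genotyped
individuals with CN≠2; frequency classes are the half-open bins
[0%, 10%), [10%, 50%), [50%, 100%) and exactly 100%.

Coordinates are 0-based half-open internally, 1-based inclusive in text files.

## Filtering

Two-stage quality filter: calls whose confidence score fails the threshold
(default: keep if score > 0.1; comparator configurable) are masked to
missing, then loci shorter than 1 kb are dropped. Separately, a
false-positive filter removes loci that segregate above a carrier-frequency
threshold (default 0.9) yet overlap no reference structural variant at ≥ 50%
*reciprocal* overlap (the shared span must be at least the fraction of *both*
interval lengths; ties at exactly the threshold count as overlapping). The
interval query is a start-sorted sweep with a running maximum of interval
ends, verified in the tests against a brute-force all-pairs oracle.

## Cross-population tests

**Class-distribution test.** Each population pair is compared on its 2×4
table of allelic-locus counts per frequency class. Two tests are offered:
Pearson chi-square without continuity correction, and an exact
probability-ordered test (`fisher_exact_2xc`) that enumerates every table
with the observed margins and sums the probabilities of tables no more
probable than the observed one — the classical two-sided Fisher convention,
computed with a log-factorial table and full vectorised enumeration over all
but the largest column margin. Empty classes are dropped (reducing the
degrees of freedom). BH-FDR is applied over a configurable family: the focal
comparisons only, or **all pairwise comparisons among all populations**
(default).

The default exists because the published table this module reproduces
(frequency-class comparisons across 12 populations) is *not* reproduced by
the nominal "chi-square with FDR over the 11 focal tests" procedure (errors
up to 161%); it is reproduced essentially exactly (≤ 2.7% relative error) by
the exact test with BH-FDR across all 66 pairwise comparisons. The acceptance
test pins this behaviour. The exact enumeration over 66 tables costs a few
seconds rather than the sub-second runtime an asymptotic chi-square would
have.

**Size test.** Wilcoxon rank-sum (Mann–Whitney) on locus lengths between
architecture classes; exact null distribution when both groups have ≤ 25
observations, normal approximation otherwise; all-tied inputs yield p = 1
with a warning.

**High-frequent detection.** A locus is high-frequent in the focal
population if its focal carrier frequency is *strictly greater* than in every
reference population and a one-sided (greater) Fisher exact test on the 2×2
carrier table is significant against every reference after BH-FDR *within
the locus* across those comparisons (default α = 0.05). Results are
partitioned by architecture class.

**Sharing.** A locus is allelic in a population if it has ≥ 1 carrier there.
The sharing analysis reports loci allelic in all populations,
population-specific loci, and the pairwise shared-count matrix.

## Differentiation

**Weir & Cockerham (1984) θ.** Per locus and allele, the three variance
components are estimated as

- a (among populations), b (among individuals within populations),
  c (between the two allele copies within individuals),

from per-population allele frequencies, observed heterozygote fractions and
sample sizes (r = 2 populations, unequal n handled through n̄ and n_c).
Multiallelic loci sum the per-allele components; the per-locus θ is
Σa/Σ(a+b+c) over alleles, and the multi-locus θ is the ratio of sums over
loci (never the mean of ratios). Negative per-locus θ values are retained:
they are sampling noise around zero and clamping them would bias the
selection-scan ranks. Loci monomorphic overall, or with fewer than 2
genotyped individuals in either population, are excluded (NaN).

The tests verify the implementation against an independent ANOVA
mean-squares oracle (MSP/MSI/MSG with E[MSG]=c, E[MSI]=c+2b,
E[MSP]=c+2b+2n_c·a) to 1e-10, and against Balding–Nichols recovery of F over
a grid. Note one subtlety: two populations with *identical* genotype tables
do **not** give θ exactly 0 under WC84 — the small-sample correction leaves
a = −(p̄q̄ − h̄/4)/(n̄−1) ≠ 0 unless the table is Hardy–Weinberg-balanced; θ
is exactly 0 only in cases like the all-heterozygote table. θ for such tables
is small and non-positive, which is what the tests assert.

**Bins.** weak ≤ 0.05 < moderate ≤ 0.15 < high ≤ 0.25 < very-high, boundary
values to the lower bin, non-positive θ = weak.

**Selection scan.** Per population pair, loci are ranked by per-locus θ and
the top ⌈fraction·m⌉ of the m ranked loci kept (default 1%); ties break by
locus identifier (stable mergesort after id ordering) so results are
deterministic. The candidate set is the union across pairs.

## Clustering

**Distances.** Individual-level Euclidean distance between copy-state
vectors, with pairwise deletion of missing loci and rescaling of the squared
distance by L/m (m = shared loci) so sparsely genotyped pairs stay
comparable; population distance is the mean over inter-population individual
pairs. A frequency-level alternative uses mean-copy-state vectors per
population.

**UPGMA.** Average-linkage agglomeration (scipy); node height = merge
distance / 2, so trees are ultrametric. Bootstrap resamples loci with
replacement; support is the fraction of replicates reproducing each clade of
the rooted full-data tree (clades, not unrooted bipartitions, because UPGMA
trees are rooted — this also gives 3-taxon trees a supported clade). Newick
serialisation carries branch lengths and clade support as internal node
labels.

**PCA.** Dosage-matrix PCA: loci mean-centred, unit-variance scaled by
default, monomorphic loci dropped, missing calls mean-imputed; full SVD
solver; component signs fixed (largest-magnitude loading positive) for
determinism.

## Admixture model

The classical no-admixture-LD model: K clusters with allele-frequency tables
p(k, l, ·); individual i has ancestry proportions q_i (Dirichlet(α) prior,
α = 1); each of the two allele copies at each locus originates from cluster
z ~ Categorical(q_i) and is drawn from that cluster's frequencies
(Dirichlet(λ) prior on p, λ = 1). Gibbs sampling alternates

1. z for every allele copy ∝ q_ik · p(k, l, allele) (vectorised across all
   copies via cumulative-sum categorical sampling),
2. q_i ~ Dirichlet(α + per-cluster copy counts of i),
3. p(k, l, ·) ~ Dirichlet(λ + per-cluster allele counts at l).

Point estimates are posterior means over retained sweeps. The per-run model
log-probability is mean(lnL) − var(lnL)/2 over retained sweeps — the
deviance-style convention used for cluster-number selection, so ΔK values are
comparable across runs. Burn-in/sampling default to 10,000/10,000 and are
reduced in tests (500/1000); convergence is not monitored, the iteration
budget is fixed.

**Evanno ΔK.** L(K) = mean lnP over replicates; L′(K) = L(K) − L(K−1);
|L″(K)| = |L′(K+1) − L′(K)|; ΔK = |L″(K)| / sd(K). ΔK is defined only for
interior K with ≥ 2 replicates and positive sd — zero sd yields missing
(NaN), never infinity. Best K is the argmax of the defined ΔK values.

**Label alignment.** The disagreement Σ_i Σ_k |q[i, σ(k)] − ref[i, k]|
decomposes over (run column, reference column) pairs, so the optimal
permutation σ is a linear assignment problem solved exactly by the Hungarian
algorithm for *any* K; this replaces the exhaustive-for-K≤8/greedy-beyond
scheme that was considered, and the exhaustive search is kept in the tests as
an oracle. `AdmixtureModel` follows the scikit-learn estimator protocol
(`get_params`/`set_params`, `fit`, trailing-underscore attributes).

## Simulator

Balding–Nichols drift: per locus an ancestral allele-frequency vector is
drawn (non-normal allele frequency ~ Beta(0.5, 2) by default, making most
loci rare); each population's frequencies are Dirichlet(anc·(1−F)/F) — the
multiallelic analogue of the Beta form, with per-allele variance F·p(1−p).
Architectures: deletion loci use alleles {0, 1} (states 0–2), duplication
{1, 2} (states 2–4), mixed {0, 1, 2} (states 0–4), and mixed loci optionally
carry a rare 3-copy amplification allele extending states to 5–6. Genotypes
are two independent allele draws (HWE within populations); admixed
individuals draw each allele copy from a source population chosen by their
ancestry proportions. Per-call confidence ~ Beta(8, 2); optional uniform
missingness. The default study-scale design is 12 populations totalling
1,093 individuals and 1,279 loci. All output is bit-identical for a fixed
seed, and the full ground truth (ancestral and realized frequencies,
ancestry, architectures) is returned.

## Pipeline and determinism

`run_pipeline` sequences filter → frequencies → (optional reference-overlap
filter) → class/size comparisons → high-frequent → sharing → Fst + bins →
selection scan → UPGMA → PCA → admixture + Evanno, writing one TSV per stage
with a header comment carrying the config hash and seed. Stage failures raise
an error naming the stage; artifacts already written are retained. All
randomness flows from the single config seed; reruns are byte-identical.

## Limitations

- The admixture sampler implements the basic model only: no
  correlated-frequencies prior, no linkage model, no convergence diagnostics.
- The exact 2×c class test enumerates the full table lattice; it is meant for
  small c (≤ ~5) and the column margins of frequency-class tables, not for
  arbitrary large tables.
- WC84 θ assumes the four-allele decomposition of copy states is correct;
  genotyping error in copy states propagates directly.
- The simulator draws loci independently (no linkage) and populations
  star-shaped from one ancestor (no nested population history).
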