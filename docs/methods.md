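# Methods

`radpair` quantifies what whole-genome amplification by multiple
displacement amplification (MDA) does to double-digest RAD-seq (ddRAD)
libraries, by comparing each sample's MDA library against a library
prepared directly from the same genomic DNA (gDNA). This note documents
the models, the synthetic data generator, the numerical choices, and the
known limitations.

## The analysis chain

For each taxon the unit of analysis is the set of *assembled loci*:
clustered read stacks passing a per-library depth threshold
(`FilterPolicy.min_coverage`, default 7 reads). Loci shared by at least
`min_samples_per_locus` libraries (default 4) form the *final dataset*.
On top of these two stages the package computes:

1. **Per-library statistics** (`sample_stats`): assembled and final
   locus counts, depth mean/SD over assembled loci (sample SD, n−1),
   observed heterozygosity (proportion of called sites carrying a
   two-allele IUPAC code, pooled over the library's final-dataset
   sequences), and GC content.
2. **Distance matrices** (`distances`): the locus-overlap dissimilarity
   `1 − |A∩B| / |A∪B|` over final-dataset presence sets, and a genetic
   distance — the mean over final-dataset SNP sites (where both
   libraries have a called base) of the average of the four
   cross-library allele comparisons, each genotype expanded to its two
   alleles. Pairs sharing fewer than `min_shared_for_distance` final
   loci (default 35) are reported as missing, never imputed.
3. **Problematic-sample screen**: sample *i* is flagged when
   d(gDNA_i, MDA_i) ≥ min over conspecific *j* of d(gDNA_i, gDNA_j) —
   i.e. when the margin Δ_i = min_j d(gDNA_i, gDNA_j) − d(gDNA_i, MDA_i)
   is ≤ 0 (the boundary is inclusive). A pair whose MDA library is as
   far from its own gDNA library as another individual is likely
   contaminated or strongly mis-genotyped.
4. **Contamination classification** (`contamination`): a reference is
   built from all taxa's gDNA final-dataset sequences, greedily
   de-replicated at 95% global identity (length-sorted, forward strand
   only), optionally augmented with user sequences (e.g. a repeat-masked
   human genome) under a non-self source label. Queries are classified
   by best hit — k-mer (k = 15) candidate lookup followed by edit-distance
   alignment (edlib; global for comparable lengths, infix for short
   queries), requiring ≥ 85% identity over ≥ 50% of the query — into
   correct taxon / incorrect taxon / human / no match, at the assembled
   and final stages (and on raw reads for real data supplied
   externally). Ties break toward the query's own taxon, then entry id,
   making classification deterministic.
5. **Inference** (`inference`): linear mixed models with random
   intercepts and backward elimination, and multivariate distance matrix
   regression (MDMR) with permutation inference (details below).
6. **Population genetics** (`popgen`): missing-data condensing, PCA +
   k-means with BIC selection, Weir–Cockerham F_ST, Mantel isolation by
   distance over great-circle distances.

## Mixed models

Responses are transformed where needed: `log`, `logit_capped`
(logit(x / cap), cap default 30,000 loci — a generous ceiling on loci a
ddRAD library could assemble), or `logit_offset` (logit(x + 0.001) for
proportions that can be exactly zero). Models are fit by REML
(statsmodels `MixedLM`); multiple and nested random intercepts
(`"pool"`, `"sample@taxon"`) are expressed as variance components over a
single trivial group. Backward elimination repeatedly drops the least
significant eliminable fixed effect with Wald F-test p > α (default
0.05), interactions always before the main effects they contain, and
refits until no term qualifies.

Denominator degrees of freedom use the residual-df approximation
n − p. A Satterthwaite approximation would be preferable for small
group counts but is not available in the fitting backend; at the sample
sizes this package targets (tens to hundreds of libraries, a handful of
pools) the residual-df Wald test is very close to the exact F test, and
the model-selection acceptance test cross-checks calibration against an
exact OLS-with-dummies analysis.

## MDMR

Distance matrix regression follows the trace (McArdle–Anderson)
formulation. With A the matrix of squared dissimilarities and C the
centering matrix, G = −½·C·A·C; H is the hat matrix of the full design
(intercept plus dummy-coded predictors). The omnibus pseudo-R² is
tr(HGH)/tr(G) and each predictor's pseudo-R² is the marginal drop-one
difference tr(HGH) − tr(H₋GH₋), divided by tr(G). Significance comes
from jointly permuting rows and columns of the dissimilarity matrix
(default 999 permutations), p = (1 + #{perm ≥ obs}) / (1 + n_perm).

Negative eigenvalue mass of G — routine for non-Euclidean
dissimilarities such as 1 − Jaccard — is retained in all traces and in
the permutation distribution; only the *reported* pseudo-R² values are
clipped into [0, 1], so a small negative omnibus trace ratio prints as
0. Rank-deficient designs are rejected with the aliased columns named
rather than silently dropped; the pipeline driver retries after removing
the pool, then the population predictor, logging each removal.

## Population genetics

**Condenser.** The goal is the largest library set with at most 50%
missing data per library over loci passing a min-samples threshold,
searched over candidate thresholds; the objective is lexicographic
(samples kept, then loci kept), and removal decisions use missingness
only, never identity or preparation method. For ≤ 15 samples the
optimum is found exactly by vectorized enumeration of all sample
subsets; above that a greedy remove-the-worst loop is used (the greedy
solution can keep fewer samples than the optimum on adversarial
matrices — the exact path exists precisely because QC-scale problems
are small).

**PCA + k-means.** Genotypes are encoded as alt-allele dosage (0/1/2;
sites with more than two alleles dropped and counted; missing genotypes
mean-imputed), centered, and projected on the PCs explaining ≥ 90%
variance (capped at 20). k-means runs with 10 seeded restarts per k and
k is chosen by minimum BIC = n·ln(WSS/n) + k·ln(n), the criterion used
by the common find-the-number-of-clusters genetic workflows.

**F_ST.** Per biallelic site the Weir–Cockerham (1984) components a
(among populations), b (among individuals within populations), c
(within individuals) are computed from sample sizes, allele frequencies
and observed heterozygote proportions; the combined estimate is the
ratio of sums θ = Σa / Σ(a+b+c) over sites, with monomorphic sites
skipped. θ/(1−θ) linearizes F_ST for isolation-by-distance regression.
Note the estimator's finite-sample behavior: for two identical
population samples it centers near −1/(2n−1), not exactly 0.

**Mantel / IBD.** The Mantel statistic is the Pearson correlation of
the off-diagonal upper triangles; the default test is one-tailed
(r ≥ observed), matching the directional isolation-by-distance
alternative, with a two-sided option. Geographic distances are
haversine on a sphere of radius 6371.0088 km. The IBD analysis drops
populations left empty by a gDNA/MDA subset filter and requires ≥ 3
populations.

## The synthetic data generator

`synthetic_data` emulates the observational design of a paired-library
MDA study: several taxa, island-model (or stepping-stone) population
structure, and a gDNA + MDA library pair per individual.

Genotypes: per locus, Binomial(L, θ) variable sites (locus length 90 bp,
θ = 0.02 by default — typical reduced-representation polymorphism);
ancestral allele frequencies Uniform(0.05, 0.95); population frequencies
Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) at the configured F_ST;
diploid Hardy–Weinberg individuals. The stepping-stone option chains
the Beta perturbation along the population sequence so differentiation
accumulates with distance (used for isolation-by-distance checks).

Sequencing: per-library locus weights are Dirichlet(α) and read depths
Multinomial(n_reads, w). gDNA uses a large concentration (α = 200,
near-even coverage); MDA uses α = 30 · (input ng / 300 ng), floored at
0.05 — the one interpretable knob tying amplification input to coverage
evenness. This Dirichlet-multinomial stand-in reproduces the observed
phenomenology (input-dependent locus dropout, inflated depth SD)
without modeling the amplification branching process itself. Defaults:
300 loci and 12,000 reads per library (≈ 40× mean coverage, the regime
where a ≥ 7× assembly threshold actually bites), per-library read counts
lognormal with σ = 0.6 (read depth in the emulated study design is
highly uneven), MDA input drawn log-uniformly from 6–360 ng.

Genotype calling: at heterozygous sites the read split is
Binomial(depth, ½) for gDNA and Beta-Binomial(depth, b, b) with
b = 0.2 for MDA (small b ⇒ strong allelic imbalance); a site is called
heterozygous only when the minor allele has ≥ 2 reads, so imbalance
produces apparent homozygosity — allelic dropout implemented at the
calling step, not as sequence error.

Contamination: `inject_contamination` replaces a Binomial(n_assembled,
fraction) set of a library's locus slots with donor-taxon sequences, in
one of two modes. `novel` emulates a contaminant too divergent to
co-cluster with the recipient's loci: each slot becomes a new,
library-private locus named for the donor, so independent contamination
events rarely share a locus and the min-samples filter strips them —
this is the pathway the stage-wise classifier quantifies. `replace`
emulates a contaminant that out-amplified the template at a homologous
cluster: the donor sequence is recorded under the original locus id,
corrupting the genotype call — the pathway the genetic-distance
problematic-sample screen detects. Real contamination is a mixture of
both; the two modes isolate the two detection routes.

All randomness flows from one mandatory seed; per-library substreams
are derived by SHA-256 hashing of the library id, so any library can be
regenerated independently and byte-identical outputs are guaranteed for
a fixed seed.

What the generator does **not** emulate: read-level error and quality
scores, adapter trimming (so the raw-reads classification stage applies
to real data only), fragment-size selection, linkage and recombination
within loci, GC-dependent amplification bias, and any DNA *quality*
effect — the input-DNA knob conflates quantity with quality, which an
observational study cannot separate either. Passing tests therefore
demonstrate that the statistical machinery recovers the artifacts this
mechanism generates, not that the mechanism is a faithful model of MDA
chemistry.

## Problem sizes

The test suite and `scripts/acceptance.py` run on deliberately small
instances chosen to keep every statistical check sharp: paired studies
of 2–3 populations × 4–6 individuals × 150–300 loci; F_ST recovery at 2
populations × 50 diploids × 500 loci; MDMR null calibration with 1,000
simulations of 12 libraries at 199 permutations; 50-replicate
directional checks; condenser oracle matrices up to 12 × 20. The main
acceptance run reports, among others: MDA/gDNA assembled-locus ratio,
MDA depth-SD excess and heterozygosity deficit, the input-DNA effect on
locus counts, MDMR pseudo-R² for population vs MDA, classifier
incorrect-match proportions at assembled vs final stages, flagging
sensitivity/false-positive rate, θ at true F = 0.10, and the
isolation-by-distance Mantel correlation.

## Known limitations

- The contamination aligner approximates, but does not reproduce,
  short-read-mapper behavior; an adapter accepts externally produced
  best-hit tables for users who prefer a dedicated mapper.
- Reverse-complement matching is off by default (ddRAD loci are
  orientation-consistent after assembly); repeat masking of any
  user-supplied genome is the user's responsibility.
- Wald F-tests with residual df are mildly anti-conservative for very
  few groups (< 5) — interpret borderline p-values accordingly.
- `.loci` files carry no per-locus depths, so depth statistics are
  only available for in-memory (simulated) datasets; file-based runs
  report them as missing and treat file loci as already depth-filtered
  by the upstream assembler.
- NJ trees carry no bootstrap support; distances are raw proportions,
  not model-corrected (JC/K2P).
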