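# Methods

This note documents the models behind each stage, the parameters that
matter, the numerical choices, what the synthetic generator does and does
not emulate, and the known limitations.

## Study design being emulated

The pipeline assumes a paired-compartment small-RNA experiment: two tumor
cell lines, each profiled as whole cells and as their secreted small
extracellular vesicles (sEVs), with three biological replicates per
group (12 samples). The scientific question is which miRNAs are
preferentially *sorted* into sEVs versus *retained* in cells, what
sequence motifs and RNA-binding proteins (RBPs) mark the sorted ones,
which cell types their target mRNAs point to, and whether a secretory
signature tracks nodal stage and survival in a patient cohort.

## Synthetic data generator

The generator (`sevmir.synthetic_data`) is first-class, tested code; its
defaults define the study conditions used throughout the tests and the
acceptance script.

**Sequences.** `n_mirnas = 500` mature sequences of length 18–25, iid
uniform over {A,C,G,U}. Exactly `round(0.2 · n)` carriers receive the
4-mer motif `GCGC` inserted at a uniform position; non-carriers are
rejection-sampled to exclude it (a retry cap raises for motifs too
frequent to exclude, e.g. 1–2-mers).

**Counts.** Count of miRNA g in sample j ~ NB with mean
s_j · λ_g · 2^(β_g·[j is sEV]) and dispersion α = 0.1
(variance μ + αμ², drawn as a gamma–Poisson mixture; α → 0 falls back to
Poisson). λ_g is log-normal(ln 100, 1); s_j is log-uniform on [0.5, 2];
β_g ~ Normal(2.0, 0.25²) for carriers and Normal(0, 0.25²) otherwise.
The per-miRNA jitter (sd 0.25) avoids degenerate identical effects; null
miRNAs get the same jitter around zero for realism. The realized β_g of
every miRNA is recorded as ground truth. A +2 log₂ mean shift at 20%
carrier fraction is a strong but plausible sorting effect; it is a
generator convention, not a biological claim.

**Interactions and markers.** 50 RBPs; the first 5 ("enriched") bind each
carrier miRNA with probability 0.5 and everything else at the background
rate 0.1. Each miRNA targets 40 of 20,000 genes uniformly; with ~100
carriers the pooled secretory target set covers roughly a quarter of the
targeted-gene universe, so a marker set drawn 60% from the pool is
clearly over-represented while uniform decoys sit at the hypergeometric
chance level. The gene-space size matters: with too few genes the pool
saturates the universe and no marker set can be enriched. Nine cell
types: one true type (overlap fraction 0.6 with the pool) and eight
decoys drawn uniformly from all genes. Setting
`target_overlap_fraction = None` makes the true type a decoy (the null
configuration).

**Cohort.** Latent score z ~ N(0,1) per patient. Signature expression is
2^(10 + z + ε), ε ~ N(0, 0.5²), so log₂ expression carries z plus noise.
Survival time ~ Exponential(rate = h₀·e^(γz)) with h₀ = 1/1000 per day
and γ = 1 by default, censored by an independent Uniform(0, 3000 days)
horizon. P(pN ≥ N1) = logistic(z); node-positive patients split
N1:N2:N3 = 50:35:15. The clinical stage cN equals pN except that
node-positive patients are recorded cN0 with probability 0.3 — the
false-negative mask that creates occult-metastasis cases. This is the
simplest mechanism producing the occult contrast; it also leaves residual
signal in cN itself (real clinical staging error is not purely
score-independent, so the generated cN0-vs-cN+ contrast is attenuated
rather than null).

**What the generator does not emulate.** Read-level artifacts (adapter,
ligation and mapping biases), miRNA families with correlated sequences,
isomiRs, compositional closure of sequencing (counts are independent NB
draws, not a fixed-sum composition), covariate structure in the cohort
(age, HPV status, treatment), and informative censoring. Passing tests
therefore demonstrate correctness of the statistics under the stated
model, not robustness to these real-data features.

## Differential abundance

Size factors are plain median-of-ratios: factor_j = median over miRNAs
positive in all samples of count_gj / geometric-mean_g. One-sided
differential secretion biases this median: with 20% of miRNAs shifted +2
log₂ and NB noise smearing the per-sample ratio distribution, the sEV
medians creep upward and fold changes shrink by ≈ 0.3 log₂ units. The
test therefore refines the factors with one trim pass — re-estimating
them after excluding the 25% of miRNAs with the most extreme preliminary
|log₂FC| (the same rationale as trimmed-mean-of-M normalization). Under a
null experiment the trim removes extremes symmetrically and is neutral;
with planted secretion it removes the carriers from the median and cuts
the bias to ≲ 0.15 log₂ units. `trim_fraction = 0` restores the plain
estimator.

Dispersion is method-of-moments per miRNA,
α̂ = max(10⁻⁸, (pooled within-condition variance − mean)/mean²), with no
shrinkage toward a trend and no outlier filtering: the full
reference-style machinery is deliberately not reimplemented, because the
artifact is validated by parameter recovery and calibration on simulated
data rather than by value-matching an external tool.

The Wald statistic is Δlog mean / SE with the delta-method variance
Var(μ̂)/μ̂² per condition, Var(μ̂) = μΣ(1/s_j)/n² + αμ²/n, referred to a
t distribution with n − 2 degrees of freedom (12 samples is too few for
the normal reference; the t reference makes the null p-values uniform —
verified by KS on 30,000 pooled null p-values). The +0.5 pseudo-count
moderates the *reported* log₂FC only, never the statistic; when a
condition mean is exactly zero the statistic falls back to the moderated
mean. Both cell lines are pooled in the default contrast (`cell_line=`
gives a stratified run). BH adjustment is computed in-house (one sorted
pass with monotonicity enforcement) and cross-checked against the
step-up definition and statsmodels.

Classification profiles: `screen` (p_adj < 0.05, log₂FC ≷ 0) feeds the
downstream screens; `strict` (additionally |log₂FC| > 1) reproduces the
narrower enriched-set convention. Both are kept as named profiles rather
than reconciled.

Clustering: rows are log₂(normalized + 1), z-scored; distance
1 − Pearson r; average linkage; the tree is cut to k = 4 clusters.
Zero-variance rows are defined to have correlation 1 with each other and
0 with everything else. The distance/linkage convention is a documented
choice, not inferred from any reference figure.

## Motif enrichment

All 4^k k-mers for k = 4..7 (21,760 motifs) are candidate sets; a miRNA
is a member iff the motif occurs as a contiguous substring of its mature
sequence (overlapping occurrences count once; membership is binary).
Sets with fewer than 6 members on the ranked universe are dropped.
Membership is built with an inverted k-mer index (linear in total
sequence length) and is verified against a naive double-loop scan in the
tests.

The ranking metric is log₂FC, descending, ties broken lexicographically
by id. The enrichment score uses hit increments |metric|^w / Σ_hits
(weight w = 1 by default; w = 0 gives the classic unweighted KS
statistic) and miss decrements 1/(N − N_hits). The running sum's signed
maximum deviation is reachable only immediately after a hit (maxima) or
immediately before one (minima), so the ES is computed from sorted hit
positions alone — this makes the permutation null cheap. Near-ties
between the positive and negative deviation (within 10⁻¹²) resolve to
the positive one. If every in-set metric is zero the increments fall
back to equal weights.

The null is gene-permutation: random member sets of identical size drawn
without replacement from the ranked ids (sample permutation is impossible
post-ranking). NES = ES / mean |null ES| of the same sign; p is the
plus-one estimator over same-sign nulls, flagged as an upper bound when
fewer than 10 same-sign draws exist. Within a screen, one shared
permutation block per set size serves all motifs of that size — each p
remains individually valid; only the (irrelevant) joint independence of
p-values across motifs is given up. The reference tool's pooled-NES FDR
machinery is replaced by BH over the permutation p-values, reported both
within each k (`fdr_per_k`) and jointly (`fdr_joint`), because top motifs
are conventionally read per k without a stated multiplicity family.
n_perm = 1000 by default; with ~500 same-sign nulls the attainable p
floor is ≈ 0.002, which BH across 256 4-mers still carries below 0.05
when several related motifs (superstrings of the planted one) share the
floor.

## RBP screen

Background = detected universe minus the compartment-enriched set
(disjoint groups; using the full universe as background would break the
χ² independence assumption). The universe is the miRNAs present in the
differential table, not all database miRNAs. Pearson χ² without
continuity correction; tables with any expected cell < 5 are flagged and,
under the default policy, tested with the two-sided Fisher exact test
instead. Zero-margin tables are untestable and excluded from ranking.
Ranking is by observed/expected ratio among RBPs with BH-adjusted
p < 0.05, ties broken by p then id; both the secretory and retained
compartments are screened.

## Target-cell screen

Universe policy `interaction` (default): genes targeted by at least one
miRNA in the interaction table — using the whole genome would inflate
significance with genes the assay could never select; `union` adds all
marker genes. The test is one-sided (over-representation), summed
exactly via the hypergeometric survival function and verified against
integer-binomial pmf summation. Pooled-target testing (one pool for all
secretory miRNAs) is the primary mode; the per-type subnetworks give the
per-miRNA detail.

## Clinical signature

Score = mean over signature miRNAs of the per-miRNA z-score of
log₂(x+1) — invariant to affine rescaling of any single miRNA's log
expression, so heavily expressed miRNAs cannot dominate (the rejected
alternative, summing raw expression, has exactly that flaw).
Zero-variance columns are excluded with a warning; patients quantified on
under half the signature are flagged.

Two-group contrasts use Welch's t (no equal-variance assumption);
multi-group uses one-way ANOVA with Tukey HSD pairwise p-values. pN takes
precedence over cN wherever both exist; cN is used only for the occult
contrast, which reports (i) cN0 vs cN+, (ii) pN0 vs pN+ within cN0
(occult), (iii) pN0 vs pN+ overall, each skipping gracefully when a
subgroup is too small.

Kaplan–Meier and the two-group log-rank statistic
(Σ(O−E))²/ΣV with the hypergeometric variance per event time, deaths
before censorings at ties, p from χ²(1) — are implemented in numpy
because the cutpoint scan and its permutation null evaluate them tens of
thousands of times; they are cross-checked against hand tabulation on
exhaustively enumerated small designs and against lifelines on random
instances.

The cutpoint search evaluates every candidate cut (distinct score values
between the 10% and 90% quantiles by default; `quantile:<k>` for a
k-point grid) subject to an arm floor of max(10, 10% of n), and returns
the minimum-p cut. That minimum is selection-biased by construction, so
the result always carries the full scan, and `n_permutations > 0` adds a
min-p permutation adjustment (shuffling scores against outcomes); in the
null simulations the unadjusted minimum rejects ~35% of the time at
nominal 5% while the permutation-adjusted p sits at ~5%.

## Problem sizes used in validation

The test-suite simulations use the default study (500 miRNAs) for the
planted-recovery checks over 25 seeds each; null calibration uses 200
matrices of 150 miRNAs (differential test), 25 zero-shift screens
(motifs), and 100 null cohorts of 150 patients with 99 permutations each
(cutpoint); survival power uses 50 cohorts of n = 300 (γ = 1) and the
occult contrast 50 cohorts of n = 400. These sizes give the binomial
pass criteria comfortable margins while keeping the suite quick.

## Known limitations

- The NB test is a two-group (optionally line-stratified) contrast, not a
  general GLM; no shrinkage, no outlier handling.
- Motifs are exact substrings: no degenerate/IUPAC symbols, no positional
  weighting, no secondary-structure context.
- The RBP and target screens inherit whatever ascertainment bias the
  interaction tables carry; the synthetic tables are unbiased by
  construction.
- The cutpoint permutation null preserves the censoring pattern but
  assumes exchangeability of scores across patients.
- TCGA-scale cohort results depend on the upstream expression
  normalization; the clinical module requires pre-normalized input and
  does not attempt to reproduce any external cohort's values.
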