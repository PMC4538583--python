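# Methods

## Design under analysis

Two primary fibroblast lines (labelled A and B; passage labels default to
PDs 32/42/52/62/72 and 16/26/46/64/74) are profiled by bulk RNA-seq at five
population doublings with three biological replicates, i.e. 30 samples. The
pipeline takes a raw gene-level count matrix, a sample sheet and gene
lengths; everything downstream is derived from those three tables.

## Normalization

A gene is *expressed* when its raw count is positive in every sample. The
filter is deliberately per-sample (not on the summed count): it guarantees
strictly positive RPKM, so logarithms never need a pseudocount, at the cost
of discarding genes silenced in even one sample. RPKM uses the pre-filter
column sums as per-sample depth; RPKM is therefore invariant to uniform
scaling of a sample's counts, and halving a gene's length doubles its RPKM.

RPKM is a *relative* measure: if regulation is asymmetric (more up than
down), the denominator grows over time and truly flat genes drift downward
in RPKM. This compositional effect is real, visible in the synthetic data,
and inherited by every relative-abundance unit; the monotonic classifier
can legitimately flag a few percent of flat genes for this reason.

## Sample-level diagnostics

Spearman correlation (mid-ranks) between all sample pairs, ordered by
average-linkage hierarchical clustering of `1 - rho`. Average linkage is the
conventional choice for correlation heatmaps; nothing downstream depends on
the linkage. PCA operates on gene-centered, unscaled log2-RPKM; components
are sign-fixed by making each component's largest-magnitude loading
positive, so results are machine-independent.

## Consensus NB exact test

Size factors are median-of-ratios over genes with all-positive counts,
reported unnormalized. Counts are scaled by their size factor and rounded to
a common scale; per group `g` with `m_g` samples, the group sum is modelled
as the sum of i.i.d. NB variables — mean `m_g mu`, variance
`m_g mu + alpha (m_g mu)^2 / m_g`. Conditioning on the total
`T = K_A + K_B`, with `mu` estimated as `T / (m_A + m_B)`:

    p = sum over splits a of T with Pr(a) <= Pr(observed) of Pr(a)
        -----------------------------------------------------------
        sum over all splits a of Pr(a)

Ties in `Pr` are counted as "as extreme" with a 1e-12 relative tolerance; `p`
is clamped to [0, 1]; an all-zero gene is untestable and reports `p = 1`
with a flag. At `alpha = 0` the NB collapses to Poisson and the test equals
the conditional binomial exact test. For `T > 5000` the sum is restricted to
splits within ±8 conditional standard deviations of the conditional mode
(always including the observed split); the truncation error is below 1e-8.
Log-space pmf evaluation via `gammaln` keeps the enumeration fast and
stable.

**Dispersion flavors.** Per-gene method-of-moments on normalized counts:
`MoM_i = max(0, (var_i - mean_i) / mean_i^2)`, where `var_i` is the pooled
*within-group* variance (so true group differences do not inflate the
estimate) and `mean_i` the grand mean. The *common* flavor uses the median
of the positive `MoM_i`; the *trended* flavor fits `MoM ~ a0 + a1/mean` by
least squares and floors each gene at its own `MoM_i` — a deliberately
conservative rule. A gene is differentially expressed only when the tests
under both flavors agree after BH adjustment (FDR < 0.05; the strict tier
asks FDR < 0.01 under both plus |log2FC| strictly > 1). Running one exact
test under two dispersion models and intersecting the calls preserves the
consensus semantics of intersecting two independent NB-based packages while
keeping the artifact self-contained.

log2FC is `log2((mean_B + 0.5) / (mean_A + 0.5))` on size-factor-normalized
group means. The pseudocount appears *only* here (to keep fold changes
finite when a gene reaches zero in one condition), never in testing.

## DEG accounting

The recurrence partition labels each DEG of comparison *t* by the earliest
comparison in which it appeared; labels partition each comparison's DEG set,
so the per-bar counts decompose into recurrent and new segments. The
two-line comparison intersects strict first-vs-last DEG sets and splits the
intersection by fold-change sign agreement. "Strong expression" for
validation-gene selection is the maximum per-group mean RPKM over both
lines, compared strictly (`> threshold`), with a curated list as an
alternative entry route.

## Fuzzy c-means profile clustering

Profiles are the 5 per-PD replicate-mean RPKM values of line 1 followed by
line 2, z-scored per gene **jointly over all 10 entries**. Joint scaling
(rather than per line) preserves the between-line offset inside one scaled
panel, which is what makes "same trend, different level" visible; per-line
scaling remains possible by building profiles per line and concatenating.
Constant raw profiles are dropped with a warning (their z-score is
undefined).

FCM minimizes `J = sum u_ik^m d_ik^2` with the standard alternating updates,
fuzzifier `m = 1.2`, objective tolerance `1e-8`, at most 500 iterations, and
30 random starts (lowest final `J` wins); initial memberships are drawn from
a flat Dirichlet, all seeded. A zero distance assigns full membership to the
coincident center(s). The objective sequence is non-increasing by
construction (each half-step is an exact minimization) and is asserted in
tests; our fixed points match the R reference implementation of cmeans to
near machine precision from identical initializations.

**Cluster number.** For each candidate c in 2..10 four validity indexes are
computed: partition coefficient (maximize), partition entropy (minimize),
Xie–Beni (minimize), Fukuyama–Sugeno (minimize). Each index votes for its
optimizing c; the modal vote wins, ties resolve to the smallest candidate.
These four are the standard fuzzy-partition suite; on planted five-archetype
data the vote recovers c = 5 reliably.

## Monotonic-trend classification

Each gene's per-PD profile is compared with the linearly increasing curve
`f(x) = x` by Spearman's rho on mid-ranks. Replicates enter through
one-replicate-per-PD paths. When the number of distinct paths is at most
1024 (3^5 = 243 for the study design) all paths are enumerated with equal
weight, so `c(i)` (mean rho) and `p(i)` (median per-path p) are the exact
expectation and median of the resampling scheme; larger designs fall back to
`n_resamples` (default 100) random draws. The per-path p-value enumerates
all `n!` permutations of the observed series, `p = P(|rho_perm| >=
|rho_obs|)` — exact also under ties, because the enumeration permutes the
observed values themselves. A constant series reports `(rho, p) = (0, 1)`.
With five time points the smallest achievable p is 2/120 ≈ 0.017 and the
next is 10/120 > 0.05, so only perfectly ordered profiles can be called:
this is why genome-wide monotone counts are small, and it bounds the
per-gene false-positive rate by construction. Classes: up (`c > 0`,
`p < alpha`), down (`c < 0`, `p < alpha`), else nonuniform; the default
`alpha` is 0.05. The median across paths was chosen over testing the
averaged profile because it is symmetric with the averaged rho and robust to
a minority of disordered paths; both readings collapse to the same answer
for noise-free profiles.

## Cross-platform concordance

qPCR expression is `2^-dCT` with `dCT = CT_target - CT_reference`
(reference gene configurable; a stably expressed transporter-family gene is
the conventional pick). Per-gene concordance with RNA-seq is Spearman's rho
across all of a line's samples, pairwise-complete, flagged unreliable below
3 pairs. Fold changes between first and last PD: RNA-seq `log2` of the
group-mean RPKM ratio (pseudocount 0.5), qPCR `-ddCT`, protein `log2` of the
given expression ratio; sign concordance requires all available platforms to
agree. Protein significance uses Welch's two-sample t-test on intensity
replicates.

## Synthetic data: what it emulates, and what it does not

Counts for gene i, sample j (line l, PD index t) are NB draws with mean
`baseline_i * offset_il * multiplier(archetype_il, t) * lib_j` and variance
`mu + alpha(mu) mu^2`:

| parameter | default | meaning |
|---|---|---|
| n_genes | 20,000 | genes before expression filtering |
| pd_labels | A: 32..72, B: 16..74 | five passage labels per line |
| n_replicates | 3 | biological replicates per PD |
| archetype fractions | flat 0.70, five regulated shapes 0.06 each | temporal shapes |
| shared_fraction | 0.7 | regulated genes with the same shape in both lines |
| effect_size | 1.0 | log2 change per PD step (monotone) or step event |
| dispersion (a0, a1) | (0.05, 1.0) | `alpha(mu) = a0 + a1/mu` |
| library_size_spread | 0.2 | log-normal sigma of per-sample depth factors |
| baseline (meanlog, sdlog) | (log 60, 1.2) | log-normal gene baseline, reads scale |
| line_offset_sdlog | 0.25 | per-gene log-normal between-line offset |
| length_range | 500–10,000 bp | uniform gene lengths (exercises RPKM only) |

Archetypes: flat; monotone up/down (`2^(±e·t)`); early step (change only
between indexes 0 and 1); late step (only between 3 and 4); parabolic
(symmetric rise–fall in log2, peak at the middle PD). Unequal library sizes
exercise size-factor estimation; per-gene line offsets separate the lines in
PCA; ~30% regulated genes echo the pervasive regulation seen in senescence
time courses. Ground truth records, per gene and line, the archetype, the
per-PD means, the monotone class (monotone archetypes only — steps and
parabolas are nonuniform by this test's standard) and DEG status per
comparison.

Not emulated: read-level artifacts (mapping, GC/length bias within a
sample), batch effects, zero inflation, isoforms, and correlated gene–gene
structure. Passing tests on this generator therefore demonstrates
correctness of the statistical machinery under the NB model the methods
assume — not robustness to the full messiness of real libraries.

Scale note: simulated depths (a few million counted reads per sample) are an
order of magnitude below typical production libraries; all statistical
checks operate at this desk scale, with sizes recorded in each test.

## Numerical choices and degenerate inputs

- Exact-test tie tolerance 1e-12 (relative) when comparing split
  probabilities; enumeration window ±8 conditional SDs beyond `T = 5000`.
- BH step-up delegated to statsmodels and verified against the brute-force
  definition; inputs outside [0, 1] are rejected.
- FCM: Dirichlet initial memberships; zero-distance points get one-hot
  memberships; empty clusters in summaries yield NaN rows with a warning;
  cluster SDs use the population convention so singletons stay finite.
- Spearman: constant series → `(0, 1)`; series longer than 8 points fall
  back to the t approximation (the exact factorial blows up).
- Validity-index vote ties → smallest c; FCM candidate range is clipped to
  the number of profiles minus one.
- All stage seeds fan out from one global seed by fixed offsets, so any
  stage can be rerun in isolation and reruns are byte-identical.

## Known limitations

- The consensus rule intersects two dispersion flavors of *one* test
  statistic; it is not a numerical reproduction of any specific external
  package pair, and agreement rates with such pairs are not claimed.
- The expression filter's per-sample positivity requirement is strict; a
  gene expressed in 29 of 30 samples is excluded from all downstream stages.
- Exact-test p-values are discrete; at very low counts they are
  conservative, which depresses power rather than inflating error.
- The monotonic classifier tests ordering only; it cannot distinguish a
  linear trend from any other strictly monotone shape, by design.
- RPKM's compositional drift (above) means "monotone in RPKM" is relative,
  not absolute, change.
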