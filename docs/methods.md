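# Methods

## Differential expression model

Counts K_ij for gene i in sample j are modelled as negative binomial with
mean μ_ij = s_j·q_i (q_i the gene's base expression, s_j the sample's size
factor) and variance μ + α_i μ². The three estimation steps:

**Size factors.** s_j = median over genes of K_ij / (Π_j' K_ij')^(1/n),
restricted to genes positive in every sample (the geometric-mean reference
is undefined otherwise; an all-zero-containing matrix raises with advice to
filter). Factors are rescaled to geometric mean 1, so normalized counts stay
on the counts scale. This is the classic median-of-ratios estimator; it is
robust to the minority of truly differential genes because they move the
ratio's tails, not its median.

**Dispersion.** Per gene, a method-of-moments estimate on normalized counts:
α̂_i = (v_i − q_i·mean_j(1/s_j)) / q_i², with v_i the within-group pooled
sample variance (so group mean differences never inflate it). A trend
α(q) = a0 + a1/q is fitted by least squares over genes with positive α̂ —
the 1/q term captures the Poisson-dominated low-count regime — and the
final value is max(α̂_i, trend(q_i), 10⁻⁸). With only four replicates per
group a per-gene estimate alone is far too noisy; taking the maximum of
gene and trend deliberately trades power for false-positive control. The
measured consequence (2,500-gene null simulation) is a type-I error of
~0.03–0.04 at a nominal raw p < 0.05 — controlled, mildly conservative.

**Exact test.** Conditional on the total S = k_A + k_B of the two group
sums, each partition (a, S−a) has probability Pr_A(a)·Pr_B(S−a), where the
group-sum distributions are NB with mean q·Σ_{j∈g} s_j and variance
q·Σ s_j + αq²·Σ s_j² (moment matching; Poisson fallback when the variance
does not exceed the mean, e.g. at the dispersion floor). The two-sided
p-value sums all partitions no more probable than the observed one,
normalized by the total — probability-ordering, the discrete analogue of a
two-sided exact test. Enumeration is exhaustive for S ≤ 20,000; beyond
that only a ±20-combined-σ window around the conditional mode is summed,
where the omitted mass is below double precision. Fold changes are
(mean_case + 1)/(mean_control + 1) on normalized counts; the pseudocount
keeps zero-mean genes defined.

DEG selection applies |log2FC| ≥ log2(fc_min) and p ≤ p_max on raw or
BH-adjusted p (both are always reported; the raw column is the default to
match the "P<0.05 / P<0.01" tier convention, FDR-adjusted selection is one
config switch). Locus-group accounting always sums to the DEG total; genes
missing from the annotation are counted as "other" and logged.

## Clustering and PCA

Distances and PCA operate on log2(normalized count + 1): on the raw scale a
handful of very highly expressed genes dominates every Euclidean distance.
Hierarchical clustering is average linkage on the exact pairwise distances
(ties broken toward the lowest-index pair, so trees are deterministic);
PCA is an SVD of gene-centered data with the sign convention that each
component's largest-magnitude loading is positive.

## Network topology test

The observed network is seeds (protein-coding DEG symbols mapped into the
interactome; the unmapped fraction is reported) plus first-degree
interactors, with the induced edge set. The null ensemble redraws the same
number of seeds uniformly from the interactome's nodes R times — matching
the observed construction, which uses only mapped seeds. No degree matching
is applied (nothing in the procedure being emulated suggests it); a
degree-matched null would be a natural extension.

Two comparison surfaces are reported:

* **KS on distributions**: two-sample Kolmogorov–Smirnov D between the
  observed network's all-pairs finite shortest-path-length multiset (and
  degree multiset) and the pooled null multisets. Multisets are held as
  value→count tables, so D is exact even when the pooled null holds
  millions of pairs; the p-value uses the asymptotic Kolmogorov law with
  effective size nm/(n+m).
* **Empirical scalar tests**: one-sided add-one p-values,
  p = (1 + #{null ≥ observed density})/(R+1) and
  p = (1 + #{null ≤ observed ASPL})/(R+1). ASPL is averaged over the
  largest connected component by default ("all finite pairs" is a config
  alternative); the component count is always reported.

The overall verdict (`TopologyComparison.rejects`) declares the seed
neighbourhood non-random if either scalar is extreme at level α/2
(Bonferroni split, family-wise level α).

**Known limitation — density power.** Under the uniform-seed null on a
preferential-attachment interactome, network density is strongly
size-confounded: null replicates that happen to sample a hub yield small,
dense networks, giving the null density distribution a heavy right tail.
Measured against a planted module, the density-alone surface has ~65% power
where ASPL has ~100%; the combined verdict inherits the ASPL power (20/20
planted runs rejected, 0/20 unplanted; true null rejection rate ~3% at
α = 0.05 over a 60-run probe). Interpret the density comparison jointly
with the network sizes it comes from.

## Enrichment

One-sided hypergeometric upper tail per term (over-representation only),
Bonferroni = min(1, m·p) over the m terms actually tested; terms with no
universe overlap are skipped and logged. The default universe is the
interactome's nodes and the default query the DEG network's proteins —
the question is "what is over-represented in the network" — with an
all-annotated-genes universe available by config.

## qPCR quantification

Technical replicates are averaged (mean) to one Ct per sample/gene before
ΔCt = Ct_target − Ct_reference; ΔΔCt = mean ΔCt(case) − mean ΔCt(control)
(group-mean form, appropriate for an unpaired cohort); fold = 2^(−ΔΔCt),
assuming perfect doubling efficiency for target and reference (no
Pfaffl-style efficiency correction). Group comparison is Student's
equal-variance t-test on per-sample ΔCt (Welch via config). Calls require
fold ≥ 2 or ≤ 0.5 *and* p < 0.05. ΔΔCt is invariant to any per-sample Ct
offset (loading differences), which the noisy generator exercises.

## Synthetic data: what it emulates, and what it does not

Defaults are the study conditions: 25,000 genes, 4 case vs 4 control,
dispersion α = 0.1, 2% of genes with planted |log2FC| = 2 split evenly
up/down, per-gene base expression log-normal(μ=5.0, σ=1.3) — median ≈ 150
counts/gene, i.e. ≈ 30M counted reads per sample, a typical HiSeq bulk
depth — and lognormal library-size factors (σ = 0.2). Counts are drawn
gamma–Poisson, so simulation and estimation share the (mean, α)
parameterization and recovery tests are well posed; α → 0 reduces to
Poisson. The interactome is Barabási–Albert (heavy-tailed degrees, as in
curated interaction databases) with extra edges planted pairwise among the
DE coding proteins — the alternative hypothesis "DE proteins are more
interconnected than chance" — at probability 0.1 by default. Ct plates get
per-gene baselines, per-sample offsets and Gaussian replicate noise.

Not emulated: mean–dispersion coupling beyond the fitted trend, GC/length
biases, batch effects, correlated co-expression modules outside the planted
one, interactome study bias, and qPCR efficiency differences. Passing tests
therefore demonstrate correctness of the statistics under the model's own
assumptions, not robustness to every artefact of real data.

## Problem sizes and numerical choices

Tests run the DE recovery at 2,000–2,500 genes, topology calibration/power
at 500-node interactomes with 25 seeds and R = 100–200 (40 and 20 seeded
runs respectively), and one full end-to-end run at 20,000 genes with a
4,000-node interactome and R = 100 — sizes at which every stage's behaviour
is already asymptotic while the whole suite stays interactive. Dispersions
are floored at 10⁻⁸; empirical p-values use the add-one rule so finite
ensembles never report zero; BH uses the standard step-up with cap at 1;
KS on integer-valued path lengths evaluates the ECDFs on the exact union
support, never on binned values.
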