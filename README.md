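# degnet

Case/control transcriptome analysis for small bulk RNA-seq cohorts, built
around the question asked of iPSC-derived neuronal cultures from anorexia
nervosa patients versus healthy controls: *which genes change expression,
and do the changed genes sit closer together in the protein-interaction
network than chance allows?*

The package implements the full chain as reusable, tested modules:

1. **Differential expression** (`degnet.de`) — median-of-ratios size factors
   s_j, per-gene NB dispersion α_i (var = μ + αμ²; method-of-moments with a
   fitted mean trend, conservative maximum rule), and a conditional exact
   test: with the group sums K_A + K_B = S fixed, the two-sided p-value is

       p = Σ_{a : Pr(a, S−a) ≤ Pr(k_A, k_B)} Pr(a, S−a) / Σ_a Pr(a, S−a),

   where each group sum is NB with moment-matched parameters. BH step-up
   FDR, DEG selection at fold ≥ 2 with p < 0.05 / 0.01 tiers, and locus-group
   accounting (protein-coding / ncRNA / pseudogene / other).
2. **Clustering & PCA** (`degnet.cluster`) — Euclidean sample distances on
   log2(normalized count + 1), average-linkage trees (Newick export), and
   two-component PCA.
3. **Network topology** (`degnet.network`) — the DEG network: protein-coding
   DEGs plus their first-degree interactors, induced from a reference
   interactome (e.g. a BioGRID export). Density and average shortest path
   length are tested against R random-seed networks: two-sample
   Kolmogorov–Smirnov on the path-length and degree distributions
   (D = sup |ECDF₁ − ECDF₂|), and one-sided add-one empirical p-values
   p = (1 + #extreme)/(R + 1) for the scalars.
4. **Enrichment** (`degnet.enrich`) — one-sided Fisher/hypergeometric
   over-representation with Bonferroni correction.
5. **qPCR** (`degnet.qpcr`) — 2^(−ΔΔCt) relative quantification
   (ΔCt = Ct_target − Ct_reference per sample, ΔΔCt = mean ΔCt difference
   between groups) with Student's t-test and volcano-style calls.
6. **Synthetic data** (`degnet.simulate`) — generators for every input with
   the cohort's statistical structure (4 vs 4 samples, ~25,000 NB genes with
   planted |log2FC| = 2 effects, a heavy-tailed interactome with a planted
   dense module among the DE proteins, triplicate Ct plates), so the whole
   chain is testable offline with known truth.

`degnet.io` reads/writes the external formats (HTSeq-style counts TSV,
sample sheets, edge lists and BioGRID tab exports, GMT, annotation tables,
Ct plates); `degnet.pipeline.run_pipeline` chains everything from one YAML
config, and the `degnet` console script exposes each stage
(`simulate`, `de`, `cluster`, `network`, `enrich`, `qpcr`, `run-all`).

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
10,000-gene cohort (4 AN vs 4 control) and print what they find:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_differential_expression.py
python analysis/03_clustering.py
python analysis/04_network_topology.py
python analysis/05_enrichment.py
python analysis/06_qpcr.py
```

From one run (seed 20260922, as committed in the scripts):

* `02`: *"230 DEGs at the 95% tier shrink to 213 at the 99% tier; locus
  groups sum to the totals and recall of planted effects is 92% at
  empirical FDR 14.1%."* — the two stringency tiers are nested, the
  accounting identities (up + down = Σ locus groups = total) hold, and the
  calls are scored against the planted truth.
* `03`: *"on the DEG panel the 4+4 samples split into pure case/control
  subtrees (True)"* — hierarchical clustering on the called DEGs separates
  the groups exactly.
* `04`: *"93% of coding DEGs map to the interactome; their network (462
  proteins, 1227 interactions) rejects the random-seed null (True): shorter
  paths than random (empirical p=0.00498, KS D=0.39 on the path-length
  distribution)."*
* `05`: *"1 of 21 terms significant after Bonferroni (alpha 0.01); top hit
  T0001 (p_bonf=7.78e-82)"* — exactly the planted pathway.
* `06`: the recovered 2^(−ΔΔCt) folds (3.83, 0.22, 0.23, 0.22 for the four
  planted genes) track the planted values (4.0, 0.25, 0.25, 0.25) and only
  those genes are called at the 2-fold / p < 0.05 criteria.

Tables and trees land under `results/`, bulky intermediates under
`scratch/`.

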