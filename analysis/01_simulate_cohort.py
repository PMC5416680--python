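#!/usr/bin/env python
"""Generate the synthetic study cohort every later step analyses.

Emulates the study design: 4 case vs 4 control bulk RNA-seq neuronal
transcriptomes (negative-binomial counts, ~2% planted DEGs at |log2FC|=2),
two overlapping annotation databanks with four locus groups, a
preferential-attachment interactome whose planted-DE coding proteins carry
extra mutual interactions, a gene-set collection with one pathway planted on
that module, and a triplicate qPCR Ct plate. A 10,000-gene cohort keeps the
full chain fast while preserving every statistical feature of the design.

Writes the bundle to scratch/cohort/ and a summary to results/.
"""

import json
from pathlib import Path

from degnet.simulate import make_paper_scale_fixture, write_fixture_bundle

SEED = 20260922
ROOT = Path(__file__).resolve().parent.parent

bundle = make_paper_scale_fixture(seed=SEED, n_genes=10_000, interactome_nodes=2500)
paths = write_fixture_bundle(bundle, ROOT / "scratch" / "cohort")

summary = {
    "seed": SEED,
    "n_genes": bundle.counts.n_genes,
    "samples": {s: bundle.counts.groups[s] for s in bundle.counts.sample_ids},
    "n_planted_de": bundle.manifest["n_planted_de"],
    "interactome": bundle.manifest["interactome"],
    "n_planted_module_proteins": len(bundle.manifest["planted_module"]),
    "qpcr_true_fold_changes": bundle.manifest["qpcr_true_fold_changes"],
}
out = ROOT / "results" / "01_cohort_summary.json"
out.parent.mkdir(exist_ok=True)
out.write_text(json.dumps(summary, indent=2))

print(f"wrote cohort bundle to {paths['counts']} (+ companions)")
print(json.dumps(summary, indent=2))
print(
    f"\nFinding: {summary['n_planted_de']} of {summary['n_genes']} genes carry a "
    "planted 4-fold expression shift; the interactome's DE coding proteins form "
    "a denser-than-random module — the signals steps 02-06 must recover."
)
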