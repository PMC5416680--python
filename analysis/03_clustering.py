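#!/usr/bin/env python
"""Sample-level structure: Euclidean distances, dendrogram, two-component PCA.

On log-scale normalized counts the case/control effect is a small fraction
of total variance (only ~2% of genes shifted), mirroring how globally
similar the two neuronal populations are; restricting to the called DEGs
separates the groups cleanly.
"""

import json
from pathlib import Path

import pandas as pd

from degnet import cluster
from degnet.io import read_count_matrix

ROOT = Path(__file__).resolve().parent.parent
COHORT = ROOT / "scratch" / "cohort"

cm = read_count_matrix(COHORT / "counts.tsv", COHORT / "samples.tsv")
mat = cluster.transform_counts(cm)

degs = pd.read_csv(ROOT / "results" / "02_degs_p01.tsv", sep="\t")
panels = {"all_genes": mat, "degs_p01": mat.loc[[g for g in degs["gene_id"] if g in mat.index]]}

summary = {}
for name, panel in panels.items():
    dist = cluster.euclidean_distances(panel)
    tree = cluster.hierarchical_cluster(dist)
    (ROOT / "results" / f"03_tree_{name}.nwk").write_text(tree.newick() + "\n")
    cut = tree.cut(2)
    purity = {
        g: len({cut[s] for s in cm.sample_ids if cm.groups[s] == g})
        for g in ("case", "control")
    }
    scores, explained = cluster.pca_two_components(panel)
    scores.assign(group=[cm.groups[s] for s in scores.index]).to_csv(
        ROOT / "results" / f"03_pca_{name}.tsv", sep="\t"
    )
    summary[name] = {
        "two_cluster_cut_pure": purity["case"] == purity["control"] == 1,
        "pc_explained": [round(float(x), 3) for x in explained],
        "leaf_order": tree.leaf_order,
    }

(ROOT / "results" / "03_clustering_summary.json").write_text(json.dumps(summary, indent=2))
print(json.dumps(summary, indent=2))
print(
    "\nFinding: on the DEG panel the 4+4 samples split into pure case/control "
    f"subtrees ({summary['degs_p01']['two_cluster_cut_pure']}); on all genes the "
    "groups are globally similar "
    f"(pure split: {summary['all_genes']['two_cluster_cut_pure']})."
)
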