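"""End-to-end orchestration: simulate -> DE -> cluster -> network -> enrich -> qPCR.

A RunConfig (flat YAML, documented keys, defaults mirroring the study's
thresholds: fold >= 2, p tiers 0.05/0.01, enrichment alpha 0.01) drives the
whole chain and a JSON manifest records seeds, versions and the count at
every filtering step, so the run's accounting is reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import cluster as _cluster
from . import de as _de
from . import enrich as _enrich
from . import network as _network
from . import qpcr as _qpcr
from .io import (
    intersect_annotation_universes,
    read_annotation,
    read_count_matrix,
    read_gmt,
    read_interactome,
    read_qpcr_plate,
)

logger = logging.getLogger("degnet")


@dataclass
class RunConfig:
    """Flat configuration for a full pipeline run.

    Input paths may be None when the stage is skipped (e.g. no qPCR plate).
    Thresholds: fc_min (fold change), p_tiers (DEG significance tiers),
    p_column ('raw' or 'adj'), alpha_enrich (Bonferroni significance),
    replicates R of the topology null, rng_seed for all stochastic steps.
    """

    counts: str = ""
    samples: str = ""
    annotation_a: str = ""
    annotation_b: str = ""
    interactome: str = ""
    interactome_dialect: str = "edge_list"
    gene_sets: str = ""
    qpcr_plate: str = ""
    qpcr_reference: str = "B2M"
    outdir: str = "run_output"
    fc_min: float = 2.0
    p_tiers: tuple[float, ...] = (0.05, 0.01)
    p_max: float = 0.01
    p_column: str = "raw"
    alpha_enrich: float = 0.01
    replicates: int = 1000
    rng_seed: int = 0
    linkage: str = "average"
    aspl_mode: str = "largest_component"
    enrich_universe: str = "pin"  # "pin" or "annotation"

    def __post_init__(self) -> None:
        if self.fc_min <= 0 or self.p_max <= 0 or self.alpha_enrich <= 0:
            raise ValueError("thresholds must be positive")
        if any(p <= 0 for p in self.p_tiers):
            raise ValueError("p tiers must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "p_tiers" in raw:
            raw["p_tiers"] = tuple(raw["p_tiers"])
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; returns (and writes) the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "rng_seed": config.rng_seed, "stages": {}}

    def fail(stage: str, err: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    # --- differential expression -------------------------------------------
    try:
        cm = read_count_matrix(config.counts, config.samples)
        ann_a = read_annotation(config.annotation_a)
        ann_b = read_annotation(config.annotation_b)
        annotation = intersect_annotation_universes(ann_a, ann_b)
        size_factors = _de.estimate_size_factors(cm)
        results = _de.de_test(cm, size_factors)
        results.to_csv(out / "de_results.tsv", sep="\t", index=False)
        tiers = {}
        degs_by_tier = {}
        for p_max in config.p_tiers:
            degs = _de.select_degs(results, config.fc_min, p_max, config.p_column)
            degs_by_tier[p_max] = degs
            tiers[str(p_max)] = {
                "n_degs": len(degs),
                **_de.partition_locus_groups(degs, annotation),
            }
        degs = degs_by_tier[min(config.p_tiers)]  # strictest tier feeds the network
        degs.table.to_csv(out / "degs.tsv", sep="\t", index=False)
        manifest["stages"]["de"] = {
            "n_genes_tested": int(len(results)),
            "n_annotated_common": len(annotation),
            "size_factors": [float(s) for s in size_factors],
            "tiers": tiers,
            "fc_min": config.fc_min,
            "p_column": config.p_column,
        }
    except Exception as e:  # noqa: BLE001
        fail("differential_expression", e)

    # --- clustering / PCA ---------------------------------------------------
    try:
        mat = _cluster.transform_counts(cm, size_factors)
        dist = _cluster.euclidean_distances(mat)
        dist.to_csv(out / "sample_distances.tsv", sep="\t")
        tree = _cluster.hierarchical_cluster(dist, config.linkage)
        (out / "sample_tree.nwk").write_text(tree.newick() + "\n", encoding="utf-8")
        pca, explained = _cluster.pca_two_components(mat)
        pca.assign(group=[cm.groups[s] for s in pca.index]).to_csv(out / "pca.tsv", sep="\t")
        manifest["stages"]["clustering"] = {
            "leaf_order": tree.leaf_order,
            "pc_explained": [float(x) for x in explained],
        }
    except Exception as e:  # noqa: BLE001
        fail("clustering", e)

    # --- network topology ---------------------------------------------------
    try:
        interactome = read_interactome(config.interactome, config.interactome_dialect)
        lg = annotation.locus_group_of()
        sym = annotation.symbol_of()
        coding_degs = [g for g in degs.gene_ids if lg.get(g) == "protein_coding"]
        seed_symbols = [sym[g] for g in coding_degs if g in sym]
        n_mapped, n_total, percent = _network.mapped_seed_fraction(seed_symbols, interactome)
        pin = _network.build_pin(seed_symbols, interactome)
        comparison = _network.compare_topology(
            pin, interactome, config.replicates, config.rng_seed, config.aspl_mode
        )
        with open(out / "topology_comparison.json", "w", encoding="utf-8") as fh:
            json.dump(comparison.to_dict(), fh, indent=2)
        np.savetxt(
            out / "null_replicates.tsv",
            np.column_stack([comparison.null_densities, comparison.null_aspl]),
            delimiter="\t", header="density\taspl", comments="",
        )
        manifest["stages"]["network"] = {
            "n_seed_candidates": n_total,
            "n_seeds_mapped": n_mapped,
            "mapped_percent": percent,
            "pin_nodes": comparison.observed.n_nodes,
            "pin_edges": comparison.observed.n_edges,
            **{k: v for k, v in comparison.to_dict().items() if k.startswith(("ks_", "empirical_"))},
        }
    except Exception as e:  # noqa: BLE001
        fail("network_topology", e)

    # --- enrichment ---------------------------------------------------------
    try:
        gmt = read_gmt(config.gene_sets)
        if config.enrich_universe == "pin":
            universe = set(interactome.nodes)
            query = set(pin.graph.nodes)
        else:
            universe = set(sym.values())
            query = set(seed_symbols)
        enr = _enrich.bonferroni(
            _enrich.fisher_enrichment(query, gmt, universe), config.alpha_enrich
        )
        table = _enrich.enrichment_table(enr)
        table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        manifest["stages"]["enrichment"] = {
            "universe": config.enrich_universe,
            "n_terms_tested": int(len(table)),
            "n_significant": int(table["significant"].sum()) if not table.empty else 0,
        }
    except Exception as e:  # noqa: BLE001
        fail("enrichment", e)

    # --- qPCR ---------------------------------------------------------------
    if config.qpcr_plate:
        try:
            plate = read_qpcr_plate(config.qpcr_plate)
            rel = _qpcr.relative_expression(plate, config.qpcr_reference,
                                            fc_min=config.fc_min, p_max=max(config.p_tiers))
            rel.to_csv(out / "qpcr_relative_expression.tsv", sep="\t", index=False)
            manifest["stages"]["qpcr"] = {
                "reference": config.qpcr_reference.upper(),
                "n_genes": int(len(rel)),
                "n_called": int((rel["call"] != "ns").sum()),
            }
        except Exception as e:  # noqa: BLE001
            fail("qpcr", e)

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline finished; outputs in %s", out)
    return manifest
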