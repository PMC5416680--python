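"""Synthetic inputs with the statistical structure the pipeline assumes.

The generators emulate the study design the analysis targets: a small
case/control cohort (4 anorexia-nervosa vs 4 control neuronal cultures) of
bulk RNA-seq counts with ~25,000 genes, a reference interactome with a
heavy-tailed degree distribution and an optionally planted dense module among
the differentially expressed seed genes, and qPCR Ct plates with a reference
gene. Counts are negative binomial, parameterized by mean mu and dispersion
alpha with var = mu + alpha*mu^2, matching the differential-expression
model so that parameter-recovery tests are well posed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import (
    AnnotationTable,
    CountMatrix,
    GeneSetCollection,
    LOCUS_GROUPS,
    QPCRPlate,
    make_gene_set,
    write_annotation,
    write_count_matrix,
    write_gmt,
    write_interactome,
    write_qpcr_plate,
)

# Study conditions: 4v4 cohort, ~25k genes, ~2% planted DEGs at |log2FC|=2,
# NB dispersion 0.1, median ~150 counts/gene (~30M counted reads/sample).
DEFAULT_N_GENES = 25_000
DEFAULT_BASELINE = (5.0, 1.3)
DEFAULT_DISPERSION = 0.1
DEFAULT_DE_FRACTION = 0.02
DEFAULT_LOG2FC = 2.0
DEFAULT_LIBSIZE_SD = 0.2


@dataclass
class SimulationDesign:
    """Parameters of the synthetic RNA-seq cohort.

    baseline_log_mean_dist is (mu, sigma) of the natural-log-normal
    distribution of per-gene base expression q_i. dispersion is the NB
    overdispersion alpha (var = mu + alpha*mu^2), either a scalar or a
    per-gene array. library_size_factors, if None, are drawn lognormal with
    sd DEFAULT_LIBSIZE_SD.
    """

    n_genes: int = DEFAULT_N_GENES
    n_case: int = 4
    n_control: int = 4
    baseline_log_mean_dist: tuple[float, float] = DEFAULT_BASELINE
    dispersion: float | np.ndarray = DEFAULT_DISPERSION
    de_fraction: float = DEFAULT_DE_FRACTION
    log2fc_effect: float = DEFAULT_LOG2FC
    library_size_factors: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("need at least one sample per group")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if np.any(np.asarray(self.dispersion) < 0):
            raise ValueError("dispersion must be >= 0")


@dataclass
class TruthTable:
    """Ground truth of a simulation, for parameter-recovery checks."""

    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    # per-gene columns: gene_id, symbol, is_de, true_log2fc, locus_group
    module_nodes: tuple[str, ...] = ()  # planted interactome module members
    qpcr: pd.DataFrame = field(default_factory=pd.DataFrame)
    # per-qPCR-gene columns: gene, true_fold_change

    @property
    def de_gene_ids(self) -> list[str]:
        if self.genes.empty:
            return []
        return list(self.genes.loc[self.genes["is_de"], "gene_id"])


def _gene_ids(n: int) -> list[str]:
    return [f"ENSG{i:08d}" for i in range(n)]


def _symbols(n: int) -> list[str]:
    return [f"GENE{i}" for i in range(n)]


def simulate_counts(design: SimulationDesign) -> tuple[CountMatrix, TruthTable]:
    """Draw an NB count matrix with planted differential expression.

    Counts for gene i, sample j are NB with mean s_j * q_i * 2^(d_i) for case
    samples (d_i = +/- log2fc_effect for DE genes, 0 otherwise) and
    s_j * q_i for controls. DE genes split ~50/50 up/down. Deterministic for
    a fixed design seed.
    """
    rng = np.random.default_rng(design.seed)
    g, nc, nk = design.n_genes, design.n_case, design.n_control
    mu0, sigma0 = design.baseline_log_mean_dist
    q = rng.lognormal(mean=mu0, sigma=sigma0, size=g)
    alpha = np.broadcast_to(np.asarray(design.dispersion, dtype=float), (g,)).copy()

    n_de = int(round(design.de_fraction * g))
    de_idx = rng.choice(g, size=n_de, replace=False)
    signs = np.ones(n_de)
    signs[: n_de // 2] = -1.0
    rng.shuffle(signs)
    true_log2fc = np.zeros(g)
    true_log2fc[de_idx] = signs * design.log2fc_effect

    if design.library_size_factors is None:
        s = rng.lognormal(mean=0.0, sigma=DEFAULT_LIBSIZE_SD, size=nc + nk)
        s /= np.exp(np.mean(np.log(s)))
    else:
        s = np.asarray(design.library_size_factors, dtype=float)
        if s.shape != (nc + nk,) or np.any(s <= 0):
            raise ValueError("library_size_factors must be positive, one per sample")

    sample_ids = [f"AN_{i+1}" for i in range(nc)] + [f"CTL_{i+1}" for i in range(nk)]
    groups = {sid: ("case" if sid.startswith("AN") else "control") for sid in sample_ids}
    is_case = np.array([groups[sid] == "case" for sid in sample_ids])

    mu = q[:, None] * s[None, :] * np.where(is_case[None, :], 2.0 ** true_log2fc[:, None], 1.0)
    counts = _nb_draw(rng, mu, alpha[:, None])

    gene_ids = _gene_ids(g)
    truth = TruthTable(
        genes=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "symbol": _symbols(g),
                "is_de": true_log2fc != 0.0,
                "true_log2fc": true_log2fc,
                "locus_group": "protein_coding",
            }
        )
    )
    cm = CountMatrix(gene_ids=gene_ids, sample_ids=sample_ids, counts=counts, groups=groups)
    return cm, truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Gamma-Poisson sample of NB(mean=mu, var=mu+alpha*mu^2); Poisson as alpha->0."""
    alpha = np.broadcast_to(alpha, mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    poi = alpha < 1e-12
    if np.any(poi):
        out[poi] = rng.poisson(mu[poi])
    if np.any(~poi):
        a = alpha[~poi]
        lam = rng.gamma(shape=1.0 / a, scale=mu[~poi] * a)
        out[~poi] = rng.poisson(lam)
    return out


def simulate_interactome(
    n_nodes: int,
    attach_m: int = 2,
    planted_module: tuple[list[str], float] | None = None,
    seed: int = 0,
    node_names: list[str] | None = None,
) -> tuple[nx.Graph, TruthTable]:
    """Preferential-attachment interactome with an optional planted dense module.

    The background is a Barabasi-Albert graph (heavy-tailed degrees, as in
    protein-interaction databases). If planted_module = (members, p_extra) is
    given, every pair of member nodes is additionally connected with
    probability p_extra; the graph stays simple.
    """
    if not n_nodes > attach_m >= 1:
        raise ValueError("need n_nodes > attach_m >= 1")
    rng = np.random.default_rng(seed)
    graph = nx.barabasi_albert_graph(n_nodes, attach_m, seed=int(rng.integers(2**31)))
    names = node_names if node_names is not None else _symbols(n_nodes)
    if len(names) != n_nodes:
        raise ValueError("node_names length must equal n_nodes")
    names = [str(n).upper() for n in names]
    graph = nx.relabel_nodes(graph, dict(enumerate(names)))

    module: tuple[str, ...] = ()
    if planted_module is not None:
        members, p_extra = planted_module
        members = [str(m).upper() for m in members]
        missing = sorted(set(members) - set(graph.nodes))
        if missing:
            raise ValueError(f"planted module members outside node set: {missing}")
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if rng.random() < p_extra and not graph.has_edge(a, b):
                    graph.add_edge(a, b)
        module = tuple(members)
    return graph, TruthTable(module_nodes=module)


def simulate_qpcr(
    n_case: int,
    n_control: int,
    true_fold_changes: dict[str, float],
    ref_gene: str = "B2M",
    ct_noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[QPCRPlate, TruthTable]:
    """Ct plate for the 2^-ddCt method: Ct = baseline - log2(rel. expression) + noise.

    true_fold_changes maps gene -> case/control expression ratio; the
    reference gene is forced to fold 1 (that is the method's assumption).
    Sample-level Ct offsets (loading differences) are included; they cancel in
    the delta-Ct normalization. Technical replicates are emitted.
    """
    ref_gene = ref_gene.upper()
    fold = {g.upper(): float(f) for g, f in true_fold_changes.items()}
    if any(f <= 0 for f in fold.values()):
        raise ValueError("fold changes must be positive")
    fold[ref_gene] = 1.0
    rng = np.random.default_rng(seed)
    genes = sorted(fold)
    base_ct = {g: 20.0 + 8.0 * rng.random() for g in genes}

    rows = []
    sample_ids = [(f"AN_{i+1}", "case") for i in range(n_case)] + [
        (f"CTL_{i+1}", "control") for i in range(n_control)
    ]
    for sid, group in sample_ids:
        shift = rng.normal(0.0, 0.3) if ct_noise_sd > 0 else 0.0
        for g in genes:
            rel = fold[g] if group == "case" else 1.0
            for rep in range(n_replicates):
                ct = base_ct[g] + shift - np.log2(rel) + rng.normal(0.0, ct_noise_sd)
                rows.append((sid, group, g, rep + 1, ct, g == ref_gene))
    plate = QPCRPlate(
        pd.DataFrame(rows, columns=["sample_id", "group", "gene", "replicate", "ct", "is_reference"])
    )
    truth = TruthTable(
        qpcr=pd.DataFrame({"gene": genes, "true_fold_change": [fold[g] for g in genes]})
    )
    return plate, truth


# ---------------------------------------------------------------------------
# Full study-scale fixture bundle
# ---------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    counts: CountMatrix
    truth: TruthTable
    annotation_a: AnnotationTable
    annotation_b: AnnotationTable
    interactome: nx.Graph
    gene_sets: GeneSetCollection
    qpcr_plate: QPCRPlate
    qpcr_truth: TruthTable
    manifest: dict


def make_paper_scale_fixture(
    seed: int = 0,
    n_genes: int = DEFAULT_N_GENES,
    interactome_nodes: int = 4000,
    module_edge_prob: float = 0.1,
) -> FixtureBundle:
    """One coherent study-scale input bundle: counts, annotation, interactome,
    gene sets with one planted-enriched term, and a qPCR plate.

    Locus groups follow roughly the genome-wide biotype mix (~55%
    protein-coding, 25% ncRNA, 15% pseudogene, 5% other). The interactome
    covers a subset of the protein-coding symbols, always including the
    planted-DE coding genes; each pair of those DE proteins gets an extra
    interaction with probability module_edge_prob, encoding the alternative
    hypothesis the topology test is designed to detect — differentially
    expressed proteins more interconnected than expected by chance. The GMT
    contains one term drawn from the planted module plus random decoy terms.
    """
    rng = np.random.default_rng(seed)
    design = SimulationDesign(n_genes=n_genes, seed=int(rng.integers(2**31)))
    counts, truth = simulate_counts(design)

    # annotation: two overlapping "databanks"; b drops a random 5% and
    # carries no extra genes, so the intersection is b's membership.
    locus = rng.choice(LOCUS_GROUPS, size=n_genes, p=[0.55, 0.25, 0.15, 0.05])
    truth.genes["locus_group"] = locus
    ann_a = AnnotationTable(
        pd.DataFrame(
            {"gene_id": truth.genes["gene_id"], "symbol": truth.genes["symbol"], "locus_group": locus}
        )
    )
    keep = rng.random(n_genes) > 0.05
    ann_b = AnnotationTable(ann_a.records[keep])

    # interactome over protein-coding symbols, planted module = DE coding genes
    coding = truth.genes[truth.genes["locus_group"] == "protein_coding"]
    pool = list(coding["symbol"])
    n_nodes = min(interactome_nodes, len(pool))
    de_coding = list(coding.loc[coding["is_de"], "symbol"])
    module_members = de_coding[: max(2, n_nodes // 4)]  # cap so the module cannot swamp a tiny graph
    others = [s for s in pool if s not in set(module_members)]
    rng.shuffle(others)
    node_names = module_members + others[: n_nodes - len(module_members)]
    rng.shuffle(node_names)
    interactome, net_truth = simulate_interactome(
        n_nodes=n_nodes,
        attach_m=2,
        planted_module=(module_members, module_edge_prob),
        seed=int(rng.integers(2**31)),
        node_names=node_names,
    )
    truth.module_nodes = net_truth.module_nodes

    # gene sets: one term enriched in the planted module, 20 decoys
    sets = [make_gene_set("T0001", "planted_module_pathway", module_members)]
    node_list = list(interactome.nodes)
    for t in range(2, 22):
        size = int(rng.integers(10, 40))
        sets.append(
            make_gene_set(f"T{t:04d}", f"decoy_pathway_{t}", rng.choice(node_list, size=size, replace=False))
        )
    gmt = GeneSetCollection(sets)

    # qPCR plate: a handful of DE genes at their planted folds + flat genes
    qpcr_genes = {}
    for sym in module_members[:4]:
        lfc = float(truth.genes.loc[truth.genes["symbol"] == sym, "true_log2fc"].iloc[0])
        qpcr_genes[sym] = 2.0 ** lfc
    for sym in ["FLAT1", "FLAT2"]:
        qpcr_genes[sym] = 1.0
    plate, qpcr_truth = simulate_qpcr(
        n_case=design.n_case,
        n_control=design.n_control,
        true_fold_changes=qpcr_genes,
        ref_gene="B2M",
        ct_noise_sd=0.15,
        seed=int(rng.integers(2**31)),
    )

    manifest = {
        "seed": seed,
        "design": {
            "n_genes": design.n_genes,
            "n_case": design.n_case,
            "n_control": design.n_control,
            "baseline_log_mean_dist": list(design.baseline_log_mean_dist),
            "dispersion": float(np.mean(design.dispersion)),
            "de_fraction": design.de_fraction,
            "log2fc_effect": design.log2fc_effect,
        },
        "n_planted_de": int(truth.genes["is_de"].sum()),
        "planted_de_fraction": float(truth.genes["is_de"].mean()),
        "interactome": {"n_nodes": interactome.number_of_nodes(), "n_edges": interactome.number_of_edges()},
        "planted_module": list(truth.module_nodes),
        "planted_enriched_term": "T0001",
        "qpcr_true_fold_changes": {g: float(f) for g, f in qpcr_genes.items()},
    }
    return FixtureBundle(counts, truth, ann_a, ann_b, interactome, gmt, plate, qpcr_truth, manifest)


def write_fixture_bundle(bundle: FixtureBundle, outdir: str | Path) -> dict[str, str]:
    """Write every bundle component to a directory; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": str(outdir / "counts.tsv"),
        "samples": str(outdir / "samples.tsv"),
        "annotation_a": str(outdir / "annotation_a.tsv"),
        "annotation_b": str(outdir / "annotation_b.tsv"),
        "interactome": str(outdir / "interactome.tsv"),
        "gene_sets": str(outdir / "gene_sets.gmt"),
        "qpcr_plate": str(outdir / "qpcr_plate.tsv"),
        "truth_genes": str(outdir / "truth_genes.tsv"),
        "manifest": str(outdir / "manifest.json"),
    }
    write_count_matrix(bundle.counts, paths["counts"], paths["samples"])
    write_annotation(bundle.annotation_a, paths["annotation_a"])
    write_annotation(bundle.annotation_b, paths["annotation_b"])
    write_interactome(bundle.interactome, paths["interactome"])
    write_gmt(bundle.gene_sets, paths["gene_sets"])
    write_qpcr_plate(bundle.qpcr_plate, paths["qpcr_plate"])
    bundle.truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
    return paths
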