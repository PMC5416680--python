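"""DEG-seeded protein-interaction networks and their topology test.

The observed network (PIN) is the subgraph induced on the DEG seed proteins
plus their first-degree interactors in a reference interactome. Its
structural properties — density and average shortest path length (ASPL) —
are compared against a null ensemble of PINs seeded by the same number of
proteins drawn uniformly at random from the interactome. Two surfaces are
reported, because a "distribution of structural properties" admits both
readings:

* a two-sample Kolmogorov-Smirnov test on the all-pairs finite
  shortest-path-length multiset and on the degree multiset, observed versus
  the pooled null ensemble (this is the KS surface that yields printed D
  statistics), and
* one-sided empirical (add-one) p-values for the scalar density and ASPL
  against the R-replicate null.

A seed set sitting in a denser-than-random neighbourhood shows up as excess
density (null >= observed rarely) and depressed ASPL (null <= observed
rarely), plus a right-shifted degree distribution / left-shifted path-length
distribution in the KS comparison.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import kolmogorov

logger = logging.getLogger("degnet")


@dataclass
class PIN:
    """Seed-expansion interaction subnetwork.

    Nodes are the mapped seeds plus their direct neighbours; edges are all
    interactome edges between those nodes (induced subgraph), so every
    non-seed node is adjacent to at least one seed.
    """

    graph: nx.Graph
    seeds: frozenset[str]
    n_seeds_requested: int = 0
    n_seeds_unmapped: int = 0


def build_pin(seeds, interactome: nx.Graph) -> PIN:
    """Seeds + first-degree interactors, with the induced edge set."""
    requested = [str(s).upper() for s in seeds]
    mapped = [s for s in requested if s in interactome]
    unmapped = len(requested) - len(mapped)
    if not mapped:
        raise ValueError(
            f"none of the {len(requested)} seed symbols map to the interactome"
        )
    if unmapped:
        logger.info("build_pin: %d of %d seeds not in interactome (dropped)", unmapped, len(requested))
    nodes = set(mapped)
    for s in mapped:
        nodes.update(interactome.neighbors(s))
    graph = nx.Graph(interactome.subgraph(nodes))
    return PIN(graph=graph, seeds=frozenset(mapped),
               n_seeds_requested=len(requested), n_seeds_unmapped=unmapped)


def mapped_seed_fraction(seeds, interactome: nx.Graph) -> tuple[int, int, int]:
    """(n_mapped, n_total, percent mapped) of seed symbols found in the interactome.

    Percent is rounded to the nearest integer (banker's rounding at .5, as
    Python's round).
    """
    requested = {str(s).upper() for s in seeds}
    if not requested:
        raise ValueError("no seeds supplied")
    n_mapped = sum(1 for s in requested if s in interactome)
    n_total = len(requested)
    return n_mapped, n_total, round(100 * n_mapped / n_total)


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    density: float
    aspl: float  # over the largest connected component (or all finite pairs)
    n_components: int
    path_lengths: Counter = field(default_factory=Counter)  # finite pairwise distances
    degrees: Counter = field(default_factory=Counter)


def topology_summary(pin: PIN | nx.Graph, aspl_mode: str = "largest_component") -> TopologySummary:
    """Density, ASPL and the path-length / degree multisets of a network.

    density = 2E / (N(N-1)); ASPL averages graph distance over unordered
    reachable pairs, restricted to the largest connected component by
    default (aspl_mode="all_finite" averages every finite pair instead).
    Path-length and degree multisets are returned as Counters.
    """
    graph = pin.graph if isinstance(pin, PIN) else pin
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("topology summary needs at least 2 nodes")
    e = graph.number_of_edges()
    density = 2.0 * e / (n * (n - 1))
    components = list(nx.connected_components(graph))
    largest = max(components, key=len)

    path_lengths: Counter = Counter()
    lcc_sum, lcc_pairs = 0, 0
    for source, dists in nx.all_pairs_shortest_path_length(graph):
        in_lcc = source in largest
        for target, d in dists.items():
            if d > 0 and source < target:  # unordered pairs once
                path_lengths[d] += 1
                if in_lcc:
                    lcc_sum += d
                    lcc_pairs += 1
    if aspl_mode == "largest_component":
        aspl = lcc_sum / lcc_pairs if lcc_pairs else float("nan")
    elif aspl_mode == "all_finite":
        tot = sum(d * c for d, c in path_lengths.items())
        npairs = sum(path_lengths.values())
        aspl = tot / npairs if npairs else float("nan")
    else:
        raise ValueError(f"unknown aspl_mode {aspl_mode!r}")
    degrees = Counter(d for _, d in graph.degree())
    return TopologySummary(
        n_nodes=n, n_edges=e, density=density, aspl=aspl,
        n_components=len(components), path_lengths=path_lengths, degrees=degrees,
    )


def sample_random_pins(
    interactome: nx.Graph, n_seeds: int, replicates: int, rng_seed: int = 0
) -> list[PIN]:
    """Null ensemble: PINs seeded by uniform draws from the interactome nodes."""
    nodes = sorted(interactome.nodes)
    if n_seeds > len(nodes):
        raise ValueError(f"n_seeds={n_seeds} exceeds interactome size {len(nodes)}")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(rng_seed)
    out = []
    for _ in range(replicates):
        seeds = rng.choice(nodes, size=n_seeds, replace=False)
        out.append(build_pin(seeds, interactome))
    return out


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov
# ---------------------------------------------------------------------------

def _ecdf_from_counts(counts: Counter, support: np.ndarray) -> np.ndarray:
    total = sum(counts.values())
    cum = np.cumsum([counts.get(v, 0) for v in support])
    return cum / total


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample KS: D = sup |ECDF_x - ECDF_y|, asymptotic p.

    x and y are either value arrays or Counters (value -> multiplicity), so
    the statistic can be computed exactly on very large multisets such as
    pooled path-length distributions. p uses the asymptotic Kolmogorov
    distribution with effective size nm/(n+m).
    """
    cx = x if isinstance(x, Counter) else Counter(np.asarray(list(x)).tolist())
    cy = y if isinstance(y, Counter) else Counter(np.asarray(list(y)).tolist())
    n, m = sum(cx.values()), sum(cy.values())
    if n == 0 or m == 0:
        raise ValueError("KS test needs non-empty samples")
    support = np.array(sorted(set(cx) | set(cy)), dtype=float)
    d = float(np.max(np.abs(
        _ecdf_from_counts(cx, support) - _ecdf_from_counts(cy, support)
    )))
    en = np.sqrt(n * m / (n + m))
    p = float(min(1.0, kolmogorov(en * d)))
    return d, p


# ---------------------------------------------------------------------------
# Observed-vs-null comparison
# ---------------------------------------------------------------------------

@dataclass
class TopologyComparison:
    observed: TopologySummary
    null_densities: np.ndarray
    null_aspl: np.ndarray
    ks_paths: tuple[float, float]
    ks_degree: tuple[float, float]
    empirical_p_density: float
    empirical_p_aspl: float
    replicates: int
    rng_seed: int

    def rejects(self, alpha: float = 0.05) -> bool:
        """Overall verdict: is the seed neighbourhood non-random?

        Rejects if either scalar property (density high, ASPL low) is
        extreme at a Bonferroni-split level alpha/2, so the two-property
        test keeps its family-wise level at alpha.
        """
        return (self.empirical_p_density <= alpha / 2) or (self.empirical_p_aspl <= alpha / 2)

    def to_dict(self) -> dict:
        return {
            "observed": {
                "n_nodes": self.observed.n_nodes,
                "n_edges": self.observed.n_edges,
                "density": self.observed.density,
                "aspl": self.observed.aspl,
                "n_components": self.observed.n_components,
            },
            "null_mean_density": float(np.mean(self.null_densities)),
            "null_mean_aspl": float(np.nanmean(self.null_aspl)),
            "ks_paths_D": self.ks_paths[0], "ks_paths_p": self.ks_paths[1],
            "ks_degree_D": self.ks_degree[0], "ks_degree_p": self.ks_degree[1],
            "empirical_p_density": self.empirical_p_density,
            "empirical_p_aspl": self.empirical_p_aspl,
            "replicates": self.replicates, "rng_seed": self.rng_seed,
        }


def compare_topology(
    pin: PIN,
    interactome: nx.Graph,
    replicates: int = 1000,
    rng_seed: int = 0,
    aspl_mode: str = "largest_component",
) -> TopologyComparison:
    """Observed PIN vs the random-seed null ensemble.

    The null draws |mapped seeds| random seeds per replicate. KS compares
    the observed path-length and degree multisets against the pooled null
    multisets. Empirical add-one p-values: density counts null >= observed
    ("denser than random"), ASPL counts null <= observed ("shorter paths
    than random"); p = (1 + #extreme) / (R + 1).
    """
    obs = topology_summary(pin, aspl_mode=aspl_mode)
    ensemble = sample_random_pins(interactome, len(pin.seeds), replicates, rng_seed)
    null_density = np.empty(replicates)
    null_aspl = np.empty(replicates)
    pooled_paths: Counter = Counter()
    pooled_degrees: Counter = Counter()
    for i, rp in enumerate(ensemble):
        summ = topology_summary(rp, aspl_mode=aspl_mode)
        null_density[i] = summ.density
        null_aspl[i] = summ.aspl
        pooled_paths.update(summ.path_lengths)
        pooled_degrees.update(summ.degrees)
    ks_paths = ks_two_sample(obs.path_lengths, pooled_paths)
    ks_degree = ks_two_sample(obs.degrees, pooled_degrees)
    p_density = (1 + int(np.sum(null_density >= obs.density))) / (replicates + 1)
    finite = np.isfinite(null_aspl)
    p_aspl = (1 + int(np.sum(null_aspl[finite] <= obs.aspl))) / (replicates + 1)
    return TopologyComparison(
        observed=obs,
        null_densities=null_density,
        null_aspl=null_aspl,
        ks_paths=ks_paths,
        ks_degree=ks_degree,
        empirical_p_density=p_density,
        empirical_p_aspl=p_aspl,
        replicates=replicates,
        rng_seed=rng_seed,
    )
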