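"""Gene-set over-representation analysis (Fisher exact / hypergeometric).

For a query list Q inside a universe U, the p-value of a term T is the
upper hypergeometric tail

    P(X >= k),  X ~ Hypergeom(N=|U|, K=|T ∩ U|, n=|Q|),  k = |Q ∩ T|,

i.e. a one-sided Fisher exact test for over-representation. Bonferroni
multiplies by the number of terms actually tested. Terms with no overlap
with the universe are skipped (and logged): they carry no testable signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .io import GeneSetCollection

logger = logging.getLogger("degnet")


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    n_query_in_term: int
    n_query: int
    n_term_in_universe: int
    n_universe: int
    p_fisher: float
    p_bonferroni: float = 1.0
    significant: bool = False


def fisher_enrichment(query, sets: GeneSetCollection, universe) -> list[EnrichmentResult]:
    """One-sided over-representation p per term; query and universe are symbols.

    Query entries are uppercased and deduplicated; query genes outside the
    universe are dropped with a warning (the test is conditional on the
    universe). Returns one result per term with universe overlap, in
    collection order.
    """
    uni = {str(g).upper() for g in universe}
    if not uni:
        raise ValueError("empty universe")
    q_all = {str(g).upper() for g in query}
    q = q_all & uni
    if len(q) < len(q_all):
        logger.warning("%d query genes outside the universe dropped", len(q_all) - len(q))
    results = []
    n_skipped = 0
    for s in sets:
        members = set(s.members) & uni
        if not members:
            n_skipped += 1
            continue
        k = len(q & members)
        p = float(hypergeom.sf(k - 1, len(uni), len(members), len(q)))
        results.append(
            EnrichmentResult(
                term_id=s.term_id,
                term_name=s.term_name,
                n_query_in_term=k,
                n_query=len(q),
                n_term_in_universe=len(members),
                n_universe=len(uni),
                p_fisher=min(1.0, p),
            )
        )
    if n_skipped:
        logger.info("%d terms with zero universe overlap skipped", n_skipped)
    return results


def bonferroni(results: list[EnrichmentResult], alpha: float = 0.01) -> list[EnrichmentResult]:
    """p_bonferroni = min(1, m*p) over the m tested terms; flag at alpha."""
    m = len(results)
    if m < 1:
        raise ValueError("no tested terms to correct")
    for r in results:
        r.p_bonferroni = min(1.0, m * r.p_fisher)
        r.significant = r.p_bonferroni < alpha
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in results])
    if not df.empty:
        df = df.sort_values("p_fisher", kind="mergesort").reset_index(drop=True)
    return df
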