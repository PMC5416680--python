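"""Negative-binomial differential expression for small case/control cohorts.

The procedure follows the classic count-based exact-test formulation:

1. *Normalization* by median-of-ratios size factors: for sample j,
   s_j = median_i ( k_ij / geomean_j' k_ij' ) over genes with all-positive
   counts, rescaled so the size factors have geometric mean 1.
2. *Dispersion* alpha_i of the NB model var = mu + alpha*mu^2, estimated per
   gene by method of moments on normalized counts (variance pooled within
   groups), then floored by a fitted mean-dispersion trend
   alpha(q) = a0 + a1/q; the per-gene value is the maximum of the gene
   estimate and the trend. The maximum rule is deliberately conservative:
   with 4 replicates per group a per-gene moment estimate alone is noisy
   enough to inflate false positives.
3. *Exact test* conditioned on the total: with the two group sums
   K_A + K_B = S fixed, the two-sided p-value sums the probabilities of all
   partitions (a, S-a) no more likely than the observed one, normalized by
   the total probability of all partitions. Group sums are modelled as NB
   with moment-matched parameters built from the size factors and the pooled
   mean.
4. *Multiplicity*: Benjamini-Hochberg step-up FDR, plus threshold-based DEG
   selection at a fold-change / p cutoff, on raw or adjusted p per config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AnnotationTable, CountMatrix, LOCUS_GROUPS

logger = logging.getLogger("degnet")

ALPHA_FLOOR = 1e-8

# ---------------------------------------------------------------------------
# Size factors
# ---------------------------------------------------------------------------

def estimate_size_factors(counts: CountMatrix | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Only genes with strictly positive counts in every sample enter the
    median (the geometric mean reference is undefined otherwise). Raises if
    no such gene exists.
    """
    k = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    k = np.asarray(k, dtype=float)
    all_pos = np.all(k > 0, axis=1)
    if not np.any(all_pos):
        raise ValueError(
            "no gene has positive counts in all samples; filter the matrix "
            "or supply size factors explicitly"
        )
    kp = k[all_pos]
    log_geomean = np.mean(np.log(kp), axis=1)
    ratios = np.log(kp) - log_geomean[:, None]
    s = np.exp(np.median(ratios, axis=0))
    return s / np.exp(np.mean(np.log(s)))


def normalized_counts(cm: CountMatrix, size_factors: np.ndarray | None = None) -> np.ndarray:
    if size_factors is None:
        size_factors = estimate_size_factors(cm)
    return cm.counts / np.asarray(size_factors)[None, :]


# ---------------------------------------------------------------------------
# Dispersion
# ---------------------------------------------------------------------------

def estimate_dispersions(
    cm: CountMatrix,
    size_factors: np.ndarray,
    alpha_floor: float = ALPHA_FLOOR,
    return_parts: bool = False,
):
    """Per-gene NB dispersions: max(method-of-moments estimate, mean trend).

    The moment estimator uses the within-group pooled sample variance v_i of
    normalized counts and corrects for the shot-noise term:
    alpha_i = (v_i - q_i * mean_j(1/s_j)) / q_i^2. The trend
    alpha(q) = a0 + a1/q is fitted by least squares over genes with a
    positive raw estimate (the gamma-family parametric trend shape).
    """
    s = np.asarray(size_factors, dtype=float)
    for g in ("case", "control"):
        if len(cm.samples_in_group(g)) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates; dispersion is not estimable")
    z = cm.counts / s[None, :]
    q = z.mean(axis=1)
    case = cm.group_mask("case")
    dof, ssq = 0, np.zeros(cm.n_genes)
    for mask in (case, ~case):
        zg = z[:, mask]
        ssq += np.sum((zg - zg.mean(axis=1, keepdims=True)) ** 2, axis=1)
        dof += mask.sum() - 1
    v = ssq / dof
    xi = np.mean(1.0 / s)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = np.where(q > 0, (v - q * xi) / q**2, 0.0)

    fit_mask = (alpha_raw > 0) & (q > 0)
    if fit_mask.sum() >= 10:
        x = np.column_stack([np.ones(fit_mask.sum()), 1.0 / q[fit_mask]])
        coef, *_ = np.linalg.lstsq(x, alpha_raw[fit_mask], rcond=None)
        a0, a1 = np.maximum(coef, 0.0)
    else:  # too few informative genes for a trend; flat fallback
        a0 = float(np.median(alpha_raw[fit_mask])) if fit_mask.any() else 0.0
        a1 = 0.0
    with np.errstate(divide="ignore"):
        trend = a0 + np.where(q > 0, a1 / q, 0.0)
    alpha = np.maximum(np.maximum(alpha_raw, trend), alpha_floor)
    logger.info(
        "dispersion trend alpha(q) = %.4g + %.4g/q; median per-gene alpha %.4g",
        a0, a1, float(np.median(alpha)),
    )
    if return_parts:
        return alpha, alpha_raw, (a0, a1)
    return alpha


# ---------------------------------------------------------------------------
# Conditioned NB exact test
# ---------------------------------------------------------------------------

def _group_sum_logpmf(x: np.ndarray, mu: float, var: float) -> np.ndarray:
    """log pmf of a group's count sum, NB by moment matching (Poisson limit)."""
    if var > mu * (1.0 + 1e-9):
        r = mu * mu / (var - mu)
        p = mu / var
        return stats.nbinom.logpmf(x, r, p)
    return stats.poisson.logpmf(x, mu)


def nb_exact_test(
    k_a: int,
    k_b: int,
    q: float,
    alpha: float,
    s_a: np.ndarray,
    s_b: np.ndarray,
) -> float:
    """Two-sided conditional exact p-value for one gene.

    Group sums K_A, K_B are modelled as NB with mean q*sum(s) and variance
    q*sum(s) + alpha*q^2*sum(s^2). Conditional on S = k_a + k_b, the p-value
    is the total probability of partitions (a, S-a) whose joint probability
    does not exceed the observed one, normalized over all partitions
    (probability-ordering two-sided tail). S = 0 carries no information and
    returns 1.
    """
    k_a, k_b = int(k_a), int(k_b)
    total = k_a + k_b
    if total == 0 or q <= 0:
        return 1.0
    s_a, s_b = np.asarray(s_a, float), np.asarray(s_b, float)
    mu_a, mu_b = q * s_a.sum(), q * s_b.sum()
    var_a = mu_a + alpha * q * q * np.sum(s_a**2)
    var_b = mu_b + alpha * q * q * np.sum(s_b**2)

    grid = _partition_grid(total, mu_a, var_a, var_b)
    logp = _group_sum_logpmf(grid, mu_a, var_a) + _group_sum_logpmf(total - grid, mu_b, var_b)
    log_obs = (
        _group_sum_logpmf(np.array([k_a]), mu_a, var_a)
        + _group_sum_logpmf(np.array([total - k_a]), mu_b, var_b)
    )[0]
    m = logp.max()
    weights = np.exp(logp - m)
    denom = weights.sum()
    # tail = partitions no more probable than observed, with fp-safe slack
    num = weights[logp <= log_obs + 1e-7].sum()
    return float(min(1.0, num / denom))


_FULL_ENUM_MAX = 20_000


def _partition_grid(total: int, mu_a: float, var_a: float, var_b: float) -> np.ndarray:
    """Values of a to enumerate for the partition sum.

    Below _FULL_ENUM_MAX the enumeration is exhaustive (exact). For very
    large totals only a window of +/- 20 combined standard deviations around
    the conditional mode is enumerated; the mass outside is negligible at
    double precision.
    """
    if total <= _FULL_ENUM_MAX:
        return np.arange(total + 1)
    mu_b = max(total - mu_a, 1.0)
    center = int(round(total * mu_a / (mu_a + mu_b)))
    half = int(20.0 * np.sqrt(var_a + var_b) + 100)
    lo, hi = max(0, center - half), min(total, center + half)
    return np.arange(lo, hi + 1)


def de_test(
    cm: CountMatrix,
    size_factors: np.ndarray | None = None,
    dispersions: np.ndarray | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Full per-gene DE table: normalized group means, fold change, p values.

    fold_change = (mean_case + pseudocount) / (mean_control + pseudocount),
    so genes with zero counts in a group remain defined. p_raw comes from the
    conditioned NB exact test, p_adj from Benjamini-Hochberg.
    """
    if size_factors is None:
        size_factors = estimate_size_factors(cm)
    if dispersions is None:
        dispersions = estimate_dispersions(cm, size_factors)
    s = np.asarray(size_factors, float)
    case = cm.group_mask("case")
    z = cm.counts / s[None, :]
    q = z.mean(axis=1)
    mean_case = z[:, case].mean(axis=1)
    mean_control = z[:, ~case].mean(axis=1)
    fold = (mean_case + pseudocount) / (mean_control + pseudocount)

    k_case = cm.counts[:, case].sum(axis=1)
    k_ctrl = cm.counts[:, ~case].sum(axis=1)
    s_case, s_ctrl = s[case], s[~case]
    p_raw = np.array(
        [
            nb_exact_test(k_case[i], k_ctrl[i], q[i], dispersions[i], s_case, s_ctrl)
            for i in range(cm.n_genes)
        ]
    )
    p_adj = adjust_bh(p_raw)
    return pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "mean_control": mean_control,
            "mean_case": mean_case,
            "fold_change": fold,
            "log2fc": np.log2(fold),
            "p_raw": p_raw,
            "p_adj": p_adj,
            "alpha": dispersions,
        }
    )


# ---------------------------------------------------------------------------
# FDR and DEG selection
# ---------------------------------------------------------------------------

def adjust_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEGSet:
    """Genes passing the fold-change and significance filters, with provenance."""

    table: pd.DataFrame  # columns: gene_id, log2fc, fold_change, p, direction
    fc_min: float
    p_max: float
    p_column: str

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])

    @property
    def n_up(self) -> int:
        return int((self.table["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["direction"] == "down").sum())


def select_degs(
    results: pd.DataFrame,
    fc_min: float = 2.0,
    p_max: float = 0.05,
    p_column: str = "raw",
) -> DEGSet:
    """Threshold selection: |log2 fold| >= log2(fc_min) and p <= p_max.

    p_column chooses raw or BH-adjusted p. Direction follows the sign of the
    fold change (case relative to control).
    """
    if fc_min <= 0 or p_max <= 0:
        raise ValueError("thresholds must be positive")
    col = {"raw": "p_raw", "adj": "p_adj"}[p_column]
    if results.empty:
        table = pd.DataFrame(columns=["gene_id", "log2fc", "fold_change", "p", "direction"])
        return DEGSet(table, fc_min, p_max, p_column)
    hit = (np.abs(results["log2fc"]) >= np.log2(fc_min)) & (results[col] <= p_max)
    table = results.loc[hit, ["gene_id", "log2fc", "fold_change"]].copy()
    table["p"] = results.loc[hit, col]
    table["direction"] = np.where(table["log2fc"] > 0, "up", "down")
    logger.info(
        "DEG selection (fold>=%g, %s p<=%g): %d genes (%d up, %d down) of %d tested",
        fc_min, p_column, p_max, len(table),
        int((table["direction"] == "up").sum()), int((table["direction"] == "down").sum()),
        len(results),
    )
    return DEGSet(table.reset_index(drop=True), fc_min, p_max, p_column)


def partition_locus_groups(degs: DEGSet, annotation: AnnotationTable) -> dict:
    """DEG accounting by locus group and direction.

    Returns the four locus-group counts (DEGs missing from the annotation are
    counted as "other" and logged), their total, and the up/down totals; the
    locus-group counts always sum to the DEG total, as do up + down.
    """
    lg = annotation.locus_group_of()
    counts = {g: 0 for g in LOCUS_GROUPS}
    n_missing = 0
    for gid in degs.gene_ids:
        group = lg.get(gid)
        if group is None:
            n_missing += 1
            group = "other"
        counts[group] += 1
    if n_missing:
        logger.warning("%d DEGs absent from annotation; counted as 'other'", n_missing)
    return {
        **counts,
        "total": sum(counts.values()),
        "n_up": degs.n_up,
        "n_down": degs.n_down,
        "n_unannotated": n_missing,
    }
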