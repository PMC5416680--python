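"""Relative qPCR quantification by the 2^(-ddCt) method.

Technical replicates are averaged to one Ct per sample and gene. Then

    dCt(sample, gene)  = Ct_gene - Ct_reference           (per sample)
    ddCt(gene)         = mean dCt(case) - mean dCt(control)
    fold change        = 2^(-ddCt)

which assumes perfect doubling per cycle for both target and reference.
Group differences in dCt are assessed with a two-sample t-test (Student's
equal-variance by default, Welch via config), and PCR-array style calls are
made at a fold-change / p-value cutoff (volcano criteria).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import QPCRPlate


def delta_ct(plate: QPCRPlate, reference: str) -> pd.DataFrame:
    """Per-sample, per-gene dCt = mean Ct(target) - mean Ct(reference).

    Technical replicates are averaged first. Hard error if any sample lacks
    the reference gene.
    """
    reference = reference.upper()
    df = plate.records
    mean_ct = df.groupby(["sample_id", "group", "gene"], as_index=False)["ct"].mean()
    ref = mean_ct[mean_ct["gene"] == reference]
    missing = set(mean_ct["sample_id"]) - set(ref["sample_id"])
    if missing:
        raise ValueError(f"reference gene {reference!r} missing in samples {sorted(missing)}")
    ref_ct = dict(zip(ref["sample_id"], ref["ct"]))
    out = mean_ct.copy()
    out["delta_ct"] = out["ct"] - out["sample_id"].map(ref_ct)
    return out[["sample_id", "group", "gene", "ct", "delta_ct"]]


def group_ttest(case_values, control_values, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test on dCt values; p=1 for identical flat groups."""
    x = np.asarray(case_values, float)
    y = np.asarray(control_values, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 values per group")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        return float("inf") * np.sign(np.mean(x) - np.mean(y)), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def ddct_fold_change(dcts: pd.DataFrame, reference: str | None = None,
                     equal_var: bool = True) -> pd.DataFrame:
    """Per-gene ddCt, 2^(-ddCt) fold change and group t-test.

    dcts is the output of delta_ct. ddCt = mean dCt(case) - mean dCt(control);
    the t-test compares per-sample dCt values between groups.
    """
    rows = []
    for gene, sub in dcts.groupby("gene", sort=False):
        case = sub.loc[sub["group"] == "case", "delta_ct"].to_numpy()
        ctrl = sub.loc[sub["group"] == "control", "delta_ct"].to_numpy()
        if len(case) == 0 or len(ctrl) == 0:
            raise ValueError(f"gene {gene!r} is missing from one group")
        ddct = float(case.mean() - ctrl.mean())
        if len(case) >= 2 and len(ctrl) >= 2:
            t, p = group_ttest(case, ctrl, equal_var=equal_var)
        else:
            t, p = float("nan"), float("nan")
        rows.append({
            "gene": gene,
            "ddct": ddct,
            "fold_change": 2.0 ** (-ddct),
            "t_statistic": t,
            "p_value": p,
        })
    return pd.DataFrame(rows)


def volcano_calls(rel: pd.DataFrame, fc_min: float = 2.0, p_max: float = 0.05) -> pd.DataFrame:
    """up / down / ns calls and volcano coordinates (log2 fold, -log10 p)."""
    out = rel.copy()
    fold = out["fold_change"].to_numpy()
    p = out["p_value"].to_numpy()
    call = np.full(len(out), "ns", dtype=object)
    with np.errstate(invalid="ignore"):
        call[(fold >= fc_min) & (p < p_max)] = "up"
        call[(fold <= 1.0 / fc_min) & (p < p_max)] = "down"
    out["call"] = call
    out["log2_fold"] = np.log2(fold)
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(p)
    return out


def relative_expression(
    plate: QPCRPlate,
    reference: str,
    fc_min: float = 2.0,
    p_max: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Full 2^(-ddCt) analysis: dCt -> ddCt fold changes -> t-tests -> calls.

    The reference gene itself is excluded from the output table (its fold
    change is 1 by construction).
    """
    dcts = delta_ct(plate, reference)
    rel = ddct_fold_change(dcts[dcts["gene"] != reference.upper()], equal_var=equal_var)
    return volcano_calls(rel, fc_min=fc_min, p_max=p_max)
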