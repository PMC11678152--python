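"""Minimal negative-binomial differential expression over a growth curve.

The engine follows the standard count-model recipe: median-of-ratios size
factors, per-feature method-of-moments NB dispersion (floored), a Wald
test on the log2 fold change of each time point against the reference
point, and Benjamini-Hochberg adjustment per contrast. Calls use the
log2FC >= 2 and adjusted p <= 0.01 rule. It is deliberately not a full
GLM framework: the bespoke content downstream is the calling and
opposite-expression logic, not the estimation machinery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LFC_THRESHOLD = 2.0
PADJ_THRESHOLD = 0.01
DISPERSION_FLOOR = 0.01


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq normalisation).

    The geometric mean per feature is taken over features with all
    positive counts; each sample's factor is the median ratio of its
    counts to those means.
    """
    log_counts = np.log(counts.replace(0, np.nan))
    log_means = log_counts.mean(axis=1, skipna=False)
    usable = log_means.notna() & np.isfinite(log_means)
    if not usable.any():
        raise ValueError("no feature has positive counts in every sample")
    ratios = log_counts.loc[usable].sub(log_means[usable], axis=0)
    sf = np.exp(ratios.median(axis=0))
    return sf


def mom_dispersion(
    norm_counts: pd.DataFrame, groups: pd.Series, floor: float = DISPERSION_FLOOR
) -> pd.Series:
    """Per-feature method-of-moments NB dispersion, pooled across groups.

    For NB counts, var = mu + alpha * mu^2, so alpha is estimated from the
    within-group sample moments and averaged over groups with >= 2
    replicates, then floored at ``floor``.
    """
    alphas = []
    for g in groups.unique():
        cols = groups.index[groups == g]
        if len(cols) < 2:
            continue
        sub = norm_counts[cols]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (var - mu) / (mu**2)
        alphas.append(a.replace([np.inf, -np.inf], np.nan))
    if not alphas:
        raise ValueError("need at least one group with >= 2 replicates")
    pooled = pd.concat(alphas, axis=1).mean(axis=1)
    return pooled.clip(lower=floor).fillna(floor)


@dataclass
class DEResult:
    feature_id: str
    contrast: str
    log2fc: float
    pvalue: float
    padj: float
    call: str  # up / down / ns


def _call(log2fc: float, padj: float) -> str:
    if np.isnan(padj):
        return "ns"
    if log2fc >= LFC_THRESHOLD and padj <= PADJ_THRESHOLD:
        return "up"
    if log2fc <= -LFC_THRESHOLD and padj <= PADJ_THRESHOLD:
        return "down"
    return "ns"


def de_test(
    counts: pd.DataFrame,
    design: pd.Series,
    reference: str,
    dispersion_floor: float = DISPERSION_FLOOR,
) -> dict[str, pd.DataFrame]:
    """Wald tests of every non-reference group against the reference.

    ``design`` maps sample name -> group label (e.g. time point). Returns
    one DataFrame per contrast, labelled ``"{group}-vs-{reference}"``,
    with columns log2fc, pvalue, padj, call. Features with zero counts
    everywhere are reported as ``ns`` with missing statistics.

    The Wald statistic uses the delta-method variance of the log ratio of
    NB group means, ``(1/n)(1/mu + alpha)`` per group, referred to the
    standard normal.
    """
    design = design.reindex(counts.columns)
    if design.isna().any():
        raise ValueError("design missing for some samples")
    if reference not in set(design):
        raise ValueError(f"reference group {reference!r} not in design")
    for g, cols in design.groupby(design):
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
    if not np.allclose(counts.to_numpy(), counts.to_numpy().round()):
        raise ValueError("counts must be integers")

    sf = size_factors(counts)
    norm = counts.div(sf, axis=1)
    alpha = mom_dispersion(norm, design, floor=dispersion_floor)

    all_zero = (counts.sum(axis=1) == 0)
    results: dict[str, pd.DataFrame] = {}
    ref_cols = design.index[design == reference]
    eps = 0.5  # pseudo-count on group means; keeps zero groups finite
    for group in [g for g in pd.unique(design) if g != reference]:
        g_cols = design.index[design == group]
        mu_a = norm[ref_cols].mean(axis=1)
        mu_b = norm[g_cols].mean(axis=1)
        lfc = np.log2((mu_b + eps) / (mu_a + eps))
        var_log = (1.0 / len(ref_cols)) * (1.0 / (mu_a + eps) + alpha) + (
            1.0 / len(g_cols)
        ) * (1.0 / (mu_b + eps) + alpha)
        se = np.sqrt(var_log)
        wald = lfc * np.log(2) / se
        pval = pd.Series(
            2.0 * stats.norm.sf(np.abs(wald)), index=counts.index
        )
        pval[all_zero] = np.nan
        mask = pval.notna()
        padj = pd.Series(np.nan, index=counts.index)
        if mask.any():
            padj[mask] = multipletests(pval[mask], method="fdr_bh")[1]
        lfc = lfc.where(~all_zero, np.nan)
        out = pd.DataFrame(
            {
                "log2fc": lfc,
                "pvalue": pval,
                "padj": padj,
            }
        )
        out["call"] = [
            _call(l, q) for l, q in zip(out["log2fc"].fillna(0), out["padj"])
        ]
        results[f"{group}-vs-{reference}"] = out
    return results


def opposite_expression(
    de_srna: dict[str, pd.DataFrame],
    de_mrna: dict[str, pd.DataFrame],
    min_contrasts: int = 2,
) -> pd.DataFrame:
    """sRNA-mRNA pairs with opposite DE calls in >= ``min_contrasts`` contrasts.

    A contrast contributes when the sRNA is called up and the mRNA down
    there, or vice versa. Both inputs must share the same contrast labels.
    """
    if set(de_srna) != set(de_mrna):
        raise ValueError("sRNA and mRNA DE results use different contrasts")
    counter: dict[tuple[str, str], int] = {}
    for contrast in de_srna:
        s = de_srna[contrast]["call"]
        m = de_mrna[contrast]["call"]
        s_up = s.index[s == "up"]
        s_down = s.index[s == "down"]
        m_up = m.index[m == "up"]
        m_down = m.index[m == "down"]
        for pair in itertools.chain(
            itertools.product(s_up, m_down), itertools.product(s_down, m_up)
        ):
            counter[pair] = counter.get(pair, 0) + 1
    rows = [
        {"srna_id": s, "mrna_id": m, "oe_contrast_count": c}
        for (s, m), c in counter.items()
        if c >= min_contrasts
    ]
    return pd.DataFrame(
        rows, columns=["srna_id", "mrna_id", "oe_contrast_count"]
    ).sort_values(["srna_id", "mrna_id"]).reset_index(drop=True)
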