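"""Downstream grouping statistics: simplified differential abundance,
Argonaute-association summaries, and tissue-specificity scoring.

The differential-abundance stage is a declared simplification: a
two-sided two-sample t-test on log2(CPM + 0.5) with Benjamini-Hochberg
correction, in place of a negative-binomial empirical-Bayes fit. It is
pluggable — externally computed results can be supplied as a table with
the same columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import jensenshannon
from statsmodels.stats.multitest import multipletests

LOG2FC_CUTOFF = 1.0


def differential_abundance(
    cpm: pd.DataFrame,
    groups: dict[str, str] | pd.Series,
    group_a: str,
    group_b: str,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = LOG2FC_CUTOFF,
) -> pd.DataFrame:
    """Per-feature log2FC (B vs A) of mean CPM with a t-test on log2 CPM.

    A 0.5 pseudocount stabilises zeros. Features with zero variance in
    both groups and equal means get p = 1. ``significant`` requires
    |log2FC| > ``lfc_threshold`` and BH-adjusted p < ``fdr_threshold``.
    """
    groups = pd.Series(groups)
    cols_a = [c for c in cpm.columns if groups.get(c) == group_a]
    cols_b = [c for c in cpm.columns if groups.get(c) == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    log_a = np.log2(cpm[cols_a].to_numpy(dtype=float) + 0.5)
    log_b = np.log2(cpm[cols_b].to_numpy(dtype=float) + 0.5)
    lfc = np.log2(cpm[cols_b].mean(axis=1) + 0.5) - np.log2(
        cpm[cols_a].mean(axis=1) + 0.5
    )
    t_res = sps.ttest_ind(log_b, log_a, axis=1)
    p = np.asarray(t_res.pvalue, dtype=float)
    degenerate = (log_a.std(axis=1) == 0) & (log_b.std(axis=1) == 0)
    p = np.where(degenerate & np.isclose(log_a.mean(axis=1), log_b.mean(axis=1)),
                 1.0, p)
    p = np.where(np.isnan(p), 1.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "feature_id": cpm.index,
            "log2fc_abundance": lfc.to_numpy(),
            "p": p,
            "fdr": fdr,
        }
    ).set_index("feature_id")
    out["significant"] = (out["log2fc_abundance"].abs() > lfc_threshold) & (
        out["fdr"] < fdr_threshold
    )
    return out


def argonaute_parse(
    frequencies: pd.DataFrame,
    associations: pd.DataFrame,
    freq_col: str = "pooled_u_freq",
) -> pd.DataFrame:
    """Group sRNA frequencies by Argonaute association.

    ``frequencies`` is indexed by species_id (or has a species_id column);
    ``associations`` has columns species_id, argonaute, with one row per
    association — an sRNA bound by several Argonautes contributes to every
    one of its groups. Species without any association form the
    'not_enriched' group. Association rows naming unknown species are
    ignored. Returns per-group n and mean frequency.
    """
    freqs = frequencies.reset_index() if frequencies.index.name else frequencies
    freqs = freqs.drop_duplicates("species_id").set_index("species_id")[freq_col]
    assoc = associations[associations["species_id"].isin(freqs.index)]
    grouped = assoc.merge(
        freqs.rename("freq"), left_on="species_id", right_index=True
    )
    rows = [
        {
            "argonaute": ago,
            "n_species": sub["species_id"].nunique(),
            "mean_u_freq": float(sub["freq"].mean()),
        }
        for ago, sub in grouped.groupby("argonaute")
    ]
    unassoc = freqs.index.difference(assoc["species_id"].unique())
    rows.append(
        {
            "argonaute": "not_enriched",
            "n_species": len(unassoc),
            "mean_u_freq": float(freqs.loc[unassoc].mean())
            if len(unassoc)
            else float("nan"),
        }
    )
    return pd.DataFrame(rows).set_index("argonaute").sort_index()


def tissue_specificity(
    expression: pd.DataFrame,
    ubiquitous_threshold: float = 0.6,
) -> pd.DataFrame:
    """Tissue-specificity S index per gene and an assigned category.

    For a gene with expression profile normalised to sum 1, the score for
    tissue t is ``S_t = 1 - JSdist(p, e_t)`` where e_t is the unit vector
    at t and JSdist the square root of the Jensen-Shannon divergence
    (log base 2). A gene expressed in exactly one tissue scores 1 there.
    The category is the argmax tissue, or 'ubiquitous' when
    ``max_t S_t < ubiquitous_threshold``; all-zero genes are 'unclassified'.
    """
    tissues = list(expression.columns)
    vals = expression.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("expression must be nonnegative")
    s_mat = np.full(vals.shape, np.nan)
    categories = []
    for i, row in enumerate(vals):
        total = row.sum()
        if total == 0:
            categories.append("unclassified")
            continue
        p = row / total
        for j in range(len(tissues)):
            e = np.zeros(len(tissues))
            e[j] = 1.0
            s_mat[i, j] = 1.0 - jensenshannon(p, e, base=2)
        best = int(np.nanargmax(s_mat[i]))
        if s_mat[i, best] < ubiquitous_threshold:
            categories.append("ubiquitous")
        else:
            categories.append(tissues[best])
    out = pd.DataFrame(s_mat, index=expression.index,
                       columns=[f"S_{t}" for t in tissues])
    out["category"] = categories
    return out


def category_enrichment(
    target_categories: pd.Series,
    background_categories: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-category 2x2 chi-square test of target vs background membership.

    The background must contain the target set. Tables with any expected
    cell below 5 are flagged and computed with Yates' continuity
    correction. P-values are BH-adjusted across categories.
    """
    if not set(target_categories.index) <= set(background_categories.index):
        raise ValueError("target set must be a subset of the background")
    rows = []
    in_target = background_categories.index.isin(target_categories.index)
    for cat in sorted(background_categories.unique()):
        in_cat = (background_categories == cat).to_numpy()
        table = np.array(
            [
                [(in_target & in_cat).sum(), (in_target & ~in_cat).sum()],
                [(~in_target & in_cat).sum(), (~in_target & ~in_cat).sum()],
            ]
        )
        expected = sps.contingency.expected_freq(table)
        small = bool((expected < 5).any())
        chi2, p, _, _ = sps.chi2_contingency(table, correction=small)
        n_t, n_b = table[0, 0], table[:, 0].sum()
        frac_t = n_t / max(1, in_target.sum())
        frac_b = n_b / len(background_categories)
        rows.append(
            {
                "category": cat,
                "n_target": int(n_t),
                "n_background": int(n_b),
                "direction": "enriched" if frac_t > frac_b else "depleted",
                "chi2": float(chi2),
                "p": float(p),
                "small_expected": small,
            }
        )
    out = pd.DataFrame(rows).set_index("category")
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] < alpha
    return out
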