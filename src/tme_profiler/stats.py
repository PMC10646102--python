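"""Cohort comparison statistics: nonparametric group tests with BH
correction, proportion tests, masked correlation matrices, and differential
expression.

The BH family is always exactly the set of variables passed in a single
call; families from different analyses are never pooled.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cohort_io import CohortManifest, ConfigurationError, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    return multipletests(pvalues, method="fdr_bh")[1]


def _kruskal_one(groups: list[np.ndarray]) -> tuple[float, float]:
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        # all observations identical: no between-group variation by definition
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def kruskal_bh(
    data: pd.DataFrame,
    groups: pd.Series,
) -> pd.DataFrame:
    """Kruskal-Wallis test per variable (column) with BH correction across
    the variable family passed in this call.

    ``data``: samples x variables; ``groups``: group label per sample.
    Returns one row per variable with H, raw p, BH-adjusted p, and group
    medians.
    """
    groups = groups.reindex(data.index)
    if groups.isna().any():
        missing = data.index[groups.isna()].tolist()
        raise ValidationError(f"samples without group label: {missing[:10]}")
    labels = [g for g in pd.unique(groups)]
    if len(labels) < 2:
        raise ValidationError("need >= 2 groups")
    for g in labels:
        if (groups == g).sum() < 2:
            raise ValidationError(f"group {g!r} has < 2 observations")

    rows = []
    for var in data.columns:
        values = [data.loc[groups == g, var].to_numpy(dtype=float) for g in labels]
        h, p = _kruskal_one(values)
        row = {"variable": var, "statistic": h, "raw_p": p}
        for g, v in zip(labels, values):
            row[f"median_{g}"] = float(np.median(v))
        rows.append(row)
    out = pd.DataFrame(rows)
    out["adj_p"] = bh_adjust(out["raw_p"].to_numpy())
    return out


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for combined n <= 20 without ties,
    otherwise normal approximation with tie and continuity correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each side needs >= 2 observations")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def proportion_test(table: np.ndarray) -> tuple[str, float]:
    """Homogeneity test on a 2 x k count table.

    Fisher exact when any expected cell is small (<= 5) on a 2x2, chi-square
    otherwise. Returns (branch, p).
    """
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValidationError(f"expected a 2 x k table, got shape {table.shape}")
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        raise ValidationError("table must hold non-negative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("table has a zero margin")
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if table.shape == (2, 2) and (expected <= 5).any():
        _, p = sps.fisher_exact(table, alternative="two-sided")
        return "fisher", float(p)
    _, p, _, _ = sps.chi2_contingency(table, correction=False)
    return "chi2", float(p)


def correlation_matrix(
    x_table: pd.DataFrame,
    y_table: pd.DataFrame,
    method: str = "spearman",
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Pairwise correlations between columns of two tables on shared samples.

    Pairwise-complete observations; pairs with < 4 complete observations are
    recorded missing with a warning. Returns ``rho``, ``p``, and a boolean
    ``mask`` that is True where the correlation is NOT significant (p > alpha).
    """
    if method not in ("spearman", "pearson"):
        raise ConfigurationError(f"unknown method {method!r}")
    shared = x_table.index.intersection(y_table.index)
    x = x_table.loc[shared]
    y = y_table.loc[shared]
    rho = pd.DataFrame(np.nan, index=x.columns, columns=y.columns)
    pmat = pd.DataFrame(np.nan, index=x.columns, columns=y.columns)
    corr = sps.spearmanr if method == "spearman" else sps.pearsonr
    for xv in x.columns:
        for yv in y.columns:
            pair = pd.concat([x[xv], y[yv]], axis=1).dropna()
            if len(pair) < 4:
                logger.warning(
                    "pair (%s, %s): %d complete observations (< 4); recorded missing",
                    xv, yv, len(pair),
                )
                continue
            r, p = corr(pair.iloc[:, 0], pair.iloc[:, 1])
            rho.loc[xv, yv] = r
            pmat.loc[xv, yv] = p
    mask = pmat > alpha
    return {"rho": rho, "p": pmat, "mask": mask}


def deg(
    expr: ExpressionMatrix,
    manifest: CohortManifest,
    group_a: str,
    group_b: str,
    pseudocount: float = 1.0,
    alpha: float = 0.05,
    test: str = "mannwhitney",
) -> pd.DataFrame:
    """Differential expression between two groups over the whole matrix.

    log2fc = log2(mean_a + pseudocount) - log2(mean_b + pseudocount) on TPM;
    per-gene two-sided Mann-Whitney raw p (or Welch t on log2(TPM+1) with
    ``test="welch"``), BH across genes; ``significant`` = adj_p < alpha.
    """
    samples_a = [s for s in manifest.samples_in(group_a) if s in expr.df.columns]
    samples_b = [s for s in manifest.samples_in(group_b) if s in expr.df.columns]
    if not samples_a or not samples_b:
        raise ValidationError(f"both groups must be non-empty: {group_a}, {group_b}")
    va = expr.df[samples_a].to_numpy(dtype=float)
    vb = expr.df[samples_b].to_numpy(dtype=float)
    log2fc = np.log2(va.mean(axis=1) + pseudocount) - np.log2(vb.mean(axis=1) + pseudocount)
    if test == "mannwhitney":
        res = sps.mannwhitneyu(va, vb, alternative="two-sided",
                               method="asymptotic", axis=1)
        raw_p = np.asarray(res.pvalue, dtype=float)
    elif test == "welch":
        res = sps.ttest_ind(np.log2(va + 1), np.log2(vb + 1), equal_var=False, axis=1)
        raw_p = np.asarray(res.pvalue, dtype=float)
    else:
        raise ConfigurationError(f"unknown test {test!r}")
    raw_p = np.where(np.isnan(raw_p), 1.0, raw_p)  # constant genes: no evidence
    adj_p = bh_adjust(raw_p)
    out = pd.DataFrame({
        "gene": expr.genes,
        "log2fc": log2fc,
        "raw_p": raw_p,
        "adj_p": adj_p,
    })
    out["significant"] = out["adj_p"] < alpha
    return out
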