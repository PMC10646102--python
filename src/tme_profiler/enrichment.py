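"""Preranked GSEA (contrast-level) and ssGSEA (sample-level) enrichment.

The enrichment score is the signed maximum deviation of a weighted
Kolmogorov-Smirnov running sum: genes in the set increment by
|metric|^alpha / sum_set |metric|^alpha, genes outside decrement by
1/(N - N_set). The preranked null is built by gene-label permutation
preserving set size; ssGSEA integrates the hit/miss ECDF difference over the
whole ranking, weighting hits by their rank position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort_io import ExpressionMatrix, GeneSet, ValidationError
from .stats import bh_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    es: float
    nes: float
    p: float
    fdr: float  # Benjamini-Hochberg over empirical p (default column)
    fdr_nes: float  # classic sign-stratified NES-ratio FDR
    size: int


def rank_genes(metric: pd.Series) -> pd.Series:
    """Sort a gene -> metric series descending, ties broken by gene symbol."""
    if metric.index.duplicated().any():
        dups = metric.index[metric.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate genes in ranked list: {dups}")
    if not np.isfinite(metric.to_numpy(dtype=float)).all():
        raise ValidationError("ranking metric must be finite")
    order = np.lexsort((metric.index.to_numpy(), -metric.to_numpy(dtype=float)))
    return metric.iloc[order]


def _hit_mask(ranked_genes: Sequence[str], geneset: GeneSet) -> np.ndarray:
    members = geneset.genes
    return np.fromiter((g in members for g in ranked_genes), dtype=bool,
                       count=len(ranked_genes))


def _es_core(weights: np.ndarray, hits: np.ndarray) -> float:
    """ES for one hit indicator vector; weights = |metric|^alpha, in rank order."""
    n = hits.size
    k = int(hits.sum())
    nr = float(weights[hits].sum())
    if nr <= 0:
        raise ValidationError("sum of hit weights is zero; cannot normalize running sum")
    step = np.where(hits, weights / nr, -1.0 / (n - k))
    running = np.cumsum(step)
    return float(running[int(np.argmax(np.abs(running)))])


def es(ranked: pd.Series, geneset: GeneSet, alpha: float = 0.0) -> float:
    """Weighted KS enrichment score of a gene set on a descending ranked list."""
    if alpha < 0:
        raise ValidationError("alpha must be >= 0")
    ranked = rank_genes(ranked)
    hits = _hit_mask(ranked.index, geneset)
    if hits.sum() == 0:
        raise ValidationError(f"gene set {geneset.name!r}: no member in ranked list")
    if hits.all():
        raise ValidationError(
            f"gene set {geneset.name!r} covers the entire universe (miss step undefined)"
        )
    weights = np.abs(ranked.to_numpy(dtype=float)) ** alpha
    return _es_core(weights, hits)


def _null_es(weights: np.ndarray, set_size: int, nperm: int,
             rng: np.random.Generator) -> np.ndarray:
    """ES under gene-label permutation: random size-matched sets."""
    n = weights.size
    # random hit positions: k smallest of iid uniforms per permutation
    u = rng.random((nperm, n))
    pos = np.argpartition(u, set_size - 1, axis=1)[:, :set_size]
    hits = np.zeros((nperm, n), dtype=bool)
    np.put_along_axis(hits, pos, True, axis=1)
    wh = np.where(hits, weights, 0.0)
    nr = wh.sum(axis=1, keepdims=True)
    step = np.where(hits, wh / nr, -1.0 / (n - set_size))
    running = np.cumsum(step, axis=1)
    imax = np.argmax(np.abs(running), axis=1)
    return running[np.arange(nperm), imax]


def preranked_gsea(
    ranked: pd.Series,
    genesets: Iterable[GeneSet],
    nperm: int = 1000,
    alpha: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA over a family of gene sets.

    Null by gene-label permutation preserving set size. NES = ES divided by
    the mean |null ES| of matching sign; p is the empirical tail probability
    with +1 smoothing on the null tail matching the observed sign (so
    enrichment in either direction is detected; under the null p is
    approximately uniform). The default ``fdr`` column is Benjamini-Hochberg
    over these p-values; the classic sign-stratified NES-ratio FDR is
    reported as ``fdr_nes``.
    """
    genesets = list(genesets)
    if not genesets:
        raise ValidationError("empty gene-set list")
    if nperm < 100:
        raise ValidationError("nperm must be >= 100")
    ranked = rank_genes(ranked)
    weights = np.abs(ranked.to_numpy(dtype=float)) ** alpha
    rng = np.random.default_rng(seed)

    rows = []
    null_pool: list[np.ndarray] = []
    for gs in genesets:
        hits = _hit_mask(ranked.index, gs)
        k = int(hits.sum())
        if k == 0:
            logger.warning("gene set %s: no member in ranked list; skipped", gs.name)
            continue
        if hits.all():
            raise ValidationError(f"gene set {gs.name!r} covers the entire universe")
        observed = _es_core(weights, hits)
        null = _null_es(weights, k, nperm, rng)
        same_sign = null[np.sign(null) == np.sign(observed)] if observed != 0 else null
        if same_sign.size == 0:
            same_sign = np.abs(null)
        nes = observed / np.mean(np.abs(same_sign))
        p = (1.0 + np.sum(np.abs(same_sign) >= abs(observed))) / (1.0 + same_sign.size)
        rows.append({"name": gs.name, "es": observed, "nes": nes, "p": p, "size": k})
        null_pool.append(null / np.mean(np.abs(same_sign)))  # null NES, roughly scaled

    if not rows:
        raise ValidationError("no gene set had any member in the ranked list")
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    all_null_nes = np.concatenate(null_pool)
    obs_nes = out["nes"].to_numpy()
    fdr_nes = np.ones(len(out))
    for i, nes_i in enumerate(obs_nes):
        if nes_i >= 0:
            num_null = np.mean(all_null_nes >= nes_i) if (all_null_nes >= 0).any() else 1.0
            denom = np.mean(obs_nes >= nes_i)
        else:
            num_null = np.mean(all_null_nes <= nes_i)
            denom = np.mean(obs_nes <= nes_i)
        fdr_nes[i] = min(1.0, num_null / denom) if denom > 0 else 1.0
    out["fdr_nes"] = fdr_nes
    return out[["name", "es", "nes", "p", "fdr", "fdr_nes", "size"]]


def ssgsea(
    expr: ExpressionMatrix,
    genesets: Iterable[GeneSet],
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """Single-sample GSEA scores (samples x gene sets).

    Per sample, genes are ordered by expression (descending, ties broken by
    gene symbol) and each score is the summed difference between the
    rank-weighted hit ECDF (weights = rank position^alpha) and the unweighted
    miss ECDF over all positions. Sets with no gene present score missing,
    with a warning. ``normalize=True`` rescales the whole matrix by its
    (max - min) range.
    """
    genesets = list(genesets)
    if not genesets:
        raise ValidationError("empty gene-set list")
    genes = np.array(expr.genes)
    values = expr.df.to_numpy(dtype=float)
    n = len(genes)
    ranks_desc = np.arange(n, 0, -1, dtype=float)  # weight of position 1..n
    scores = np.full((expr.shape[1], len(genesets)), np.nan)

    member_masks = []
    for gs in genesets:
        mask = np.fromiter((g in gs.genes for g in genes), dtype=bool, count=n)
        if mask.sum() == 0:
            logger.warning("gene set %s: no member present; score recorded missing", gs.name)
        member_masks.append(mask)

    for j in range(expr.shape[1]):
        col = values[:, j]
        order = np.lexsort((genes, -col))
        w = ranks_desc ** alpha
        for s, mask in enumerate(member_masks):
            k = int(mask.sum())
            if k == 0 or k == n:
                continue
            hits = mask[order]
            wh = np.where(hits, w, 0.0)
            p_hit = np.cumsum(wh) / wh.sum()
            p_miss = np.cumsum(~hits) / (n - k)
            scores[j, s] = float(np.sum(p_hit - p_miss))

    out = pd.DataFrame(scores, index=expr.samples, columns=[gs.name for gs in genesets])
    out.index.name = "sample_id"
    if normalize:
        rng_span = np.nanmax(scores) - np.nanmin(scores)
        if rng_span > 0:
            out = out / rng_span
    return out
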