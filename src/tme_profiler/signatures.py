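"""Cohort z-score machinery and composite transcriptomic scores.

All composite scores reduce to per-gene z-scores taken across the whole
cohort (not within groups): the non-functional CD8 rule's "median TPM for
cohort" anchors that choice. z-scores use the population SD by default
(configurable to the sample SD via ``ddof``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort_io import ConfigurationError, ExpressionMatrix, GeneSet, ValidationError

logger = logging.getLogger(__name__)

TRANSFORMS = ("none", "log2p1")

TIS_LABELS = ("TIS_neg", "undetermined", "TIS_pos")


@dataclass(frozen=True)
class SignatureDefinition:
    """A named composite score: gene membership + aggregation rule."""

    name: str
    genes: GeneSet
    aggregation: str = "mean_z"  # mean_z | sum_z | weighted_sum
    transform: str = "log2p1"  # applied per cell before standardization

    def __post_init__(self):
        if self.aggregation not in ("mean_z", "sum_z", "weighted_sum"):
            raise ConfigurationError(f"unknown aggregation {self.aggregation!r}")
        if self.transform not in TRANSFORMS:
            raise ConfigurationError(f"unknown transform {self.transform!r}")
        if self.aggregation == "weighted_sum" and self.genes.weights is None:
            raise ConfigurationError(
                f"signature {self.name!r}: weighted_sum requires weights on the gene set"
            )


def _apply_transform(values: pd.DataFrame, transform: str) -> pd.DataFrame:
    if transform == "none":
        return values
    if transform == "log2p1":
        return np.log2(values + 1.0)
    raise ConfigurationError(f"unknown transform {transform!r}")


def cohort_zscores(
    expr: ExpressionMatrix, transform: str = "none", ddof: int = 0
) -> pd.DataFrame:
    """Per-gene z-scores across samples (genes x samples).

    Each gene is standardized to mean 0, SD 1 across the cohort. Genes with
    zero variance map to all-zero rows with a logged warning.
    """
    if expr.shape[1] < 2:
        raise ValidationError("z-scores require at least 2 samples (SD undefined)")
    values = _apply_transform(expr.df, transform)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=ddof)
    zero_var = sd == 0
    if zero_var.any():
        logger.warning(
            "%d gene(s) with zero variance mapped to all-zero z-scores: %s",
            int(zero_var.sum()),
            values.index[zero_var].tolist()[:10],
        )
    safe_sd = sd.where(~zero_var, 1.0)
    z = values.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[zero_var] = 0.0
    return z


def _require_genes(expr: ExpressionMatrix, genes: Sequence[str], score: str) -> None:
    missing = [g for g in genes if g not in expr.df.index]
    if missing:
        raise ValidationError(f"{score}: gene(s) absent from matrix: {missing}")


def sum_z_score(
    expr: ExpressionMatrix,
    genes: Sequence[str],
    transform: str = "log2p1",
    ddof: int = 0,
    score_name: str = "sum_z",
) -> pd.Series:
    """Sum of per-gene cohort z-scores over the given genes, per sample."""
    _require_genes(expr, genes, score_name)
    z = cohort_zscores(expr, transform=transform, ddof=ddof)
    return z.loc[list(genes)].sum(axis=0).rename(score_name)


def dysfunction_score(
    expr: ExpressionMatrix,
    genes: Sequence[str] = ("HAVCR2", "LAG3", "PDCD1"),
    transform: str = "log2p1",
    ddof: int = 0,
) -> pd.Series:
    """T cell dysfunction: sum of z-scores of HAVCR2 (TIM3), LAG3, PDCD1 (PD-1)."""
    return sum_z_score(expr, genes, transform, ddof, "dysfunction_score")


def sting_score(
    expr: ExpressionMatrix,
    genes: Sequence[str] = ("TMEM173", "CGAS", "CCL5", "CXCL10", "IRF3"),
    transform: str = "log2p1",
    ddof: int = 0,
    aggregation: str = "sum_z",
) -> pd.Series:
    """Composite STING-pathway score over TMEM173, CGAS, CCL5, CXCL10, IRF3.

    Defaults to a sum of z-scores, mirroring the dysfunction score's
    construction; set ``aggregation="mean_z"`` for a mean.
    """
    s = sum_z_score(expr, genes, transform, ddof, "sting_score")
    if aggregation == "mean_z":
        s = s / len(genes)
    elif aggregation != "sum_z":
        raise ConfigurationError(f"unknown aggregation {aggregation!r}")
    return s


def ifng_score(
    expr: ExpressionMatrix,
    signature: SignatureDefinition,
    ddof: int = 0,
) -> pd.Series:
    """Interferon-gamma (or any mean-z) signature score per sample.

    Mean of per-gene z-scores of log2(TPM+1) over the signature genes present
    in the matrix; the fraction present is logged, zero present is an error.
    """
    genes = sorted(signature.genes.genes)
    present = [g for g in genes if g in expr.df.index]
    if not present:
        raise ValidationError(
            f"signature {signature.name!r}: none of {len(genes)} genes present"
        )
    if len(present) < len(genes):
        logger.warning(
            "signature %s: %d/%d genes present in matrix",
            signature.name, len(present), len(genes),
        )
    z = cohort_zscores(expr, transform=signature.transform, ddof=ddof).loc[present]
    if signature.aggregation == "mean_z":
        score = z.mean(axis=0)
    elif signature.aggregation == "sum_z":
        score = z.sum(axis=0)
    else:  # weighted_sum
        w = pd.Series({g: signature.genes.weights[g] for g in present})
        score = z.mul(w, axis=0).sum(axis=0)
    return score.rename(f"{signature.name}_score")


def tis_classify(
    scores: pd.Series,
    thresholds: Optional[tuple[float, float]] = None,
) -> pd.Series:
    """Three-way T cell-inflamed classification of per-sample scores.

    score < t_low -> TIS_neg; score > t_high -> TIS_pos; else undetermined
    (both comparisons strict). Default thresholds are the cohort tertiles of
    the score.
    """
    if len(scores) == 0:
        raise ValidationError("empty score vector")
    if thresholds is None:
        t_low, t_high = np.quantile(scores.to_numpy(), [1 / 3, 2 / 3])
    else:
        t_low, t_high = thresholds
        if not t_low < t_high:
            raise ConfigurationError(
                f"thresholds must satisfy t_low < t_high, got ({t_low}, {t_high})"
            )
    labels = pd.Series("undetermined", index=scores.index, name="tis_class")
    labels[scores < t_low] = "TIS_neg"
    labels[scores > t_high] = "TIS_pos"
    return labels


def nonfunctional_cd8_classify(
    dysfunction: pd.Series,
    fgfbp2_tpm: pd.Series,
    cd8_fraction: pd.Series,
    dysfunction_cutoff: float = 1.0,
) -> pd.Series:
    """Flag samples with non-functional CD8 T cell transcriptomes.

    Flag = dysfunction score strictly > ``dysfunction_cutoff`` AND FGFBP2 TPM
    strictly below the whole-cohort median. Samples without CD8 infiltration
    (cd8_fraction == 0) are recorded as missing so they drop out of any
    percentage denominator.
    """
    if len(dysfunction) == 0:
        raise ValidationError("empty cohort")
    if not (dysfunction.index.equals(fgfbp2_tpm.index) and dysfunction.index.equals(cd8_fraction.index)):
        raise ValidationError("dysfunction, FGFBP2, and CD8 vectors must cover identical samples")
    median = float(fgfbp2_tpm.median())
    flag = (dysfunction > dysfunction_cutoff) & (fgfbp2_tpm < median)
    flag = flag.astype("boolean")
    flag[cd8_fraction == 0] = pd.NA
    return flag.rename("nonfunctional_cd8")


def nonfunctional_cd8_percentage(flags: pd.Series) -> float:
    """Percent flagged among samples with non-zero CD8 infiltration."""
    valid = flags.dropna()
    if len(valid) == 0:
        raise ValidationError("no samples with non-zero CD8 infiltration")
    return 100.0 * float(valid.sum()) / len(valid)
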