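"""Signature-matrix deconvolution of bulk expression into cell-type fractions.

Constrained (non-negative) least squares over marker genes against a
reference of expected TPM-scale expression per cell type, with an "other"
remainder absorbing unexplained signal (tumor/stroma). Mixture samples are
re-normalized to the TPM scale (1e6 over all genes) before fitting, so the
estimate is invariant to any positive rescaling of a sample.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .cohort_io import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

OTHER = "other"


class SignatureMatrix:
    """Marker genes x cell types reference matrix (TPM-scale expression)."""

    def __init__(self, values: pd.DataFrame):
        values = values.copy().astype(float)
        values.index = values.index.astype(str).str.strip()
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate marker genes in signature: {dups}")
        if (values < 0).any().any():
            raise ValidationError("signature matrix must be non-negative")
        zero_cols = values.columns[(values == 0).all(axis=0)].tolist()
        if zero_cols:
            raise ValidationError(f"signature matrix has all-zero columns: {zero_cols}")
        self._df = values

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def cell_types(self) -> list[str]:
        return self._df.columns.tolist()

    @property
    def marker_genes(self) -> list[str]:
        return self._df.index.tolist()

    @classmethod
    def read(cls, path: str | Path) -> "SignatureMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def write(self, path: str | Path) -> None:
        df = self._df.copy()
        df.index.name = "gene"
        df.to_csv(path, sep="\t", float_format="%.6g")


def deconvolve(
    expr: ExpressionMatrix,
    sig: SignatureMatrix,
    cell_type_scales: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Estimate cell-type fractions for every sample (samples x types + other).

    Per sample: non-negative least squares of the TPM-normalized mixture on
    the signature's marker-gene columns; estimated weights, divided by the
    per-type mRNA-content scales (default 1), are the absolute fractions, with
    ``other = max(0, 1 - sum)``; rows are renormalized to sum to 1.
    """
    markers = [g for g in sig.marker_genes if g in expr.df.index]
    n_total = len(sig.marker_genes)
    if len(markers) < 0.5 * n_total:
        raise ValidationError(
            f"only {len(markers)}/{n_total} signature marker genes present "
            f"in the mixture (>= 50% required)"
        )
    if len(markers) < n_total:
        dropped = sorted(set(sig.marker_genes) - set(markers))
        logger.warning(
            "dropping %d signature marker gene(s) absent from mixture: %s",
            len(dropped), dropped[:10],
        )
    scales = np.ones(len(sig.cell_types))
    if cell_type_scales is not None:
        scales = np.array([cell_type_scales.get(t, 1.0) for t in sig.cell_types])
        if (scales <= 0).any():
            raise ValidationError("cell-type scales must be positive")

    totals = expr.df.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValidationError(f"all-zero expression vector for sample(s): {bad}")
    mixture = expr.df.div(totals, axis=1) * 1e6  # TPM renormalization
    S = sig.df.loc[markers].to_numpy()
    M = mixture.loc[markers].to_numpy()

    rows = []
    for j, sample in enumerate(expr.samples):
        w, _ = nnls(S, M[:, j])
        w = np.maximum(w, 0.0) / scales
        other = max(0.0, 1.0 - w.sum())
        row = np.append(w, other)
        rows.append(row / row.sum())
    out = pd.DataFrame(rows, index=expr.samples, columns=[*sig.cell_types, OTHER])
    out.index.name = "sample_id"
    return out
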