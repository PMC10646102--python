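"""Data model, validation, and readers/writers for every on-disk artifact.

All tables are UTF-8 TSV with a header row. Gene symbols are matched
case-sensitively after whitespace trimming; no alias resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("PCM", "MBM", "ECM")

VARIANT_CLASSES = ("missense", "nonsense", "frameshift", "splice", "synonymous", "other")

PATHOGENICITY_LEVELS = ("pathogenic", "likely_pathogenic", "VUS", "likely_benign", "benign")

HLA_LOCI = ("HLA-A", "HLA-B", "HLA-C", "HLA-DPA1", "HLA-DPB1", "HLA-DQB1", "HLA-DRB1")
HLA_CLASS_I = ("HLA-A", "HLA-B", "HLA-C")
HLA_CLASS_II = ("HLA-DPA1", "HLA-DPB1", "HLA-DQB1", "HLA-DRB1")


class FormatError(ValueError):
    """A file does not conform to its expected on-disk layout."""


class ValidationError(ValueError):
    """A parsed value violates a domain invariant."""


class ConfigurationError(ValueError):
    """An invalid parameter combination was supplied."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


class ExpressionMatrix:
    """Genes x samples TPM matrix with a gene-symbol row index.

    Wraps a :class:`pandas.DataFrame` (rows = genes, columns = samples) and
    enforces: unique gene symbols, unique sample ids, finite non-negative
    values.
    """

    def __init__(self, values: pd.DataFrame):
        if not isinstance(values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (genes x samples)")
        values = values.copy()
        values.index = values.index.astype(str).str.strip()
        values.columns = values.columns.astype(str).str.strip()
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene symbols: {dups}")
        if values.columns.duplicated().any():
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        arr = values.to_numpy(dtype=float, copy=False)
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at gene {values.index[bad[0]]!r}, "
                f"sample {values.columns[bad[1]]!r}"
            )
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative TPM at gene {values.index[bad[0]]!r}, "
                f"sample {values.columns[bad[1]]!r}"
            )
        self._df = values.astype(float)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def genes(self) -> list[str]:
        return self._df.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self._df.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix({self.shape[0]} genes x {self.shape[1]} samples)"


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TPM table.

    First column holds gene symbols, header row holds sample ids. Duplicate
    gene rows are collapsed by per-cell maximum TPM with a logged warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file or missing header") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found (missing header?)")
    df.index = df.index.astype(str).str.strip()
    columns = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            gene = df.index[converted.isna().to_numpy().argmax()]
            raise ValidationError(
                f"{path}: non-numeric value at gene {gene!r}, sample {col!r}"
            )
        columns[col] = converted
    values = pd.DataFrame(columns, index=df.index)
    neg = values.lt(0)
    if neg.any().any():
        col = neg.any().idxmax()
        gene = values.index[neg[col].to_numpy().argmax()]
        raise ValidationError(f"{path}: negative value at gene {gene!r}, sample {col!r}")
    if values.index.duplicated().any():
        dups = values.index[values.index.duplicated()].unique().tolist()
        logger.warning(
            "collapsing %d duplicated gene symbol(s) by max TPM: %s", len(dups), dups
        )
        values = values.groupby(level=0, sort=False).max()
    return ExpressionMatrix(values)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.df.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols, optionally weighted."""

    name: str
    genes: frozenset[str]
    weights: Optional[Mapping[str, float]] = None

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if self.weights is not None and set(self.weights) != set(self.genes):
            raise ValidationError(
                f"gene set {self.name!r}: weights must cover exactly the member genes"
            )

    def __len__(self) -> int:
        return len(self.genes)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets in GMT dialect: name <tab> description <tab> genes...

    The description field is discarded; duplicate genes within a line are
    deduplicated.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            name = fields[0].strip()
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            sets.append(GeneSet(name=name, genes=genes))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, description, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------


@dataclass
class CohortManifest:
    """Per-sample group labels and optional annotations."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        required = {"sample_id", "group"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValidationError(f"manifest missing required columns: {sorted(missing)}")
        if self.df["sample_id"].duplicated().any():
            dups = self.df.loc[self.df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids in manifest: {dups}")
        bad = set(self.df["group"]) - set(GROUPS)
        if bad:
            raise ValidationError(
                f"unknown group label(s) {sorted(bad)}; expected one of {GROUPS}"
            )
        self.df = self.df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    def groups(self) -> pd.Series:
        """Group label per sample, indexed by sample id."""
        return self.df.set_index("sample_id")["group"]

    def group_counts(self) -> dict[str, int]:
        return {g: int((self.df["group"] == g).sum()) for g in GROUPS}

    def samples_in(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ValidationError(f"unknown group {group!r}")
        return self.df.loc[self.df["group"] == group, "sample_id"].tolist()

    def __len__(self) -> int:
        return len(self.df)


def read_manifest(path: str | Path) -> CohortManifest:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "pdl1_positive" in df.columns:
        df["pdl1_positive"] = df["pdl1_positive"].map(
            {"True": True, "False": False, "true": True, "false": False, "": pd.NA}
        )
    return CohortManifest(df)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    df = manifest.df.copy()
    if "pdl1_positive" in df.columns:
        df["pdl1_positive"] = df["pdl1_positive"].map(
            lambda v: "" if pd.isna(v) else str(bool(v))
        )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationRecord:
    sample_id: str
    gene: str
    variant_class: str
    pathogenicity: str
    germline_flagged: bool = False

    def __post_init__(self):
        if self.variant_class not in VARIANT_CLASSES:
            raise ValidationError(
                f"unknown variant class {self.variant_class!r}; expected {VARIANT_CLASSES}"
            )
        if self.pathogenicity not in PATHOGENICITY_LEVELS:
            raise ValidationError(
                f"unknown pathogenicity {self.pathogenicity!r}; expected {PATHOGENICITY_LEVELS}"
            )


def read_mutations(path: str | Path) -> list[MutationRecord]:
    """Read a MAF-like TSV of somatic mutation calls."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "gene", "variant_class", "pathogenicity", "germline_flagged"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: mutation table missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        flag = str(row.germline_flagged).strip().lower()
        if flag not in ("true", "false"):
            raise ValidationError(
                f"{path}: germline_flagged must be True/False, got {row.germline_flagged!r}"
            )
        records.append(
            MutationRecord(
                sample_id=row.sample_id.strip(),
                gene=row.gene.strip(),
                variant_class=row.variant_class.strip(),
                pathogenicity=row.pathogenicity.strip(),
                germline_flagged=(flag == "true"),
            )
        )
    return records


def mutations_to_frame(records: Sequence[MutationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.sample_id, r.gene, r.variant_class, r.pathogenicity, r.germline_flagged)
            for r in records
        ],
        columns=["sample_id", "gene", "variant_class", "pathogenicity", "germline_flagged"],
    )


def write_mutations(records: Sequence[MutationRecord], path: str | Path) -> None:
    mutations_to_frame(records).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# HLA genotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HLAGenotype:
    sample_id: str
    locus: str
    allele1: str
    allele2: str

    def __post_init__(self):
        if self.locus not in HLA_LOCI:
            raise ValidationError(f"unknown HLA locus {self.locus!r}; expected {HLA_LOCI}")
        if not self.allele1 or not self.allele2:
            raise ValidationError(
                f"sample {self.sample_id!r} locus {self.locus}: both alleles required"
            )


def read_hla(path: str | Path) -> list[HLAGenotype]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "locus", "allele1", "allele2"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: HLA table missing columns {sorted(missing)}")
    return [
        HLAGenotype(
            sample_id=row.sample_id.strip(),
            locus=row.locus.strip(),
            allele1=row.allele1.strip(),
            allele2=row.allele2.strip(),
        )
        for row in df.itertuples(index=False)
    ]


def write_hla(genotypes: Sequence[HLAGenotype], path: str | Path) -> None:
    pd.DataFrame(
        [(g.sample_id, g.locus, g.allele1, g.allele2) for g in genotypes],
        columns=["sample_id", "locus", "allele1", "allele2"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Neoantigens
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NeoantigenRecord:
    sample_id: str
    peptide: str
    ic50: float  # nmol/L

    def __post_init__(self):
        if not (np.isfinite(self.ic50) and self.ic50 > 0):
            raise ValidationError(
                f"sample {self.sample_id!r} peptide {self.peptide!r}: "
                f"IC50 must be positive and finite, got {self.ic50}"
            )


def read_neoantigens(path: str | Path) -> list[NeoantigenRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "peptide", "ic50"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: neoantigen table missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        try:
            ic50 = float(row.ic50)
        except ValueError as exc:
            raise ValidationError(
                f"{path}: non-numeric IC50 {row.ic50!r} for sample {row.sample_id!r}"
            ) from exc
        records.append(
            NeoantigenRecord(sample_id=row.sample_id.strip(), peptide=row.peptide.strip(), ic50=ic50)
        )
    return records


def write_neoantigens(records: Sequence[NeoantigenRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.sample_id, r.peptide, r.ic50) for r in records],
        columns=["sample_id", "peptide", "ic50"],
    ).to_csv(path, sep="\t", index=False)
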