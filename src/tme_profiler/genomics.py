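"""Genomic features: TMB, pathogenicity filtering, mutation frequencies,
HLA homozygosity, and neoantigen affinity binning.

Conventions fixed here: only pathogenic / likely-pathogenic variants count as
"mutations" for frequency analyses; TMB counts non-synonymous missense
variants not flagged germline over a 1.4 MB sequencing footprint with a
high/low boundary at >= 10 mutations per MB; IC50 bins are lower-closed
half-open intervals at 50 / 500 / 5000 nmol/L.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import pandas as pd

from .cohort_io import (
    HLA_LOCI,
    CohortManifest,
    ConfigurationError,
    HLAGenotype,
    MutationRecord,
    NeoantigenRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

PATHOGENIC_LEVELS = ("pathogenic", "likely_pathogenic")

TMB_FOOTPRINT_MB = 1.4  # megabases sequenced per tumor (592-gene panel)
TMB_CUTOFF = 10.0  # mutations per MB; >= cutoff is TMB-high

NEOANTIGEN_BINS = ("high", "intermediate", "low", "none")
# lower-closed half-open bin edges in nmol/L
_BIN_EDGES = (50.0, 500.0, 5000.0)


@dataclass(frozen=True)
class TmbResult:
    sample_id: str
    count: int
    tmb: float  # mutations per MB
    tmb_class: str  # high | low


@dataclass(frozen=True)
class FrequencyResult:
    group: str
    gene: str
    k: int  # mutated samples
    n: int  # assessed samples
    pct: float  # 100*k/n, half-up to one decimal


def filter_pathogenic(records: Sequence[MutationRecord]) -> list[MutationRecord]:
    """Keep exactly pathogenic and likely-pathogenic records."""
    return [r for r in records if r.pathogenicity in PATHOGENIC_LEVELS]


def tmb(
    records: Sequence[MutationRecord],
    sample_ids: Optional[Sequence[str]] = None,
    footprint_mb: float = TMB_FOOTPRINT_MB,
    cutoff: float = TMB_CUTOFF,
) -> list[TmbResult]:
    """Tumor mutational burden per sample.

    Counts non-synonymous missense mutations not flagged germline;
    tmb = count / footprint_mb; class is "high" iff tmb >= cutoff (boundary
    is high). ``sample_ids`` fixes the samples reported (zero-count samples
    included); default is the samples appearing in ``records``.
    """
    if footprint_mb <= 0:
        raise ConfigurationError(f"footprint_mb must be > 0, got {footprint_mb}")
    counts: dict[str, int] = {}
    for r in records:
        if r.variant_class == "missense" and not r.germline_flagged:
            counts[r.sample_id] = counts.get(r.sample_id, 0) + 1
    if sample_ids is None:
        sample_ids = sorted({r.sample_id for r in records})
    out = []
    for sid in sample_ids:
        count = counts.get(sid, 0)
        value = count / footprint_mb
        out.append(TmbResult(sid, count, value, "high" if value >= cutoff else "low"))
    return out


def tmb_frame(results: Sequence[TmbResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.sample_id, r.count, r.tmb, r.tmb_class) for r in results],
        columns=["sample_id", "count", "tmb", "tmb_class"],
    )


def _round_pct(k: int, n: int) -> float:
    # half-up to one decimal, matching conventional percentage reporting
    return float((Decimal(100 * k) / Decimal(n)).quantize(Decimal("0.1"), ROUND_HALF_UP))


def mutation_frequency(
    records: Sequence[MutationRecord],
    manifest: CohortManifest,
    gene: str,
    group: str,
    assessed: Optional[Sequence[str]] = None,
) -> FrequencyResult:
    """Fraction of assessed samples in a group carrying a retained mutation.

    ``records`` should be pre-filtered by :func:`filter_pathogenic` (applied
    defensively here as well). ``assessed`` lists the samples with sequencing
    coverage for the gene; default is all samples in the group.
    """
    group_samples = set(manifest.samples_in(group))
    if assessed is None:
        assessed_set = group_samples
    else:
        assessed_set = set(assessed) & group_samples
    n = len(assessed_set)
    if n == 0:
        raise ValidationError(f"no assessed samples for {gene} in group {group}")
    retained = filter_pathogenic(records)
    mutated = {r.sample_id for r in retained if r.gene == gene} & assessed_set
    k = len(mutated)
    return FrequencyResult(group=group, gene=gene, k=k, n=n, pct=_round_pct(k, n))


def hla_homozygosity(
    genotypes: Sequence[HLAGenotype],
    loci: Sequence[str] = HLA_LOCI,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample per-locus homozygosity calls and per-locus cohort rates.

    A sample is homozygous at a locus iff its two alleles are string-equal
    after whitespace normalization. Samples missing a locus are excluded from
    that locus's denominator (logged).

    Returns (calls, rates): ``calls`` has one row per (sample, locus) with a
    boolean ``homozygous``; ``rates`` has per-locus n, homozygous count and
    percentage.
    """
    bad = set(loci) - set(HLA_LOCI)
    if bad:
        raise ValidationError(f"loci not among the assessed seven: {sorted(bad)}")
    rows = []
    for g in genotypes:
        if g.locus not in loci:
            continue
        rows.append({
            "sample_id": g.sample_id,
            "locus": g.locus,
            "homozygous": g.allele1.strip() == g.allele2.strip(),
        })
    calls = pd.DataFrame(rows, columns=["sample_id", "locus", "homozygous"])
    samples = calls["sample_id"].unique()
    rates = []
    for locus in loci:
        at_locus = calls[calls["locus"] == locus]
        missing = len(samples) - len(at_locus)
        if missing > 0:
            logger.warning("%d sample(s) missing locus %s excluded from denominator",
                           missing, locus)
        n = len(at_locus)
        k = int(at_locus["homozygous"].sum())
        rates.append({
            "locus": locus,
            "n": n,
            "homozygous": k,
            "pct": _round_pct(k, n) if n else float("nan"),
        })
    return calls, pd.DataFrame(rates)


def neoantigen_bin(ic50: float) -> str:
    """Affinity bin for an IC50 (nmol/L): [0,50) high, [50,500) intermediate,
    [500,5000) low, [5000,inf) none. Boundaries are lower-closed."""
    if not ic50 > 0:
        raise ValidationError(f"IC50 must be positive, got {ic50}")
    if ic50 < _BIN_EDGES[0]:
        return "high"
    if ic50 < _BIN_EDGES[1]:
        return "intermediate"
    if ic50 < _BIN_EDGES[2]:
        return "low"
    return "none"


def neoantigen_load(records: Sequence[NeoantigenRecord]) -> pd.DataFrame:
    """Count of neoantigens per affinity bin per sample (+ total)."""
    rows: dict[str, dict[str, int]] = {}
    for r in records:
        bins = rows.setdefault(r.sample_id, {b: 0 for b in NEOANTIGEN_BINS})
        bins[neoantigen_bin(r.ic50)] += 1
    out = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=list(NEOANTIGEN_BINS)
    ).fillna(0).astype(int)
    out.index.name = "sample_id"
    out["total"] = out.sum(axis=1)
    return out.sort_index()
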