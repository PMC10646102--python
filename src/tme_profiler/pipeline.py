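"""End-to-end orchestration: simulate or load a cohort, compute every score
and feature, run all group comparisons, and emit the report tables.

Each report table mirrors one analysis panel: per-sample signature scores and
classifications, immune-cell fractions, TMB, HLA homozygosity, neoantigen
loads, per-group Kruskal-Wallis/BH comparisons, driver mutation frequencies,
PTEN-mutant vs wild-type angiogenesis enrichment, metabolic-vs-immune
correlation matrices, and the MBM-vs-PCM differential expression table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__, datasets
from .cohort_io import (
    GROUPS,
    ConfigurationError,
    ValidationError,
    mutations_to_frame,
    read_expression,
    read_hla,
    read_manifest,
    read_mutations,
    read_neoantigens,
)
from .deconv import SignatureMatrix, deconvolve
from .enrichment import ssgsea
from .genomics import (
    TMB_CUTOFF,
    TMB_FOOTPRINT_MB,
    filter_pathogenic,
    hla_homozygosity,
    mutation_frequency,
    neoantigen_load,
    tmb,
    tmb_frame,
)
from .signatures import (
    SignatureDefinition,
    dysfunction_score,
    ifng_score,
    nonfunctional_cd8_classify,
    sting_score,
    tis_classify,
)
from .stats import correlation_matrix, deg, kruskal_bh, mann_whitney
from .synthetic import DRIVER_GENES, GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)

REPORT_TABLES = (
    "sample_scores.tsv",
    "immune_fractions.tsv",
    "tmb.tsv",
    "mutation_frequency.tsv",
    "hla_homozygosity.tsv",
    "neoantigen_load.tsv",
    "group_tests.tsv",
    "pten_angiogenesis.tsv",
    "metabolic_immune_correlation.tsv",
    "cytokine_immune_correlation.tsv",
    "deg_mbm_vs_pcm.tsv",
)

CYTOKINES = ("TNF", "IL12A", "IL12B")


@dataclass
class PipelineConfig:
    """Inputs, thresholds, and seed for one pipeline run.

    Exactly one of ``input_dir`` (a directory holding expression.tsv,
    manifest.tsv, mutations.tsv, hla.tsv, neoantigens.tsv and a deconvolution
    signature) or ``simulate`` must be provided.
    """

    input_dir: Optional[Path] = None
    signature_matrix: Optional[Path] = None  # required with input_dir
    simulate: Optional[GeneratorConfig] = None
    tmb_cutoff: float = TMB_CUTOFF
    tmb_footprint_mb: float = TMB_FOOTPRINT_MB
    tis_thresholds: Optional[tuple[float, float]] = None  # None -> tertiles
    dysfunction_cutoff: float = 1.0
    alpha: float = 0.05
    seed: int = 0
    out_dir: Path = Path("results")

    def validate(self) -> None:
        if (self.input_dir is None) == (self.simulate is None):
            raise ConfigurationError(
                "exactly one of input_dir or a simulate block must be provided"
            )
        if self.input_dir is not None and self.signature_matrix is None:
            raise ConfigurationError("input_dir requires a signature_matrix path")


def _config_hash(config: PipelineConfig) -> str:
    # out_dir is where the report lands, not part of the scientific config
    fields = {k: repr(v) for k, v in vars(config).items() if k != "out_dir"}
    blob = json.dumps(fields, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(config: PipelineConfig, write: bool = True) -> dict[str, pd.DataFrame]:
    """Run the full analysis; returns the report tables keyed by file name
    (without extension) and optionally writes them under ``config.out_dir``."""
    config.validate()

    # ------------------------------------------------------------------ load
    if config.simulate is not None:
        _stage("simulate")
        cohort = generate_cohort(config.simulate)
        expr, manifest = cohort.expression, cohort.manifest
        mutations, hla, neoantigens = cohort.mutations, cohort.hla, cohort.neoantigens
        sig_matrix = SignatureMatrix(cohort.reference_profiles)
    else:
        _stage("load")
        d = Path(config.input_dir)
        expr = read_expression(d / "expression.tsv")
        manifest = read_manifest(d / "manifest.tsv")
        mutations = read_mutations(d / "mutations.tsv")
        hla = read_hla(d / "hla.tsv")
        neoantigens = read_neoantigens(d / "neoantigens.tsv")
        sig_matrix = SignatureMatrix.read(config.signature_matrix)
    groups = manifest.groups().reindex(expr.samples)
    logger.info("cohort: %d samples (%s), %d genes", len(manifest),
                manifest.group_counts(), expr.shape[0])

    tables: dict[str, pd.DataFrame] = {}
    immune_sets = datasets.immune_signature_sets()
    toy_sets = datasets.toy_metabolic_sets()

    # ----------------------------------------------------------- deconvolve
    _stage("deconvolution")
    fractions = deconvolve(expr, sig_matrix)
    tables["immune_fractions"] = fractions.reset_index()

    # ---------------------------------------------------------------- scores
    _stage("signature scores")
    ifng = ifng_score(expr, SignatureDefinition("ifng", immune_sets["IFNG"]))
    tis_scores = ifng_score(expr, SignatureDefinition("tis", immune_sets["TIS"]))
    tis = tis_classify(tis_scores, config.tis_thresholds)
    dysf = dysfunction_score(expr)
    sting = sting_score(expr)
    fgfbp2 = expr.df.loc["FGFBP2"] if "FGFBP2" in expr.df.index else None
    if fgfbp2 is None:
        raise ValidationError("FGFBP2 absent from expression matrix")
    cd8_col = next((c for c in fractions.columns if "CD8" in c.upper()), None)
    if cd8_col is None:
        raise ValidationError("no CD8 T cell column in deconvolution output")
    nonfunc = nonfunctional_cd8_classify(
        dysf, fgfbp2, fractions[cd8_col], config.dysfunction_cutoff
    )
    scores = pd.DataFrame({
        "sample_id": expr.samples,
        "group": groups.to_numpy(),
        "ifng_score": ifng.to_numpy(),
        "tis_score": tis_scores.to_numpy(),
        "tis_class": tis.to_numpy(),
        "dysfunction_score": dysf.to_numpy(),
        "sting_score": sting.to_numpy(),
        "fgfbp2_tpm": fgfbp2.to_numpy(),
        "nonfunctional_cd8": nonfunc.to_numpy(),
    })
    tables["sample_scores"] = scores

    # -------------------------------------------------------------- genomics
    _stage("genomic features")
    tmb_results = tmb(mutations, sample_ids=manifest.sample_ids,
                      footprint_mb=config.tmb_footprint_mb, cutoff=config.tmb_cutoff)
    tmb_df = tmb_frame(tmb_results)
    tables["tmb"] = tmb_df

    pathogenic = filter_pathogenic(mutations)
    freq_rows = []
    for group in GROUPS:
        if not manifest.samples_in(group):
            continue
        for gene in DRIVER_GENES:
            r = mutation_frequency(pathogenic, manifest, gene, group)
            freq_rows.append({"group": r.group, "gene": r.gene, "k": r.k,
                              "n": r.n, "pct": r.pct})
    tables["mutation_frequency"] = pd.DataFrame(freq_rows)

    group_of = manifest.groups()
    homo_rows = []
    for group in GROUPS:
        members = set(manifest.samples_in(group))
        if not members:
            continue
        calls, rates = hla_homozygosity([g for g in hla if g.sample_id in members])
        rates.insert(0, "group", group)
        homo_rows.append(rates)
    tables["hla_homozygosity"] = pd.concat(homo_rows, ignore_index=True)

    load = neoantigen_load(neoantigens).reindex(manifest.sample_ids).fillna(0).astype(int)
    load.index.name = "sample_id"
    tables["neoantigen_load"] = load.reset_index()

    # ------------------------------------------------------------ enrichment
    _stage("ssGSEA")
    metabolic = ssgsea(expr, [toy_sets[k] for k in ("OXPHOS", "TCA", "GLYC")])
    angio = ssgsea(expr, [toy_sets["ANGIOGENESIS"]])["ANGIOGENESIS"]

    # ----------------------------------------------------------- group tests
    _stage("group comparisons")
    variables = pd.DataFrame({
        "ifng_score": ifng,
        "dysfunction_score": dysf,
        "sting_score": sting,
        "tmb": tmb_df.set_index("sample_id")["tmb"].reindex(expr.samples),
        "OXPHOS_ssgsea": metabolic["OXPHOS"],
        "TCA_ssgsea": metabolic["TCA"],
        "GLYC_ssgsea": metabolic["GLYC"],
    })
    for gene in CYTOKINES:
        if gene in expr.df.index:
            variables[f"{gene}_tpm"] = expr.df.loc[gene]
    for col in fractions.columns:
        variables[f"fraction_{col}"] = fractions[col]
    tables["group_tests"] = kruskal_bh(variables, group_of)

    # --------------------------------------------- PTEN-mut vs wt angiogenesis
    _stage("PTEN angiogenesis")
    mut_df = mutations_to_frame(pathogenic)
    pten_mut = set(mut_df.loc[mut_df["gene"] == "PTEN", "sample_id"])
    pten_rows = []
    for group in GROUPS:
        members = manifest.samples_in(group)
        if not members:
            continue
        scores_g = angio.reindex(members)
        is_mut = pd.Series([s in pten_mut for s in members], index=members)
        a = scores_g[is_mut].dropna()
        b = scores_g[~is_mut].dropna()
        if len(a) >= 2 and len(b) >= 2:
            stat, p = mann_whitney(a, b)
        else:
            stat, p = float("nan"), float("nan")
        pten_rows.append({
            "group": group,
            "n_mut": len(a),
            "n_wt": len(b),
            "median_angio_mut": float(a.median()) if len(a) else float("nan"),
            "median_angio_wt": float(b.median()) if len(b) else float("nan"),
            "mw_statistic": stat,
            "p": p,
        })
    tables["pten_angiogenesis"] = pd.DataFrame(pten_rows)

    # ------------------------------------------------- correlation matrices
    _stage("correlation matrices")
    imm_cols = [c for c in fractions.columns if c != "other"]
    met_rows, cyt_rows = [], []
    for group in GROUPS:
        members = manifest.samples_in(group)
        if len(members) < 4:
            continue
        cm = correlation_matrix(metabolic.reindex(members),
                                fractions.reindex(members)[imm_cols],
                                method="spearman", alpha=config.alpha)
        for xv in cm["rho"].index:
            for yv in cm["rho"].columns:
                met_rows.append({
                    "group": group, "pathway": xv, "cell_type": yv,
                    "rho": cm["rho"].loc[xv, yv], "p": cm["p"].loc[xv, yv],
                    "not_significant": bool(cm["mask"].loc[xv, yv]),
                })
        cyt = pd.DataFrame({g: expr.df.loc[g] for g in CYTOKINES if g in expr.df.index})
        cmc = correlation_matrix(cyt.reindex(members),
                                 fractions.reindex(members)[imm_cols],
                                 method="spearman", alpha=config.alpha)
        for xv in cmc["rho"].index:
            for yv in cmc["rho"].columns:
                cyt_rows.append({
                    "group": group, "cytokine": xv, "cell_type": yv,
                    "rho": cmc["rho"].loc[xv, yv], "p": cmc["p"].loc[xv, yv],
                    "not_significant": bool(cmc["mask"].loc[xv, yv]),
                })
    tables["metabolic_immune_correlation"] = pd.DataFrame(met_rows)
    tables["cytokine_immune_correlation"] = pd.DataFrame(cyt_rows)

    # -------------------------------------------------------------------- DEG
    _stage("differential expression")
    if manifest.samples_in("MBM") and manifest.samples_in("PCM"):
        tables["deg_mbm_vs_pcm"] = deg(expr, manifest, "MBM", "PCM", alpha=config.alpha)
    else:
        tables["deg_mbm_vs_pcm"] = pd.DataFrame(
            columns=["gene", "log2fc", "raw_p", "adj_p", "significant"]
        )

    # ------------------------------------------------------------------ write
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")
        run_manifest = {
            "tool": "tme-profiler",
            "version": __version__,
            "seed": int(config.seed),
            "config_hash": _config_hash(config),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "n_samples": len(manifest),
            "group_counts": manifest.group_counts(),
            "tables": sorted(f"{n}.tsv" for n in tables),
        }
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(run_manifest, fh, indent=2, sort_keys=True)
    return tables
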