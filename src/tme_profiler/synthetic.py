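"""Synthetic three-group melanoma cohort generator with planted effects.

Emulates the statistical structure the downstream analysis assumes: bulk
expression as a convex mixture of cell-type reference profiles (ten immune
types plus tumor) under multiplicative log-normal noise, group-specific
additive log2 shifts on named signature gene families, Bernoulli driver
mutations with group-specific probabilities, negative-binomial mutation
burdens, per-locus HLA homozygosity, and log-uniform neoantigen binding
affinities. Every table derives from a single master seed through spawned
child seeds, so adding a table never perturbs an existing one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import (
    GROUPS,
    HLA_LOCI,
    CohortManifest,
    ConfigurationError,
    ExpressionMatrix,
    GeneSet,
    HLAGenotype,
    MutationRecord,
    NeoantigenRecord,
    write_expression,
    write_hla,
    write_manifest,
    write_mutations,
    write_neoantigens,
)

# Ten immune cell types quantified by the deconvolution step, plus tumor.
IMMUNE_CELL_TYPES = (
    "B cells",
    "M1 macrophages",
    "M2 macrophages",
    "Monocytes",
    "Neutrophils",
    "NK cells",
    "CD4 T cells",
    "CD8 T cells",
    "Tregs",
    "mDC",
)
CELL_TYPES = IMMUNE_CELL_TYPES + ("tumor",)

MARKERS_PER_TYPE = 20

# Composite-score gene families. IFNG/TIS memberships follow the published
# anti-PD-1 response signatures (6-gene interferon-gamma preliminary set and
# 18-gene expanded T cell-inflamed set); the exhaustion and STING families are
# fixed by their definitions.
IFNG_SIGNATURE = ("IFNG", "STAT1", "IDO1", "CXCL9", "CXCL10", "HLA-DRA")
TIS_SIGNATURE = (
    "CCL5", "CD27", "CD274", "CD276", "CD8A", "CMKLR1", "CXCL9", "CXCR6",
    "HLA-DQA1", "HLA-DRB1", "HLA-E", "IDO1", "LAG3", "NKG7", "PDCD1LG2",
    "PSMB10", "STAT1", "TIGIT",
)
DYSFUNCTION_GENES = ("HAVCR2", "LAG3", "PDCD1")
STING_GENES = ("TMEM173", "CGAS", "CCL5", "CXCL10", "IRF3")
CYTOKINE_GENES = ("TNF", "IL12A", "IL12B")
ANGIO_REGULATORS = ("VEGFA", "STAT3", "AKT1", "PIK3CA", "CCL2")
OTHER_NAMED_GENES = ("FGFBP2",)

# Toy metabolic / angiogenesis gene-set families for enrichment analyses.
TOY_SETS = {
    "OXPHOS": tuple(f"OXPHOS_{i:02d}" for i in range(1, 21)),
    "TCA": tuple(f"TCA_{i:02d}" for i in range(1, 16)),
    "GLYC": tuple(f"GLYC_{i:02d}" for i in range(1, 16)),
    "ANGIOGENESIS": tuple(f"ANGIO_{i:02d}" for i in range(1, 21)),
}

# name -> genes targeted by a planted (group, signature) log2 shift
SHIFT_TARGETS: dict[str, tuple[str, ...]] = {
    "ifng": IFNG_SIGNATURE,
    "tis": TIS_SIGNATURE,
    "dysfunction": DYSFUNCTION_GENES,
    "sting": STING_GENES,
    "tnf": ("TNF",),
    "il12b": ("IL12B",),
    "oxphos": TOY_SETS["OXPHOS"],
    "tca": TOY_SETS["TCA"],
    "glyc": TOY_SETS["GLYC"],
}

DRIVER_GENES = ("BRAF", "NRAS", "NF1", "PTEN")

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _named_genes() -> list[str]:
    seen: list[str] = []
    for family in (
        IFNG_SIGNATURE, TIS_SIGNATURE, DYSFUNCTION_GENES, STING_GENES,
        CYTOKINE_GENES, ANGIO_REGULATORS, OTHER_NAMED_GENES,
        *TOY_SETS.values(),
    ):
        for g in family:
            if g not in seen:
                seen.append(g)
    return seen


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort.

    Defaults emulate the three-group melanoma cohort: 350 primary cutaneous
    (PCM), 94 brain metastases (MBM), 870 extracranial metastases (ECM), with
    the group-level effects the analysis is designed to detect (lower
    interferon-gamma/T cell-inflamed/STING expression and higher mutation
    burden, PTEN mutation rate, and oxidative metabolism in MBM).
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"PCM": 350, "MBM": 94, "ECM": 870}
    )
    seed: int = 0
    n_genes: int = 1000
    noise_sigma: float = 0.25  # SD of log2-scale multiplicative noise
    dirichlet_conc: Mapping[str, Sequence[float]] = field(default_factory=lambda: {
        # order follows CELL_TYPES; MBM depleted in B/M2/NK/Treg/mDC, higher M1
        "PCM": (2.0, 1.0, 2.0, 1.5, 1.5, 1.5, 2.0, 2.0, 1.5, 1.0, 16.0),
        "MBM": (0.8, 1.5, 1.2, 1.5, 1.5, 1.0, 2.0, 2.0, 0.8, 0.6, 16.0),
        "ECM": (1.6, 1.0, 1.6, 1.5, 1.5, 1.4, 2.0, 2.0, 1.3, 0.9, 16.0),
    })
    min_tumor_fraction: float = 0.3
    signature_shift: Mapping[tuple[str, str], float] = field(default_factory=lambda: {
        ("MBM", "ifng"): -1.0,
        ("MBM", "tis"): -1.0,
        ("MBM", "dysfunction"): 0.5,
        ("MBM", "sting"): -0.7,
        ("MBM", "tnf"): -1.0,
        ("MBM", "il12b"): -1.0,
        ("MBM", "oxphos"): 1.0,
        ("MBM", "tca"): 0.8,
        ("MBM", "glyc"): 0.4,
    })
    # extra log2 shift on angiogenesis genes + VEGFA/STAT3 in PTEN-mutant
    # samples of the named group
    pten_angiogenesis_shift: float = 0.8
    pten_angiogenesis_group: str = "MBM"
    mutation_prob: Mapping[tuple[str, str], float] = field(default_factory=lambda: {
        ("PCM", "BRAF"): 0.50, ("MBM", "BRAF"): 0.478, ("ECM", "BRAF"): 0.50,
        ("PCM", "NRAS"): 0.25, ("MBM", "NRAS"): 0.22, ("ECM", "NRAS"): 0.25,
        ("PCM", "NF1"): 0.15, ("MBM", "NF1"): 0.15, ("ECM", "NF1"): 0.15,
        ("PCM", "PTEN"): 0.081, ("MBM", "PTEN"): 0.163, ("ECM", "PTEN"): 0.060,
    })
    tmb_mean: Mapping[str, float] = field(
        default_factory=lambda: {"PCM": 9.0, "MBM": 14.0, "ECM": 9.0}
    )  # mutations per MB
    tmb_dispersion: float = 3.0  # negative-binomial size parameter
    footprint_mb: float = 1.4
    homozygosity_prob: Mapping[str, float] = field(
        default_factory=lambda: {locus: 0.15 for locus in HLA_LOCI}
    )
    ic50_log10_range: tuple[float, float] = (0.5, 4.5)
    neoantigens_per_mutation: float = 2.0
    pdl1_positive_prob: float = 0.3

    def validate(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ConfigurationError(f"unknown group {g!r}")
            if n < 1:
                raise ConfigurationError(f"group {g}: count must be >= 1, got {n}")
        if self.n_genes < 10 * len(CELL_TYPES):
            raise ConfigurationError(
                f"n_genes must be >= {10 * len(CELL_TYPES)} "
                f"(10 per cell type), got {self.n_genes}"
            )
        for g, conc in self.dirichlet_conc.items():
            if len(conc) != len(CELL_TYPES):
                raise ConfigurationError(
                    f"group {g}: Dirichlet concentration needs {len(CELL_TYPES)} entries"
                )
            if any(c <= 0 for c in conc):
                raise ConfigurationError(f"group {g}: Dirichlet concentrations must be > 0")
        for key, p in {**dict(self.mutation_prob),
                       **{(l, ""): p for l, p in self.homozygosity_prob.items()}}.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability out of [0,1] for {key}: {p}")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if not 0.0 <= self.min_tumor_fraction < 1.0:
            raise ConfigurationError("min_tumor_fraction must be in [0, 1)")
        lo, hi = self.ic50_log10_range
        if not lo < hi:
            raise ConfigurationError("ic50_log10_range must be increasing")


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator."""

    true_fractions: pd.DataFrame  # samples x cell types, rows sum to 1
    true_group_shifts: dict[tuple[str, str], float]
    true_mutants: set[tuple[str, str]]  # (sample_id, gene)


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    manifest: CohortManifest
    mutations: list[MutationRecord]
    hla: list[HLAGenotype]
    neoantigens: list[NeoantigenRecord]
    truth: SyntheticTruth
    reference_profiles: pd.DataFrame  # genes x cell types, TPM per column


def gene_universe(n_genes: int) -> tuple[list[str], dict[str, list[str]]]:
    """Gene symbols for a universe of ``n_genes``: disjoint cell-type marker
    blocks first, then the named signature genes, then background filler.

    Returns (all genes, cell type -> marker genes).
    """
    markers: dict[str, list[str]] = {}
    genes: list[str] = []
    for t, cell_type in enumerate(CELL_TYPES):
        tag = "".join(ch for ch in cell_type.upper() if ch.isalnum())
        block = [f"{tag}_MK{i:02d}" for i in range(1, MARKERS_PER_TYPE + 1)]
        markers[cell_type] = block
        genes.extend(block)
    named = _named_genes()
    genes.extend(named)
    if len(genes) > n_genes:
        raise ConfigurationError(
            f"n_genes={n_genes} too small; need >= {len(genes)} for markers "
            f"and named signature genes"
        )
    genes.extend(f"BG_{i:04d}" for i in range(1, n_genes - len(genes) + 1))
    return genes, markers


def generate_reference_profiles(config: GeneratorConfig) -> pd.DataFrame:
    """Cell-type mean expression profiles (genes x cell types, TPM columns).

    Background expression is log-normal; each cell type's disjoint marker
    block sits 3 log2 units above background. Columns are TPM-normalized
    (sum 1e6). Deterministic given the config seed.
    """
    config.validate()
    genes, markers = gene_universe(config.n_genes)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 101]))
    base = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=(len(genes), len(CELL_TYPES)))
    profiles = pd.DataFrame(base, index=genes, columns=list(CELL_TYPES))
    for cell_type in CELL_TYPES:
        profiles.loc[markers[cell_type], cell_type] *= 2.0 ** 3
    profiles = profiles / profiles.sum(axis=0) * 1e6
    return profiles


def marker_gene_map(config: GeneratorConfig) -> dict[str, list[str]]:
    return gene_universe(config.n_genes)[1]


def toy_genesets() -> list[GeneSet]:
    """The packaged toy OXPHOS/TCA/GLYC/ANGIOGENESIS gene-set family."""
    return [GeneSet(name=k, genes=frozenset(v)) for k, v in TOY_SETS.items()]


def _sample_ids(config: GeneratorConfig) -> list[tuple[str, str]]:
    out = []
    for group in GROUPS:
        n = config.n_per_group.get(group, 0)
        out.extend((f"{group}_{i:04d}", group) for i in range(1, n + 1))
    return out


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate the full labeled cohort with planted effects."""
    config.validate()
    master = np.random.SeedSequence([int(config.seed), 7])
    (ss_frac, ss_noise, ss_mut, ss_hla, ss_neo, ss_manifest) = master.spawn(6)

    profiles = generate_reference_profiles(config)
    genes = profiles.index.tolist()
    ids_groups = _sample_ids(config)
    sample_ids = [s for s, _ in ids_groups]
    group_of = {s: g for s, g in ids_groups}

    # --- mixing fractions -------------------------------------------------
    rng = np.random.default_rng(ss_frac)
    fractions = np.empty((len(sample_ids), len(CELL_TYPES)))
    for i, (sid, group) in enumerate(ids_groups):
        f = rng.dirichlet(np.asarray(config.dirichlet_conc[group], dtype=float))
        tumor_ix = len(CELL_TYPES) - 1
        if f[tumor_ix] < config.min_tumor_fraction:
            scale = (1.0 - config.min_tumor_fraction) / (1.0 - f[tumor_ix])
            f = f * scale
            f[tumor_ix] = config.min_tumor_fraction
        fractions[i] = f / f.sum()
    true_fractions = pd.DataFrame(fractions, index=sample_ids, columns=list(CELL_TYPES))

    # --- mutations (before expression: PTEN status feeds angiogenesis) ---
    rng = np.random.default_rng(ss_mut)
    mutations: list[MutationRecord] = []
    true_mutants: set[tuple[str, str]] = set()
    filler_genes = [g for g in genes if g.startswith("BG_")]
    for sid, group in ids_groups:
        n_driver = 0
        for gene in DRIVER_GENES:
            p = config.mutation_prob.get((group, gene), 0.0)
            if rng.random() < p:
                mutations.append(
                    MutationRecord(sid, gene, "missense", "pathogenic", False)
                )
                true_mutants.add((sid, gene))
                n_driver += 1
        mean_count = config.tmb_mean[group] * config.footprint_mb
        r = config.tmb_dispersion
        count = int(rng.negative_binomial(r, r / (r + mean_count)))
        for _ in range(max(0, count - n_driver)):
            gene = filler_genes[rng.integers(len(filler_genes))]
            mutations.append(MutationRecord(sid, gene, "missense", "VUS", False))
        # non-qualifying records exercising downstream filters
        if rng.random() < 0.3:
            gene = filler_genes[rng.integers(len(filler_genes))]
            mutations.append(MutationRecord(sid, gene, "missense", "VUS", True))
        if rng.random() < 0.3:
            gene = filler_genes[rng.integers(len(filler_genes))]
            mutations.append(MutationRecord(sid, gene, "synonymous", "benign", False))

    # --- expression -------------------------------------------------------
    rng = np.random.default_rng(ss_noise)
    expr = profiles.to_numpy() @ fractions.T  # genes x samples, sums to 1e6
    log2_shift = np.zeros_like(expr)
    gene_ix = {g: i for i, g in enumerate(genes)}
    for (group, sig_name), shift in config.signature_shift.items():
        targets = SHIFT_TARGETS.get(sig_name)
        if targets is None:
            raise ConfigurationError(
                f"unknown signature {sig_name!r}; known: {sorted(SHIFT_TARGETS)}"
            )
        rows = [gene_ix[g] for g in targets]
        cols = [j for j, (sid, g) in enumerate(ids_groups) if g == group]
        log2_shift[np.ix_(rows, cols)] += shift
    if config.pten_angiogenesis_shift:
        targets = list(TOY_SETS["ANGIOGENESIS"]) + ["VEGFA", "STAT3"]
        rows = [gene_ix[g] for g in targets]
        cols = [
            j for j, (sid, g) in enumerate(ids_groups)
            if g == config.pten_angiogenesis_group and (sid, "PTEN") in true_mutants
        ]
        if cols:
            log2_shift[np.ix_(rows, cols)] += config.pten_angiogenesis_shift
    expr = expr * 2.0 ** log2_shift
    if config.noise_sigma > 0:
        expr = expr * 2.0 ** rng.normal(0.0, config.noise_sigma, size=expr.shape)
    expr = expr / expr.sum(axis=0) * 1e6  # re-establish TPM normalization
    expression = ExpressionMatrix(pd.DataFrame(expr, index=genes, columns=sample_ids))

    # --- HLA ---------------------------------------------------------------
    rng = np.random.default_rng(ss_hla)
    allele_pools = {
        locus: [f"{locus.removeprefix('HLA-')}*{i:02d}:01" for i in range(1, 13)]
        for locus in HLA_LOCI
    }
    hla: list[HLAGenotype] = []
    for sid, group in ids_groups:
        for locus in HLA_LOCI:
            pool = allele_pools[locus]
            a1 = pool[rng.integers(len(pool))]
            if rng.random() < config.homozygosity_prob[locus]:
                a2 = a1
            else:
                a2 = a1
                while a2 == a1:
                    a2 = pool[rng.integers(len(pool))]
            hla.append(HLAGenotype(sid, locus, a1, a2))

    # --- neoantigens --------------------------------------------------------
    rng = np.random.default_rng(ss_neo)
    qualifying = {}
    for m in mutations:
        if m.variant_class == "missense" and not m.germline_flagged:
            qualifying[m.sample_id] = qualifying.get(m.sample_id, 0) + 1
    lo, hi = config.ic50_log10_range
    neoantigens: list[NeoantigenRecord] = []
    aa = np.array(list(_AA))
    for sid, group in ids_groups:
        lam = config.neoantigens_per_mutation * qualifying.get(sid, 0) + 1.0
        n = int(rng.poisson(lam))
        for _ in range(n):
            peptide = "".join(aa[rng.integers(len(aa), size=9)])
            ic50 = float(10.0 ** rng.uniform(lo, hi))
            neoantigens.append(NeoantigenRecord(sid, peptide, ic50))

    # --- manifest -----------------------------------------------------------
    rng = np.random.default_rng(ss_manifest)
    manifest = CohortManifest(pd.DataFrame({
        "sample_id": sample_ids,
        "group": [group_of[s] for s in sample_ids],
        "pdl1_positive": [bool(rng.random() < config.pdl1_positive_prob)
                          for _ in sample_ids],
        "sex": [("M" if rng.random() < 0.617 else "F") for _ in sample_ids],
        "age_band": [("<67" if rng.random() < 0.489 else ">=67") for _ in sample_ids],
    }))

    truth = SyntheticTruth(
        true_fractions=true_fractions,
        true_group_shifts=dict(config.signature_shift),
        true_mutants=true_mutants,
    )
    return SyntheticCohort(
        expression=expression,
        manifest=manifest,
        mutations=mutations,
        hla=hla,
        neoantigens=neoantigens,
        truth=truth,
        reference_profiles=profiles,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write all cohort artifacts plus truth tables as TSV; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "manifest": outdir / "manifest.tsv",
        "mutations": outdir / "mutations.tsv",
        "hla": outdir / "hla.tsv",
        "neoantigens": outdir / "neoantigens.tsv",
        "reference_profiles": outdir / "reference_profiles.tsv",
        "truth_fractions": outdir / "truth_fractions.tsv",
        "truth_mutants": outdir / "truth_mutants.tsv",
    }
    write_expression(cohort.expression, paths["expression"])
    write_manifest(cohort.manifest, paths["manifest"])
    write_mutations(cohort.mutations, paths["mutations"])
    write_hla(cohort.hla, paths["hla"])
    write_neoantigens(cohort.neoantigens, paths["neoantigens"])
    ref = cohort.reference_profiles.copy()
    ref.index.name = "gene"
    ref.to_csv(paths["reference_profiles"], sep="\t", float_format="%.6g")
    tf = cohort.truth.true_fractions.copy()
    tf.index.name = "sample_id"
    tf.to_csv(paths["truth_fractions"], sep="\t", float_format="%.9g")
    pd.DataFrame(sorted(cohort.truth.true_mutants), columns=["sample_id", "gene"]).to_csv(
        paths["truth_mutants"], sep="\t", index=False
    )
    return paths
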