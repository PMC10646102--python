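#!/usr/bin/env python
"""Genomic features: TMB, driver mutation frequencies, HLA homozygosity,
and neoantigen affinity loads, per group.
"""

import argparse
from pathlib import Path

import pandas as pd

from tme_profiler.cohort_io import (
    GROUPS,
    read_hla,
    read_manifest,
    read_mutations,
    read_neoantigens,
)
from tme_profiler.genomics import (
    filter_pathogenic,
    hla_homozygosity,
    mutation_frequency,
    neoantigen_load,
    tmb,
    tmb_frame,
)
from tme_profiler.synthetic import DRIVER_GENES


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--out", type=Path, default=Path("results/tables"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    manifest = read_manifest(args.cohort / "manifest.tsv")
    mutations = read_mutations(args.cohort / "mutations.tsv")
    hla = read_hla(args.cohort / "hla.tsv")
    neoantigens = read_neoantigens(args.cohort / "neoantigens.tsv")

    tmb_df = tmb_frame(tmb(mutations, sample_ids=manifest.sample_ids))
    tmb_df.to_csv(args.out / "tmb.tsv", sep="\t", index=False, float_format="%.6g")
    tmb_df["group"] = manifest.groups().reindex(tmb_df["sample_id"]).to_numpy()
    high_pct = tmb_df.groupby("group")["tmb_class"].apply(
        lambda s: 100 * (s == "high").mean())
    print("TMB-high percentage: "
          + ", ".join(f"{g}={high_pct[g]:.1f}%" for g in GROUPS))

    pathogenic = filter_pathogenic(mutations)
    rows = []
    for group in GROUPS:
        for gene in DRIVER_GENES:
            r = mutation_frequency(pathogenic, manifest, gene, group)
            rows.append({"group": group, "gene": gene, "k": r.k, "n": r.n, "pct": r.pct})
    freq = pd.DataFrame(rows)
    freq.to_csv(args.out / "mutation_frequency.tsv", sep="\t", index=False)
    pten = freq[freq["gene"] == "PTEN"].set_index("group")["pct"]
    print("pathogenic PTEN mutation rate: "
          + ", ".join(f"{g}={pten[g]:.1f}%" for g in GROUPS))

    homo = []
    for group in GROUPS:
        members = set(manifest.samples_in(group))
        _, rates = hla_homozygosity([g for g in hla if g.sample_id in members])
        rates.insert(0, "group", group)
        homo.append(rates)
    pd.concat(homo, ignore_index=True).to_csv(
        args.out / "hla_homozygosity.tsv", sep="\t", index=False)

    load = neoantigen_load(neoantigens)
    load.to_csv(args.out / "neoantigen_load.tsv", sep="\t")
    print(f"neoantigen load table: {len(load)} samples, "
          f"median total {load['total'].median():.0f} peptides")


if __name__ == "__main__":
    main()
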