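#!/usr/bin/env python
"""Composite signature scores and T cell-inflamed classification per sample.

Reads the cohort written by 01_simulate_cohort.py, computes the
interferon-gamma score, T cell-inflamed class, T cell dysfunction score, and
STING score, and compares them across PCM / MBM / ECM with Kruskal-Wallis +
Benjamini-Hochberg.
"""

import argparse
from pathlib import Path

import pandas as pd

from tme_profiler.cohort_io import read_expression, read_manifest
from tme_profiler.datasets import immune_signature_sets
from tme_profiler.signatures import (
    SignatureDefinition,
    dysfunction_score,
    ifng_score,
    sting_score,
    tis_classify,
)
from tme_profiler.stats import kruskal_bh


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--out", type=Path, default=Path("results/tables"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    expr = read_expression(args.cohort / "expression.tsv")
    manifest = read_manifest(args.cohort / "manifest.tsv")
    sets = immune_signature_sets()

    ifng = ifng_score(expr, SignatureDefinition("ifng", sets["IFNG"]))
    tis_s = ifng_score(expr, SignatureDefinition("tis", sets["TIS"]))
    scores = pd.DataFrame({
        "sample_id": expr.samples,
        "group": manifest.groups().reindex(expr.samples).to_numpy(),
        "ifng_score": ifng.to_numpy(),
        "tis_score": tis_s.to_numpy(),
        "tis_class": tis_classify(tis_s).to_numpy(),
        "dysfunction_score": dysfunction_score(expr).to_numpy(),
        "sting_score": sting_score(expr).to_numpy(),
    })
    scores.to_csv(args.out / "sample_scores.tsv", sep="\t", index=False,
                  float_format="%.6g")

    tests = kruskal_bh(
        scores.set_index("sample_id")[["ifng_score", "dysfunction_score", "sting_score"]],
        manifest.groups(),
    )
    tests.to_csv(args.out / "signature_group_tests.tsv", sep="\t", index=False,
                 float_format="%.4g")

    med = scores.groupby("group")["ifng_score"].median()
    print("median IFNg score: "
          + ", ".join(f"{g}={med[g]:.3f}" for g in ("PCM", "MBM", "ECM")))
    tis_pct = (scores.groupby("group")["tis_class"]
               .apply(lambda s: 100 * (s == "TIS_pos").mean()))
    print("TIS(+) percentage: "
          + ", ".join(f"{g}={tis_pct[g]:.1f}%" for g in ("PCM", "MBM", "ECM")))
    for _, row in tests.iterrows():
        print(f"{row['variable']}: KW H={row['statistic']:.2f}, "
              f"adjusted p={row['adj_p']:.3g}")


if __name__ == "__main__":
    main()
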