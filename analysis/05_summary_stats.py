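#!/usr/bin/env python
"""Length/GC contrasts, insertion-site logos and the feature bubble matrix.

Compares intron length and GC content across lineages (IIA-RT/M, IIB-RT/M,
IIB-LHE, IIB-like) with a two-way ANOVA (lineage x organelle is degenerate
for a single-compartment cohort, so the organelle factor reduces away) and
Tukey HSD on lineage cells; builds insertion-site sequence logos from
flanking windows; and writes the family-by-feature bubble matrix.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _cohort_config import COHORT_DIR

from intronscape.io import load_cohort
from intronscape.stats import bubble_matrix, insertion_site_logo, two_way_anova_tukey

FEATURES = "results/features_mt.tsv"


def lineage(row) -> str:
    if row.subgroup.startswith("IIA"):
        return "IIA-RTM"
    if row.subgroup == "IIB-like":
        return "IIB-like"
    return "IIB-LHE" if row.iep_type == "LHE" else "IIB-RTM"


def main() -> None:
    if not Path(FEATURES).exists():
        sys.exit("run analysis/02_annotate_structures.py first")
    df = pd.read_csv(FEATURES, sep="\t")
    truth = load_cohort(COHORT_DIR).truth.set_index("intron_id")
    df["lineage"] = [
        lineage(truth.loc[i]) for i in df.intron_id
    ]

    summary = df.groupby("lineage").agg(
        n=("length", "size"), mean_length_nt=("length", "mean"), mean_gc_pct=("gc_pct", "mean")
    ).round(1)
    print(summary.to_string())
    summary.to_csv("results/lineage_summary_mt.tsv", sep="\t")

    # single-compartment cohort: the organelle factor has one level
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res_len = two_way_anova_tukey(df.length, df.lineage, ["mt"] * len(df))
        res_gc = two_way_anova_tukey(df.gc_pct, df.lineage, ["mt"] * len(df))
    res_len.anova.to_csv("results/anova_length_mt.tsv", sep="\t", index=False)
    res_gc.anova.to_csv("results/anova_gc_mt.tsv", sep="\t", index=False)
    if res_len.tukey is not None:
        res_len.tukey.to_csv("results/tukey_length_mt.tsv", sep="\t", index=False)
    p_len = res_len.anova.set_index("effect")["PR(>F)"].iloc[0]
    p_gc = res_gc.anova.set_index("effect")["PR(>F)"].iloc[0]
    print(f"lineage effect on length: p = {p_len:.2e}; on GC: p = {p_gc:.2e}")

    # insertion-site logo for the most abundant family
    data = load_cohort(COHORT_DIR)
    top = df.family.value_counts().idxmax()
    wins = [
        r.upstream_flank[-20:] + r.downstream_flank[:20]
        for r in data.introns
        if truth.loc[r.id, "family"] == top
        and len(r.upstream_flank) >= 20 and len(r.downstream_flank) >= 20
    ]
    lp = insertion_site_logo(wins)
    logo = lp.frequencies.copy()
    logo["information_bits"] = lp.information
    logo.to_csv(f"results/logo_{top}.tsv", sep="\t")
    print(f"insertion-site logo for {top} ({lp.n} members): "
          f"mean IC {lp.information.mean():.2f} bits -> results/logo_{top}.tsv")

    # bubble matrix over structural features
    feats = ["branchpoint", "three_prime_AY", "Ia", "IC2", "ID2", "ID2a", "IE", "DIIIa"]
    bm_input = df.assign(branchpoint=df.branchpoint == "present").assign(
        ebs2=df.ebs2 == "found"
    )
    bm = bubble_matrix(bm_input, feats + ["ebs2"])
    bm.to_csv("results/bubble_matrix_mt.tsv", sep="\t")
    print(f"bubble matrix: {bm.shape[0]} families x {len(feats) + 1} features "
          "-> results/bubble_matrix_mt.tsv")


if __name__ == "__main__":
    main()
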