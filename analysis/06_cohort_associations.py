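"""Step 6 — cohort statistics and figures.

Runs the full association battery on the per-sample summaries: the paired
expanded-vs-wild-type methylation contrast, methylation-length and
methylation-age correlations, the promoter-methylation coupling, the
symptomatic-vs-presymptomatic contrast before and after age adjustment,
longitudinal stability and familial transmission classifications, and the
blood-vs-cerebellum contrasts. Writes tidy TSVs and summary figures.

Usage: python analysis/06_cohort_associations.py [--results results]
"""

import argparse
from pathlib import Path

import pandas as pd

from c9meth import run_association_battery
from c9meth.io import read_fixture


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", default="results")
    args = ap.parse_args()
    res = Path(args.results)

    cohort = read_fixture(res / "fixture")
    sample_meth = pd.read_csv(res / "sample_methylation.tsv", sep="\t")
    sample_repeats = pd.read_csv(res / "sample_repeats.tsv", sep="\t")

    out = run_association_battery(sample_meth, sample_repeats, cohort.meta)
    out["associations"].to_csv(res / "associations.tsv", sep="\t", index=False)
    out["longitudinal"].to_csv(res / "longitudinal.tsv", sep="\t", index=False)
    out["familial"].to_csv(res / "familial.tsv", sep="\t", index=False)

    a = out["associations"].set_index("statistic_name")
    headline = [
        "expanded_vs_wt_prop_methylated",
        "prop_methylated_vs_max_repeats",
        "prop_methylated_vs_age",
        "prop_methylated_vs_promoter_methylation",
        "prop_methylated_group_unadjusted",
        "prop_methylated_group_adjusted[group]",
        "max_repeats_vs_age",
        "motif_fraction_vs_max_repeats",
    ]
    print(f"{'statistic':45s} {'estimate':>9s} {'p':>10s}  n")
    for name in headline:
        if name in a.index:
            row = a.loc[name]
            print(f"{name:45s} {row['estimate']:9.3f} {row['p_value']:10.3g} "
                  f"{int(row['n']):3d}")

    lg = out["longitudinal"]["classification"].value_counts().to_dict()
    fm = out["familial"]["classification"].value_counts().to_dict()
    print(f"longitudinal: {lg}")
    print(f"familial transmissions: {fm}")

    # figures
    from c9meth import plots

    meta = cohort.meta
    blood0 = meta[(meta["tissue"] == "blood") & (meta["timepoint_years"] == 0)]
    me = sample_meth[(sample_meth["allele"] == "expanded")
                     & sample_meth["sample_id"].isin(blood0["sample_id"])]
    me = me.merge(meta, on="sample_id")
    re_ = sample_repeats[(sample_repeats["allele"] == "expanded")
                         & sample_repeats["sample_id"].isin(blood0["sample_id"])]
    joint = me.merge(re_[["sample_id", "max_repeats"]], on="sample_id")
    plots.allele_boxplot(
        sample_meth[sample_meth["sample_id"].isin(blood0["sample_id"])],
        "median_prop_methylated", res / "allele_prop_boxplot.png",
        ylabel="median proportion methylated")
    plots.scatter_with_fit(joint["max_repeats"], joint["median_prop_methylated"],
                           res / "meth_vs_length.png", "max repeats",
                           "median proportion methylated")
    plots.scatter_with_fit(me["age_at_collection"], me["median_prop_methylated"],
                           res / "meth_vs_age.png", "age at collection (years)",
                           "median proportion methylated")
    if len(out["familial"]):
        plots.pedigree_barplot(out["familial"], res / "pedigrees.png")
    print("figures written to", res)


if __name__ == "__main__":
    main()
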