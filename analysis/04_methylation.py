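"""Step 4 — per-read and per-sample CpG methylation.

Per read: median 5mC score and the proportion of CpGs with score >= 128
(the top half of the 0-255 scale). Per sample and allele: median of per-read
medians, median proportion, and the within-sample min-max range. Also writes
the main-vs-alternate cutoff comparison (>= 128 vs > 75% of the scale) and a
waterfall matrix for the deepest sample.

Usage: python analysis/04_methylation.py [--results results]
"""

import argparse
from pathlib import Path

import pandas as pd

from c9meth import summarize_reads, summarize_sample, waterfall_matrix
from c9meth.io import read_fixture
from c9meth.methylation import compare_thresholds


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", default="results")
    args = ap.parse_args()
    res = Path(args.results)

    cohort = read_fixture(res / "fixture")
    reads = pd.read_csv(res / "reads_methylation_purity.tsv", sep="\t")
    alleles = pd.read_csv(res / "alleles_methylation_purity.tsv", sep="\t")
    cpg = cohort.cpg[cohort.cpg["read_id"].isin(reads["read_id"])]

    read_meth = summarize_reads(cpg, alleles)
    read_meth = read_meth.merge(reads[["read_id", "sample_id"]], on="read_id")
    read_meth.to_csv(res / "read_methylation.tsv", sep="\t", index=False)

    sample_meth = summarize_sample(read_meth)
    sample_meth.to_csv(res / "sample_methylation.tsv", sep="\t", index=False)

    for allele, grp in sample_meth.groupby("allele"):
        med = grp["median_prop_methylated"].median()
        print(f"{allele:>10}: median proportion methylated {med:.1%} "
              f"(range {grp['median_prop_methylated'].min():.1%}-"
              f"{grp['median_prop_methylated'].max():.1%} across samples)")

    thr = compare_thresholds(cpg, reads, alleles)
    thr["table"].to_csv(res / "threshold_comparison.tsv", sep="\t", index=False)
    for allele, r in thr["spearman"].items():
        if r is not None:
            print(f"cutoff agreement ({allele}): Spearman r = {r.estimate:.3f}")

    deepest = sample_meth.sort_values("n_reads", ascending=False)["sample_id"].iloc[0]
    ids = reads.loc[reads["sample_id"] == deepest, "read_id"]
    mat = waterfall_matrix(cpg[cpg["read_id"].isin(ids)])
    mat.to_csv(res / "waterfall_deepest_sample.tsv", sep="\t")
    print(f"waterfall matrix for {deepest}: {mat.shape[0]} reads x "
          f"{mat.shape[1]} CpG columns")


if __name__ == "__main__":
    main()
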