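"""Step 5 — repeat length and sequence purity.

Length per read is the span from the first to the last exact GGGGCC
occurrence divided by six; the per-sample maximum is the primary length
estimate (the convention most consistent with Southern blotting) and the
min-max range measures somatic mosaicism. Purity (GC fraction and the
fraction of the tract covered by exact motif copies) is computed on the
stringent QC branch, length on the permissive branch.

Usage: python analysis/05_repeat_length_purity.py [--results results]
"""

import argparse
from pathlib import Path

import pandas as pd

from c9meth import measure_reads
from c9meth.io import read_fixture
from c9meth.repeats import summarize_sample_repeats


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", default="results")
    args = ap.parse_args()
    res = Path(args.results)

    read_fixture(res / "fixture")  # validates the fixture is intact
    summaries = {}
    for branch in ("length", "methylation_purity"):
        reads = pd.read_csv(res / f"reads_{branch}.tsv", sep="\t")
        alleles = pd.read_csv(res / f"alleles_{branch}.tsv", sep="\t")
        meas = measure_reads(reads, alleles)
        motif_free = meas.attrs["motif_free_reads"]  # merge() drops attrs
        meas = meas.merge(reads[["read_id", "sample_id"]], on="read_id")
        name = "repeat_measurements" if branch == "length" else "purity_measurements"
        meas.to_csv(res / f"{name}.tsv", sep="\t", index=False)
        if motif_free:
            print(f"branch {branch}: {len(motif_free)} motif-free reads excluded")
        summaries[branch] = summarize_sample_repeats(meas)

    # merged per-sample table: length from the permissive branch, purity from
    # the stringent branch
    sample_repeats = summaries["length"].drop(
        columns=["median_gc", "median_motif_fraction"]
    ).merge(
        summaries["methylation_purity"][
            ["sample_id", "allele", "median_gc", "median_motif_fraction"]],
        on=["sample_id", "allele"], how="left",
    )
    sample_repeats.to_csv(res / "sample_repeats.tsv", sep="\t", index=False)

    exp = sample_repeats[sample_repeats["allele"] == "expanded"]
    print(f"expanded alleles: max repeats {exp['max_repeats'].min()}"
          f"-{exp['max_repeats'].max()} across samples "
          f"(median {exp['max_repeats'].median():.0f})")
    print(f"median within-sample length range: {exp['range_repeats'].median():.0f} units")
    print(f"median motif purity: {exp['median_motif_fraction'].median():.1%}; "
          f"median GC: {exp['median_gc'].median():.1%}")


if __name__ == "__main__":
    main()
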