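"""Step 2 — consensus-read QC, two parallel profiles.

Applies the stringent profile (>=7 passes, >=0.99 predicted accuracy; used
for methylation and sequence-purity analyses) and the permissive profile
(>=1 pass, >=0.80 accuracy; used for repeat-length analysis). Both require
10 bp-100 kb reads spanning both locus flanks. Writes the kept-read tables
and per-read QC reports under results/.

Usage: python analysis/02_qc_filtering.py [--results results]
"""

import argparse
from pathlib import Path

from c9meth import filter_reads
from c9meth.filtering import PROFILES
from c9meth.io import read_fixture


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", default="results")
    args = ap.parse_args()
    res = Path(args.results)

    cohort = read_fixture(res / "fixture")
    print(f"{len(cohort.reads)} input reads")
    for name, profile in sorted(PROFILES.items()):
        kept, report = filter_reads(cohort.reads, profile, return_report=True)
        kept.to_csv(res / f"reads_{name}.tsv", sep="\t", index=False)
        report.to_csv(res / f"qc_report_{name}.tsv", sep="\t", index=False)
        print(f"profile {name}: kept {len(kept)}/{len(cohort.reads)} "
              f"({len(kept) / len(cohort.reads):.1%})")
        failed = report[~report["kept"]]
        if len(failed):
            top = failed["fail_reasons"].value_counts().head(3)
            for reason, n in top.items():
                print(f"    {n:4d} failed: {reason}")


if __name__ == "__main__":
    main()
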