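"""End-to-end orchestration.

Stage order follows the two parallel QC branches of the analysis design:

* stringent branch — filter (>=7 passes, >=0.99 accuracy) -> per-sample
  allele assignment -> methylation summaries + sequence purity;
* permissive branch — filter (>=1 pass, >=0.80 accuracy) -> per-sample
  allele assignment -> repeat-length summaries;

followed by the cohort association battery. All randomness flows from the
single configured seed; re-running with the same seed overwrites the output
directory deterministically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .alleles import assign_alleles_per_sample
from .filtering import LENGTH_PROFILE, METHYLATION_PURITY_PROFILE, filter_reads
from .methylation import (
    ALTERNATE_THRESHOLD,
    MAIN_THRESHOLD,
    compare_thresholds,
    summarize_reads,
    summarize_sample,
    waterfall_matrix,
)
from .records import EXPANDED, WILD_TYPE
from .repeats import measure_reads, summarize_sample_repeats
from .simulate import SimulationConfig, simulate_cohort
from .stats import run_association_battery
from . import io as cio

log = logging.getLogger("c9meth")


@dataclass
class PipelineConfig:
    seed: int
    #: Directory with a tabular fixture, or None to simulate one in-run.
    input_dir: Optional[str] = None
    input_format: str = "fixture_tsv"  # or "bam" (reads+cpg only; meta via TSV)
    output_dir: str = "c9meth_out"
    k: int = 6
    main_threshold: int = MAIN_THRESHOLD
    alternate_threshold: int = ALTERNATE_THRESHOLD
    make_plots: bool = False
    write_fixture: bool = False
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self):
        if self.simulation.seed is None:
            self.simulation.seed = self.seed


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False)
    return len(df)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write TSVs, optional PNGs and a JSON manifest.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # stage: input
    if config.input_dir is None:
        cohort = simulate_cohort(config.simulation)
        if config.write_fixture:
            cio.write_fixture(cohort, out / "fixture")
    elif config.input_format == "fixture_tsv":
        cohort = cio.read_fixture(config.input_dir)
    elif config.input_format == "bam":
        bams = sorted(Path(config.input_dir).glob("*.bam")) + sorted(
            Path(config.input_dir).glob("*.sam"))
        if not bams:
            raise FileNotFoundError(f"no .bam/.sam under {config.input_dir}")
        reads, cpg = cio.read_bam(bams[0])
        meta_path = Path(config.input_dir) / "meta.tsv"
        meta = pd.read_csv(meta_path, sep="\t") if meta_path.exists() else None
        cohort = cio.SimulatedCohort(reads=reads, cpg=cpg, truth=None, meta=meta)
    else:
        raise ValueError(f"unknown input format {config.input_format!r}")
    reads, cpg, meta = cohort.reads, cohort.cpg, cohort.meta
    counts["input_reads"] = len(reads)
    counts["input_cpg_calls"] = len(cpg)

    # stage: filtering (two parallel profiles)
    strict, strict_report = filter_reads(reads, METHYLATION_PURITY_PROFILE, return_report=True)
    loose, loose_report = filter_reads(reads, LENGTH_PROFILE, return_report=True)
    counts["methylation_purity_reads"] = _write(strict, out / "reads_methylation_purity.tsv")
    counts["length_reads"] = _write(loose, out / "reads_length.tsv")
    _write(strict_report, out / "qc_report_methylation_purity.tsv")
    _write(loose_report, out / "qc_report_length.tsv")
    log.info("filtering kept %d/%d (stringent) and %d/%d (permissive) reads",
             len(strict), len(reads), len(loose), len(reads))

    # stage: allele assignment, per sample within each branch
    alleles_strict = assign_alleles_per_sample(strict, k=config.k, seed=config.seed)
    alleles_loose = assign_alleles_per_sample(loose, k=config.k, seed=config.seed)
    counts["alleles_methylation_purity"] = _write(alleles_strict, out / "alleles_methylation_purity.tsv")
    counts["alleles_length"] = _write(alleles_loose, out / "alleles_length.tsv")

    # stage: methylation metrics (stringent branch)
    cpg_strict = cpg[cpg["read_id"].isin(strict["read_id"])]
    read_meth = summarize_reads(cpg_strict, alleles_strict, threshold=config.main_threshold)
    read_meth = read_meth.merge(strict[["read_id", "sample_id"]], on="read_id")
    dropped = len(strict) - read_meth["read_id"].nunique()
    if dropped:
        log.info("%d reads had zero CpG calls and were excluded from methylation", dropped)
    sample_meth = summarize_sample(read_meth)
    counts["read_methylation"] = _write(read_meth, out / "read_methylation.tsv")
    counts["sample_methylation"] = _write(sample_meth, out / "sample_methylation.tsv")

    thr = compare_thresholds(cpg_strict, strict, alleles_strict,
                             t1=config.main_threshold, t2=config.alternate_threshold)
    _write(thr["table"], out / "threshold_comparison.tsv")

    # stage: repeat metrics — purity from the stringent branch, length from
    # the permissive branch
    meas_strict = measure_reads(strict, alleles_strict)
    meas_strict = meas_strict.merge(strict[["read_id", "sample_id"]], on="read_id")
    meas_loose = measure_reads(loose, alleles_loose)
    meas_loose = meas_loose.merge(loose[["read_id", "sample_id"]], on="read_id")
    counts["repeat_measurements"] = _write(meas_loose, out / "repeat_measurements.tsv")
    _write(meas_strict, out / "purity_measurements.tsv")

    sum_len = summarize_sample_repeats(meas_loose)
    sum_pur = summarize_sample_repeats(meas_strict)
    sample_repeats = sum_len.drop(columns=["median_gc", "median_motif_fraction"]).merge(
        sum_pur[["sample_id", "allele", "median_gc", "median_motif_fraction"]],
        on=["sample_id", "allele"], how="left",
    )
    counts["sample_repeats"] = _write(sample_repeats, out / "sample_repeats.tsv")

    # stage: cohort statistics
    results: dict[str, pd.DataFrame] = {}
    if meta is not None and len(meta):
        results = run_association_battery(sample_meth, sample_repeats, meta)
        counts["associations"] = _write(results["associations"], out / "associations.tsv")
        _write(results["longitudinal"], out / "longitudinal.tsv")
        _write(results["familial"], out / "familial.tsv")

    # stage: waterfall matrices for one representative sample per allele
    if len(sample_meth):
        rep = sample_meth.sort_values("n_reads", ascending=False)["sample_id"].iloc[0]
        rep_reads = strict[strict["sample_id"] == rep]
        rep_calls = alleles_strict[alleles_strict["read_id"].isin(rep_reads["read_id"])]
        for allele in (WILD_TYPE, EXPANDED):
            ids = rep_calls.loc[rep_calls["label"] == allele, "read_id"]
            mat = waterfall_matrix(cpg_strict[cpg_strict["read_id"].isin(ids)])
            mat.to_csv(out / f"waterfall_{allele}.tsv", sep="\t")
            if config.make_plots and len(mat):
                from . import plots

                plots.waterfall(mat, out / f"waterfall_{allele}.png",
                                title=f"{rep} ({allele})")

    if config.make_plots and meta is not None and len(meta):
        _make_plots(out, sample_meth, sample_repeats, meta, results)

    manifest = {
        "package": "c9meth",
        "version": __version__,
        "seed": config.seed,
        # path fields are excluded so that two runs of the same configuration
        # into different directories produce byte-identical manifests
        "config": {
            k: v for k, v in dataclasses.asdict(config).items()
            if k not in ("simulation", "output_dir", "input_dir")
        },
        "simulation": (dataclasses.asdict(config.simulation)
                       if config.input_dir is None else None),
        "counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _make_plots(out: Path, sample_meth, sample_repeats, meta, results) -> None:
    from . import plots

    blood0 = meta[(meta["tissue"] == "blood") & (meta["timepoint_years"] == 0)]
    me = sample_meth[(sample_meth["allele"] == EXPANDED)
                     & sample_meth["sample_id"].isin(blood0["sample_id"])]
    me = me.merge(meta, on="sample_id")
    re_ = sample_repeats[(sample_repeats["allele"] == EXPANDED)
                         & sample_repeats["sample_id"].isin(blood0["sample_id"])]
    joint = me.merge(re_[["sample_id", "max_repeats"]], on="sample_id")
    plots.allele_boxplot(
        sample_meth[sample_meth["sample_id"].isin(blood0["sample_id"])],
        "median_prop_methylated", out / "allele_prop_boxplot.png",
        ylabel="median proportion methylated")
    plots.scatter_with_fit(joint["max_repeats"], joint["median_prop_methylated"],
                           out / "meth_vs_length.png", "max repeats",
                           "median proportion methylated")
    plots.scatter_with_fit(me["age_at_collection"], me["median_prop_methylated"],
                           out / "meth_vs_age.png", "age at collection (years)",
                           "median proportion methylated")
    longi = sample_meth[sample_meth["allele"] == EXPANDED].merge(meta, on="sample_id")
    longi = longi[longi["tissue"] == "blood"]
    multi = longi.groupby("individual_id")["sample_id"].transform("nunique") > 1
    if multi.any():
        plots.longitudinal_dotplot(longi[multi], "median_prop_methylated",
                                   out / "longitudinal.png",
                                   ylabel="median proportion methylated")
    fam = results.get("familial") if results else None
    if fam is not None and len(fam):
        plots.pedigree_barplot(fam, out / "pedigrees.png")
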