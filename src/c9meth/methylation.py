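"""Per-read and per-sample CpG methylation summaries and waterfall matrices.

Each CpG carries an integer 5mC probability score from 0 to 255. Two
summaries are computed per read: the median score, and the proportion of
CpGs that are "likely methylated". The main methylated/unmethylated cutoff
is score >= 128 (the top half of the scale); the alternate cutoff used for
sensitivity checks is strictly greater than 75% of the scale (score > 191,
i.e. >= 192). Per-sample values are medians over reads, reported with the
min-max range.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .records import require_columns

MAIN_THRESHOLD = 128
#: The "> 75%" alternate rule: strictly greater than 0.75 * 255 = 191.25,
#: i.e. scores of 192 and above.
ALTERNATE_THRESHOLD = 192


def summarize_read(scores, threshold: int = MAIN_THRESHOLD,
                   alternate_strict: bool = False) -> tuple[float, float, int]:
    """(median score, proportion methylated, n CpGs) for one read.

    The even-count median is the mean of the two middle values. With the
    default rule a CpG counts as methylated when score >= threshold; with
    ``alternate_strict`` the comparison is strict (the alternate cutoff's
    published wording).
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("summarize_read requires at least one CpG")
    if not (0 <= threshold <= 255):
        raise ValueError("threshold must lie in [0, 255]")
    meth = (arr > threshold) if alternate_strict else (arr >= threshold)
    return float(np.median(arr)), float(meth.mean()), int(arr.size)


def summarize_reads(
    cpg: pd.DataFrame,
    alleles: pd.DataFrame | None = None,
    threshold: int = MAIN_THRESHOLD,
    alternate_strict: bool = False,
) -> pd.DataFrame:
    """Per-read methylation table from the CpG call table.

    Reads with zero CpG calls simply do not appear (they are logged by the
    pipeline, not a crash). If an allele table is given, its labels are
    merged in.
    """
    require_columns(cpg, ["read_id", "score"], "cpg")
    if not (0 <= threshold <= 255):
        raise ValueError("threshold must lie in [0, 255]")
    grouped = cpg.groupby("read_id", sort=True)["score"]
    meth = (cpg["score"] > threshold) if alternate_strict else (cpg["score"] >= threshold)
    out = pd.DataFrame(
        {
            "n_cpgs": grouped.size(),
            "median_score": grouped.median(),
            "prop_methylated": meth.groupby(cpg["read_id"], sort=True).mean(),
        }
    ).reset_index()
    if alleles is not None:
        out = out.merge(alleles[["read_id", "label"]], on="read_id", how="left")
        out = out.rename(columns={"label": "allele"})
    return out


def summarize_sample(read_meth: pd.DataFrame,
                     by: tuple[str, ...] = ("sample_id", "allele")) -> pd.DataFrame:
    """Per-sample/allele aggregates: median of per-read medians and
    proportions, with min/max/range of the proportion."""
    require_columns(read_meth, ["median_score", "prop_methylated", *by], "read methylation")
    if read_meth.empty:
        return pd.DataFrame(
            columns=[*by, "n_reads", "median_of_median_scores",
                     "median_prop_methylated", "min_prop", "max_prop", "range_prop"]
        )
    g = read_meth.groupby(list(by), sort=True)
    out = g.agg(
        n_reads=("median_score", "size"),
        median_of_median_scores=("median_score", "median"),
        median_prop_methylated=("prop_methylated", "median"),
        min_prop=("prop_methylated", "min"),
        max_prop=("prop_methylated", "max"),
    ).reset_index()
    out["range_prop"] = out["max_prop"] - out["min_prop"]
    return out


def compare_thresholds(
    cpg: pd.DataFrame,
    reads: pd.DataFrame,
    alleles: pd.DataFrame,
    t1: int = MAIN_THRESHOLD,
    t2: int = ALTERNATE_THRESHOLD,
) -> dict:
    """Per-sample methylated proportions at the main (>= t1) and alternate
    (> t2 - 1, i.e. >= t2) cutoffs, with their Spearman correlation per
    allele.

    Returns ``{"table": DataFrame, "spearman": {allele: AssociationResult}}``;
    with fewer than 3 samples (or a constant vector) the correlation is
    reported as undefined rather than raised.
    """
    from .stats import spearman  # local import to avoid a cycle

    cpg_s = cpg.merge(reads[["read_id", "sample_id"]], on="read_id")
    rm1 = summarize_reads(cpg_s, alleles, threshold=t1)
    rm2 = summarize_reads(cpg_s, alleles, threshold=t2 - 1, alternate_strict=True)
    s1 = summarize_sample(rm1.merge(reads[["read_id", "sample_id"]], on="read_id"))
    s2 = summarize_sample(rm2.merge(reads[["read_id", "sample_id"]], on="read_id"))
    table = s1[["sample_id", "allele", "median_prop_methylated"]].merge(
        s2[["sample_id", "allele", "median_prop_methylated"]],
        on=["sample_id", "allele"],
        suffixes=("_main", "_alternate"),
    )
    corr = {}
    for allele, grp in table.groupby("allele"):
        x = grp["median_prop_methylated_main"].to_numpy()
        y = grp["median_prop_methylated_alternate"].to_numpy()
        if len(grp) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
            corr[allele] = None  # undefined: too few samples or constant
        else:
            corr[allele] = spearman(x, y)
    return {"table": table, "spearman": corr}


MISSING = np.nan


def waterfall_matrix(cpg: pd.DataFrame, reads: pd.DataFrame | None = None) -> pd.DataFrame:
    """Reads-by-CpG-ordinal matrix of scores for one allele group.

    Rows are reads sorted by descending CpG count (ties by read id); column
    ``j`` holds the score of the (j+1)-th CpG of that read. Cells beyond a
    read's CpG count are NaN — explicitly distinct from a score of 0.
    """
    require_columns(cpg, ["read_id", "read_pos_0based", "score"], "cpg")
    if cpg.empty:
        return pd.DataFrame()
    counts = cpg.groupby("read_id").size()
    row_ids = sorted(counts.index, key=lambda r: (-counts[r], r))
    width = int(counts.max())
    mat = np.full((len(row_ids), width), MISSING)
    row_of = {r: i for i, r in enumerate(row_ids)}
    srt = cpg.sort_values(["read_id", "read_pos_0based"], kind="mergesort")
    ordinal = srt.groupby("read_id").cumcount().to_numpy()
    rows = srt["read_id"].map(row_of).to_numpy()
    mat[rows, ordinal] = srt["score"].to_numpy()
    return pd.DataFrame(mat, index=pd.Index(row_ids, name="read_id"),
                        columns=[f"cpg_{j + 1}" for j in range(width)])
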