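"""Tabular schemas shared across the pipeline.

All collections are plain :class:`pandas.DataFrame` objects with fixed column
sets; the constants below are the single source of truth for those columns.

Coordinate convention: internal positions are 0-based half-open; anything
written for human consumption (reports, plots) is 1-based inclusive and says
so in its header.
"""

from __future__ import annotations

import pandas as pd

#: One consensus (HiFi) read.
READ_COLUMNS = [
    "read_id",
    "individual_id",
    "sample_id",
    "sequence",
    "n_passes",
    "predicted_accuracy",
    "spans_left_flank",
    "spans_right_flank",
]

#: One CpG site on one read; ``score`` is the integer 5mC probability (0-255).
CPG_COLUMNS = ["read_id", "read_pos_0based", "score"]

#: Simulation ground truth, one row per read.
TRUTH_COLUMNS = [
    "read_id",
    "individual_id",
    "true_allele",
    "true_repeat_count",
    "true_n_interruptions",
    "true_interruption_units",
    "true_tract_meth_fraction",
    "true_flank_meth_fraction",
    "true_spans_left",
    "true_spans_right",
]

#: Per-sample clinical and pedigree metadata.
META_COLUMNS = [
    "sample_id",
    "individual_id",
    "group",
    "sex",
    "tissue",
    "timepoint_years",
    "age_at_collection",
    "age_at_onset",
    "promoter_methylation_pct",
    "promoter_hypermethylated",
    "southern_repeats",
    "southern_smear",
    "father_id",
    "pedigree_id",
    "wt_genotype_repeats",
]

WILD_TYPE = "wild_type"
EXPANDED = "expanded"

#: The pathogenic hexanucleotide motif.
REPEAT_MOTIF = "GGGGCC"


def require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    """Raise ``ValueError`` naming any column missing from ``df``."""
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing column(s): {', '.join(missing)}")
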