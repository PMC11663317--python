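"""Read QC profiles and locus-span detection.

Two consensus-read QC profiles gate the downstream analyses: a stringent one
for methylation and sequence-purity work (>=7 full passes, predicted accuracy
>=0.99) and a permissive one for repeat-length work (>=1 pass, accuracy
>=0.80). Both require 10 bp <= read length <= 100 kb and, because a read must
contain the full expansion to measure it, both flanks of the locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .records import READ_COLUMNS, require_columns
from .simulate import ANCHOR_LENGTH, default_anchors


@dataclass(frozen=True)
class FilterProfile:
    name: str
    min_full_passes: int
    min_predicted_accuracy: float
    min_read_length: int = 10
    max_read_length: int = 100_000
    require_both_flanks: bool = True


#: Stringent profile used for methylation and purity analyses.
METHYLATION_PURITY_PROFILE = FilterProfile("methylation_purity", 7, 0.99)
#: Permissive profile used for repeat-length analysis.
LENGTH_PROFILE = FilterProfile("length", 1, 0.80)

PROFILES = {p.name: p for p in (METHYLATION_PURITY_PROFILE, LENGTH_PROFILE)}

_REQUIRED = ["read_id", "sequence", "n_passes", "predicted_accuracy",
             "spans_left_flank", "spans_right_flank"]


def filter_reads(
    reads: pd.DataFrame, profile: FilterProfile, return_report: bool = False
):
    """Return the reads passing every threshold of ``profile``.

    Order is preserved and the input is not modified. With
    ``return_report=True`` additionally returns a per-read QC table with one
    boolean column per condition and a semicolon-joined ``fail_reasons``
    column (empty for kept reads).
    """
    require_columns(reads, _REQUIRED, "reads")
    for col in _REQUIRED:
        if reads[col].isna().any():
            bad = reads.loc[reads[col].isna(), "read_id"].iloc[0]
            raise ValueError(f"read {bad!r} is missing required metadata field {col!r}")

    length = reads["sequence"].str.len()
    checks = pd.DataFrame(
        {
            "pass_count_ok": reads["n_passes"] >= profile.min_full_passes,
            "accuracy_ok": reads["predicted_accuracy"] >= profile.min_predicted_accuracy,
            "min_length_ok": length >= profile.min_read_length,
            "max_length_ok": length <= profile.max_read_length,
            "spans_ok": (
                (reads["spans_left_flank"] & reads["spans_right_flank"])
                if profile.require_both_flanks
                else pd.Series(True, index=reads.index)
            ),
        },
        index=reads.index,
    )
    keep = checks.all(axis=1)
    kept = reads.loc[keep].copy()
    if not return_report:
        return kept

    reasons = checks.apply(
        lambda r: ";".join(c for c, ok in r.items() if not ok), axis=1
    )
    report = pd.concat(
        [reads[["read_id"]], checks, reasons.rename("fail_reasons")], axis=1
    )
    report.insert(1, "kept", keep)
    return kept, report


def spans_locus(sequence: str, left_anchor: str, right_anchor: str) -> bool:
    """True iff both flank anchors occur in the read, left before right.

    Anchors are the tract-proximal flank termini and must be at least
    20 bp to keep spurious matches unlikely.
    """
    if len(left_anchor) < ANCHOR_LENGTH or len(right_anchor) < ANCHOR_LENGTH:
        raise ValueError(f"anchors must be at least {ANCHOR_LENGTH} bases long")
    i = sequence.find(left_anchor)
    if i == -1:
        return False
    return sequence.find(right_anchor, i + len(left_anchor)) != -1


def annotate_spans(
    reads: pd.DataFrame, left_anchor: str | None = None, right_anchor: str | None = None
) -> pd.DataFrame:
    """Recompute the flank-span flags of ``reads`` from sequence content."""
    if left_anchor is None or right_anchor is None:
        la, ra = default_anchors()
        left_anchor = left_anchor or la
        right_anchor = right_anchor or ra
    out = reads.copy()
    out["spans_left_flank"] = reads["sequence"].map(lambda s: left_anchor in s)
    out["spans_right_flank"] = reads["sequence"].map(lambda s: right_anchor in s)
    return out
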