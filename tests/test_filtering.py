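"""QC profile filtering against a brute-force per-read oracle."""

import numpy as np
import pandas as pd
import pytest

from c9meth import LENGTH_PROFILE, METHYLATION_PURITY_PROFILE, filter_reads, spans_locus
from c9meth.filtering import FilterProfile, PROFILES, annotate_spans
from c9meth.simulate import LEFT_FLANK, RIGHT_FLANK, default_anchors


def _oracle_keep(row, p):
    n = len(row["sequence"])
    return (
        row["n_passes"] >= p.min_full_passes
        and row["predicted_accuracy"] >= p.min_predicted_accuracy
        and p.min_read_length <= n <= p.max_read_length
        and (not p.require_both_flanks
             or (row["spans_left_flank"] and row["spans_right_flank"]))
    )


def _random_reads(rng, n):
    return pd.DataFrame(
        {
            "read_id": [f"r{i}" for i in range(n)],
            "sequence": ["A" * int(rng.integers(1, 200)) for _ in range(n)],
            "n_passes": rng.integers(0, 20, size=n),
            "predicted_accuracy": np.round(rng.uniform(0.7, 1.0, size=n), 4),
            "spans_left_flank": rng.random(n) < 0.8,
            "spans_right_flank": rng.random(n) < 0.8,
        }
    )


@pytest.mark.parametrize("profile", list(PROFILES.values()))
def test_filter_matches_oracle_on_random_reads(profile):
    rng = np.random.default_rng(7)
    reads = _random_reads(rng, 500)
    kept, report = filter_reads(reads, profile, return_report=True)
    expected = {r["read_id"] for _, r in reads.iterrows() if _oracle_keep(r, profile)}
    assert set(kept["read_id"]) == expected
    assert set(report.loc[report["kept"], "read_id"]) == expected
    # failed rows always carry at least one reason; kept rows none
    assert (report.loc[~report["kept"], "fail_reasons"] != "").all()
    assert (report.loc[report["kept"], "fail_reasons"] == "").all()


def test_profiles_have_published_thresholds():
    assert METHYLATION_PURITY_PROFILE.min_full_passes == 7
    assert METHYLATION_PURITY_PROFILE.min_predicted_accuracy == 0.99
    assert LENGTH_PROFILE.min_full_passes == 1
    assert LENGTH_PROFILE.min_predicted_accuracy == 0.80
    for p in (METHYLATION_PURITY_PROFILE, LENGTH_PROFILE):
        assert p.min_read_length == 10 and p.max_read_length == 100_000
        assert p.require_both_flanks


def test_stringent_is_subset_of_permissive(small_cohort):
    stringent = filter_reads(small_cohort.reads, METHYLATION_PURITY_PROFILE)
    permissive = filter_reads(small_cohort.reads, LENGTH_PROFILE)
    assert set(stringent["read_id"]) <= set(permissive["read_id"])
    # filtering never reorders or mutates
    assert list(permissive["read_id"]) == [
        r for r in small_cohort.reads["read_id"] if r in set(permissive["read_id"])
    ]


def test_boundary_values_are_inclusive():
    p = FilterProfile("edge", 7, 0.99, min_read_length=10, max_read_length=20)
    reads = pd.DataFrame(
        {
            "read_id": ["lo", "hi", "passes", "acc"],
            "sequence": ["A" * 10, "A" * 20, "A" * 15, "A" * 15],
            "n_passes": [7, 7, 7, 7],
            "predicted_accuracy": [0.99, 0.99, 0.99, 0.99],
            "spans_left_flank": [True] * 4,
            "spans_right_flank": [True] * 4,
        }
    )
    assert len(filter_reads(reads, p)) == 4


def test_missing_metadata_is_a_hard_error():
    reads = pd.DataFrame(
        {
            "read_id": ["a", "b"],
            "sequence": ["ACGT", "ACGT"],
            "n_passes": [5, None],
            "predicted_accuracy": [0.9, 0.9],
            "spans_left_flank": [True, True],
            "spans_right_flank": [True, True],
        }
    )
    with pytest.raises(ValueError, match="'b'.*n_passes"):
        filter_reads(reads, LENGTH_PROFILE)


def test_spans_locus_and_annotate():
    la, ra = default_anchors()
    tract = "GGGGCC" * 8
    full = LEFT_FLANK + tract + RIGHT_FLANK
    assert spans_locus(full, la, ra)
    assert not spans_locus(tract + RIGHT_FLANK, la, ra)
    assert not spans_locus(LEFT_FLANK + tract, la, ra)
    # order matters: right anchor before left anchor does not span
    assert not spans_locus(RIGHT_FLANK + tract + LEFT_FLANK, la, ra)
    with pytest.raises(ValueError):
        spans_locus(full, "ACGT", ra)

    reads = pd.DataFrame(
        {
            "read_id": ["full", "left_only"],
            "sequence": [full, LEFT_FLANK + tract],
            "spans_left_flank": [False, False],  # deliberately wrong
            "spans_right_flank": [False, False],
        }
    )
    ann = annotate_spans(reads)
    assert list(ann["spans_left_flank"]) == [True, True]
    assert list(ann["spans_right_flank"]) == [True, False]
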