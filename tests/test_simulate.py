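"""Generator behaviour: noise-free limits, completeness, determinism."""

import numpy as np
import pandas as pd
import pytest

from c9meth import simulate_cohort
from c9meth.simulate import LEFT_FLANK, RIGHT_FLANK, REPEAT_MOTIF, default_anchors

from conftest import small_config


def test_flank_constants_have_expected_structure():
    for flank in (LEFT_FLANK, RIGHT_FLANK):
        assert len(flank) == 120
        assert REPEAT_MOTIF not in flank
        assert flank.count("CG") == 9
    # junctions create no CpG across boundaries
    joined = LEFT_FLANK + REPEAT_MOTIF * 5 + RIGHT_FLANK
    assert joined.count("CG") == 9 + 9 + 4
    la, ra = default_anchors()
    assert len(la) == len(ra) == 20


def test_noise_free_expanded_tract_is_exact():
    cfg = small_config(
        interruption_rate=0.0,
        truncation_rate=0.0,
        expanded_modal_length=100,
        mosaicism_dispersion=0.0,
    )
    cohort = simulate_cohort(cfg)
    expanded = cohort.truth[cohort.truth["true_allele"] == "expanded"]
    assert (expanded["true_repeat_count"] == 100).all()
    seqs = cohort.reads.set_index("read_id")["sequence"]
    for rid in expanded["read_id"]:
        assert REPEAT_MOTIF * 100 in seqs[rid]


def test_noise_free_mean_model_scores():
    # With zero noise and the mean score model, expansion CpGs score
    # round(0.2*255)=51 and flank CpGs round(0.9*255)=230 when the whole
    # flank is treated as the read-end window.
    cfg = small_config(
        score_model="mean",
        score_noise_sd=0.0,
        expansion_meth_slope=0.0,
        expansion_meth_intercept=0.2,
        wt_meth_level=0.2,
        flank_cpg_meth_level=0.9,
        flank_end_window=120,
        individual_meth_jitter_sd=0.0,
        truncation_rate=0.0,
        interruption_rate=0.0,
    )
    cohort = simulate_cohort(cfg)
    scores = cohort.cpg["score"].to_numpy()
    assert set(np.unique(scores)) == {51, 230}
    # every full-span read carries exactly 18 flank CpGs (nine per flank)
    per_read = cohort.cpg.groupby("read_id")["score"]
    n_flank = per_read.apply(lambda s: int((s == 230).sum()))
    assert (n_flank == 18).all()


def test_cpg_calls_cover_every_cg(small_cohort):
    seqs = small_cohort.reads.set_index("read_id")["sequence"]
    counts = small_cohort.cpg.groupby("read_id").size()
    for rid, seq in seqs.items():
        assert counts.get(rid, 0) == seq.count("CG")
    # and every call sits on a CG
    merged = small_cohort.cpg.merge(small_cohort.reads[["read_id", "sequence"]], on="read_id")
    for pos, seq in zip(merged["read_pos_0based"], merged["sequence"]):
        assert seq[pos:pos + 2] == "CG"


def test_expanded_lengths_right_skewed(default_cohort):
    expanded = default_cohort.truth[default_cohort.truth["true_allele"] == "expanded"]
    lengths = expanded["true_repeat_count"]
    assert lengths.mean() > lengths.median()


def test_mean_expansion_score_increases_with_repeat_count():
    cfg = small_config(
        score_model="mean",
        score_noise_sd=0.0,
        individual_meth_jitter_sd=0.0,
        interruption_rate=0.0,
        truncation_rate=0.0,
        flank_end_window=0,
    )
    cohort = simulate_cohort(cfg)
    truth = cohort.truth[cohort.truth["true_allele"] == "expanded"]
    # tract-level mean score is an affine increasing function of repeat count
    by_count = truth.sort_values("true_repeat_count")
    levels = by_count["true_tract_meth_fraction"].to_numpy()
    counts = by_count["true_repeat_count"].to_numpy()
    distinct = np.unique(counts)
    if len(distinct) > 1:
        level_of = {c: levels[counts == c].max() for c in distinct}
        vals = [level_of[c] for c in distinct]
        assert all(b > a or b == pytest.approx(0.98) for a, b in zip(vals, vals[1:]))


def test_seed_determinism():
    a = simulate_cohort(small_config(seed=42))
    b = simulate_cohort(small_config(seed=42))
    pd.testing.assert_frame_equal(a.reads, b.reads)
    pd.testing.assert_frame_equal(a.cpg, b.cpg)
    pd.testing.assert_frame_equal(a.truth, b.truth)
    pd.testing.assert_frame_equal(a.meta, b.meta)
    c = simulate_cohort(small_config(seed=43))
    assert not a.reads["sequence"].equals(c.reads["sequence"])


def test_cohort_structure_matches_design(default_cohort):
    meta = default_cohort.meta
    blood0 = meta[(meta["tissue"] == "blood") & (meta["timepoint_years"] == 0)]
    assert len(blood0) == 27
    assert blood0["group"].value_counts().to_dict() == {
        "ALS": 15, "presymptomatic": 11, "FTD": 1,
    }
    blood = meta[meta["tissue"] == "blood"]
    assert len(blood) == 34  # 27 individuals + 7 extra longitudinal draws
    longi = blood.groupby("individual_id").size()
    assert (longi > 1).sum() == 6 and longi[longi > 1].sum() == 13
    kids = blood0[blood0["father_id"] != ""]
    assert len(kids) == 7 and kids["pedigree_id"].nunique() == 4


@pytest.mark.parametrize(
    "overrides",
    [
        {"seed": None},
        {"n_individuals": 0},
        {"wt_repeat_range": (1, 30)},
        {"wt_repeat_range": (2, 31)},
        {"expanded_modal_length": 10},
        {"interruption_rate": 1.5},
        {"score_model": "uniform"},
        {"reads_per_allele_range": (0, 3)},
    ],
)
def test_invalid_configs_refused(overrides):
    cfg = small_config(**overrides)
    with pytest.raises(ValueError):
        simulate_cohort(cfg)
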