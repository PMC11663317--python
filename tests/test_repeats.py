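"""Repeat location, counting and purity against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from c9meth import count_repeats, locate_tract, measure_reads, purity
from c9meth.repeats import exact_motif_count, summarize_sample_repeats

MOTIF = "GGGGCC"


def _oracle_locate(seq, motif):
    hits = [i for i in range(len(seq) - len(motif) + 1) if seq[i:i + len(motif)] == motif]
    if not hits:
        return None
    return hits[0], hits[-1] + len(motif)


def _random_repeatish(rng):
    """Random sequence with occasional motif runs and interruptions."""
    parts = []
    for _ in range(int(rng.integers(1, 8))):
        if rng.random() < 0.6:
            parts.append(MOTIF * int(rng.integers(0, 6)))
        else:
            parts.append("".join(rng.choice(list("ACGT"), size=int(rng.integers(0, 12)))))
    return "".join(parts)


def test_locate_count_purity_match_oracle_on_random_sequences():
    rng = np.random.default_rng(17)
    seen_with_motif = 0
    for _ in range(500):
        seq = _random_repeatish(rng)
        expected = _oracle_locate(seq, MOTIF)
        if expected is None:
            with pytest.raises(ValueError):
                locate_tract(seq)
            continue
        seen_with_motif += 1
        start, end = locate_tract(seq)
        assert (start, end) == expected
        assert count_repeats(seq) == (end - start) // 6
        tract = seq[start:end]
        gc, motif_frac = purity(seq)
        assert gc == pytest.approx(
            sum(1 for b in tract if b in "GC") / len(tract)
        )
        # greedy non-overlapping count, brute force
        n, i = 0, 0
        while i <= len(tract) - 6:
            if tract[i:i + 6] == MOTIF:
                n += 1
                i += 6
            else:
                i += 1
        assert exact_motif_count(tract) == n
        assert motif_frac == pytest.approx(6 * n / len(tract))
    assert seen_with_motif > 100  # the generator actually exercises the path


def test_pure_tract_counts_exactly():
    for n in (1, 2, 30, 100, 1000):
        seq = "TTTT" + MOTIF * n + "AAAA"
        assert count_repeats(seq) == n
        gc, mf = purity(seq)
        # every base of GGGGCC is G or C, so a pure tract is 100% GC
        assert gc == 1.0 and mf == 1.0


def test_interruption_lengthens_span_but_lowers_purity():
    # one substituted unit in the middle: span still covers it
    seq = MOTIF * 10 + "GGGACC" + MOTIF * 10
    assert count_repeats(seq) == 21
    gc, mf = purity(seq)
    assert mf == pytest.approx(20 * 6 / (21 * 6))
    assert gc == pytest.approx(125 / 126)  # one A among 126 tract bases


def test_measure_reads_flags_motif_free():
    reads = pd.DataFrame(
        {
            "read_id": ["ok", "none"],
            "sequence": [MOTIF * 5, "ACGTACGTACGT"],
        }
    )
    out = measure_reads(reads)
    assert list(out["read_id"]) == ["ok"]
    assert out.attrs["motif_free_reads"] == ["none"]
    assert out.loc[0, "repeat_count"] == 5
    assert out.loc[0, "tract_span"] == 30


def test_summarize_sample_repeats_uses_max_as_primary():
    meas = pd.DataFrame(
        {
            "sample_id": ["S1"] * 4,
            "allele": ["expanded"] * 4,
            "repeat_count": [900, 1000, 1200, 950],
            "gc_fraction": [0.66, 0.65, 0.64, 0.66],
            "motif_fraction": [0.99, 0.98, 0.95, 0.99],
        }
    )
    out = summarize_sample_repeats(meas)
    row = out.iloc[0]
    assert row["max_repeats"] == 1200
    assert row["median_repeats"] == 975.0
    assert row["min_repeats"] == 900
    assert row["range_repeats"] == 300
    assert row["median_gc"] == pytest.approx(0.655)
    assert row["median_motif_fraction"] == pytest.approx(0.985)


def test_truth_recovery_on_uninterrupted_cohort():
    from conftest import small_config
    from c9meth import simulate_cohort

    cohort = simulate_cohort(small_config(interruption_rate=0.0, truncation_rate=0.0))
    meas = measure_reads(cohort.reads).merge(cohort.truth, on="read_id")
    assert (meas["repeat_count"] == meas["true_repeat_count"]).all()
    assert (meas["motif_fraction"] == 1.0).all()
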