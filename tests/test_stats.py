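"""Statistical layer against independent enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss

from c9meth import (
    adjusted_group_test,
    classify_longitudinal,
    classify_transmission,
    spearman,
    wilcoxon_paired,
    wilcoxon_unpaired,
)
from c9meth.stats import (
    benjamini_hochberg,
    hypermethylation_contrast,
    simulate_confounded_group_replicates,
)


# -- oracles ---------------------------------------------------------------

def _oracle_spearman_r(x, y):
    """Pearson correlation of average ranks (the definition)."""
    rx = ss.rankdata(x)
    ry = ss.rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


def _oracle_signed_rank_p(d):
    """Exact two-sided signed-rank p by enumerating all 2^n sign vectors.

    Assumes no zeros and no tied absolute differences.
    """
    n = len(d)
    ranks = ss.rankdata(np.abs(d))
    w_obs = ranks[np.asarray(d) > 0].sum()
    total = 2 ** n
    signs = np.array(list(itertools.product([0, 1], repeat=n)))
    w_all = signs @ ranks
    mu = n * (n + 1) / 4
    p = np.sum(np.abs(w_all - mu) >= np.abs(w_obs - mu) - 1e-12) / total
    return min(1.0, p)


def _oracle_rank_sum_p(a, b):
    """Exact two-sided rank-sum p by enumerating label assignments."""
    pooled = np.concatenate([a, b])
    ranks = ss.rankdata(pooled)
    n, m = len(a), len(b)
    w_obs = ranks[:n].sum()
    mu = n * (n + m + 1) / 2
    stats = [ranks[list(c)].sum() for c in itertools.combinations(range(n + m), n)]
    stats = np.asarray(stats)
    p = np.mean(np.abs(stats - mu) >= np.abs(w_obs - mu) - 1e-12)
    return min(1.0, float(p))


# -- spearman --------------------------------------------------------------

def test_spearman_matches_rank_pearson_oracle():
    rng = np.random.default_rng(23)
    for _ in range(200):
        n = int(rng.integers(3, 25))
        x = rng.integers(0, 10, size=n).astype(float)  # ties likely
        y = rng.normal(size=n)
        if np.all(x == x[0]):
            continue
        res = spearman(x, y)
        assert res.estimate == pytest.approx(_oracle_spearman_r(x, y), abs=1e-10)
        assert res.n == n and res.status == "ok"


def test_spearman_degenerate_inputs():
    assert spearman([1, 2], [3, 4]).status == "too_few_pairs"
    assert spearman([1, 1, 1], [1, 2, 3]).status == "undefined_constant"
    # NaN pairs are dropped before everything else
    res = spearman([1, 2, 3, np.nan], [1, 2, 3, 4])
    assert res.n == 3 and res.estimate == pytest.approx(1.0)


# -- wilcoxon paired -------------------------------------------------------

def test_wilcoxon_paired_matches_enumeration_oracle():
    rng = np.random.default_rng(29)
    done = 0
    while done < 60:
        n = int(rng.integers(4, 11))
        d = np.round(rng.normal(0.3, 1.0, size=n), 3)
        if (d == 0).any() or np.unique(np.abs(d)).size < n:
            continue
        a = rng.normal(size=n)
        res = wilcoxon_paired(a + d, a)
        assert res.p_value == pytest.approx(_oracle_signed_rank_p(d), abs=1e-9)
        assert res.n == n
        done += 1


def test_wilcoxon_paired_zeros_and_large_n():
    res = wilcoxon_paired([1.0, 1.0], [1.0, 1.0])
    assert res.status == "all_differences_zero" and res.p_value == 1.0
    # n > 25 switches to the normal approximation; sanity: strong signal
    rng = np.random.default_rng(1)
    a = rng.normal(1.0, 0.2, 40)
    b = rng.normal(0.0, 0.2, 40)
    assert wilcoxon_paired(a, b).p_value < 1e-6


# -- wilcoxon unpaired -----------------------------------------------------

def test_wilcoxon_unpaired_matches_enumeration_oracle():
    rng = np.random.default_rng(31)
    done = 0
    while done < 60:
        n, m = int(rng.integers(3, 7)), int(rng.integers(3, 7))
        a = np.round(rng.normal(0.5, 1.0, n), 3)
        b = np.round(rng.normal(0.0, 1.0, m), 3)
        if np.unique(np.concatenate([a, b])).size < n + m:
            continue  # oracle assumes no ties
        res = wilcoxon_unpaired(a, b)
        assert res.p_value == pytest.approx(_oracle_rank_sum_p(a, b), abs=1e-9)
        done += 1
    with pytest.raises(ValueError):
        wilcoxon_unpaired([], [1.0])


# -- adjusted regression ---------------------------------------------------

def test_adjusted_group_test_matches_normal_equations():
    rng = np.random.default_rng(37)
    n = 40
    group = (rng.random(n) < 0.5).astype(float)
    age = rng.normal(50, 10, n)
    y = 0.3 * group + 0.01 * age + rng.normal(0, 0.5, n)
    res = adjusted_group_test(y, group, age)
    X = np.column_stack([np.ones(n), group, age])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    for i, lab in enumerate(["intercept", "group", "age"]):
        assert res[lab].estimate == pytest.approx(beta[i], abs=1e-10)
    # p-value oracle from the classic t formula
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - 3)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
    t = beta / se
    p = 2 * ss.t.sf(np.abs(t), df=n - 3)
    for i, lab in enumerate(["intercept", "group", "age"]):
        assert res[lab].p_value == pytest.approx(p[i], rel=1e-8)


def test_adjusted_group_test_recovers_pure_age_signal():
    # when y is a function of age alone, the group coefficient vanishes and
    # the age coefficient is recovered exactly (noise-free fit)
    age = np.array([40.0, 45.0, 50.0, 55.0, 60.0, 65.0, 70.0, 48.0])
    group = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
    y = 2.0 * age
    res = adjusted_group_test(y, group, age)
    assert res["age"].estimate == pytest.approx(2.0, abs=1e-9)
    assert res["group"].estimate == pytest.approx(0.0, abs=1e-9)


def test_adjusted_group_test_singular_design_raises():
    with pytest.raises(ValueError, match="singular"):
        adjusted_group_test([1.0, 2.0, 3.0, 4.0, 5.0],
                            [0, 0, 1, 1, 1], [0, 0, 1, 1, 1])


# -- classification rules --------------------------------------------------

def test_longitudinal_rule_boundaries():
    assert classify_longitudinal([0.40, 0.49]) == "stable"      # change 0.09
    assert classify_longitudinal([0.40, 0.50]) == "variable"    # exactly 0.10
    assert classify_longitudinal([0.40, 0.45, 0.51]) == "variable"
    assert classify_longitudinal([0.5, 0.5]) == "stable"
    with pytest.raises(ValueError):
        classify_longitudinal([0.4])
    assert classify_longitudinal([10.0, 10.9], relative=True) == "stable"
    assert classify_longitudinal([10.0, 11.0], relative=True) == "variable"


def test_transmission_rule_boundaries():
    assert classify_transmission(0.50, 0.40) == "decrease"   # exactly 0.10
    assert classify_transmission(0.50, 0.41) == "stable"
    assert classify_transmission(0.40, 0.50) == "increase"
    assert classify_transmission(0.50, 0.50) == "stable"


def test_hypermethylation_contrast_handles_empty_group():
    out = hypermethylation_contrast([0.1, 0.2, 0.3], [False, False, False])
    assert out["result"].status == "not_testable"
    assert np.isnan(out["median_hyper"])
    out = hypermethylation_contrast([0.1, 0.2, 0.8, 0.9], [False, False, True, True])
    assert out["result"].status == "ok"
    assert out["median_hyper"] == pytest.approx(0.85)


def test_benjamini_hochberg_against_direct_formula():
    p = np.array([0.001, 0.01, 0.03, 0.04, 0.8])
    q = benjamini_hochberg(p)
    m = len(p)
    raw = p * m / (np.arange(m) + 1)
    expected = np.minimum.accumulate(raw[::-1])[::-1]
    assert np.allclose(q, np.minimum(expected, 1.0))


def test_confounded_replicates_show_the_confounding_pattern():
    df = simulate_confounded_group_replicates(n_replicates=50, seed=3)
    assert len(df) == 50
    # age drives the response, so the unadjusted contrast is almost always
    # significant while the adjusted group coefficient usually is not
    assert (df["unadjusted_p"] < 0.05).mean() > 0.9
    assert (df["adjusted_group_p"] >= 0.05).mean() > 0.7
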