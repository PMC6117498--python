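"""Topic ratios, containment, effect sizes, Welch tests and group contrasts."""

import math

import numpy as np
import pingouin
import pytest
from scipy import stats as sp_stats

import reviewminer as rm
from reviewminer.interest_mining import pooled_sd


LABELS = ["ME", "MC", "MAP", "CS", "F", "OP", "PP", "S", "DAP"]


# ---------------------------------------------------------------------------
# Topic ratios and containment
# ---------------------------------------------------------------------------

def test_floor_zeroes_small_entries_only():
    theta = np.array([[0.245, 0.10, 0.655]])
    out = rm.topic_ratios(theta, ["a", "b", "c"]).ratios
    assert out[0, 0] == 0.245          # above 1/9: unchanged
    assert out[0, 1] == 0.0            # 0.10 < 1/9: zeroed
    assert out[0, 2] == 0.655
    identity = rm.topic_ratios(theta, ["a", "b", "c"], floor=0.0).ratios
    np.testing.assert_array_equal(identity, theta)
    with pytest.raises(ValueError):
        rm.topic_ratios(theta, ["a", "b", "c"], floor=1.5)


def test_thresholding_never_increases_and_containment_monotone():
    rng = np.random.default_rng(0)
    theta = rng.dirichlet([0.5] * 4, size=200)
    labels = list("abcd")
    prev = None
    for floor in (0.0, 0.1, 0.25, 0.5):
        ratios = rm.topic_ratios(theta, labels, floor=floor)
        assert (ratios.ratios <= theta + 1e-15).all()
        frac = rm.containment_fraction(ratios)
        if prev is not None:
            assert (frac <= prev + 1e-12).all()
        prev = frac


def test_containment_matches_count_oracle():
    rng = np.random.default_rng(1)
    theta = rng.dirichlet([0.3] * 3, size=50)
    groups = ["g1" if i < 30 else "g2" for i in range(50)]
    ratios = rm.topic_ratios(theta, list("abc"), groups=groups)
    frac = rm.containment_fraction(ratios, "g1")
    oracle = (ratios.ratios[:30] > 0).sum(axis=0) / 30
    np.testing.assert_allclose(frac, oracle)
    col = ratios.ratios.copy()
    assert rm.containment_fraction(
        rm.topic_ratios(np.ones((5, 2)) * 0.5, ["a", "b"]))[0] == 1.0
    with pytest.raises(ValueError):
        rm.containment_fraction(ratios, "missing-group")


# ---------------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------------

def test_cohens_d_textbook_cases():
    assert rm.cohens_d(1.0, 1.0, 50, 0.0, 1.0, 50) == pytest.approx(1.0)
    assert rm.cohens_d(0.3, 0.2, 40, 0.3, 0.2, 40) == pytest.approx(0.0)
    assert rm.cohens_d(1.0, 0.0, 10, 1.0, 0.0, 10) is None  # zero pooled var


def test_cohens_d_matches_formula_and_reference_on_random_stats():
    rng = np.random.default_rng(2)
    for _ in range(200):
        m1, m2 = rng.normal(size=2)
        s1, s2 = rng.uniform(0.1, 2.0, size=2)
        n1, n2 = rng.integers(2, 500, size=2)
        d = rm.cohens_d(m1, s1, int(n1), m2, s2, int(n2))
        sp = math.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
        assert d == pytest.approx((m1 - m2) / sp, abs=1e-12)


def test_cohens_d_agrees_with_pingouin_on_samples():
    rng = np.random.default_rng(3)
    x = rng.normal(0.4, 1.2, size=300)
    y = rng.normal(0.0, 0.8, size=200)
    ours = rm.cohens_d(x.mean(), x.std(ddof=1), len(x),
                       y.mean(), y.std(ddof=1), len(y))
    ref = pingouin.compute_effsize(x, y, eftype="cohen")
    assert ours == pytest.approx(ref, abs=1e-9)


@pytest.mark.parametrize("d,band", [
    (0.005, "small"), (-0.005, "small"),
    (0.01, "medium"), (0.1, "medium"),
    (0.20, "large"), (0.25, "large"), (0.49, "large"),
    (0.50, "very large"), (0.79, "very large"),
    (0.80, "huge"), (1.58, "huge"), (-1.55, "huge"), (3.5, "huge"),
])
def test_effect_band_cut_points(d, band):
    assert rm.effect_band(d) == band


# ---------------------------------------------------------------------------
# t statistics
# ---------------------------------------------------------------------------

def test_welch_identical_groups():
    t, df, p = rm.welch_t(0.4, 0.1, 30, 0.4, 0.1, 30)
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
    assert rm.welch_t(0.4, 0.0, 30, 0.4, 0.0, 30) == (None, None, None)


def test_welch_matches_scipy_reference():
    rng = np.random.default_rng(5)
    for _ in range(200):
        m1, m2 = rng.normal(size=2)
        s1, s2 = rng.uniform(0.05, 3.0, size=2)
        n1, n2 = (int(v) for v in rng.integers(2, 1000, size=2))
        t, df, p = rm.welch_t(m1, s1, n1, m2, s2, n2)
        ref = sp_stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2,
                                            equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)
        assert math.copysign(1, t) == math.copysign(1, m1 - m2) or m1 == m2


def test_student_t_matches_scipy_reference():
    ref = sp_stats.ttest_ind_from_stats(0.6, 0.3, 40, 0.4, 0.5, 60,
                                        equal_var=True)
    t, df, p = rm.student_t(0.6, 0.3, 40, 0.4, 0.5, 60)
    assert t == pytest.approx(ref.statistic, abs=1e-12)
    assert df == 98
    assert p == pytest.approx(ref.pvalue, abs=1e-12)


def test_t_from_printed_summary_unit_pooled_sd():
    # delta_u == d means s_pooled = 1; with n1=n2=2, sqrt(1/2+1/2)=1 so t = Δu
    assert rm.t_from_printed_summary(0.3, 0.3, 2, 2) == pytest.approx(0.3)
    with pytest.raises(ValueError):
        rm.t_from_printed_summary(0.3, 0.0, 10, 10)


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def _ratio_matrix_from_truth(corpus, truth, scheme):
    ratios = rm.topic_ratios(
        truth.theta_true, rm.load_taxonomy().label_ids,
        doc_ids=[r.doc_id for r in corpus],
        groups=rm.group_tags_for_corpus(corpus, scheme))
    return ratios


def test_planted_effect_has_correct_sign(small_labeled_corpus):
    corpus, truth = small_labeled_corpus
    scheme = rm.load_grouping_scheme("acute_vs_chronic")
    ratios = _ratio_matrix_from_truth(corpus, truth, scheme)
    results = {r.topic: r for r in rm.compare_groups(ratios, scheme)}
    assert len(results) == 9
    assert results["S"].delta_u > 0          # symptoms planted high in acute
    assert results["S"].cohen_d > 0 and results["S"].welch_t > 0
    assert results["F"].delta_u < 0          # financing planted high in chronic


def test_identical_groups_show_no_large_effects():
    rng = np.random.default_rng(7)
    theta = rng.dirichlet([1.0] * 9, size=4000)
    groups = ["g1"] * 2000 + ["g2"] * 2000
    ratios = rm.topic_ratios(theta, LABELS, groups=groups)
    results = rm.compare_groups(ratios, group_pair=("g1", "g2"))
    assert len(results) == 9
    for r in results:
        assert r.band in {"small", "medium"}


def test_zero_variance_topic_marked_undefined_without_side_effects():
    theta = np.tile([0.5, 0.3, 0.2], (40, 1))
    theta[:20, 0] += 0.001 * np.arange(20) / 20
    theta /= theta.sum(axis=1, keepdims=True)
    ratios = rm.topic_ratios(theta, list("abc"), floor=0.0,
                             groups=["g1"] * 20 + ["g2"] * 20)
    # a column of exact zeros (every entry below the floor) has no variance
    ratios.ratios[:, 2] = 0.0
    results = rm.compare_groups(ratios, group_pair=("g1", "g2"))
    by_topic = {r.topic: r for r in results}
    assert by_topic["c"].cohen_d is None
    assert by_topic["c"].band is None
    assert by_topic["a"].cohen_d is not None


def test_compare_groups_requires_both_groups():
    ratios = rm.topic_ratios(np.full((4, 2), 0.5), ["a", "b"],
                             groups=["g1"] * 4)
    with pytest.raises(ValueError, match="non-empty"):
        rm.compare_groups(ratios, group_pair=("g1", "g2"))


def test_bonferroni_flag_inflates_p_values():
    rng = np.random.default_rng(9)
    theta = rng.dirichlet([1.0] * 3, size=400)
    ratios = rm.topic_ratios(theta, list("abc"), floor=0.0,
                             groups=["g1"] * 200 + ["g2"] * 200)
    plain = rm.compare_groups(ratios, group_pair=("g1", "g2"))
    adj = rm.compare_groups(ratios, group_pair=("g1", "g2"),
                            p_adjust="bonferroni")
    for a, b in zip(plain, adj):
        assert b.p_value >= a.p_value - 1e-15


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def test_null_rejection_rate_is_near_alpha():
    rate = rm.simulate_null_rejection_rate(n_reps=2000, n_per_group=50, seed=13)
    assert abs(rate - 0.05) < 0.015


def test_planted_effect_recovery():
    d_hat = rm.simulate_planted_effect(d_true=0.5, n_per_group=5000, seed=17)
    assert abs(d_hat - 0.5) <= 0.15
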