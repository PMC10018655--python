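import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctiq import (LatentRatingModel, Question, RatingDesign, generate_ratings,
                  true_auc)
from ctiq.vgc import (auc_binormal, auc_trapezoidal, bootstrap_vgc,
                      orient_ratings, per_reader_auc, proportion_table,
                      vgc_curve)
from conftest import oriented_from_lists, pairwise_auc_oracle


# ------------------------------------------------------------- orientation

def test_five_step_scale_is_reversed(rating_set_factory):
    rs = rating_set_factory(seed=1, scale_size=5)
    oriented = orient_ratings(rs, "Q1")
    raw = rs.data[(rs.data.condition == "test")].pivot(
        index="case_id", columns="reader_id", values="rating")
    assert np.array_equal(oriented.test_matrix, 6 - raw.values)


def test_three_step_scale_kept_as_is(rating_set_factory):
    rs = rating_set_factory(seed=2, scale_size=3)
    oriented = orient_ratings(rs, "Q1")
    raw = rs.data[(rs.data.condition == "test")].pivot(
        index="case_id", columns="reader_id", values="rating")
    assert np.array_equal(oriented.test_matrix, raw.values)


def test_missing_pair_member_is_named(rating_set_factory):
    rs = rating_set_factory(seed=3)
    rs.data = rs.data.iloc[1:]  # drop one reference rating
    with pytest.raises(ValueError, match="case001"):
        orient_ratings(rs, "Q1")


def test_unknown_question_rejected(rating_set_factory):
    with pytest.raises(ValueError, match="Q99"):
        orient_ratings(rating_set_factory(seed=4), "Q99")


# --------------------------------------------------------------- VGC curve

def test_identical_arms_curve_on_diagonal():
    o = oriented_from_lists([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], 5)
    pts = vgc_curve(o)
    assert np.allclose(pts[:, 0], pts[:, 1])
    assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)


def test_perfect_separation_curve_through_corner():
    o = oriented_from_lists([5, 5, 5], [1, 1, 1], 5)
    pts = vgc_curve(o)
    assert any(np.allclose(p, (0.0, 1.0)) for p in pts)
    assert np.isclose(auc_trapezoidal(o), 1.0)


def test_curve_matches_hand_enumeration():
    o = oriented_from_lists([3, 3, 4], [1, 2, 3], 5)
    pts = vgc_curve(o)
    # thresholds t = 5..1: x = frac(ref >= t), y = frac(test >= t)
    expected = [(0.0, 0.0), (0.0, 0.0), (0.0, 1.0 / 3.0), (1.0 / 3.0, 1.0),
                (2.0 / 3.0, 1.0), (1.0, 1.0)]
    assert np.allclose(pts, expected)
    assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)


# --------------------------------------------------------- trapezoidal AUC

def test_identical_multisets_auc_exactly_half():
    o = oriented_from_lists([1, 2, 2, 5, 3], [3, 2, 1, 2, 5], 5)
    assert auc_trapezoidal(o) == 0.5


def test_small_example_equals_pair_counting():
    o = oriented_from_lists([3, 3, 4], [1, 2, 3], 5)
    # 7 wins + 2 ties / 2 out of 9 pairs
    assert np.isclose(auc_trapezoidal(o), 8.0 / 9.0)


@settings(max_examples=200, derandomize=True)
@given(st.data())
def test_trapezoid_equals_pairwise_oracle(data):
    scale = data.draw(st.sampled_from([3, 5]))
    n = data.draw(st.integers(1, 50))
    test = data.draw(st.lists(st.integers(1, scale), min_size=n, max_size=n))
    ref = data.draw(st.lists(st.integers(1, scale), min_size=n, max_size=n))
    o = oriented_from_lists(test, ref, scale)
    assert np.isclose(auc_trapezoidal(o), pairwise_auc_oracle(test, ref),
                      atol=1e-12)


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.integers(1, 5), min_size=1, max_size=30),
       st.lists(st.integers(1, 5), min_size=1, max_size=30))
def test_auc_complementarity(a, b):
    n = min(len(a), len(b))
    o_ab = oriented_from_lists(a[:n], b[:n], 5)
    o_ba = oriented_from_lists(b[:n], a[:n], 5)
    assert np.isclose(auc_trapezoidal(o_ab) + auc_trapezoidal(o_ba), 1.0)


def test_rank_invariance_under_monotone_relabeling():
    rng = np.random.default_rng(8)
    test = rng.integers(1, 6, 40)
    ref = rng.integers(1, 6, 40)
    base = auc_trapezoidal(oriented_from_lists(test, ref, 5))
    relabel = {1: 1, 2: 3, 3: 4, 4: 6, 5: 9}  # strictly monotone
    t2 = np.vectorize(relabel.get)(test)
    r2 = np.vectorize(relabel.get)(ref)
    relabeled = auc_trapezoidal(oriented_from_lists(t2, r2, 9))
    assert np.isclose(base, relabeled)


# ------------------------------------------------------------ binormal AUC

def test_binormal_symmetric_fit_near_half(rating_set_factory):
    rs = rating_set_factory(delta=0.0, seed=5, n_cases=300, n_readers=2,
                            sigma_case=0.0, sigma_reader=0.0)
    assert abs(auc_binormal(orient_ratings(rs, "Q1")) - 0.5) < 0.05


def test_binormal_recovers_generative_auc(rating_set_factory):
    model = LatentRatingModel(delta=1.0, sigma_case=0.0, sigma_reader=0.0)
    rs = rating_set_factory(delta=1.0, seed=6, n_cases=2000, n_readers=1,
                            sigma_case=0.0, sigma_reader=0.0)
    fitted = auc_binormal(orient_ratings(rs, "Q1"))
    assert abs(fitted - true_auc(model)) < 0.03


def test_binormal_degenerate_input_rejected():
    o = oriented_from_lists([3, 3, 3], [3, 3, 3], 5)
    with pytest.raises(ValueError):
        auc_binormal(o)


# --------------------------------------------------------------- bootstrap

def test_perfect_separation_gives_degenerate_ci(rating_set_factory):
    rs = rating_set_factory(seed=7)
    # force strict separation: test always above reference after orientation
    data = rs.data.copy()
    data.loc[data.condition == "test", "rating"] = 1   # oriented 5
    data.loc[data.condition == "reference", "rating"] = 5  # oriented 1
    rs.data = data
    res = bootstrap_vgc(rs, "Q1", n_boot=200, seed=1)
    assert res.auc == 1.0 and res.ci_low == 1.0 and res.ci_high == 1.0
    assert res.significant


def test_bootstrap_is_seed_deterministic(rating_set_factory):
    rs = rating_set_factory(delta=0.5, seed=8)
    a = bootstrap_vgc(rs, "Q1", n_boot=300, seed=11)
    b = bootstrap_vgc(rs, "Q1", n_boot=300, seed=11)
    assert (a.auc, a.ci_low, a.ci_high) == (b.auc, b.ci_low, b.ci_high)
    c = bootstrap_vgc(rs, "Q1", n_boot=300, seed=12)
    assert (a.ci_low, a.ci_high) != (c.ci_low, c.ci_high)


def test_bootstrap_replicates_match_loop_reference(rating_set_factory):
    """The vectorised fixed-reader bootstrap equals a per-replicate loop
    that redraws cases and recomputes the pooled AUC."""
    rs = rating_set_factory(delta=0.5, seed=9, n_cases=8, n_readers=3)
    oriented = orient_ratings(rs, "Q1")
    from ctiq.vgc import _bootstrap_aucs
    rng = np.random.default_rng(5)
    fast = _bootstrap_aucs(oriented, "fixed_reader", 50, rng)
    rng = np.random.default_rng(5)
    slow = []
    for _ in range(50):
        idx = rng.integers(0, 8, size=8)
        t = oriented.test_matrix[idx].ravel()
        r = oriented.reference_matrix[idx].ravel()
        slow.append(pairwise_auc_oracle(list(t), list(r)))
    assert np.allclose(fast, slow)


def test_random_reader_ci_wider_on_average(rating_set_factory):
    """With nonzero reader variance, resampling readers adds CI width."""
    widths = {"fixed_reader": [], "random_reader": []}
    for seed in range(6):
        rs = rating_set_factory(delta=0.6, seed=20 + seed, sigma_reader=0.6)
        for mode in widths:
            res = bootstrap_vgc(rs, "Q1", mode=mode, n_boot=500, seed=seed)
            widths[mode].append(res.ci_high - res.ci_low)
    assert np.mean(widths["random_reader"]) > np.mean(widths["fixed_reader"])


def test_bootstrap_validation(rating_set_factory):
    rs = rating_set_factory(seed=10)
    with pytest.raises(ValueError):
        bootstrap_vgc(rs, "Q1", n_boot=0, seed=1)
    with pytest.raises(ValueError):
        bootstrap_vgc(rs, "Q1", mode="no_such_mode", n_boot=10, seed=1)


def test_per_reader_auc_shape(rating_set_factory):
    rs = rating_set_factory(delta=1.0, seed=11)
    aucs = per_reader_auc(orient_ratings(rs, "Q1"))
    assert aucs.shape == (5,)
    assert np.all((aucs >= 0) & (aucs <= 1))


# -------------------------------------------------------------- proportions

def test_unanimous_answers_proportion_one(rating_set_factory):
    rs = rating_set_factory(seed=12, scale_size=3)
    rs.data["rating"] = 1
    props = proportion_table(rs)
    assert np.allclose(props[1], 1.0)
    assert np.allclose(props[[2, 3]], 0.0)


def test_proportions_match_hand_tally(rating_set_factory):
    rs = rating_set_factory(seed=13, scale_size=3, n_cases=2, n_readers=2)
    # fixed pattern: ratings 1,2,3,1 for test; 2,2,3,3 for reference
    data = rs.data.sort_values(["condition", "case_id", "reader_id"]).reset_index(drop=True)
    data.loc[data.condition == "test", "rating"] = [1, 2, 3, 1]
    data.loc[data.condition == "reference", "rating"] = [2, 2, 3, 3]
    rs.data = data
    props = proportion_table(rs)
    assert np.allclose(props.loc[("Q1", "test")], [0.5, 0.25, 0.25])
    assert np.allclose(props.loc[("Q1", "reference")], [0.0, 0.5, 0.5])


def test_proportions_sum_to_one(rating_set_factory):
    rs = rating_set_factory(delta=0.3, seed=14)
    props = proportion_table(rs)
    assert np.allclose(props.sum(axis=1), 1.0)
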