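"""Unit tests for the composite challenge score formulas."""

import numpy as np
import pytest

from dreambench.errors import ValidationError
from dreambench.fixtures import make_network_fixture, make_pwm_fixture
from dreambench.io import RankedEdgeList
from dreambench.nulls import (
    GREATER_IS_BETTER,
    NullDistribution,
)
from dreambench.scores import (
    ParameterEstimate,
    RankTable,
    TimeCourseSet,
    aggregate_mean_rank,
    compute_parsimony_weight,
    edge_prediction_to_binary,
    rank_table_from_scores,
    score_combined_logp_pair,
    score_d3c3,
    score_d6c3,
    score_d7c1_final,
    score_d7c1_topology,
    score_mean_neglogp,
    score_network_inference,
    score_olfaction,
    score_parameter_distance,
    score_parsimony_network,
    score_pwm_family,
    score_sysgenb,
    score_timecourse_distance,
)


# ---------------------------------------------------------------------------
# log-p combiners
# ---------------------------------------------------------------------------

def test_combined_logp_pair():
    assert score_combined_logp_pair(1.0, 1.0) == 0.0
    assert score_combined_logp_pair(0.01, 0.01) == pytest.approx(2.0)
    assert score_combined_logp_pair(0.3, 0.07) == pytest.approx(
        score_combined_logp_pair(0.07, 0.3)
    )
    with pytest.raises(ValidationError):
        score_combined_logp_pair(0.0, 0.5)
    with pytest.raises(ValidationError):
        score_combined_logp_pair(0.5, 1.5)


def test_mean_neglogp():
    assert score_mean_neglogp([1.0, 1.0, 1.0]) == 0.0
    assert score_mean_neglogp([0.1] * 5) == pytest.approx(1.0)
    ps = [0.3, 0.01, 0.9, 0.5]
    assert score_mean_neglogp(ps) == pytest.approx(score_mean_neglogp(ps[::-1]))
    with pytest.raises(ValidationError):
        score_mean_neglogp([])


def test_sysgenb():
    assert score_sysgenb(1.0, 1.0) == 0.0
    assert score_sysgenb(0.1, 0.1) == pytest.approx(2.0)
    assert score_sysgenb(0.2, 0.05) == pytest.approx(score_sysgenb(0.05, 0.2))


def test_d6c3_literal_product_and_log_mode():
    assert score_d6c3([1.0, 1.0, 1.0, 1.0]) == pytest.approx(-0.25)
    assert score_d6c3([0.1] * 4) == pytest.approx(-2.5e-5)
    assert score_d6c3([0.1] * 4, log_mode=True) == pytest.approx(1.0)
    with pytest.raises(ValidationError, match="4 p-values"):
        score_d6c3([0.1, 0.2, 0.3])


def test_d7c1_combiners():
    assert score_d7c1_final(1.0, 1.0) == 0.0
    assert score_d7c1_final(0.01, 0.01) == pytest.approx(4.0)  # no 1/2 factor
    assert score_d7c1_topology(0.001) == pytest.approx(3.0)


# ---------------------------------------------------------------------------
# parameter and time-course distances
# ---------------------------------------------------------------------------

def test_parameter_distance():
    true = np.full(45, 2.0)
    assert score_parameter_distance(
        ParameterEstimate(estimated=true, true_values=true)
    ) == 0.0
    est = true.copy()
    est[0] *= 10.0  # one decade off among Np = 45
    d = score_parameter_distance(ParameterEstimate(estimated=est, true_values=true))
    assert d == pytest.approx(1.0 / 45.0)
    swapped = score_parameter_distance(
        ParameterEstimate(estimated=true, true_values=est)
    )
    assert swapped == pytest.approx(d)
    with pytest.raises(ValidationError):
        ParameterEstimate(estimated=-est, true_values=true)


def _constant_courses(value, n_courses=3, n_times=40):
    return [np.full((n_times, 1), float(value)) for _ in range(n_courses)]


def test_timecourse_distance():
    golds = _constant_courses(1.0)
    tc = TimeCourseSet(courses=[g.copy() for g in golds], golds=golds)
    assert score_timecourse_distance(tc) == 0.0
    # a single retained residual of 0.3 at gold 1: 1.8 / 90 = 0.02
    courses = [g.copy() for g in golds]
    courses[0][20, 0] += 0.3
    tc = TimeCourseSet(courses=courses, golds=golds)
    assert score_timecourse_distance(tc) == pytest.approx(0.02)


def test_timecourse_burn_in_ignored():
    golds = _constant_courses(1.0)
    courses = [g.copy() for g in golds]
    courses[0][:10, 0] += 99.0  # inside the 10-point burn-in window
    tc = TimeCourseSet(courses=courses, golds=golds)
    assert score_timecourse_distance(tc) == 0.0


def test_timecourse_validation():
    with pytest.raises(ValidationError, match="burn-in"):
        TimeCourseSet(
            courses=[np.zeros((5, 1))], golds=[np.zeros((5, 1))], burn_in=10
        )
    with pytest.raises(ValidationError, match="shape"):
        TimeCourseSet(courses=[np.zeros((20, 1))], golds=[np.zeros((20, 2))])


# ---------------------------------------------------------------------------
# parsimony
# ---------------------------------------------------------------------------

def test_parsimony_network_score():
    assert score_parsimony_network([0.1] * 7, r=0.01, n_edges=10) == pytest.approx(0.9)
    assert score_parsimony_network([0.1] * 7, r=0.5, n_edges=0) == pytest.approx(1.0)
    scores = [
        score_parsimony_network([0.1] * 7, r=0.01, n_edges=ne) for ne in (0, 5, 10, 20)
    ]
    assert all(a > b for a, b in zip(scores, scores[1:]))


def test_parsimony_weight():
    assert compute_parsimony_weight([2.0], [20]) == pytest.approx(0.1)
    assert compute_parsimony_weight([2.0, 3.0], [20, 10]) == pytest.approx(0.1)
    # adding a participant can only lower or keep r
    assert compute_parsimony_weight([2.0, 0.5], [20, 10]) <= 0.1
    with pytest.raises(ValidationError):
        compute_parsimony_weight([], [])


# ---------------------------------------------------------------------------
# rank aggregation
# ---------------------------------------------------------------------------

def test_aggregate_mean_rank():
    rt = RankTable(
        teams=["a", "b", "c"],
        contexts=["x", "y", "z"],
        ranks=np.array([[1, 1, 1], [2, 3, 2], [3, 2, 3]], dtype=float),
    )
    out = aggregate_mean_rank(rt)
    assert out["a"] == 1.0
    assert out["b"] == pytest.approx(np.mean([2, 3, 2]))


def test_rank_table_from_scores_average_ties():
    scores = np.array([[0.9, 0.5], [0.9, 0.7], [0.1, 0.2]])
    rt = rank_table_from_scores(["a", "b", "c"], ["x", "y"], scores)
    assert rt.ranks[0, 0] == rt.ranks[1, 0] == 1.5  # tied best -> both 1.5
    assert rt.ranks[2, 0] == 3.0
    # smaller-is-better orientation flips the ranking
    rt2 = rank_table_from_scores(
        ["a", "b", "c"], ["x", "y"], scores, greater_is_better=False
    )
    assert rt2.ranks[2, 0] == 1.0


def test_rank_table_validation():
    with pytest.raises(ValidationError):
        RankTable(teams=["a", "b"], contexts=["x"], ranks=np.array([[1.0], [3.0]]))


# ---------------------------------------------------------------------------
# olfaction-style z aggregation
# ---------------------------------------------------------------------------

def test_score_olfaction():
    nulls = [
        NullDistribution([0.1, 0.2, 0.3], GREATER_IS_BETTER) for _ in range(3)
    ]
    zero = score_olfaction([0.2, 0.2, 0.2], nulls)
    assert zero["final"] == pytest.approx(0.0)
    out = score_olfaction([0.5, 0.3, 0.4], nulls)
    assert out["zscores"] == pytest.approx([3.0, 1.0, 2.0])
    assert out["final"] == pytest.approx(2.0)
    with pytest.raises(ValidationError):
        score_olfaction([0.1], nulls)


# ---------------------------------------------------------------------------
# network inference
# ---------------------------------------------------------------------------

def _uniform_nulls(labels_list, n_null, seed):
    from dreambench.metrics import BinaryPrediction, auroc, aupr

    rng = np.random.default_rng(seed)
    roc_nulls, pr_nulls = [], []
    for labels in labels_list:
        rocs, prs = [], []
        for _ in range(n_null):
            bp = BinaryPrediction(scores=rng.random(len(labels)), labels=labels)
            rocs.append(auroc(bp))
            prs.append(aupr(bp))
        roc_nulls.append(NullDistribution(rocs, GREATER_IS_BETTER))
        pr_nulls.append(NullDistribution(prs, GREATER_IS_BETTER))
    return roc_nulls, pr_nulls


def test_edge_prediction_to_binary():
    pred = RankedEdgeList(edges=[("a", "b", 0.9), ("b", "c", 0.4)])
    gold = {("a", "b"), ("c", "a")}
    bp = edge_prediction_to_binary(pred, gold)
    # universe {a,b,c}: 6 ordered candidate pairs
    assert bp.labels.sum() == 2
    assert bp.scores.size == 6
    with pytest.raises(ValidationError, match="outside the node universe"):
        edge_prediction_to_binary(
            RankedEdgeList(edges=[("zz", "b", 0.9)]), gold
        )


def test_score_network_inference_self_scoring():
    golds, preds = [], []
    for i in range(3):
        gold, _ = make_network_fixture(n_nodes=5, n_edges=5, quality=0.0, seed=i)
        golds.append(gold)
        nodes = [f"g{k + 1}" for k in range(5)]
        preds.append(
            RankedEdgeList(
                edges=[(s, t, 1.0) for s, t in sorted(gold)],
                node_universe=frozenset(nodes),
            )
        )
    labels_list = []
    for gold in golds:
        nodes = [f"g{k + 1}" for k in range(5)]
        labels_list.append(
            np.array(
                [1 if (s, t) in gold else 0 for s in nodes for t in nodes if s != t]
            )
        )
    nulls = _uniform_nulls(labels_list, n_null=50, seed=0)
    report = score_network_inference(preds, golds, nulls)
    for net in report["per_network"]:
        assert net["auroc"] == 1.0
        assert net["aupr"] == 1.0
    # gold self-score is maximal for these nulls: every p at its floor
    floor = 1.0 / 51.0
    assert report["final"] == pytest.approx(-np.log10(floor))
    assert set(report) == {"per_network", "s_auroc", "s_aupr", "final"}


# ---------------------------------------------------------------------------
# PWM family
# ---------------------------------------------------------------------------

def test_score_pwm_family_self_scoring_and_determinism():
    golds, _ = make_pwm_fixture(n_matrices=3, n_rows=4, n_cols=3, quality=0.5, seed=1)
    report = score_pwm_family(golds, golds, n_null=40, seed=7)
    assert report["distances"] == [0.0, 0.0, 0.0]
    assert report["final"] == pytest.approx(-np.log10(1.0 / 41.0))
    again = score_pwm_family(golds, golds, n_null=40, seed=7)
    assert report == again
    with pytest.raises(ValidationError, match="shape"):
        mismatched, _ = make_pwm_fixture(n_matrices=3, n_rows=4, n_cols=5, seed=2)
        score_pwm_family(mismatched, golds, n_null=10, seed=0)


# ---------------------------------------------------------------------------
# expression-prediction rank profiles
# ---------------------------------------------------------------------------

def test_score_d3c3_perfect_and_inverted():
    rng = np.random.default_rng(3)
    gold = rng.normal(size=(12, 5))
    from scipy.stats import rankdata

    perfect = rankdata(gold, method="ordinal", axis=0).astype(float)
    report = score_d3c3(perfect, gold)
    assert report["per_time_rho"] == pytest.approx([1.0] * 5)
    # perfect prediction: both family p-values are astronomically small
    # (bounded below by the documented analytic floor, never zero)
    assert 1e-300 <= report["p_time"] < 1e-10
    assert 1e-300 <= report["p_gene"] < 1e-10
    inverted = (12 + 1) - perfect
    inv = score_d3c3(inverted, gold)
    assert inv["per_time_rho"] == pytest.approx([-1.0] * 5)
    # the two-sided association test treats perfect anti-correlation as
    # equally strong association
    assert inv["final"] == pytest.approx(report["final"])


def test_score_d3c3_rejects_non_permutation_columns():
    gold = np.random.default_rng(0).normal(size=(10, 4))
    bad = np.ones((10, 4))
    with pytest.raises(ValidationError, match="permutation"):
        score_d3c3(bad, gold)


def test_score_d3c3_random_prediction_pvalues_not_extreme():
    rng = np.random.default_rng(8)
    gold = rng.normal(size=(20, 6))
    from scipy.stats import rankdata

    random_ranks = rankdata(
        rng.normal(size=gold.shape), method="ordinal", axis=0
    ).astype(float)
    report = score_d3c3(random_ranks, gold)
    assert 0.0 < report["p_time"] <= 1.0
    assert 0.0 < report["p_gene"] <= 1.0
    assert report["final"] < 5.0  # far from the self-score regime
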