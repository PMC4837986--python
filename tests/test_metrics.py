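"""Unit tests for the atomic metric catalogue.

Expected values are either trivial closed forms or were computed by hand /
by an independent brute-force oracle (exhaustive pair enumeration for the
ranking and concordance metrics), frozen here.
"""

import math

import numpy as np
import pytest

from dreambench.errors import ValidationError
from dreambench.metrics import (
    BinaryPrediction,
    ConfusionCounts,
    PairedSeries,
    SurvivalRecord,
    auroc,
    aupr,
    balanced_accuracy,
    concordance_correlation,
    concordance_index,
    frobenius_distance,
    jaccard,
    matthews_cc,
    normalized_squared_error,
    pearson,
    probabilistic_concordance,
    rmse,
    spearman,
)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def auroc_by_pair_counting(scores, labels):
    """Exhaustive Mann-Whitney enumeration: ties count 1/2 per pair."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def concordance_by_enumeration(records, higher_is_riskier=True):
    """Brute-force admissible-pair enumeration of Harrell's C."""
    num = den = 0.0
    for a in records:
        for b in records:
            if not (a.time < b.time and a.event == 1):
                continue
            den += 1
            ra, rb = (a.risk, b.risk) if higher_is_riskier else (-a.risk, -b.risk)
            num += 1.0 if ra > rb else (0.5 if ra == rb else 0.0)
    return num / den


# ---------------------------------------------------------------------------
# ranking metrics
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "scores, labels, expected",
    [
        ((0.9, 0.8, 0.2, 0.1), (1, 1, 0, 0), 1.0),     # perfect separation
        ((0.1, 0.2, 0.8, 0.9), (1, 1, 0, 0), 0.0),     # inverted ranking
        ((0.8, 0.6, 0.6, 0.3), (1, 0, 1, 0), 0.875),   # one tie -> 3.5/4
    ],
)
def test_auroc_examples(scores, labels, expected):
    assert auroc(BinaryPrediction(scores=scores, labels=labels)) == expected


def test_auroc_rejects_degenerate_labels():
    with pytest.raises(ValidationError, match="no negative"):
        auroc(BinaryPrediction(scores=[0.1, 0.2], labels=[1, 1]))
    with pytest.raises(ValidationError, match="no positive"):
        auroc(BinaryPrediction(scores=[0.1, 0.2], labels=[0, 0]))


def test_auroc_matches_pair_counting_on_random_instances():
    rng = np.random.default_rng(7)
    for _ in range(200):
        n = int(rng.integers(4, 30))
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            continue
        scores = np.round(rng.random(n), 2)  # rounded so ties occur
        bp = BinaryPrediction(scores=scores, labels=labels)
        assert auroc(bp) == pytest.approx(
            auroc_by_pair_counting(scores, labels), abs=1e-12
        )


def test_auroc_label_flip_identity():
    rng = np.random.default_rng(1)
    for _ in range(50):
        scores = rng.random(20)  # tie-free almost surely
        labels = rng.integers(0, 2, size=20)
        if labels.sum() in (0, 20):
            continue
        a = auroc(BinaryPrediction(scores=scores, labels=labels))
        b = auroc(BinaryPrediction(scores=scores, labels=1 - labels))
        assert a + b == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize(
    "scores, labels, expected",
    [
        ((0.9, 0.8, 0.2, 0.1), (1, 1, 0, 0), 1.0),
        # positives ranked 3rd and 4th: AP = (1/3 + 2/4)/2 = 5/12 by hand
        ((0.9, 0.8, 0.2, 0.1), (0, 0, 1, 1), 5.0 / 12.0),
        # single positive ranked first among 5
        ((0.9, 0.5, 0.4, 0.3, 0.2), (1, 0, 0, 0, 0), 1.0),
    ],
)
def test_aupr_examples(scores, labels, expected):
    assert aupr(BinaryPrediction(scores=scores, labels=labels)) == pytest.approx(
        expected, abs=1e-12
    )


def test_ranking_metrics_invariant_under_monotone_transform():
    rng = np.random.default_rng(3)
    scores = rng.random(40)
    labels = rng.integers(0, 2, size=40)
    labels[0], labels[1] = 0, 1
    bp = BinaryPrediction(scores=scores, labels=labels)
    transformed = BinaryPrediction(scores=np.exp(3 * scores) + 5, labels=labels)
    assert auroc(bp) == pytest.approx(auroc(transformed), abs=1e-12)
    assert aupr(bp) == pytest.approx(aupr(transformed), abs=1e-12)


# ---------------------------------------------------------------------------
# confusion-matrix metrics
# ---------------------------------------------------------------------------

def test_matthews_cc_examples():
    assert matthews_cc(ConfusionCounts(tp=5, fp=0, tn=5, fn=0)) == 1.0
    assert matthews_cc(ConfusionCounts(tp=1, fp=1, tn=1, fn=1)) == 0.0
    # hand evaluation: (6*3 - 2*1)/sqrt(8*7*5*4) = 16/sqrt(1120)
    assert matthews_cc(ConfusionCounts(tp=6, fp=2, tn=3, fn=1)) == pytest.approx(
        16.0 / math.sqrt(1120.0)
    )


def test_matthews_cc_zero_denominator_returns_zero_with_warning():
    with pytest.warns(RuntimeWarning, match="zero denominator"):
        assert matthews_cc(ConfusionCounts(tp=0, fp=0, tn=5, fn=3)) == 0.0


def test_balanced_accuracy():
    assert balanced_accuracy(ConfusionCounts(tp=10, fn=0, tn=10, fp=0)) == 1.0
    assert balanced_accuracy(ConfusionCounts(tp=8, fn=2, tn=5, fp=5)) == 0.65
    assert balanced_accuracy(ConfusionCounts(tp=0, fn=10, tn=0, fp=10)) == 0.0
    with pytest.raises(ValidationError):
        balanced_accuracy(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))


def test_jaccard():
    assert jaccard({"x", "y", "z"}, {"x", "y", "z"}) == 1.0
    assert jaccard({"a"}, {"b", "c"}) == 0.0
    assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5
    with pytest.raises(ValidationError):
        jaccard(set(), set())


# ---------------------------------------------------------------------------
# correlation metrics
# ---------------------------------------------------------------------------

def test_correlations():
    s = PairedSeries(predicted=[1.0, 2.0, 3.0, 4.0], observed=[1.0, 2.0, 3.0, 4.0])
    assert pearson(s) == pytest.approx(1.0)
    assert spearman(s) == pytest.approx(1.0)
    rev = PairedSeries(predicted=[4.0, 3.0, 2.0, 1.0], observed=[1.0, 2.0, 3.0, 4.0])
    assert spearman(rev) == pytest.approx(-1.0)
    # rank-difference formula: 1 - 6*2/(4*15) = 0.8
    mixed = PairedSeries(predicted=[1, 2, 3, 4], observed=[1, 3, 2, 4])
    assert spearman(mixed) == pytest.approx(0.8)
    with pytest.raises(ValidationError, match="zero variance"):
        pearson(PairedSeries(predicted=[1.0, 1.0], observed=[1.0, 2.0]))


def test_concordance_correlation():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert concordance_correlation(
        PairedSeries(predicted=x, observed=x)
    ) == pytest.approx(1.0)
    # location bias: CCC < Pearson (which stays 1)
    shifted = PairedSeries(predicted=x + 2.0, observed=x)
    assert pearson(shifted) == pytest.approx(1.0)
    assert concordance_correlation(shifted) < 1.0
    # hand evaluation of the closed form on 4 pairs
    s = PairedSeries(predicted=[1.0, 2.0, 3.0, 4.0], observed=[1.0, 3.0, 2.0, 5.0])
    assert concordance_correlation(s) == pytest.approx(2.75 / 3.5)


# ---------------------------------------------------------------------------
# concordance index
# ---------------------------------------------------------------------------

def _records(rows):
    return [SurvivalRecord(time=t, event=e, risk=r) for t, e, r in rows]


def test_concordance_index_examples():
    # risk perfectly anti-ordered with time, no censoring
    perfect = _records([(1, 1, 4.0), (2, 1, 3.0), (3, 1, 2.0), (4, 1, 1.0)])
    assert concordance_index(perfect) == 1.0
    # all risks equal: every admissible pair ties
    flat = _records([(1, 1, 0.5), (2, 1, 0.5), (3, 1, 0.5)])
    assert concordance_index(flat) == 0.5
    # orientation flag flips a perfect score into zero
    assert concordance_index(perfect, higher_risk_shorter_survival=False) == 0.0


def test_concordance_index_with_censoring_matches_enumeration():
    recs = _records([(1.0, 1, 2.0), (2.0, 0, 3.0), (3.0, 1, 1.0), (4.0, 1, 0.5)])
    assert concordance_index(recs) == concordance_by_enumeration(recs)


def test_concordance_index_random_instances_match_enumeration():
    rng = np.random.default_rng(11)
    for _ in range(100):
        n = int(rng.integers(3, 9))
        recs = _records(
            [
                (float(rng.integers(1, 6)), int(rng.integers(0, 2)), float(rng.integers(0, 4)))
                for _ in range(n)
            ]
        )
        if not any(r.event for r in recs):
            continue
        try:
            got = concordance_index(recs)
        except ValidationError:
            continue
        assert got == concordance_by_enumeration(recs)


def test_concordance_index_matches_lifelines_on_tiefree_times():
    lifelines_utils = pytest.importorskip("lifelines.utils")
    rng = np.random.default_rng(5)
    times = rng.exponential(size=30)
    events = rng.integers(0, 2, size=30)
    events[0] = 1
    risks = rng.normal(size=30)
    recs = _records(list(zip(times, events, risks)))
    # lifelines orients predictions as survival scores (higher = longer life)
    expected = lifelines_utils.concordance_index(times, -risks, events)
    assert concordance_index(recs) == pytest.approx(expected, abs=1e-12)


def test_concordance_index_no_censoring_equals_kendall_complement():
    # tie-free risks, no censoring: C = 1 - (discordant pairs / all pairs)
    rng = np.random.default_rng(13)
    for _ in range(20):
        n = int(rng.integers(3, 9))
        times = rng.permutation(n) + 1.0
        risks = rng.permutation(n).astype(float)
        recs = _records([(t, 1, r) for t, r in zip(times, risks)])
        disc = sum(
            1
            for a in recs
            for b in recs
            if a.time < b.time and a.risk < b.risk
        )
        total = n * (n - 1) / 2
        assert concordance_index(recs) == pytest.approx(1 - disc / total)


def test_concordance_index_requires_admissible_pairs():
    with pytest.raises(ValidationError, match="admissible"):
        concordance_index(_records([(1, 0, 1.0), (2, 0, 2.0)]))


# ---------------------------------------------------------------------------
# probabilistic concordance
# ---------------------------------------------------------------------------

def test_probabilistic_concordance_recovers_hard_ci_in_zero_sd_limit():
    rng = np.random.default_rng(2)
    recs = _records(
        [
            (float(t), int(e), float(r))
            for t, e, r in zip(
                rng.exponential(size=12), rng.integers(0, 2, size=12), rng.normal(size=12)
            )
        ]
    )
    recs[0] = SurvivalRecord(time=recs[0].time, event=1, risk=recs[0].risk)
    sd = np.full(12, 1e-9)
    assert probabilistic_concordance(recs, sd) == pytest.approx(
        concordance_index(recs), abs=1e-6
    )


def test_probabilistic_concordance_hand_example():
    from scipy.stats import norm

    # 3 events at times 1, 2, 4 with risks 3, 1, 2 and sds 1, 1, 2
    recs = _records([(1.0, 1, 3.0), (2.0, 1, 1.0), (4.0, 1, 2.0)])
    sd = [1.0, 1.0, 2.0]
    # pair (1,2): dt=1, s=sqrt(2), concordant  -> Phi(1/sqrt 2)
    # pair (1,3): dt=3, s=sqrt(5), concordant  -> Phi(3/sqrt 5)
    # pair (2,3): dt=2, s=sqrt(5), discordant  -> 1 - Phi(2/sqrt 5)
    expected = (
        norm.cdf(1 / np.sqrt(2))
        + norm.cdf(3 / np.sqrt(5))
        + (1 - norm.cdf(2 / np.sqrt(5)))
    ) / 3
    assert probabilistic_concordance(recs, sd) == pytest.approx(expected, abs=1e-12)


def test_probabilistic_concordance_tied_times_contribute_half():
    recs = _records([(2.0, 1, 5.0), (2.0, 1, 1.0)])
    assert probabilistic_concordance(recs, [0.5, 0.5]) == 0.5


def test_probabilistic_concordance_rejects_negative_sd():
    recs = _records([(1.0, 1, 1.0), (2.0, 1, 0.0)])
    with pytest.raises(ValidationError):
        probabilistic_concordance(recs, [-1.0, 1.0])


# ---------------------------------------------------------------------------
# error / distance metrics
# ---------------------------------------------------------------------------

def test_normalized_squared_error():
    assert normalized_squared_error([1.0, 2.0], [1.0, 2.0]) == 0.0
    # 0.3^2 / (0.01 + 0.04) = 1.8
    assert normalized_squared_error([1.3], [1.0]) == pytest.approx(1.8)
    base = normalized_squared_error([1.3, 0.5], [1.0, 0.8])
    doubled = normalized_squared_error([1.6, 0.2], [1.0, 0.8])
    assert doubled == pytest.approx(4 * base)
    with pytest.raises(ValidationError, match="length mismatch"):
        normalized_squared_error([1.0], [1.0, 2.0])


def test_normalized_squared_error_permutation_invariant():
    rng = np.random.default_rng(4)
    pred, gold = rng.normal(size=10), rng.normal(size=10)
    perm = rng.permutation(10)
    assert normalized_squared_error(pred, gold) == pytest.approx(
        normalized_squared_error(pred[perm], gold[perm]), rel=1e-12
    )


def test_rmse():
    same = PairedSeries(predicted=[1.0, 2.0], observed=[1.0, 2.0])
    assert rmse(same) == 0.0
    s = PairedSeries(predicted=[0.0, 0.0], observed=[3.0, 4.0])
    assert rmse(s) == pytest.approx(math.sqrt(12.5))
    scaled = PairedSeries(predicted=[0.0, 0.0], observed=[9.0, 12.0])
    assert rmse(scaled) == pytest.approx(3 * rmse(s))


def test_frobenius_distance():
    a = np.array([[1.0, 2.0], [3.0, 4.0]])
    assert frobenius_distance(a, a) == 0.0
    assert frobenius_distance(a, np.zeros((2, 2))) == pytest.approx(math.sqrt(30.0))
    with pytest.raises(ValidationError, match="shape mismatch"):
        frobenius_distance(a, np.zeros((2, 3)))


def test_frobenius_distance_is_a_metric():
    rng = np.random.default_rng(6)
    for _ in range(50):
        a, b, c = rng.normal(size=(3, 4, 5))
        assert frobenius_distance(a, b) == pytest.approx(frobenius_distance(b, a))
        assert frobenius_distance(a, b) + frobenius_distance(b, c) >= (
            frobenius_distance(a, c) - 1e-12
        )


# ---------------------------------------------------------------------------
# property-based invariants
# ---------------------------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    scores=st.lists(
        st.floats(0, 1, allow_nan=False).map(lambda x: round(x, 2)),
        min_size=4,
        max_size=25,
    ),
    data=st.data(),
)
def test_auroc_properties_hold_on_arbitrary_inputs(scores, data):
    n = len(scores)
    labels = data.draw(
        st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
            lambda ls: 0 < sum(ls) < n
        )
    )
    bp = BinaryPrediction(scores=scores, labels=labels)
    value = auroc(bp)
    assert 0.0 <= value <= 1.0
    assert value == pytest.approx(auroc_by_pair_counting(scores, labels), abs=1e-12)
    # flipping the labels mirrors the score around 1/2
    flipped = auroc(BinaryPrediction(scores=scores, labels=[1 - l for l in labels]))
    assert value + flipped == pytest.approx(1.0, abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    pairs=st.lists(
        st.tuples(
            st.floats(-5, 5, allow_nan=False), st.floats(0.1, 5, allow_nan=False)
        ),
        min_size=2,
        max_size=12,
    )
)
def test_normalized_squared_error_nonnegative_and_permutation_invariant(pairs):
    pred = np.array([p for p, _ in pairs])
    gold = np.array([g for _, g in pairs])
    e = normalized_squared_error(pred, gold)
    assert e >= 0.0
    perm = np.random.default_rng(0).permutation(len(pairs))
    assert normalized_squared_error(pred[perm], gold[perm]) == pytest.approx(
        e, rel=1e-9, abs=1e-12
    )
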