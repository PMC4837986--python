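"""Composite per-challenge-family score formulas.

Assembles the atomic metrics and null-model machinery into the final
scores the challenge families report: log-p combiners, multi-network
inference scores, PWM-family scores, parsimony-penalized signaling scores,
parameter/time-course distances, rank aggregation and z-score aggregation.

All logarithms in the score formulas are base 10 — a single, documented
convention; the families that print a bare "log" differ from the log10
families only by a constant scale factor.  Composite scorers return plain
dicts with stable key names, serializable to JSON as structured reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _stats

from .errors import ValidationError
from .metrics import BinaryPrediction, auroc, aupr, frobenius_distance
from .nulls import (
    SMALLER_IS_BETTER,
    NullDistribution,
    empirical_pvalue,
    random_pwm,
    zscore_against_null,
)
from .io import RankedEdgeList
from .pwm import PWMatrix

__all__ = [
    "ANALYTIC_PVALUE_FLOOR",
    "TimeCourseSet",
    "ParameterEstimate",
    "RankTable",
    "score_combined_logp_pair",
    "score_mean_neglogp",
    "edge_prediction_to_binary",
    "score_network_inference",
    "score_pwm_family",
    "score_parsimony_network",
    "compute_parsimony_weight",
    "score_sysgenb",
    "score_d6c3",
    "score_parameter_distance",
    "score_timecourse_distance",
    "score_d7c1_final",
    "score_d7c1_topology",
    "aggregate_mean_rank",
    "rank_table_from_scores",
    "score_olfaction",
    "score_d3c3",
]

#: floor applied to analytic (closed-form) p-values before a log-p combiner.
#: Closed-form association p-values underflow to exactly 0 at perfect
#: correlation; clamping at the smallest practically representable scale
#: keeps every log defined while remaining unreachable by any imperfect
#: prediction.  Empirical p-values need no floor: add-one smoothing already
#: bounds them below by 1/(N+1).
ANALYTIC_PVALUE_FLOOR = 1e-300


def _check_pvalues(ps, what: str = "p-value") -> np.ndarray:
    ps = np.asarray(ps, dtype=float).ravel()
    if ps.size == 0:
        raise ValidationError(f"empty {what} vector")
    if np.any(~np.isfinite(ps)) or np.any(ps <= 0) or np.any(ps > 1):
        raise ValidationError(f"every {what} must lie in (0, 1]")
    return ps


# ---------------------------------------------------------------------------
# log-p combiners
# ---------------------------------------------------------------------------

def score_combined_logp_pair(p_a: float, p_b: float) -> float:
    """``-(1/2) * log10(p_a * p_b)``.

    One implementation serves both challenge families that print this
    combiner (gene-expression prediction and epitope-antibody recognition);
    they are algebraically the same formula.
    """
    ps = _check_pvalues([p_a, p_b])
    return float(-0.5 * (np.log10(ps[0]) + np.log10(ps[1])))


def score_mean_neglogp(pvalues: Sequence[float]) -> float:
    """``-(1/N) * sum_i log10(p_i)`` — the log-transformed p-value average."""
    ps = _check_pvalues(pvalues)
    return float(-np.mean(np.log10(ps)))


def score_sysgenb(p_pheno1: float, p_pheno2: float) -> float:
    """Systems-genetics phenotype score ``-(log10 p1 + log10 p2)``."""
    ps = _check_pvalues([p_pheno1, p_pheno2])
    return float(-(np.log10(ps[0]) + np.log10(ps[1])))


def score_d6c3(pvalues: Sequence[float], *, log_mode: bool = False) -> float:
    """Promoter-activity score over exactly four metric p-values.

    The published formula is the literal product form ``-(1/4) * prod p_j``,
    which yields tiny negative numbers unlike every sibling combiner; it is
    evaluated literally here.  ``log_mode=True`` switches to the
    mean-neglogp combiner as an explicitly named alternative.
    """
    ps = _check_pvalues(pvalues)
    if ps.size != 4:
        raise ValidationError(f"expected exactly 4 p-values, got {ps.size}")
    if log_mode:
        return score_mean_neglogp(ps)
    return float(-0.25 * np.prod(ps))


def score_d7c1_final(p_param: float, p_timecourse: float) -> float:
    """Parameter-estimation final score ``-log10(p_param * p_timecourse)``.

    Note: no 1/2 factor, unlike :func:`score_combined_logp_pair`.
    """
    ps = _check_pvalues([p_param, p_timecourse])
    return float(-(np.log10(ps[0]) + np.log10(ps[1])))


def score_d7c1_topology(p_topology: float) -> float:
    """Topology sub-challenge score ``-log10(p_topology)``."""
    ps = _check_pvalues([p_topology])
    return float(-np.log10(ps[0]))


# ---------------------------------------------------------------------------
# network inference
# ---------------------------------------------------------------------------

def edge_prediction_to_binary(
    prediction: RankedEdgeList,
    gold_edges: set,
    node_universe: Sequence | None = None,
) -> BinaryPrediction:
    """Turn a ranked edge list into a binary classification over candidates.

    The candidate set is every ordered node pair (self-loops excluded) over
    the node universe — taken from the gold standard's node set unless
    supplied.  Listed edges keep their confidence; unlisted candidates share
    one confidence below the minimum listed value, so they tie (and ranking
    metrics count those ties 1/2 per pair).  Prediction edges outside the
    universe are an error listing the offenders.
    """
    gold_edges = {(s, t) for s, t in gold_edges}
    if node_universe is None:
        node_universe = prediction.node_universe
    if node_universe is None:
        node_universe = {n for e in gold_edges for n in e}
    universe = sorted(node_universe)
    uset = set(universe)
    offenders = [
        (s, t) for s, t in prediction.edge_pairs if s not in uset or t not in uset
    ]
    if offenders:
        raise ValidationError(
            f"prediction edges outside the node universe: {offenders}"
        )
    stray_gold = [(s, t) for s, t in gold_edges if s not in uset or t not in uset]
    if stray_gold:
        raise ValidationError(f"gold edges outside the node universe: {stray_gold}")
    conf = {(s, t): c for s, t, c in prediction.edges}
    fill = (min(conf.values()) - 1.0) if conf else 0.0
    scores, labels = [], []
    for s in universe:
        for t in universe:
            if s == t:
                continue
            scores.append(conf.get((s, t), fill))
            labels.append(1 if (s, t) in gold_edges else 0)
    return BinaryPrediction(scores=np.array(scores), labels=np.array(labels))


def score_network_inference(
    predictions: Sequence[RankedEdgeList],
    golds: Sequence[set],
    nulls: tuple,
) -> dict:
    """Multi-network score: per-network AUROC/AUPR p-values, combined.

    ``nulls`` is a pair ``(auroc_nulls, aupr_nulls)`` of NullDistribution
    lists, one per network.  Reports per-network metrics and p-values, the
    two mean-neglogp intermediate scores and their mean as the final score.
    """
    auroc_nulls, aupr_nulls = nulls
    if not (len(predictions) == len(golds) == len(auroc_nulls) == len(aupr_nulls)):
        raise ValidationError(
            "predictions, golds and both null lists must have matching lengths"
        )
    if not predictions:
        raise ValidationError("need at least one network")
    per_network = []
    p_aurocs, p_auprs = [], []
    for pred, gold, n_roc, n_pr in zip(predictions, golds, auroc_nulls, aupr_nulls):
        bp = edge_prediction_to_binary(pred, gold)
        a_roc, a_pr = auroc(bp), aupr(bp)
        p_roc = empirical_pvalue(a_roc, n_roc)
        p_pr = empirical_pvalue(a_pr, n_pr)
        p_aurocs.append(p_roc)
        p_auprs.append(p_pr)
        per_network.append(
            {"auroc": a_roc, "aupr": a_pr, "p_auroc": p_roc, "p_aupr": p_pr}
        )
    s_auroc = score_mean_neglogp(p_aurocs)
    s_aupr = score_mean_neglogp(p_auprs)
    return {
        "per_network": per_network,
        "s_auroc": s_auroc,
        "s_aupr": s_aupr,
        "final": 0.5 * (s_auroc + s_aupr),
    }


# ---------------------------------------------------------------------------
# PWM family
# ---------------------------------------------------------------------------

def score_pwm_family(
    predicted: Sequence[PWMatrix],
    gold: Sequence[PWMatrix],
    n_null: int,
    seed: int,
) -> dict:
    """Binding-specificity score for a family of PWM predictions.

    Per pair, the Frobenius distance to the gold PWM is converted into an
    empirical p-value against ``n_null`` random PWMs of the same shape
    (smaller distance is better); the family score is the mean-neglogp of
    those p-values.  Deterministic given the seed.
    """
    if len(predicted) != len(gold) or not gold:
        raise ValidationError("need equally many (>=1) predicted and gold PWMs")
    if n_null < 1:
        raise ValidationError("need n_null >= 1")
    rng = np.random.default_rng(seed)
    distances, pvalues, floors = [], [], []
    for pred_m, gold_m in zip(predicted, gold):
        if pred_m.values.shape != gold_m.values.shape:
            raise ValidationError(
                f"PWM shape mismatch: predicted {pred_m.values.shape} vs "
                f"gold {gold_m.values.shape}"
            )
        d = frobenius_distance(pred_m.values, gold_m.values)
        null_d = np.array(
            [
                frobenius_distance(
                    random_pwm(gold_m.n_rows, gold_m.n_cols, rng).values,
                    gold_m.values,
                )
                for _ in range(n_null)
            ]
        )
        null = NullDistribution(null_d, tail=SMALLER_IS_BETTER, name="frobenius")
        distances.append(d)
        pvalues.append(empirical_pvalue(d, null))
        floors.append(null.pvalue_floor)
    return {
        "distances": distances,
        "pvalues": pvalues,
        "pvalue_floor": floors[0],
        "final": score_mean_neglogp(pvalues),
    }


# ---------------------------------------------------------------------------
# parsimony-penalized signaling score
# ---------------------------------------------------------------------------

def score_parsimony_network(
    protein_pvalues: Sequence[float], r: float, n_edges: int
) -> float:
    """``S = Spred - r * Ne`` with ``Spred`` the mean-neglogp over proteins.

    ``r`` is a per-edge weight (see :func:`compute_parsimony_weight`) and
    ``n_edges`` the size of the submitted network; the penalty rewards
    parsimonious models.
    """
    if r < 0:
        raise ValidationError("edge weight r must be >= 0")
    if n_edges < 0:
        raise ValidationError("edge count must be >= 0")
    return score_mean_neglogp(protein_pvalues) - r * n_edges


def compute_parsimony_weight(
    cohort_scores: Sequence[float], cohort_edges: Sequence[int]
) -> float:
    """Minimum over participants of prediction score / edge count."""
    scores = np.asarray(cohort_scores, dtype=float).ravel()
    edges = np.asarray(cohort_edges, dtype=float).ravel()
    if scores.size == 0 or scores.shape != edges.shape:
        raise ValidationError("need a non-empty, matched cohort of scores and edges")
    if np.any(edges <= 0):
        raise ValidationError("edge counts must be positive")
    return float(np.min(scores / edges))


# ---------------------------------------------------------------------------
# parameter and time-course distances
# ---------------------------------------------------------------------------

@dataclass
class ParameterEstimate:
    """Estimated vs true model parameters (strictly positive)."""

    estimated: np.ndarray
    true_values: np.ndarray

    def __post_init__(self) -> None:
        est = np.asarray(self.estimated, dtype=float).ravel()
        true = np.asarray(self.true_values, dtype=float).ravel()
        if est.shape != true.shape or est.size == 0:
            raise ValidationError("estimated and true parameter vectors must match")
        if np.any(est <= 0) or np.any(true <= 0) or not (
            np.all(np.isfinite(est)) and np.all(np.isfinite(true))
        ):
            raise ValidationError(
                "parameters must be finite and strictly positive (log-ratio)"
            )
        object.__setattr__(self, "estimated", est)
        object.__setattr__(self, "true_values", true)

    @property
    def n_parameters(self) -> int:
        return int(self.estimated.size)


def score_parameter_distance(est: ParameterEstimate) -> float:
    """Mean squared log10-ratio ``(1/Np) sum [log10(est_i/true_i)]^2``.

    ``Np`` is taken from the vector length, never hard-coded.
    """
    ratios = np.log10(est.estimated / est.true_values)
    return float(np.mean(ratios**2))


@dataclass
class TimeCourseSet:
    """Predicted and gold time courses with the shared noise model.

    ``courses``/``golds`` are matched lists of (time x species) matrices;
    the first ``burn_in`` time points of every course are ignored (the
    initial segment was given to participants, so it carries no predictive
    information).
    """

    courses: list
    golds: list
    sigma_b: float = 0.1
    sigma_s: float = 0.2
    burn_in: int = 10

    def __post_init__(self) -> None:
        if len(self.courses) != len(self.golds) or not self.courses:
            raise ValidationError("need equally many (>=1) predicted and gold courses")
        courses = [np.atleast_2d(np.asarray(c, dtype=float)) for c in self.courses]
        golds = [np.atleast_2d(np.asarray(g, dtype=float)) for g in self.golds]
        for k, (c, g) in enumerate(zip(courses, golds)):
            if c.shape != g.shape:
                raise ValidationError(
                    f"course {k}: prediction shape {c.shape} != gold shape {g.shape}"
                )
            if self.burn_in >= c.shape[0]:
                raise ValidationError(
                    f"course {k}: burn-in {self.burn_in} >= course length {c.shape[0]}"
                )
        if self.burn_in < 0:
            raise ValidationError("burn-in must be >= 0")
        object.__setattr__(self, "courses", courses)
        object.__setattr__(self, "golds", golds)


def score_timecourse_distance(tc: TimeCourseSet) -> float:
    """Noise-normalized time-course distance, averaged over retained points.

    Sums the normalized squared error over every retained entry of every
    course and divides by the total retained count (for the canonical 3
    courses of 40 points with a 10-point burn-in this is the printed 1/90
    normalization).
    """
    total = 0.0
    count = 0
    for pred, gold in zip(tc.courses, tc.golds):
        p, g = pred[tc.burn_in :], gold[tc.burn_in :]
        denom = tc.sigma_b**2 + tc.sigma_s**2 * g**2
        total += float(np.sum((p - g) ** 2 / denom))
        count += p.size
    return total / count


# ---------------------------------------------------------------------------
# rank aggregation
# ---------------------------------------------------------------------------

@dataclass
class RankTable:
    """Per-context ranks for a set of teams (1 = best).

    Within each context the ranks must be a permutation of 1..n_teams,
    allowing average ranks on ties.
    """

    teams: list
    contexts: list
    ranks: np.ndarray

    def __post_init__(self) -> None:
        ranks = np.asarray(self.ranks, dtype=float)
        if ranks.shape != (len(self.teams), len(self.contexts)):
            raise ValidationError(
                f"ranks shape {ranks.shape} does not match "
                f"{len(self.teams)} teams x {len(self.contexts)} contexts"
            )
        n = len(self.teams)
        expected_sum = n * (n + 1) / 2
        for j, ctx in enumerate(self.contexts):
            col = ranks[:, j]
            if not np.isclose(col.sum(), expected_sum):
                raise ValidationError(
                    f"context {ctx!r}: ranks are not a (tie-averaged) "
                    f"permutation of 1..{n}"
                )
        object.__setattr__(self, "ranks", ranks)


def rank_table_from_scores(
    teams: Sequence,
    contexts: Sequence,
    scores: np.ndarray,
    *,
    greater_is_better: bool = True,
) -> RankTable:
    """Rank teams within each context from raw scores (average ranks on ties)."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (len(teams), len(contexts)):
        raise ValidationError("scores must be a (teams x contexts) matrix")
    oriented = -scores if greater_is_better else scores
    ranks = _stats.rankdata(oriented, method="average", axis=0)
    return RankTable(teams=list(teams), contexts=list(contexts), ranks=ranks)


def aggregate_mean_rank(rt: RankTable) -> dict:
    """Final score per team: the mean rank across contexts (lower = better)."""
    means = rt.ranks.mean(axis=1)
    return {team: float(m) for team, m in zip(rt.teams, means)}


# ---------------------------------------------------------------------------
# z-score aggregation (olfaction-style)
# ---------------------------------------------------------------------------

def score_olfaction(
    correlation_means: Sequence[float], nulls: Sequence[NullDistribution]
) -> dict:
    """Mean z-score of per-component mean correlations against their nulls."""
    if len(correlation_means) != len(nulls) or not nulls:
        raise ValidationError("need one null distribution per component")
    zs = [zscore_against_null(obs, null) for obs, null in zip(correlation_means, nulls)]
    return {"zscores": zs, "final": float(np.mean(zs))}


# ---------------------------------------------------------------------------
# rank-table expression prediction (time-profiles x gene-profiles)
# ---------------------------------------------------------------------------

def _spearman_family_pvalue(rhos_ps, floor: float) -> float:
    """Combine per-profile association p-values by Fisher's method (log space)."""
    ps = np.clip([p for _, p in rhos_ps], floor, 1.0)
    stat = -2.0 * np.sum(np.log(ps))
    # chi-square survival in log space: robust to very large statistics
    logp = _stats.chi2.logsf(stat, df=2 * len(ps))
    return float(np.clip(np.exp(logp), floor, 1.0))


def score_d3c3(
    pred_ranks: np.ndarray,
    gold: np.ndarray,
    *,
    p_floor: float = ANALYTIC_PVALUE_FLOOR,
) -> dict:
    """Expression-prediction score from per-time and per-gene rank profiles.

    ``pred_ranks`` is a (genes x time points) matrix whose columns are rank
    permutations 1..n_genes (most induced to most repressed); ``gold`` is
    the measured expression (or its ranks) with the same shape.  Spearman
    correlations and their association-test p-values are computed per time
    point (down columns) and per gene (across rows); each profile family is
    combined into a single p-value by Fisher's method, and the final score
    is ``-(1/2) log10(p_time * p_gene)``.
    """
    pred = np.asarray(pred_ranks, dtype=float)
    gold = np.asarray(gold, dtype=float)
    if pred.shape != gold.shape or pred.ndim != 2:
        raise ValidationError(
            f"prediction shape {pred.shape} must equal gold shape {gold.shape}"
        )
    n_genes, n_times = pred.shape
    if n_genes < 3 or n_times < 3:
        raise ValidationError("need at least 3 genes and 3 time points")
    expected = np.arange(1, n_genes + 1)
    for j in range(n_times):
        if not np.array_equal(np.sort(pred[:, j]), expected):
            raise ValidationError(
                f"time column {j}: ranks are not a permutation of 1..{n_genes}"
            )
    per_time = [_stats.spearmanr(pred[:, j], gold[:, j]) for j in range(n_times)]
    per_gene = [_stats.spearmanr(pred[i, :], gold[i, :]) for i in range(n_genes)]
    time_pairs = [(float(r.statistic), float(r.pvalue)) for r in per_time]
    gene_pairs = [(float(r.statistic), float(r.pvalue)) for r in per_gene]
    p_time = _spearman_family_pvalue(time_pairs, p_floor)
    p_gene = _spearman_family_pvalue(gene_pairs, p_floor)
    return {
        "per_time_rho": [r for r, _ in time_pairs],
        "per_gene_rho": [r for r, _ in gene_pairs],
        "p_time": p_time,
        "p_gene": p_gene,
        "final": score_combined_logp_pair(p_time, p_gene),
    }
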