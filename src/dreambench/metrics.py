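"""Atomic scoring metrics.

Stateless implementations of every elementary statistic the composite
challenge scores are assembled from: ranking metrics for binary
classification (AUROC, AUPR), confusion-matrix summaries, correlation
measures, censoring-aware concordance, and the noise-normalized error and
matrix distances used by the response-prediction challenges.

Conventions (shared by every metric here):

* ties between a positive and a negative in a ranking metric contribute 1/2
  per pair; Spearman uses average ranks;
* AUPR is the step-wise (non-interpolated) precision-recall area, ranking by
  descending score with tied scores grouped at a single threshold;
* the concordance index uses Harrell's admissible-pair rule — a pair is
  usable only when the record with the earlier time is an observed event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _stats
from sklearn import metrics as _skm

from .errors import ValidationError

__all__ = [
    "BinaryPrediction",
    "ConfusionCounts",
    "SurvivalRecord",
    "PairedSeries",
    "auroc",
    "aupr",
    "matthews_cc",
    "sensitivity",
    "specificity",
    "balanced_accuracy",
    "jaccard",
    "pearson",
    "spearman",
    "concordance_index",
    "probabilistic_concordance",
    "concordance_correlation",
    "normalized_squared_error",
    "rmse",
    "frobenius_distance",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class BinaryPrediction:
    """Paired confidence scores and binary labels (1 = positive)."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels)
        if scores.ndim != 1 or labels.ndim != 1:
            raise ValidationError("scores and labels must be 1-D vectors")
        if scores.shape != labels.shape:
            raise ValidationError(
                f"scores (n={scores.size}) and labels (n={labels.size}) "
                "must have equal length"
            )
        if not np.all(np.isfinite(scores)):
            raise ValidationError("non-finite confidence scores")
        uniq = set(np.unique(labels).tolist())
        if not uniq <= {0, 1}:
            raise ValidationError(f"labels must be in {{0,1}}, found {sorted(uniq)}")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels.astype(int))

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int(self.labels.size - self.labels.sum())

    def require_both_classes(self) -> None:
        if self.n_positive == 0:
            raise ValidationError("degenerate labels: no positive examples")
        if self.n_negative == 0:
            raise ValidationError("degenerate labels: no negative examples")


@dataclass
class ConfusionCounts:
    """Entries of a 2x2 confusion matrix."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
            setattr(self, name, int(v))


@dataclass
class SurvivalRecord:
    """One subject: follow-up time, event flag and a predicted risk.

    ``event`` is 1 when the event was observed and 0 when the record is
    censored at ``time``.  The orientation of ``risk`` (whether larger means
    riskier, i.e. shorter expected survival) is declared by the caller of
    the concordance functions.
    """

    time: float
    event: int
    risk: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise ValidationError(f"time must be finite and >= 0, got {self.time!r}")
        if self.event not in (0, 1):
            raise ValidationError(f"event must be 0 or 1, got {self.event!r}")
        if not np.isfinite(self.risk):
            raise ValidationError(f"risk must be finite, got {self.risk!r}")


@dataclass
class PairedSeries:
    """A predicted and an observed real vector of equal length."""

    predicted: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        pred = np.asarray(self.predicted, dtype=float)
        obs = np.asarray(self.observed, dtype=float)
        if pred.ndim != 1 or obs.ndim != 1 or pred.shape != obs.shape:
            raise ValidationError(
                f"predicted (n={pred.size}) and observed (n={obs.size}) must be "
                "1-D vectors of equal length"
            )
        if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(obs))):
            raise ValidationError("non-finite values in paired series")
        object.__setattr__(self, "predicted", pred)
        object.__setattr__(self, "observed", obs)

    def require_length(self, n: int) -> None:
        if self.predicted.size < n:
            raise ValidationError(f"need at least {n} pairs, got {self.predicted.size}")


# ---------------------------------------------------------------------------
# ranking metrics
# ---------------------------------------------------------------------------

def auroc(p: BinaryPrediction) -> float:
    """Area under the ROC curve.

    Equals the Mann-Whitney statistic: the fraction of (positive, negative)
    pairs where the positive outranks the negative, ties counted 1/2.
    """
    p.require_both_classes()
    return float(_skm.roc_auc_score(p.labels, p.scores))


def aupr(p: BinaryPrediction) -> float:
    """Step-wise (non-interpolated) area under the precision-recall curve."""
    p.require_both_classes()
    return float(_skm.average_precision_score(p.labels, p.scores))


# ---------------------------------------------------------------------------
# confusion-matrix metrics
# ---------------------------------------------------------------------------

def matthews_cc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient.

    Returns 0 (with a warning) when any factor of the denominator is zero;
    this is the standard convention for degenerate cohorts.
    """
    tp, fp, tn, fn = (float(c.tp), float(c.fp), float(c.tn), float(c.fn))
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        warnings.warn(
            "Matthews correlation undefined (zero denominator factor); returning 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom_sq)


def sensitivity(c: ConfusionCounts) -> float:
    """True positive rate tp/(tp+fn)."""
    if c.tp + c.fn == 0:
        raise ValidationError("sensitivity undefined: no positive examples (tp+fn=0)")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """True negative rate tn/(tn+fp)."""
    if c.tn + c.fp == 0:
        raise ValidationError("specificity undefined: no negative examples (tn+fp=0)")
    return c.tn / (c.tn + c.fp)


def balanced_accuracy(c: ConfusionCounts) -> float:
    """Mean of sensitivity and specificity."""
    return 0.5 * (sensitivity(c) + specificity(c))


def jaccard(a: set, b: set) -> float:
    """|a n b| / |a u b|; undefined (error) when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValidationError("Jaccard similarity undefined for two empty sets")
    return len(a & b) / len(union)


# ---------------------------------------------------------------------------
# correlation metrics
# ---------------------------------------------------------------------------

def _require_variance(s: PairedSeries) -> None:
    s.require_length(2)
    if np.ptp(s.predicted) == 0:
        raise ValidationError("predicted vector has zero variance")
    if np.ptp(s.observed) == 0:
        raise ValidationError("observed vector has zero variance")


def pearson(s: PairedSeries) -> float:
    """Product-moment correlation between predicted and observed."""
    _require_variance(s)
    return float(_stats.pearsonr(s.predicted, s.observed).statistic)


def spearman(s: PairedSeries) -> float:
    """Rank correlation (average ranks on ties)."""
    _require_variance(s)
    return float(_stats.spearmanr(s.predicted, s.observed).statistic)


def concordance_correlation(s: PairedSeries) -> float:
    """Lin's concordance correlation coefficient (CCC).

    2*cov(x,y) / (var(x) + var(y) + (mean(x) - mean(y))^2) with population
    (1/n) moments.  Unlike Pearson it penalizes location and scale bias, so
    it measures *agreement* on a continuous scale, not just association.
    """
    s.require_length(2)
    x, y = s.predicted, s.observed
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()          # population moments
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        raise ValidationError("CCC undefined: zero total denominator")
    return float(2 * cov / denom)


# ---------------------------------------------------------------------------
# concordance for (possibly censored) survival-type outcomes
# ---------------------------------------------------------------------------

def _survival_arrays(records: Sequence[SurvivalRecord]):
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    r = np.array([r.risk for r in records], dtype=float)
    return t, e, r


def concordance_index(
    records: Sequence[SurvivalRecord], *, higher_risk_shorter_survival: bool = True
) -> float:
    """Harrell's concordance index over admissible record pairs.

    A pair is admissible when the record with the strictly earlier time is
    an observed event (censored-vs-censored pairs, pairs whose earlier time
    is censored, and tied-time pairs carry no ordering information and are
    excluded).  A pair is concordant when the predicted risks order the two
    subjects the same way as their event times; tied risks count 1/2.

    ``higher_risk_shorter_survival`` declares the orientation of the
    prediction; the default treats larger values as riskier.
    """
    t, e, r = _survival_arrays(records)
    if not higher_risk_shorter_survival:
        r = -r
    # admissible: t_i < t_j and event_i == 1 (i indexes rows)
    adm = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_adm = int(adm.sum())
    if n_adm == 0:
        raise ValidationError("no admissible pairs (all censored or tied times)")
    conc = r[:, None] > r[None, :]
    tied = r[:, None] == r[None, :]
    score = (adm & conc).sum() + 0.5 * (adm & tied).sum()
    return float(score / n_adm)


def probabilistic_concordance(
    records: Sequence[SurvivalRecord],
    sd: Sequence[float],
    *,
    higher_risk_shorter_survival: bool = True,
) -> float:
    """Probabilistic concordance — a soft variant of the concordance index.

    Each admissible pair contributes the probability, under a normal model
    of the observed outcome difference with pooled variance
    ``sd_i**2 + sd_j**2``, that the observed ordering reflects the true one:
    a concordant pair contributes ``Phi(dt / s)``, a discordant pair
    ``1 - Phi(dt / s)`` and a risk tie 1/2.  As every sd tends to 0 this
    recovers :func:`concordance_index` on tie-free times.

    Tied observed times are admissible here when at least one record is an
    event; such a pair contributes exactly 1/2 regardless of the predicted
    ordering (``Phi(0)``), reflecting total uncertainty about the true
    ordering.  This is a documented variant: the exact weighted wpc-index
    used by the drug-sensitivity challenges is defined in external
    supplementary material and is deliberately not reproduced here.
    """
    t, e, r = _survival_arrays(records)
    sd = np.asarray(sd, dtype=float)
    if sd.shape != t.shape:
        raise ValidationError("need one standard deviation per record")
    if np.any(sd < 0) or not np.all(np.isfinite(sd)):
        raise ValidationError("standard deviations must be finite and >= 0")
    if not higher_risk_shorter_survival:
        r = -r
    n = t.size
    total = 0.0
    n_adm = 0
    for i in range(n):
        for j in range(i + 1, n):
            if t[i] < t[j]:
                a, b = i, j
            elif t[j] < t[i]:
                a, b = j, i
            else:
                # tied times: admissible iff at least one event
                if e[i] == 0 and e[j] == 0:
                    continue
                n_adm += 1
                total += 0.5
                continue
            if e[a] != 1:  # earlier record censored: no ordering information
                continue
            n_adm += 1
            dt = t[b] - t[a]
            s = float(np.hypot(sd[a], sd[b]))
            p_obs = 1.0 if s == 0 else float(_stats.norm.cdf(dt / s))
            if r[a] > r[b]:        # prediction concordant with observation
                total += p_obs
            elif r[a] < r[b]:
                total += 1.0 - p_obs
            else:
                total += 0.5
    if n_adm == 0:
        raise ValidationError("no admissible pairs (all censored or tied times)")
    return total / n_adm


# ---------------------------------------------------------------------------
# error / distance metrics
# ---------------------------------------------------------------------------

def normalized_squared_error(
    pred, gold, sigma_b: float = 0.1, sigma_s: float = 0.2
) -> float:
    """Measurement-noise-normalized squared error.

    ``sum_i (pred_i - gold_i)^2 / (sigma_b^2 + sigma_s^2 * gold_i^2)``.

    ``sigma_b`` is a baseline (signal-independent) noise level and
    ``sigma_s`` a signal-dependent one; the defaults 0.1 and 0.2 are the
    values used by the signaling-response challenges.  With noise actually
    drawn from this variance model every term has unit expectation.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    gold = np.asarray(gold, dtype=float).ravel()
    if pred.shape != gold.shape:
        raise ValidationError(
            f"length mismatch: prediction n={pred.size}, gold n={gold.size}"
        )
    if sigma_b < 0 or sigma_s < 0 or (sigma_b == 0 and sigma_s == 0):
        raise ValidationError("sigma_b, sigma_s must be >= 0 and not both 0")
    denom = sigma_b**2 + sigma_s**2 * gold**2
    if np.any(denom == 0):
        raise ValidationError("zero denominator (gold value 0 with sigma_b = 0)")
    return float(np.sum((pred - gold) ** 2 / denom))


def rmse(s: PairedSeries) -> float:
    """Root mean squared error between predicted and observed."""
    if s.predicted.size == 0:
        raise ValidationError("rmse undefined on empty input")
    return float(np.sqrt(np.mean((s.predicted - s.observed) ** 2)))


def frobenius_distance(a, b) -> float:
    """Frobenius distance ||a - b||_F between two equally shaped matrices."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b, "fro") if a.ndim == 2 else np.linalg.norm(a - b))
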