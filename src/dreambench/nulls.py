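"""Empirical and exact null distributions.

Challenge scores become comparable across metrics by converting them into
p-values against a stated null: either an empirical null (the statistic
recomputed on shuffled gold standards or random predictions) or, where the
prediction space is small enough to enumerate, an exact combinatorial null.

Every stochastic operation takes an explicit integer seed and is
reproducible bit-for-bit; there is no hidden global RNG state.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .errors import ValidationError
from .pwm import PWMatrix, normalize_columns

__all__ = [
    "GREATER_IS_BETTER",
    "SMALLER_IS_BETTER",
    "NullDistribution",
    "AssignmentNullSpec",
    "empirical_pvalue",
    "zscore_against_null",
    "random_pwm",
    "shuffled_gold_null",
    "assignment_tail_probability",
    "assignment_tail_probability_mc",
]

GREATER_IS_BETTER = "greater_is_better"
SMALLER_IS_BETTER = "smaller_is_better"

#: hard cap on the number of assignments the exact enumerator will visit
_ENUMERATION_LIMIT = 2_000_000


@dataclass
class NullDistribution:
    """A finite sample of a score statistic under a stated null.

    ``tail`` declares, once and explicitly, which direction of the statistic
    counts as better (the challenge corpus mixes greater-is-better metrics
    such as AUROC with smaller-is-better distances); it is never inferred.
    """

    samples: np.ndarray
    tail: str
    name: str = field(default="statistic")

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float).ravel()
        if samples.size == 0:
            raise ValidationError("a null distribution needs at least one sample")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("null samples must be finite")
        if self.tail not in (GREATER_IS_BETTER, SMALLER_IS_BETTER):
            raise ValidationError(
                f"tail must be {GREATER_IS_BETTER!r} or {SMALLER_IS_BETTER!r}, "
                f"got {self.tail!r}"
            )
        object.__setattr__(self, "samples", samples)

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def pvalue_floor(self) -> float:
        """Smallest p-value this null can produce: 1/(N+1)."""
        return 1.0 / (self.n + 1)

    def pvalue(self, observed: float) -> float:
        return empirical_pvalue(observed, self)

    def zscore(self, observed: float) -> float:
        return zscore_against_null(observed, self)

    # -- single-column CSV with a two-line header (name, tail) -------------
    def to_csv(self, path) -> None:
        """Write the samples so a published null can be replayed elsewhere."""
        lines = [self.name, self.tail]
        lines.extend(repr(float(x)) for x in self.samples)
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path) -> "NullDistribution":
        lines = Path(path).read_text().splitlines()
        if len(lines) < 3:
            raise ValidationError(
                f"{path}: expected 2 header lines (name, tail) plus samples"
            )
        name, tail = lines[0].strip(), lines[1].strip()
        samples = np.array([float(x) for x in lines[2:] if x.strip()], dtype=float)
        return cls(samples=samples, tail=tail, name=name)


def empirical_pvalue(observed: float, null: NullDistribution) -> float:
    """Add-one-smoothed empirical p-value.

    ``(1 + #{null samples at least as extreme as observed}) / (N + 1)``,
    where "extreme" follows the declared tail direction.  The add-one
    smoothing guarantees p >= 1/(N+1) > 0, so downstream log-p combiners
    never see a zero.
    """
    if not np.isfinite(observed):
        raise ValidationError("observed statistic must be finite")
    if null.tail == GREATER_IS_BETTER:
        c = int(np.count_nonzero(null.samples >= observed))
    else:
        c = int(np.count_nonzero(null.samples <= observed))
    return (1 + c) / (null.n + 1)


def zscore_against_null(observed: float, null: NullDistribution) -> float:
    """(observed - mean(null)) / sd(null), sample sd with N-1 denominator."""
    if null.n < 2:
        raise ValidationError("z-score needs a null with at least 2 samples")
    sd = float(np.std(null.samples, ddof=1))
    if sd == 0:
        raise ValidationError("z-score undefined: null has zero standard deviation")
    return float((observed - np.mean(null.samples)) / sd)


# ---------------------------------------------------------------------------
# null generators
# ---------------------------------------------------------------------------

def random_pwm(n_rows: int, n_cols: int, rng_seed) -> PWMatrix:
    """A random position weight matrix.

    Entries are i.i.d. uniform(0,1), then each column is rescaled to sum to
    one.  ``rng_seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValidationError("PWM dimensions must be positive")
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator
    ) else rng_seed
    values = normalize_columns(rng.uniform(size=(n_rows, n_cols)))
    return PWMatrix(values=values, name="random")


def shuffled_gold_null(
    metric: Callable,
    prediction,
    gold,
    n: int,
    rng_seed: int,
    *,
    tail: str = GREATER_IS_BETTER,
    name: str = "statistic",
) -> NullDistribution:
    """Empirical null from uniformly permuted gold standards.

    Calls ``metric(prediction, permuted_gold)`` on ``n`` independent uniform
    permutations of the gold standard (permuted along the first axis for
    arrays, element order for sequences).  Deterministic given the seed.
    """
    if n < 1:
        raise ValidationError("need n >= 1 null samples")
    rng = np.random.default_rng(rng_seed)
    gold_arr = np.asarray(gold)
    samples = np.empty(n, dtype=float)
    for i in range(n):
        perm = rng.permutation(gold_arr.shape[0])
        samples[i] = float(metric(prediction, gold_arr[perm]))
    return NullDistribution(samples=samples, tail=tail, name=name)


# ---------------------------------------------------------------------------
# exact assignment null
# ---------------------------------------------------------------------------

@dataclass
class AssignmentNullSpec:
    """Null model of uniformly random identity assignments.

    ``n_slots`` measured entities each receive one of ``n_categories``
    candidate identities; ``injective`` forbids assigning the same identity
    twice (e.g. 4 measured proteins drawn from 7 molecular species).
    """

    n_slots: int
    n_categories: int
    injective: bool = True

    def __post_init__(self) -> None:
        if self.n_slots < 1 or self.n_categories < 1:
            raise ValidationError("n_slots and n_categories must be positive")
        if self.injective and self.n_slots > self.n_categories:
            raise ValidationError(
                "injective assignment needs n_slots <= n_categories"
            )

    @property
    def n_assignments(self) -> int:
        if self.injective:
            return math.perm(self.n_categories, self.n_slots)
        return self.n_categories**self.n_slots


def _iter_assignments(spec: AssignmentNullSpec):
    cats = range(spec.n_categories)
    if spec.injective:
        return itertools.permutations(cats, spec.n_slots)
    return itertools.product(cats, repeat=spec.n_slots)


def assignment_tail_probability(spec: AssignmentNullSpec, k: int) -> float:
    """Exact P(#correct >= k) under a uniformly random assignment.

    Without loss of generality the true assignment maps slot i to category
    i; a random assignment is correct on slot i when it also does.  Computed
    by exhaustive enumeration; raises when the assignment space exceeds the
    enumeration bound (use :func:`assignment_tail_probability_mc` then).
    """
    if not 0 <= k <= spec.n_slots:
        raise ValidationError(f"k must be in [0, {spec.n_slots}], got {k}")
    total = spec.n_assignments
    if total > _ENUMERATION_LIMIT:
        raise ValidationError(
            f"{total} assignments exceed the enumeration bound "
            f"({_ENUMERATION_LIMIT}); use assignment_tail_probability_mc"
        )
    if k == 0:
        return 1.0
    hits = 0
    for assignment in _iter_assignments(spec):
        correct = sum(1 for i, c in enumerate(assignment) if c == i)
        if correct >= k:
            hits += 1
    return hits / total


def assignment_tail_probability_mc(
    spec: AssignmentNullSpec, k: int, n_draws: int, rng_seed: int
) -> float:
    """Monte-Carlo estimate of P(#correct >= k) for large assignment spaces."""
    if not 0 <= k <= spec.n_slots:
        raise ValidationError(f"k must be in [0, {spec.n_slots}], got {k}")
    if n_draws < 1:
        raise ValidationError("need n_draws >= 1")
    rng = np.random.default_rng(rng_seed)
    slots = np.arange(spec.n_slots)
    hits = 0
    for _ in range(n_draws):
        if spec.injective:
            draw = rng.permutation(spec.n_categories)[: spec.n_slots]
        else:
            draw = rng.integers(0, spec.n_categories, size=spec.n_slots)
        if int(np.count_nonzero(draw == slots)) >= k:
            hits += 1
    return hits / n_draws
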