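"""Deterministic synthetic gold standards and graded-quality predictions.

Every scorer in the package can be exercised without any download: these
generators build a gold standard and a prediction whose fidelity is
controlled by a single ``quality`` knob in [0, 1] — 1 reproduces the gold
standard itself, 0 is pure noise, and intermediate values interpolate so
that every scorer's expected score improves monotonically with quality.

For gold standards that are *discrete* (edge indicators, binary labels) the
quality knob acts as a mixture: each item is informative (carries the gold
indicator) with probability ``quality`` and pure uniform noise otherwise.
For continuous gold standards the prediction is the gold plus
``(1 - quality)``-scaled noise.  Identical arguments always produce
bit-identical fixtures.

Two layers are provided: ``make_*`` generators draw a gold standard *and* a
prediction from one seed, while the ``graded_*`` helpers draw a fresh
prediction of stated quality against an existing gold standard (this is
what the bundled challenges use, so one frozen gold can face many
submissions).

None of this emulates the biological content of any real challenge data
set — only the statistical shape the scoring procedures consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .errors import ValidationError
from .io import RankedEdgeList
from .metrics import BinaryPrediction, SurvivalRecord
from .nulls import AssignmentNullSpec, random_pwm
from .pwm import PWMatrix, normalize_columns
from .scores import ParameterEstimate, TimeCourseSet

__all__ = [
    "FixtureSpec",
    "make_network_fixture",
    "make_timecourse_fixture",
    "make_survival_fixture",
    "make_pwm_fixture",
    "make_binary_fixture",
    "make_table_fixture",
    "make_assignment_fixture",
    "make_parameter_fixture",
    "make_fixture",
    "graded_edge_prediction",
    "graded_binary_scores",
    "graded_table_ranks",
    "graded_survival_risk",
    "graded_pwm_prediction",
    "graded_timecourse_prediction",
    "graded_parameter_estimate",
    "graded_assignment",
]

_KINDS = (
    "network",
    "pwm",
    "timecourse",
    "survival",
    "table",
    "assignment",
    "binary",
    "parameters",
)


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic fixture."""

    kind: str
    quality: float
    seed: int
    sizes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(f"unknown fixture kind {self.kind!r}; one of {_KINDS}")
        if not 0.0 <= self.quality <= 1.0:
            raise ValidationError(f"quality must be in [0,1], got {self.quality}")
        if self.seed is None:
            raise ValidationError("a seed is mandatory")


def _check_quality(quality: float) -> None:
    if not 0.0 <= quality <= 1.0:
        raise ValidationError(f"quality must be in [0,1], got {quality}")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def _erdos_renyi_edges(rng, nodes, n_edges):
    n = len(nodes)
    candidates = [(i, j) for i in range(n) for j in range(n) if i != j]
    idx = rng.choice(len(candidates), size=n_edges, replace=False)
    return {(nodes[candidates[k][0]], nodes[candidates[k][1]]) for k in idx}


def _scale_free_edges(rng, nodes, n_edges):
    """Directed preferential attachment, trimmed to the exact edge budget."""
    n = len(nodes)
    in_degree = np.ones(n)  # +1 smoothing so isolated nodes stay reachable
    edges = set()
    guard = 0
    while len(edges) < n_edges:
        guard += 1
        if guard > 100 * n_edges + 1000:
            raise ValidationError(
                "preferential attachment stalled; edge budget infeasible"
            )
        src = int(rng.integers(n))
        tgt = int(rng.choice(n, p=in_degree / in_degree.sum()))
        if src == tgt or (nodes[src], nodes[tgt]) in edges:
            continue
        edges.add((nodes[src], nodes[tgt]))
        in_degree[tgt] += 1
    return edges


def graded_edge_prediction(
    gold_edges: set, nodes, quality: float, seed: int
) -> RankedEdgeList:
    """Rank every candidate ordered pair with mixture-graded confidences."""
    _check_quality(quality)
    rng = np.random.default_rng(seed)
    edges = []
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            indicator = 1.0 if (s, t) in gold_edges else 0.0
            conf = indicator if rng.random() < quality else rng.random()
            edges.append((s, t, conf))
    return RankedEdgeList(edges=edges, node_universe=frozenset(nodes))


def make_network_fixture(
    n_nodes: int = 50,
    n_edges: int = 100,
    topology: str = "erdos_renyi",
    quality: float = 0.5,
    seed: int = 0,
):
    """A directed gold network and a graded-quality ranked edge prediction.

    The defaults mirror the in-silico network-inference setting of about 50
    nodes and 100 directed edges.  Returns ``(gold_edge_set, RankedEdgeList)``.
    """
    _check_quality(quality)
    if n_edges > n_nodes * (n_nodes - 1):
        raise ValidationError(
            f"{n_edges} edges infeasible for {n_nodes} nodes (directed, no loops)"
        )
    if topology not in ("erdos_renyi", "scale_free"):
        raise ValidationError(f"unknown topology {topology!r}")
    rng = np.random.default_rng(seed)
    nodes = [f"g{i + 1}" for i in range(n_nodes)]
    gold = (
        _erdos_renyi_edges(rng, nodes, n_edges)
        if topology == "erdos_renyi"
        else _scale_free_edges(rng, nodes, n_edges)
    )
    pred_seed = int(rng.integers(2**31))
    return gold, graded_edge_prediction(gold, nodes, quality, pred_seed)


# ---------------------------------------------------------------------------
# time courses
# ---------------------------------------------------------------------------

def graded_timecourse_prediction(
    golds,
    sigma_b: float,
    sigma_s: float,
    burn_in: int,
    quality: float,
    seed: int,
) -> TimeCourseSet:
    """Gold courses plus ``(1-quality)``-scaled heteroscedastic noise."""
    _check_quality(quality)
    rng = np.random.default_rng(seed)
    courses = []
    for gold in golds:
        gold = np.atleast_2d(np.asarray(gold, dtype=float))
        sd = np.sqrt(sigma_b**2 + sigma_s**2 * gold**2)
        courses.append(gold + (1.0 - quality) * rng.normal(scale=sd))
    return TimeCourseSet(
        courses=courses,
        golds=[np.atleast_2d(np.asarray(g, dtype=float)) for g in golds],
        sigma_b=sigma_b,
        sigma_s=sigma_s,
        burn_in=burn_in,
    )


def make_timecourse_fixture(
    n_courses: int = 3,
    n_times: int = 40,
    burn_in: int = 10,
    sigma_b: float = 0.1,
    sigma_s: float = 0.2,
    quality: float = 0.5,
    seed: int = 0,
    n_species: int = 1,
) -> TimeCourseSet:
    """Smooth gold trajectories plus heteroscedastic prediction noise.

    The prediction is ``gold + (1 - quality) * eps`` with
    ``eps ~ N(0, sigma_b^2 + sigma_s^2 * gold^2)`` — the same variance that
    normalizes the squared-error score, so at quality 0 each retained point
    contributes 1 to the score in expectation (an analytic anchor).
    """
    _check_quality(quality)
    if n_times <= burn_in:
        raise ValidationError("n_times must exceed burn_in")
    rng = np.random.default_rng(seed)
    t = np.arange(n_times)[:, None]
    golds = []
    for _ in range(n_courses):
        amp = rng.uniform(0.5, 1.5, size=(1, n_species))
        freq = rng.uniform(0.5, 2.0, size=(1, n_species))
        phase = rng.uniform(0, 2 * np.pi, size=(1, n_species))
        offset = rng.uniform(0.5, 1.5, size=(1, n_species))
        golds.append(offset + amp * np.sin(2 * np.pi * freq * t / n_times + phase))
    pred_seed = int(rng.integers(2**31))
    return graded_timecourse_prediction(
        golds, sigma_b, sigma_s, burn_in, quality, pred_seed
    )


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------

def graded_survival_risk(times, quality: float, seed: int) -> np.ndarray:
    """Risk scores mixing a perfect-ranking oracle with standard normal noise.

    The oracle component is ``-log(observed time)`` standardized, so quality
    1 orders every admissible pair correctly and quality 0 is uninformative.
    """
    _check_quality(quality)
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    oracle = -np.log(times)
    z = (oracle - oracle.mean()) / oracle.std() if times.size > 1 else oracle
    return quality * z + (1.0 - quality) * rng.normal(size=times.size)


def make_survival_fixture(
    n: int = 100,
    censor_rate: float = 0.2,
    quality: float = 0.5,
    seed: int = 0,
) -> list:
    """A censored survival cohort with a graded-quality risk prediction.

    Event times are exponential with per-subject log-rate eta ~ N(0,1);
    each record is independently censored with probability ``censor_rate``
    (the censoring time falling uniformly before the event).
    """
    _check_quality(quality)
    if not 0.0 <= censor_rate < 1.0:
        raise ValidationError(f"censor_rate must be in [0,1), got {censor_rate}")
    rng = np.random.default_rng(seed)
    eta = rng.normal(size=n)
    event_time = rng.exponential(scale=np.exp(-eta))
    censored = rng.random(n) < censor_rate
    observed = np.where(censored, event_time * rng.random(n), event_time)
    risk = graded_survival_risk(observed, quality, int(rng.integers(2**31)))
    return [
        SurvivalRecord(time=float(t), event=int(not c), risk=float(r))
        for t, c, r in zip(observed, censored, risk)
    ]


# ---------------------------------------------------------------------------
# PWMs
# ---------------------------------------------------------------------------

def graded_pwm_prediction(golds, quality: float, seed: int) -> list:
    """Column-renormalized convex mix of each gold PWM with a fresh random one."""
    _check_quality(quality)
    rng = np.random.default_rng(seed)
    preds = []
    for gold in golds:
        noise = random_pwm(gold.n_rows, gold.n_cols, rng)
        mixed = normalize_columns(
            quality * gold.values + (1.0 - quality) * noise.values
        )
        preds.append(PWMatrix(values=mixed, name=gold.name))
    return preds


def make_pwm_fixture(
    n_matrices: int = 3,
    n_rows: int = 4,
    n_cols: int = 8,
    quality: float = 0.5,
    seed: int = 0,
):
    """Gold PWMs and predicted PWMs at the requested fidelity.

    At quality 1 the Frobenius distances are exactly 0.  Returns
    ``(gold_list, pred_list)``.
    """
    _check_quality(quality)
    rng = np.random.default_rng(seed)
    golds = [
        PWMatrix(values=random_pwm(n_rows, n_cols, rng).values, name=f"pwm{k + 1}")
        for k in range(n_matrices)
    ]
    return golds, graded_pwm_prediction(golds, quality, int(rng.integers(2**31)))


# ---------------------------------------------------------------------------
# binary cohorts, tables, assignments, parameters
# ---------------------------------------------------------------------------

def graded_binary_scores(labels, quality: float, seed: int) -> BinaryPrediction:
    """Mixture-graded confidences for fixed binary labels."""
    _check_quality(quality)
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=int)
    informative = rng.random(labels.size) < quality
    scores = np.where(informative, labels.astype(float), rng.random(labels.size))
    return BinaryPrediction(scores=scores, labels=labels)


def make_binary_fixture(
    n_pos: int = 50,
    n_neg: int = 150,
    quality: float = 0.5,
    seed: int = 0,
) -> BinaryPrediction:
    """Binary labels with mixture-graded confidence scores.

    Defaults echo the classic target-identification setting of 50 true
    targets among 200 candidates.
    """
    _check_quality(quality)
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    rng.shuffle(labels)
    return graded_binary_scores(labels, quality, int(rng.integers(2**31)))


def graded_table_ranks(gold: np.ndarray, quality: float, seed: int) -> np.ndarray:
    """Per-column rank permutations correlated with the gold table."""
    _check_quality(quality)
    rng = np.random.default_rng(seed)
    gold = np.asarray(gold, dtype=float)
    zgold = (gold - gold.mean(axis=0)) / gold.std(axis=0)
    noisy = quality * zgold + (1.0 - quality) * rng.normal(size=gold.shape)
    return _stats.rankdata(noisy, method="ordinal", axis=0).astype(float)


def make_table_fixture(
    n_rows: int = 50,
    n_cols: int = 8,
    quality: float = 0.5,
    seed: int = 0,
):
    """A gold value table and a predicted per-column rank table.

    Models the expression-prediction setting: ``n_rows`` genes at
    ``n_cols`` time points, the submission being a rank permutation per
    column (most induced to most repressed).  Returns
    ``(gold_values, predicted_ranks)``.
    """
    _check_quality(quality)
    rng = np.random.default_rng(seed)
    gold = rng.normal(size=(n_rows, n_cols))
    return gold, graded_table_ranks(gold, quality, int(rng.integers(2**31)))


def graded_assignment(
    spec: AssignmentNullSpec, quality: float = 0.5, seed: int = 0
) -> list:
    """A predicted identity assignment with quality-graded correctness.

    The true assignment maps slot i to category i.  Each slot is kept
    correct with probability ``quality``; the remaining slots receive a
    random (injectivity-respecting when required) incorrect category.
    """
    _check_quality(quality)
    rng = np.random.default_rng(seed)
    keep = rng.random(spec.n_slots) < quality
    assignment = [-1] * spec.n_slots
    used = set()
    for i in range(spec.n_slots):
        if keep[i]:
            assignment[i] = i
            if spec.injective:
                used.add(i)
    for i in range(spec.n_slots):
        if assignment[i] >= 0:
            continue
        if spec.injective:
            choices = [c for c in range(spec.n_categories) if c != i and c not in used]
            if not choices:  # forced: only the correct category remains
                choices = [c for c in range(spec.n_categories) if c not in used]
            pick = int(rng.choice(choices))
            used.add(pick)
        else:
            choices = [c for c in range(spec.n_categories) if c != i]
            pick = int(rng.choice(choices))
        assignment[i] = pick
    return assignment


#: kept under the generator naming convention used by the other fixtures
make_assignment_fixture = graded_assignment


def graded_parameter_estimate(
    true_values, log_error_scale: float, quality: float, seed: int
) -> ParameterEstimate:
    """An estimate off by ``(1-quality)*eps`` decades per parameter."""
    _check_quality(quality)
    rng = np.random.default_rng(seed)
    true = np.asarray(true_values, dtype=float)
    eps = rng.normal(scale=log_error_scale, size=true.size)
    est = true * 10.0 ** ((1.0 - quality) * eps)
    return ParameterEstimate(estimated=est, true_values=true)


def make_parameter_fixture(
    n_parameters: int = 18,
    log_error_scale: float = 0.5,
    quality: float = 0.5,
    seed: int = 0,
) -> ParameterEstimate:
    """True kinetic parameters and a graded-quality estimate.

    True parameters are log-uniform over two decades; quality 1 recovers
    them exactly.
    """
    _check_quality(quality)
    rng = np.random.default_rng(seed)
    true = 10.0 ** rng.uniform(-1, 1, size=n_parameters)
    return graded_parameter_estimate(
        true, log_error_scale, quality, int(rng.integers(2**31))
    )


def make_fixture(spec: FixtureSpec):
    """Dispatch a :class:`FixtureSpec` to the matching generator."""
    makers = {
        "network": make_network_fixture,
        "pwm": make_pwm_fixture,
        "timecourse": make_timecourse_fixture,
        "survival": make_survival_fixture,
        "table": make_table_fixture,
        "binary": make_binary_fixture,
        "parameters": make_parameter_fixture,
    }
    if spec.kind == "assignment":
        null_spec = AssignmentNullSpec(
            n_slots=spec.sizes.get("n_slots", 4),
            n_categories=spec.sizes.get("n_categories", 7),
            injective=spec.sizes.get("injective", True),
        )
        return graded_assignment(null_spec, quality=spec.quality, seed=spec.seed)
    return makers[spec.kind](**spec.sizes, quality=spec.quality, seed=spec.seed)
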