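"""Bundled end-to-end challenge scorers.

Each class binds one challenge family's scoring procedure to synthetic
template and gold-standard providers, following one framework contract:
``score`` a submission file, ``download_template`` an example submission,
``download_goldstandard`` the gold file.  The same contract is what
scaffolded plugin challenges implement, so the registry and CLI treat
bundled and user challenges identically.

The bundled gold standards are synthetic and deliberately small; they
exercise the full scoring pipeline (parsers, metrics, empirical nulls,
composite formulas) rather than reproduce any historical leaderboard.
Every stochastic ingredient (gold generation, null sampling, template
noise) is seeded and reproducible.
"""

from __future__ import annotations

import os
import sys
from pathlib import Path

import numpy as np

from . import fixtures as fx
from . import io as dio
from .errors import FormatError, ScoringError, UsageError, ValidationError
from .metrics import (
    BinaryPrediction,
    PairedSeries,
    SurvivalRecord,
    aupr,
    auroc,
    concordance_index,
    normalized_squared_error,
    rmse,
)
from .nulls import (
    GREATER_IS_BETTER,
    SMALLER_IS_BETTER,
    AssignmentNullSpec,
    NullDistribution,
    assignment_tail_probability,
    empirical_pvalue,
)
from .scores import (
    ParameterEstimate,
    score_combined_logp_pair,
    score_d3c3,
    score_d7c1_final,
    score_network_inference,
    score_pwm_family,
    score_timecourse_distance,
)

__all__ = ["Challenge", "BUNDLED_CHALLENGES", "cache_root"]


def cache_root() -> Path:
    """Per-user cache directory for templates and gold standards.

    Resolved by platform convention, overridable with the
    ``DREAMBENCH_CACHE`` environment variable.
    """
    env = os.environ.get("DREAMBENCH_CACHE")
    if env:
        return Path(env)
    if sys.platform.startswith("win"):
        base = os.environ.get("LOCALAPPDATA", Path.home() / "AppData" / "Local")
        return Path(base) / "dreambench"
    return Path.home() / ".config" / "dreambench"


class Challenge:
    """Framework contract every challenge follows.

    Subclasses set the descriptor attributes (nickname, title,
    sub_challenges, orientation) and implement the in-memory hooks
    ``make_prediction`` / ``score_prediction`` plus the file hooks
    ``read_submission`` / ``write_prediction`` / ``write_gold``; the base
    class provides scoring-from-file and the idempotent template and
    gold-standard providers on top.
    """

    nickname: str = ""
    title: str = ""
    summary: str = ""
    sub_challenges: tuple = ()
    #: orientation of the report's "final" value
    orientation: str = GREATER_IS_BETTER
    #: fidelity of the example submission served as template
    template_quality: float = 0.3
    #: filename extension of submissions
    extension: str = ".csv"
    DEFAULTS: dict = {}

    def __init__(self, seed: int | None = None, config: dict | None = None):
        cfg = dict(self.DEFAULTS)
        if config:
            unknown = set(config) - set(cfg) - {"seed"}
            if unknown:
                raise ValidationError(
                    f"{self.nickname}: unknown config keys {sorted(unknown)}"
                )
            cfg.update(config)
        if seed is not None:
            cfg["seed"] = int(seed)
        cfg.setdefault("seed", 0)
        self.config = cfg
        self._cache: dict = {}

    # -- seeds --------------------------------------------------------------
    def _rng(self, tag: str, sub: str | None = None) -> np.random.Generator:
        """Independent, reproducible stream per (purpose, sub-challenge)."""
        tags = {"gold": 0, "null": 1, "template": 2}
        sub_index = 0 if sub is None else self.sub_challenges.index(sub) + 1
        base = self.config["gold_seed"] if tag in ("gold", "template") else (
            self.config["seed"]
        )
        ss = np.random.SeedSequence(
            entropy=int(base), spawn_key=(tags[tag], sub_index)
        )
        return np.random.default_rng(ss)

    # -- sub-challenge handling --------------------------------------------
    def resolve_sub(self, sub: str | None) -> str | None:
        if self.sub_challenges:
            if sub is None:
                raise UsageError(
                    f"{self.nickname} requires a sub-challenge; valid names: "
                    f"{', '.join(self.sub_challenges)}"
                )
            if sub not in self.sub_challenges:
                raise UsageError(
                    f"{self.nickname}: unknown sub-challenge {sub!r}; valid names: "
                    f"{', '.join(self.sub_challenges)}"
                )
            return sub
        if sub is not None:
            raise UsageError(f"{self.nickname} has no sub-challenges")
        return None

    # -- framework entry points ---------------------------------------------
    def score(self, filename, sub_challenge: str | None = None) -> dict:
        """Score a submission file; returns a JSON-serializable report."""
        sub = self.resolve_sub(sub_challenge)
        prediction = self.read_submission(filename, sub)
        report = self.score_prediction(prediction, sub)
        return {
            "challenge": self.nickname,
            "sub_challenge": sub,
            **report,
            "orientation": self.orientation,
            "provenance": {
                "seed": int(self.config["seed"]),
                "gold_seed": int(self.config["gold_seed"]),
                "null_size": self.config.get("n_null"),
            },
        }

    def _cache_path(self, kind: str, sub: str | None) -> Path:
        directory = cache_root() / self.nickname
        directory.mkdir(parents=True, exist_ok=True)
        stem = sub or "main"
        return directory / f"{stem}_{kind}{self.extension}"

    def download_template(self, sub_challenge: str | None = None) -> Path:
        """Write (once) and return a valid example submission file."""
        sub = self.resolve_sub(sub_challenge)
        path = self._cache_path("template", sub)
        if not path.exists():
            rng = self._rng("template", sub)
            pred = self.make_prediction(
                self.template_quality, int(rng.integers(2**31)), sub
            )
            self.write_prediction(pred, path, sub)
        return path

    def download_goldstandard(self, sub_challenge: str | None = None) -> Path:
        sub = self.resolve_sub(sub_challenge)
        path = self._cache_path("goldstandard", sub)
        if not path.exists():
            self.write_gold(path, sub)
        return path

    def load_gold(self, path, sub_challenge: str | None = None) -> None:
        """Replace the bundled gold standard with one read from ``path``.

        Only challenges whose gold standard is a plain data file support
        this; the rest raise.
        """
        raise UsageError(
            f"{self.nickname} does not support an external gold standard; "
            "the bundled synthetic gold is used"
        )

    # -- hooks ---------------------------------------------------------------
    def make_prediction(self, quality: float, seed: int, sub: str | None = None):
        raise NotImplementedError

    def score_prediction(self, prediction, sub: str | None = None) -> dict:
        raise NotImplementedError

    def read_submission(self, path, sub: str | None = None):
        raise NotImplementedError

    def write_prediction(self, prediction, path, sub: str | None = None) -> None:
        raise NotImplementedError

    def write_gold(self, path, sub: str | None = None) -> None:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# binary classification families
# ---------------------------------------------------------------------------

class _BinaryChallenge(Challenge):
    """Shared plumbing for item-scoring challenges with binary gold labels."""

    def _item_ids(self):
        n = self.config["n_pos"] + self.config["n_neg"]
        return [f"item_{i + 1:04d}" for i in range(n)]

    def _gold_labels(self) -> np.ndarray:
        if "labels" not in self._cache:
            rng = self._rng("gold")
            labels = np.concatenate(
                [
                    np.ones(self.config["n_pos"], dtype=int),
                    np.zeros(self.config["n_neg"], dtype=int),
                ]
            )
            rng.shuffle(labels)
            self._cache["labels"] = labels
        return self._cache["labels"]

    def make_prediction(self, quality, seed, sub=None) -> BinaryPrediction:
        return fx.graded_binary_scores(self._gold_labels(), quality, seed)

    def read_submission(self, path, sub=None) -> BinaryPrediction:
        table = dio.read_prediction_table(path)
        ids = self._item_ids()
        if table.row_ids != ids or table.shape[1] != 1:
            raise FormatError(
                f"{path}: expected one 'score' column for rows "
                f"{ids[0]}..{ids[-1]} ({len(ids)} items)"
            )
        return BinaryPrediction(
            scores=table.values[:, 0], labels=self._gold_labels()
        )

    def write_prediction(self, prediction: BinaryPrediction, path, sub=None) -> None:
        table = dio.PredictionTable(
            self._item_ids(), ["score"], prediction.scores[:, None]
        )
        dio.write_prediction_table(table, path)

    def write_gold(self, path, sub=None) -> None:
        table = dio.PredictionTable(
            self._item_ids(), ["label"], self._gold_labels()[:, None].astype(float)
        )
        dio.write_prediction_table(table, path)

    def load_gold(self, path, sub_challenge=None) -> None:
        table = dio.read_prediction_table(path)
        labels = table.values[:, 0]
        if not set(np.unique(labels)) <= {0.0, 1.0}:
            raise FormatError(f"{path}: gold labels must be 0/1")
        if labels.size != len(self._item_ids()):
            raise FormatError(
                f"{path}: expected {len(self._item_ids())} labels, got {labels.size}"
            )
        self._cache.clear()
        self._cache["labels"] = labels.astype(int)


class D2C1(_BinaryChallenge):
    nickname = "D2C1"
    title = "BCL6 Transcriptional Target Prediction"
    summary = (
        "Identify true transcriptional targets among candidate genes; "
        "submissions are confidence-scored gene lists evaluated with the "
        "AUROC and AUPR ranking metrics."
    )
    DEFAULTS = {"n_pos": 20, "n_neg": 60, "gold_seed": 20201, "seed": 20201}

    def score_prediction(self, prediction: BinaryPrediction, sub=None) -> dict:
        a_roc, a_pr = auroc(prediction), aupr(prediction)
        return {"auroc": a_roc, "aupr": a_pr, "final": 0.5 * (a_roc + a_pr)}


class D5C1(_BinaryChallenge):
    nickname = "D5C1"
    title = "Epitope-Antibody Recognition Specificity Prediction"
    summary = (
        "Classify peptides as antibody-reactive or not; AUROC and AUPR are "
        "converted to empirical p-values against random-score nulls and "
        "combined as -1/2 (log10 p_AUROC + log10 p_AUPR)."
    )
    DEFAULTS = {
        "n_pos": 5,
        "n_neg": 45,
        "n_null": 200,
        "gold_seed": 50101,
        "seed": 50101,
    }

    def _nulls(self):
        if "nulls" not in self._cache:
            rng = self._rng("null")
            labels = self._gold_labels()
            rocs, prs = [], []
            for _ in range(self.config["n_null"]):
                bp = BinaryPrediction(
                    scores=rng.random(labels.size), labels=labels
                )
                rocs.append(auroc(bp))
                prs.append(aupr(bp))
            self._cache["nulls"] = (
                NullDistribution(rocs, GREATER_IS_BETTER, name="auroc"),
                NullDistribution(prs, GREATER_IS_BETTER, name="aupr"),
            )
        return self._cache["nulls"]

    def score_prediction(self, prediction: BinaryPrediction, sub=None) -> dict:
        null_roc, null_pr = self._nulls()
        a_roc, a_pr = auroc(prediction), aupr(prediction)
        p_roc = empirical_pvalue(a_roc, null_roc)
        p_pr = empirical_pvalue(a_pr, null_pr)
        return {
            "auroc": a_roc,
            "aupr": a_pr,
            "p_auroc": p_roc,
            "p_aupr": p_pr,
            "final": score_combined_logp_pair(p_roc, p_pr),
        }


# ---------------------------------------------------------------------------
# signaling cascade identification (exact assignment null)
# ---------------------------------------------------------------------------

class D3C1(Challenge):
    nickname = "D3C1"
    title = "Signaling Cascade Identification"
    summary = (
        "Identify four measured proteins among seven candidate molecular "
        "species; the final score is the exact probability of k or more "
        "correct identities under a random (injective) assignment."
    )
    orientation = SMALLER_IS_BETTER  # final score is a probability
    SPECIES = (
        "complex",
        "kinase",
        "phosphorylated_complex",
        "phosphorylated_protein",
        "protein",
        "phosphatase",
        "activated_phosphatase",
    )
    DEFAULTS = {"n_slots": 4, "n_categories": 7, "gold_seed": 30101, "seed": 30101}

    @property
    def null_spec(self) -> AssignmentNullSpec:
        return AssignmentNullSpec(
            n_slots=self.config["n_slots"],
            n_categories=self.config["n_categories"],
            injective=True,
        )

    def make_prediction(self, quality, seed, sub=None) -> list:
        return fx.graded_assignment(self.null_spec, quality, seed)

    def score_prediction(self, prediction, sub=None) -> dict:
        spec = self.null_spec
        prediction = [int(c) for c in prediction]
        if len(prediction) != spec.n_slots:
            raise ScoringError(
                f"expected {spec.n_slots} assignments, got {len(prediction)}"
            )
        if any(not 0 <= c < spec.n_categories for c in prediction):
            raise ScoringError("assignment indices out of range")
        if len(set(prediction)) != len(prediction):
            raise ScoringError("assignment must be injective (no repeated species)")
        k = sum(1 for i, c in enumerate(prediction) if c == i)
        p = assignment_tail_probability(spec, k)
        return {"n_correct": k, "final": p}

    def read_submission(self, path, sub=None) -> list:
        table = dio.read_prediction_table(path)
        n = self.config["n_slots"]
        expected = [f"protein_{i + 1}" for i in range(n)]
        if table.row_ids != expected or table.shape[1] != 1:
            raise FormatError(
                f"{path}: expected a single 'species_index' column for rows "
                f"{expected}"
            )
        out = []
        for rid, value in zip(table.row_ids, table.values[:, 0]):
            if value != int(value) or not 1 <= value <= self.config["n_categories"]:
                raise FormatError(
                    f"{path}: row {rid}: species_index must be an integer in "
                    f"[1, {self.config['n_categories']}], got {value}"
                )
            out.append(int(value) - 1)
        return out

    def write_prediction(self, prediction, path, sub=None) -> None:
        n = self.config["n_slots"]
        table = dio.PredictionTable(
            [f"protein_{i + 1}" for i in range(n)],
            ["species_index"],
            (np.asarray(prediction, dtype=float) + 1)[:, None],
        )
        dio.write_prediction_table(table, path)

    def write_gold(self, path, sub=None) -> None:
        # the true assignment maps protein i to species i
        self.write_prediction(list(range(self.config["n_slots"])), path, sub)


# ---------------------------------------------------------------------------
# signaling response prediction (normalized squared error + empirical p)
# ---------------------------------------------------------------------------

class D3C2(Challenge):
    nickname = "D3C2"
    title = "Signaling Response Prediction"
    summary = (
        "Predict withheld signaling measurements; the distance to the gold "
        "standard is the measurement-noise-normalized squared error E and "
        "the final score is E's empirical p-value under a random-prediction "
        "null (smaller is better)."
    )
    orientation = SMALLER_IS_BETTER
    sub_challenges = ("phosphoproteomic", "cytokine")
    DEFAULTS = {
        "n_points": 5,
        "sigma_b": 0.1,
        "sigma_s": 0.2,
        "n_null": 100,
        "gold_seed": 30201,
        "seed": 30201,
    }

    def _gold_values(self, sub) -> np.ndarray:
        key = ("gold", sub)
        if key not in self._cache:
            rng = self._rng("gold", sub)
            self._cache[key] = rng.uniform(0.5, 2.0, size=self.config["n_points"])
        return self._cache[key]

    def _noise_sd(self, gold) -> np.ndarray:
        return np.sqrt(
            self.config["sigma_b"] ** 2 + self.config["sigma_s"] ** 2 * gold**2
        )

    def make_prediction(self, quality, seed, sub=None) -> np.ndarray:
        gold = self._gold_values(sub)
        rng = np.random.default_rng(seed)
        return gold + (1.0 - quality) * rng.normal(scale=self._noise_sd(gold))

    def _null(self, sub) -> NullDistribution:
        key = ("null", sub)
        if key not in self._cache:
            gold = self._gold_values(sub)
            rng = self._rng("null", sub)
            sd = self._noise_sd(gold)
            samples = [
                normalized_squared_error(
                    gold + rng.normal(scale=sd),
                    gold,
                    self.config["sigma_b"],
                    self.config["sigma_s"],
                )
                for _ in range(self.config["n_null"])
            ]
            self._cache[key] = NullDistribution(
                samples, SMALLER_IS_BETTER, name="normalized_squared_error"
            )
        return self._cache[key]

    def score_prediction(self, prediction, sub=None) -> dict:
        gold = self._gold_values(sub)
        e = normalized_squared_error(
            prediction, gold, self.config["sigma_b"], self.config["sigma_s"]
        )
        p = empirical_pvalue(e, self._null(sub))
        return {"normalized_squared_error": e, "final": p}

    def _row_ids(self):
        return [f"m_{i + 1:03d}" for i in range(self.config["n_points"])]

    def read_submission(self, path, sub=None) -> np.ndarray:
        table = dio.read_prediction_table(
            path, expected_shape=(self.config["n_points"], 1)
        )
        if table.row_ids != self._row_ids():
            raise FormatError(f"{path}: unexpected measurement ids")
        return table.values[:, 0]

    def write_prediction(self, prediction, path, sub=None) -> None:
        table = dio.PredictionTable(
            self._row_ids(), ["value"], np.asarray(prediction, dtype=float)[:, None]
        )
        dio.write_prediction_table(table, path)

    def write_gold(self, path, sub=None) -> None:
        self.write_prediction(self._gold_values(sub), path, sub)


# ---------------------------------------------------------------------------
# gene expression prediction (rank tables, Spearman profiles)
# ---------------------------------------------------------------------------

class D3C3(Challenge):
    nickname = "D3C3"
    title = "Gene Expression Prediction"
    summary = (
        "Predict per-time-point rank lists of gene expression changes; "
        "Spearman profiles over time points and genes yield two combined "
        "association p-values and the final score -1/2 log10(p_T * p_G)."
    )
    DEFAULTS = {"n_genes": 20, "n_times": 8, "gold_seed": 30301, "seed": 30301}

    def _gold_values(self) -> np.ndarray:
        if "gold" not in self._cache:
            rng = self._rng("gold")
            self._cache["gold"] = rng.normal(
                size=(self.config["n_genes"], self.config["n_times"])
            )
        return self._cache["gold"]

    def make_prediction(self, quality, seed, sub=None) -> np.ndarray:
        return fx.graded_table_ranks(self._gold_values(), quality, seed)

    def score_prediction(self, prediction, sub=None) -> dict:
        return score_d3c3(prediction, self._gold_values())

    def _ids(self):
        genes = [f"gene_{i + 1:03d}" for i in range(self.config["n_genes"])]
        times = [f"t{j + 1}" for j in range(self.config["n_times"])]
        return genes, times

    def read_submission(self, path, sub=None) -> np.ndarray:
        genes, times = self._ids()
        table = dio.read_prediction_table(
            path, expected_shape=(len(genes), len(times))
        )
        if table.row_ids != genes or table.column_ids != times:
            raise FormatError(f"{path}: unexpected gene or time-point ids")
        return table.values

    def write_prediction(self, prediction, path, sub=None) -> None:
        genes, times = self._ids()
        table = dio.PredictionTable(genes, times, np.asarray(prediction, dtype=float))
        dio.write_prediction_table(table, path)

    def write_gold(self, path, sub=None) -> None:
        genes, times = self._ids()
        table = dio.PredictionTable(genes, times, self._gold_values())
        dio.write_prediction_table(table, path)


# ---------------------------------------------------------------------------
# in-silico network inference (multi-network AUROC/AUPR p-values)
# ---------------------------------------------------------------------------

class D3C4(Challenge):
    nickname = "D3C4"
    title = "In Silico Network Inference"
    summary = (
        "Reverse-engineer directed gene networks from expression data; per "
        "data set, AUROC and AUPR get empirical p-values against random "
        "predictions and the final score is the mean of the two "
        "mean-neglog10-p intermediate scores."
    )
    extension = ".txt"
    DEFAULTS = {
        "n_networks": 5,
        "n_nodes": 5,
        "n_edges": 5,
        "topology": "erdos_renyi",
        "n_null": 100,
        "gold_seed": 30401,
        "seed": 30401,
    }

    @property
    def _nodes(self):
        return [f"g{i + 1}" for i in range(self.config["n_nodes"])]

    def _network_names(self):
        return [f"net{i + 1}" for i in range(self.config["n_networks"])]

    def _golds(self) -> list:
        if "golds" not in self._cache:
            rng = self._rng("gold")
            make = (
                fx._erdos_renyi_edges
                if self.config["topology"] == "erdos_renyi"
                else fx._scale_free_edges
            )
            self._cache["golds"] = [
                make(rng, self._nodes, self.config["n_edges"])
                for _ in range(self.config["n_networks"])
            ]
        return self._cache["golds"]

    def _candidate_labels(self, gold) -> np.ndarray:
        nodes = self._nodes
        return np.array(
            [
                1 if (s, t) in gold else 0
                for s in nodes
                for t in nodes
                if s != t
            ]
        )

    def _nulls(self):
        if "nulls" not in self._cache:
            rng = self._rng("null")
            roc_nulls, pr_nulls = [], []
            for gold in self._golds():
                labels = self._candidate_labels(gold)
                rocs, prs = [], []
                for _ in range(self.config["n_null"]):
                    bp = BinaryPrediction(
                        scores=rng.random(labels.size), labels=labels
                    )
                    rocs.append(auroc(bp))
                    prs.append(aupr(bp))
                roc_nulls.append(
                    NullDistribution(rocs, GREATER_IS_BETTER, name="auroc")
                )
                pr_nulls.append(
                    NullDistribution(prs, GREATER_IS_BETTER, name="aupr")
                )
            self._cache["nulls"] = (roc_nulls, pr_nulls)
        return self._cache["nulls"]

    def make_prediction(self, quality, seed, sub=None) -> list:
        rng = np.random.default_rng(seed)
        return [
            fx.graded_edge_prediction(
                gold, self._nodes, quality, int(rng.integers(2**31))
            )
            for gold in self._golds()
        ]

    def score_prediction(self, prediction, sub=None) -> dict:
        golds = self._golds()
        if len(prediction) != len(golds):
            raise ScoringError(
                f"expected {len(golds)} edge lists, got {len(prediction)}"
            )
        universe = frozenset(self._nodes)
        prediction = [
            dio.RankedEdgeList(edges=p.edges, node_universe=universe)
            for p in prediction
        ]
        return score_network_inference(prediction, golds, self._nulls())

    def read_submission(self, path, sub=None) -> list:
        blocks = dio.read_multi_edge_list(path)
        names = self._network_names()
        if list(blocks) != names:
            raise FormatError(
                f"{path}: expected blocks {names}, found {list(blocks)}"
            )
        return [blocks[name] for name in names]

    def write_prediction(self, prediction, path, sub=None) -> None:
        dio.write_multi_edge_list(
            dict(zip(self._network_names(), prediction)), path
        )

    def write_gold(self, path, sub=None) -> None:
        named = {
            name: dio.RankedEdgeList(
                edges=[(s, t, 1.0) for s, t in sorted(gold)]
            )
            for name, gold in zip(self._network_names(), self._golds())
        }
        dio.write_multi_edge_list(named, path)


# ---------------------------------------------------------------------------
# peptide recognition domain specificity (PWM Frobenius p-values)
# ---------------------------------------------------------------------------

class D4C1(Challenge):
    nickname = "D4C1"
    title = "Peptide Recognition Domain Specificity Prediction"
    summary = (
        "Predict position weight matrices for peptide recognition domains; "
        "each Frobenius distance to the mapped PWM gets an empirical "
        "p-value against random PWMs and the family score is the mean "
        "-log10 p."
    )
    sub_challenges = ("kinase", "pdz", "sh3")
    extension = ".txt"
    DEFAULTS = {
        "n_matrices": {"kinase": 3, "pdz": 4, "sh3": 3},
        "n_rows": 4,
        "n_cols": 2,
        "n_null": 100,
        "gold_seed": 40101,
        "seed": 40101,
    }

    def _golds(self, sub) -> list:
        key = ("gold", sub)
        if key not in self._cache:
            rng = self._rng("gold", sub)
            from .nulls import random_pwm
            from .pwm import PWMatrix

            self._cache[key] = [
                PWMatrix(
                    values=random_pwm(
                        self.config["n_rows"], self.config["n_cols"], rng
                    ).values,
                    name=f"{sub}_{k + 1}",
                )
                for k in range(self.config["n_matrices"][sub])
            ]
        return self._cache[key]

    def make_prediction(self, quality, seed, sub=None) -> list:
        return fx.graded_pwm_prediction(self._golds(sub), quality, seed)

    def score_prediction(self, prediction, sub=None) -> dict:
        gold = self._golds(sub)
        null_seed = int(self._rng("null", sub).integers(2**31))
        return score_pwm_family(
            prediction, gold, self.config["n_null"], null_seed
        )

    def read_submission(self, path, sub=None) -> list:
        matrices = dio.read_pwm_file(path)
        gold = self._golds(sub)
        if len(matrices) != len(gold):
            raise FormatError(
                f"{path}: expected {len(gold)} PWM blocks, found {len(matrices)}"
            )
        return matrices

    def write_prediction(self, prediction, path, sub=None) -> None:
        dio.write_pwm_file(prediction, path)

    def write_gold(self, path, sub=None) -> None:
        dio.write_pwm_file(self._golds(sub), path)


# ---------------------------------------------------------------------------
# parameter estimation (parameter + time-course distances)
# ---------------------------------------------------------------------------

class D7C1(Challenge):
    nickname = "D7C1"
    title = "Network Topology and Parameter Inference"
    summary = (
        "Estimate hidden kinetic parameters and predict perturbation time "
        "courses; parameter and time-course distances get empirical "
        "p-values from a random-prediction null and the final score is "
        "-log10(p_param * p_timecourse)."
    )
    DEFAULTS = {
        "n_parameters": 18,
        "log_error_scale": 0.5,
        "n_times": 15,
        "burn_in": 10,
        "sigma_b": 0.1,
        "sigma_s": 0.2,
        "n_null": 100,
        "gold_seed": 70101,
        "seed": 70101,
    }

    def _gold(self):
        if "gold" not in self._cache:
            rng = self._rng("gold")
            true_params = 10.0 ** rng.uniform(-1, 1, size=self.config["n_parameters"])
            t = np.arange(self.config["n_times"], dtype=float)
            course = (
                rng.uniform(0.5, 1.5)
                + rng.uniform(0.5, 1.5)
                * np.sin(2 * np.pi * rng.uniform(0.5, 2.0) * t / t.size
                         + rng.uniform(0, 2 * np.pi))
            )[:, None]
            self._cache["gold"] = (true_params, [course])
        return self._cache["gold"]

    def make_prediction(self, quality, seed, sub=None):
        true_params, gold_courses = self._gold()
        rng = np.random.default_rng(seed)
        est = fx.graded_parameter_estimate(
            true_params,
            self.config["log_error_scale"],
            quality,
            int(rng.integers(2**31)),
        )
        tc = fx.graded_timecourse_prediction(
            gold_courses,
            self.config["sigma_b"],
            self.config["sigma_s"],
            self.config["burn_in"],
            quality,
            int(rng.integers(2**31)),
        )
        return est, tc

    def _nulls(self):
        if "nulls" not in self._cache:
            rng = self._rng("null")
            d_params, d_tcs = [], []
            for _ in range(self.config["n_null"]):
                est, tc = self.make_prediction(0.0, int(rng.integers(2**31)))
                d_params.append(float(np.mean(
                    np.log10(est.estimated / est.true_values) ** 2
                )))
                d_tcs.append(score_timecourse_distance(tc))
            self._cache["nulls"] = (
                NullDistribution(d_params, SMALLER_IS_BETTER, name="d_param"),
                NullDistribution(d_tcs, SMALLER_IS_BETTER, name="d_timecourse"),
            )
        return self._cache["nulls"]

    def score_prediction(self, prediction, sub=None) -> dict:
        from .scores import score_parameter_distance

        est, tc = prediction
        d_param = score_parameter_distance(est)
        d_tc = score_timecourse_distance(tc)
        null_param, null_tc = self._nulls()
        p_param = empirical_pvalue(d_param, null_param)
        p_tc = empirical_pvalue(d_tc, null_tc)
        return {
            "d_param": d_param,
            "d_timecourse": d_tc,
            "p_param": p_param,
            "p_timecourse": p_tc,
            "final": score_d7c1_final(p_param, p_tc),
        }

    def _row_ids(self):
        params = [f"param_{i + 1:02d}" for i in range(self.config["n_parameters"])]
        tcs = [f"tc_{i + 1:02d}" for i in range(self.config["n_times"])]
        return params + tcs

    def read_submission(self, path, sub=None):
        n_p = self.config["n_parameters"]
        table = dio.read_prediction_table(
            path, expected_shape=(n_p + self.config["n_times"], 1)
        )
        if table.row_ids != self._row_ids():
            raise FormatError(f"{path}: unexpected row ids")
        values = table.values[:, 0]
        params, course = values[:n_p], values[n_p:][:, None]
        true_params, gold_courses = self._gold()
        try:
            est = ParameterEstimate(estimated=params, true_values=true_params)
        except ValidationError as err:
            raise FormatError(f"{path}: {err}") from None
        tc = fx.TimeCourseSet(
            courses=[course],
            golds=gold_courses,
            sigma_b=self.config["sigma_b"],
            sigma_s=self.config["sigma_s"],
            burn_in=self.config["burn_in"],
        )
        return est, tc

    def write_prediction(self, prediction, path, sub=None) -> None:
        est, tc = prediction
        values = np.concatenate([est.estimated, tc.courses[0][:, 0]])
        table = dio.PredictionTable(self._row_ids(), ["value"], values[:, None])
        dio.write_prediction_table(table, path)

    def write_gold(self, path, sub=None) -> None:
        true_params, gold_courses = self._gold()
        values = np.concatenate([true_params, gold_courses[0][:, 0]])
        table = dio.PredictionTable(self._row_ids(), ["value"], values[:, None])
        dio.write_prediction_table(table, path)


# ---------------------------------------------------------------------------
# survival prognosis (concordance index)
# ---------------------------------------------------------------------------

class D7C2(Challenge):
    nickname = "D7C2"
    title = "Breast Cancer Prognosis"
    summary = (
        "Predict patient survival risk; submissions are scored with the "
        "exact concordance index against the held-out survival data, "
        "accounting for censoring."
    )
    DEFAULTS = {"n": 40, "censor_rate": 0.2, "gold_seed": 70201, "seed": 70201}

    def _gold_records(self) -> list:
        if "gold" not in self._cache:
            rng = self._rng("gold")
            eta = rng.normal(size=self.config["n"])
            event_time = rng.exponential(scale=np.exp(-eta))
            censored = rng.random(self.config["n"]) < self.config["censor_rate"]
            observed = np.where(
                censored, event_time * rng.random(self.config["n"]), event_time
            )
            self._cache["gold"] = [
                SurvivalRecord(time=float(t), event=int(not c), risk=0.0)
                for t, c in zip(observed, censored)
            ]
        return self._cache["gold"]

    def make_prediction(self, quality, seed, sub=None) -> np.ndarray:
        times = [r.time for r in self._gold_records()]
        return fx.graded_survival_risk(times, quality, seed)

    def score_prediction(self, prediction, sub=None) -> dict:
        gold = self._gold_records()
        prediction = np.asarray(prediction, dtype=float)
        if prediction.shape != (len(gold),):
            raise ScoringError(
                f"expected {len(gold)} risk scores, got {prediction.shape}"
            )
        records = [
            SurvivalRecord(time=r.time, event=r.event, risk=float(p))
            for r, p in zip(gold, prediction)
        ]
        ci = concordance_index(records)
        return {"concordance_index": ci, "final": ci}

    def read_submission(self, path, sub=None) -> np.ndarray:
        records = dio.read_survival_table(path)
        if len(records) != len(self._gold_records()):
            raise FormatError(
                f"{path}: expected {len(self._gold_records())} patients, "
                f"got {len(records)}"
            )
        return np.array([r.risk for r in records])

    def write_prediction(self, prediction, path, sub=None) -> None:
        gold = self._gold_records()
        records = [
            SurvivalRecord(time=r.time, event=r.event, risk=float(p))
            for r, p in zip(gold, prediction)
        ]
        dio.write_survival_table(records, path)

    def write_gold(self, path, sub=None) -> None:
        dio.write_survival_table(self._gold_records(), path)

    def load_gold(self, path, sub_challenge=None) -> None:
        self._cache.clear()
        self._cache["gold"] = dio.read_survival_table(path)


# ---------------------------------------------------------------------------
# ALS progression prediction (RMSE)
# ---------------------------------------------------------------------------

class D7C3(Challenge):
    nickname = "D7C3"
    title = "ALS Prediction (Phil Bowen Prize4Life)"
    summary = (
        "Predict each patient's future functional-decline slope; the score "
        "is the root mean squared error against the observed slopes "
        "(smaller is better)."
    )
    orientation = SMALLER_IS_BETTER
    DEFAULTS = {"n_patients": 30, "slope_sd": 0.6, "gold_seed": 70301, "seed": 70301}

    def _gold_slopes(self) -> np.ndarray:
        if "gold" not in self._cache:
            rng = self._rng("gold")
            self._cache["gold"] = rng.normal(
                loc=-1.0, scale=self.config["slope_sd"], size=self.config["n_patients"]
            )
        return self._cache["gold"]

    def make_prediction(self, quality, seed, sub=None) -> np.ndarray:
        gold = self._gold_slopes()
        rng = np.random.default_rng(seed)
        return gold + (1.0 - quality) * rng.normal(
            scale=self.config["slope_sd"], size=gold.size
        )

    def score_prediction(self, prediction, sub=None) -> dict:
        value = rmse(PairedSeries(predicted=prediction, observed=self._gold_slopes()))
        return {"rmse": value, "final": value}

    def _row_ids(self):
        return [f"patient_{i + 1:03d}" for i in range(self.config["n_patients"])]

    def read_submission(self, path, sub=None) -> np.ndarray:
        table = dio.read_prediction_table(
            path, expected_shape=(self.config["n_patients"], 1)
        )
        if table.row_ids != self._row_ids():
            raise FormatError(f"{path}: unexpected patient ids")
        return table.values[:, 0]

    def write_prediction(self, prediction, path, sub=None) -> None:
        table = dio.PredictionTable(
            self._row_ids(), ["slope"], np.asarray(prediction, dtype=float)[:, None]
        )
        dio.write_prediction_table(table, path)

    def write_gold(self, path, sub=None) -> None:
        self.write_prediction(self._gold_slopes(), path, sub)


#: bundled challenge classes, keyed by nickname
BUNDLED_CHALLENGES = {
    cls.nickname: cls
    for cls in (D2C1, D3C1, D3C2, D3C3, D3C4, D4C1, D5C1, D7C1, D7C2, D7C3)
}
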