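"""Challenge registry and nickname grammar.

A challenge is referred to by a compact nickname of the form ``DXCY``:
``X`` is the challenge-series version and ``Y`` the challenge number, with
``dot`` encoding fractional versions (``D9dot5C1``) and the challenge part
optional (``D8dot5``).  The registry maps nicknames to descriptors — title,
summary, sub-challenge names, score orientation and, where a scoring
procedure is bundled or plugged in, a factory that builds the scorer.
"""

from __future__ import annotations

import difflib
import importlib.util
import re
from dataclasses import dataclass

import yaml

from .challenges import BUNDLED_CHALLENGES, Challenge
from .errors import UnknownChallengeError, UsageError, ValidationError

__all__ = [
    "parse_nickname",
    "render_nickname",
    "ChallengeDescriptor",
    "Registry",
    "default_registry",
    "load_config_file",
]

_NICKNAME_RE = re.compile(r"^D(\d+)(?:dot(\d+))?(?:C(\d+))?$")
_GRAMMAR = (
    "nicknames take the form DXCY — D, a version (integers, 'dot' for "
    "fractional versions, e.g. 8dot5), and an optional challenge number "
    "after C (e.g. D8C1, D9dot5C1, D8dot5)"
)


def parse_nickname(s: str):
    """Parse ``DXCY`` into ``(version, challenge_number_or_None)``."""
    if not s:
        raise ValidationError(f"empty nickname; {_GRAMMAR}")
    m = _NICKNAME_RE.match(s)
    if not m:
        raise ValidationError(f"cannot parse nickname {s!r}; {_GRAMMAR}")
    major, frac, challenge = m.groups()
    version = float(f"{major}.{frac}") if frac is not None else float(major)
    return version, (int(challenge) if challenge is not None else None)


def render_nickname(version: float, challenge: int | None = None) -> str:
    """Inverse of :func:`parse_nickname`."""
    if version <= 0:
        raise ValidationError(f"version must be positive, got {version}")
    if version == int(version):
        ver = str(int(version))
    else:
        ver = f"{version:g}".replace(".", "dot")
    out = f"D{ver}"
    if challenge is not None:
        out += f"C{int(challenge)}"
    return out


# status values a descriptor can carry
STATUS_BUNDLED = "bundled"            # end-to-end scorer + synthetic gold shipped
STATUS_LIBRARY = "library"            # metric formulas available as library calls
STATUS_NO_GOLD = "no gold standard"   # metrics generic; gold never released
STATUS_EXTERNAL = "external"          # scored by an external tool
STATUS_OUT_OF_SCOPE = "out of scope"  # needs machinery beyond this package
STATUS_UNRELEASED = "metric unreleased"
STATUS_OPEN = "open challenge"
STATUS_PLUGIN = "plugin"


@dataclass
class ChallengeDescriptor:
    """Registry entry for one challenge."""

    nickname: str
    title: str
    summary: str = ""
    sub_challenges: tuple = ()
    status: str = STATUS_LIBRARY
    factory: type | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        parse_nickname(self.nickname)  # must satisfy the grammar

    @property
    def scorable(self) -> bool:
        return self.factory is not None


class Registry:
    """Nickname-indexed collection of challenge descriptors."""

    def __init__(self):
        self._entries: dict[str, ChallengeDescriptor] = {}

    def register(self, descriptor: ChallengeDescriptor) -> None:
        if descriptor.nickname in self._entries:
            raise ValidationError(
                f"nickname {descriptor.nickname} already registered"
            )
        self._entries[descriptor.nickname] = descriptor

    def nicknames(self) -> list:
        return sorted(self._entries, key=lambda n: parse_nickname(n))

    def __contains__(self, nickname: str) -> bool:
        return nickname in self._entries

    def get(self, nickname: str) -> ChallengeDescriptor:
        try:
            return self._entries[nickname]
        except KeyError:
            close = difflib.get_close_matches(nickname, self._entries, n=3)
            hint = f"; did you mean {', '.join(close)}?" if close else ""
            raise UnknownChallengeError(
                f"unknown challenge {nickname!r}{hint}"
            ) from None

    def challenge(
        self, nickname: str, seed: int | None = None, config: dict | None = None
    ) -> Challenge:
        """Instantiate the scoring procedure bound to a nickname."""
        desc = self.get(nickname)
        if desc.factory is None:
            raise UsageError(
                f"{nickname} ({desc.title}) has no bundled scoring procedure "
                f"(status: {desc.status}); its metric formulas are available "
                "as library functions"
            )
        return desc.factory(seed=seed, config=config)

    def info(self, nickname: str) -> str:
        """Human-readable description: title, summary, sub-challenges, status."""
        desc = self.get(nickname)
        lines = [f"{desc.nickname}: {desc.title}", f"status: {desc.status}"]
        if desc.summary:
            lines.append(desc.summary)
        if desc.notes:
            lines.append(desc.notes)
        if desc.sub_challenges:
            lines.append("sub-challenges:")
            lines.extend(f"  - {s}" for s in desc.sub_challenges)
        if desc.factory is not None:
            orientation = getattr(desc.factory, "orientation", None)
            if orientation:
                lines.append(f"final-score orientation: {orientation}")
        return "\n".join(lines)

    # -- plugin discovery ---------------------------------------------------
    def discover(self, plugins_dir) -> list:
        """Register every challenge laid out under ``plugins_dir``.

        A plugin is a directory holding a ``challenge.yaml`` descriptor and
        a ``scoring.py`` module defining a :class:`Challenge` subclass named
        after the nickname.  Returns the nicknames registered.
        """
        from pathlib import Path

        plugins_dir = Path(plugins_dir)
        found = []
        for yaml_path in sorted(plugins_dir.glob("*/challenge.yaml")):
            meta = yaml.safe_load(yaml_path.read_text()) or {}
            nickname = meta.get("nickname", yaml_path.parent.name)
            scoring_py = yaml_path.parent / "scoring.py"
            if not scoring_py.exists():
                raise ValidationError(f"{yaml_path.parent}: missing scoring.py")
            spec = importlib.util.spec_from_file_location(
                f"dreambench_plugin_{nickname}", scoring_py
            )
            module = importlib.util.module_from_spec(spec)
            spec.loader.exec_module(module)
            cls = getattr(module, nickname, None)
            if cls is None or not issubclass(cls, Challenge):
                raise ValidationError(
                    f"{scoring_py}: must define a Challenge subclass named "
                    f"{nickname}"
                )
            self.register(
                ChallengeDescriptor(
                    nickname=nickname,
                    title=meta.get("title", nickname),
                    summary=meta.get("summary", ""),
                    sub_challenges=tuple(meta.get("sub_challenges", ()) or ()),
                    status=getattr(cls, "status", STATUS_PLUGIN),
                    factory=cls,
                )
            )
            found.append(nickname)
        return found


def _catalog() -> list:
    """Descriptors for the historical challenge corpus.

    Bundled entries ship an end-to-end synthetic scorer; the rest carry the
    metadata plus a pointer to the library functions implementing their
    metric, mirroring each challenge's availability.
    """
    lib = STATUS_LIBRARY
    rows = [
        # nickname, title, status, sub-challenges, notes
        ("D2C1", None, None, (), ""),
        ("D2C2", "Protein-Protein Interaction Network Inference", lib, (),
         "binary classification over candidate interactions: metrics.auroc/aupr"),
        ("D2C3", "Synthetic Five-Gene Network Inference", lib, (),
         "per-network AUROC/AUPR: metrics.auroc/aupr"),
        ("D2C4", "In Silico Network Inference", lib, (),
         "AUROC/AUPR on 50-node/100-edge networks; fixtures.make_network_fixture"),
        ("D2C5", "Genome-Scale Network Inference", lib, (),
         "AUROC/AUPR at genome scale: metrics.auroc/aupr"),
        ("D3C1", None, None, (), ""),
        ("D3C2", None, None, (), ""),
        ("D3C3", None, None, (), ""),
        ("D3C4", None, None, (), ""),
        ("D4C1", None, None, (), ""),
        ("D4C2", "In Silico Network Challenge", lib, (),
         "same procedure as D3C4: scores.score_network_inference"),
        ("D4C3", "Predictive Signaling Network Modeling", lib, (),
         "parsimony-penalized score: scores.score_parsimony_network"),
        ("D5C1", None, None, (), ""),
        ("D5C2", "Transcription Factor DNA Motif Recognition", lib, (),
         "Pearson/Spearman + AUROC/AUPR; cohort comparison: plotting module"),
        ("D5C3", "Systems Genetics Challenge", lib, ("SysGenA", "SysGenB"),
         "SysGenA: score_network_inference; SysGenB: scores.score_sysgenb"),
        ("D5C4", "Network Inference Challenge", lib, (),
         "same procedure as D3C4: scores.score_network_inference"),
        ("D6C1", "Alternative Splicing", STATUS_OUT_OF_SCOPE, (),
         "alignment-based AUPR needs a transcript aligner"),
        ("D6C2", "Parameter Estimation (re-run as D7C1)", lib, (),
         "see D7C1"),
        ("D6C3", "Gene Expression Prediction (promoter activity)", lib, (),
         "four-metric combiner: scores.score_d6c3 (literal and log modes)"),
        ("D6C4", "FlowCAP2 Molecular Classification of AML", lib, (),
         "AUPR, Matthews CC, Jaccard, Pearson: metrics module"),
        ("D7C1", None, None, (), ""),
        ("D7C2", None, None, (), ""),
        ("D7C3", None, None, (), ""),
        ("D7C4", "NCI-DREAM Drug Sensitivity", lib, ("sensitivity", "synergy"),
         "probabilistic concordance variant: metrics.probabilistic_concordance "
         "(exact wpc weighting is defined in external supplements)"),
        ("D8C1", "HPN-DREAM Breast Cancer Network Inference", lib,
         ("experimental", "in_silico", "visualization"),
         "per-context AUROC then mean rank: scores.aggregate_mean_rank"),
        ("D8C2", "NIEHS-NCATS-UNC DREAM Toxicogenetics", lib,
         ("cytotoxicity", "population"),
         "Pearson + probabilistic concordance, rank-averaged: scores module"),
        ("D8C3", "Whole-Cell Parameter Estimation", STATUS_EXTERNAL, (),
         "scored by an external MATLAB implementation"),
        ("D8dot5", "The Rheumatoid Arthritis Responder", lib,
         ("das28", "nonresponse"),
         "Spearman (sub 1) and AUROC/AUPR (sub 2): metrics module"),
        ("D9C1", "The Broad-DREAM Gene Essentiality Prediction", lib,
         ("all_features", "top10", "top100"),
         "mean per-gene Spearman: metrics.spearman"),
        ("D9C2", "Acute Myeloid Leukemia Outcome Prediction", STATUS_NO_GOLD,
         ("remission", "remission_duration", "survival"),
         "AUROC/BAC and CI/Pearson formulas available; gold never released"),
        ("D9C3", "Alzheimer's Disease Big Data", STATUS_NO_GOLD,
         ("cognition", "amyloid", "imaging"),
         "Pearson/Spearman/AUROC/BAC/CCC formulas available; gold never released"),
        ("D9C4", "ICGC-TCGA-DREAM Somatic Mutation Calling", lib,
         ("SNV", "SV"),
         "sensitivity/specificity/balanced accuracy: metrics module"),
        ("D9dot5C1", "Olfactory Challenge", lib, ("individual", "population"),
         "z-score aggregation: scores.score_olfaction"),
        ("D9dot5C2", "Prostate Cancer", lib,
         ("survival", "time_to_event", "discontinuation"),
         "CI/RMSE/AUPR available; integrated AUC is an external definition"),
        ("D10C1", "DREAM ALS Stratification Prize4Life", STATUS_OPEN, (), ""),
        ("D10C2", "Somatic Mutation Calling Tumor Heterogeneity",
         STATUS_UNRELEASED, (), ""),
        ("D10C3", "Somatic Mutation Calling RNA (SMC-RNA)",
         STATUS_UNRELEASED, (), ""),
    ]
    descriptors = []
    for nickname, title, status, subs, notes in rows:
        if nickname in BUNDLED_CHALLENGES:
            cls = BUNDLED_CHALLENGES[nickname]
            descriptors.append(
                ChallengeDescriptor(
                    nickname=nickname,
                    title=cls.title,
                    summary=cls.summary,
                    sub_challenges=tuple(cls.sub_challenges),
                    status=STATUS_BUNDLED,
                    factory=cls,
                    notes=notes,
                )
            )
        else:
            descriptors.append(
                ChallengeDescriptor(
                    nickname=nickname,
                    title=title,
                    sub_challenges=tuple(subs),
                    status=status,
                    notes=notes,
                )
            )
    return descriptors


def default_registry() -> Registry:
    """A fresh registry pre-loaded with the historical challenge corpus."""
    registry = Registry()
    for desc in _catalog():
        registry.register(desc)
    return registry


def score_submission(
    nickname: str,
    submission_path,
    sub_challenge: str | None = None,
    gold_path=None,
    seed: int | None = None,
    config: dict | None = None,
    registry: Registry | None = None,
) -> dict:
    """One-call scoring: dispatch a submission file to the bound scorer.

    ``gold_path`` optionally replaces the bundled gold standard for the
    challenges whose gold is a plain data file.
    """
    registry = registry or default_registry()
    challenge = registry.challenge(nickname, seed=seed, config=config)
    if gold_path is not None:
        challenge.load_gold(gold_path, sub_challenge)
    return challenge.score(submission_path, sub_challenge=sub_challenge)


def load_config_file(path) -> dict:
    """Read a YAML/JSON config fixing seeds, null sizes, dialects per challenge.

    Layout: an optional top-level ``seed`` plus one mapping per nickname,
    e.g. ``{"seed": 7, "D3C4": {"n_null": 500}}``.
    """
    from pathlib import Path

    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return data
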