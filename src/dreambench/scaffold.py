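"""Developer scaffolding for new challenges.

``scaffold_challenge`` lays out the directory convention a plugin challenge
follows — sub-directories for templates, gold standards, p-value data and
training-data generators, a README stub, a ``challenge.yaml`` descriptor
and a ``scoring.py`` exposing the framework contract (score /
download_template / download_goldstandard).  A scaffolded directory is
discovered by :meth:`dreambench.registry.Registry.discover` without any
further code changes.
"""

from __future__ import annotations

from pathlib import Path

from .errors import ValidationError
from .registry import parse_nickname

__all__ = ["scaffold_challenge"]

_SUBDIRS = ("templates", "goldstandard", "data", "generator")

_README = """\
# {nickname}

Fill in the challenge metadata:

- Synapse identifier:
- Acronym:
- Summary:

Directory layout: `templates/` holds example submissions, `goldstandard/`
the gold-standard files, `data/` any data needed to compute p-values, and
`generator/` code related to training-data generation.
"""

_YAML = """\
nickname: {nickname}
title: {nickname} (fill in the title)
summary: ""
sub_challenges: []
"""

_SCORING = '''\
"""Scoring procedure for {nickname}.

Fill in the three framework functions; once they work the challenge is
automatically available to the registry and the command-line application.
"""

from pathlib import Path

from dreambench.challenges import Challenge

HERE = Path(__file__).parent


class {nickname}(Challenge):
    nickname = "{nickname}"
    title = "{nickname} (fill in the title)"
    status = "stub"  # drop this line once the scorer is implemented
    sub_challenges = ()
    DEFAULTS = {{"gold_seed": 0, "seed": 0}}

    def score(self, filename, sub_challenge=None):
        raise NotImplementedError(
            "{nickname}: scoring procedure not implemented yet"
        )

    def download_template(self, sub_challenge=None):
        return HERE / "templates" / "template.csv"

    def download_goldstandard(self, sub_challenge=None):
        return HERE / "goldstandard" / "goldstandard.csv"
'''


def scaffold_challenge(nickname: str, target_dir) -> list:
    """Create the directory tree and stub files for a new challenge.

    Refuses to touch an existing non-empty directory.  Returns the created
    paths (directories first, then files).
    """
    parse_nickname(nickname)  # validate against the grammar
    root = Path(target_dir) / nickname
    if root.exists() and any(root.iterdir()):
        raise ValidationError(f"refusing to scaffold into non-empty {root}")
    created = []
    root.mkdir(parents=True, exist_ok=True)
    created.append(root)
    for sub in _SUBDIRS:
        path = root / sub
        path.mkdir(exist_ok=True)
        created.append(path)
    files = {
        root / "README.md": _README.format(nickname=nickname),
        root / "challenge.yaml": _YAML.format(nickname=nickname),
        root / "scoring.py": _SCORING.format(nickname=nickname),
    }
    for path, content in files.items():
        path.write_text(content)
        created.append(path)
    return created
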