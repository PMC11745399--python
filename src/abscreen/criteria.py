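"""Named Boolean inclusion/exclusion criteria and their config files.

A criterion is a short key plus an instruction telling the judge when to
answer true or false for one record. Criteria sets are stored as YAML/JSON
files with a top-level ``criteria`` list; three example sets covering a
physiotherapy economics review, a hereditary-neuropathy treatment review
and a digital-health cost-effectiveness review ship with the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .errors import ConfigurationError

BUNDLED_CRITERIA = ("physio", "neuro", "digihealth")


@dataclass(frozen=True)
class Criterion:
    """One named screening criterion.

    Parameters
    ----------
    key:
        Short identifier, unique within a criteria set.
    instruction:
        Text stating when the judge should return true vs. false.
    """

    key: str
    instruction: str

    def __post_init__(self) -> None:
        if not self.key or not self.key.strip():
            raise ConfigurationError("criterion key must be non-empty")
        if not self.instruction or not self.instruction.strip():
            raise ConfigurationError(
                f"criterion {self.key!r} has an empty instruction"
            )


def validate_criteria(criteria: Sequence[Criterion]) -> Sequence[Criterion]:
    """Check non-emptiness and key uniqueness; returns the input."""
    if not criteria:
        raise ConfigurationError("criteria set is empty")
    keys = [c.key for c in criteria]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ConfigurationError(f"duplicate criterion keys: {dupes}")
    return criteria


def _from_mapping(doc: dict) -> list[Criterion]:
    try:
        items: Iterable[dict] = doc["criteria"]
    except (KeyError, TypeError):
        raise ConfigurationError("criteria file must have a top-level 'criteria' list")
    crits = [Criterion(key=str(d["key"]), instruction=str(d["instruction"])) for d in items]
    validate_criteria(crits)
    return crits


def load_criteria(path: str | Path) -> list[Criterion]:
    """Load a criteria set from a YAML or JSON file, preserving order."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return _from_mapping(doc)


def bundled_criteria(name: str) -> list[Criterion]:
    """Load one of the packaged example criteria sets.

    ``name`` is one of ``physio`` (7 criteria), ``neuro`` (5) or
    ``digihealth`` (6).
    """
    if name not in BUNDLED_CRITERIA:
        raise ConfigurationError(
            f"unknown bundled criteria set {name!r}; choose from {BUNDLED_CRITERIA}"
        )
    ref = resources.files("abscreen").joinpath(f"data/criteria/{name}.yaml")
    doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _from_mapping(doc)
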