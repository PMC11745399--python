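"""Synthetic screening corpora with known generative parameters.

The generator emulates the statistical skeleton of a title/abstract
screening task: a corpus of n records of which a fraction π (the
prevalence) is truly includable; a judge that, independently per
criterion, answers true with probability s (sensitivity) for includable
records and f (false-positive rate) for excludable ones; and a rate of
records whose judging fails outright. Because the parameters are known,
the operating point of the strict all-criteria-true rule has a closed
form — recall Π s_c, specificity 1 − Π f_c — against which empirical
pipeline output can be checked.

All randomness flows through one seeded generator per call; there is no
module-level random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .records import ReviewDataset, ScreeningRecord, build_record_text

__all__ = [
    "CriterionProfile",
    "SimulationConfig",
    "generate_review",
    "simulate_verdicts",
    "expected_operating_point",
]


@dataclass(frozen=True)
class CriterionProfile:
    """Per-criterion judge behavior: P(true | includable) and P(true | excludable)."""

    key: str
    sensitivity: float
    false_positive_rate: float

    def __post_init__(self) -> None:
        for name in ("sensitivity", "false_positive_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic review corpus."""

    n_records: int
    prevalence: float
    profiles: Sequence[CriterionProfile] = field(default_factory=tuple)
    failure_rate: float = 0.0
    seed: int = 28
    on_degenerate: str = "resample"  # or "error"

    def __post_init__(self) -> None:
        if self.n_records < 10:
            raise ValueError("n_records must be >= 10")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        if not (0.0 <= self.failure_rate < 1.0):
            raise ValueError("failure_rate must be in [0, 1)")
        if self.on_degenerate not in ("resample", "error"):
            raise ValueError("on_degenerate must be 'resample' or 'error'")


_TOPICS = (
    "exercise therapy", "manual therapy", "gait training", "pain education",
    "balance training", "resistance training", "aquatic therapy",
    "workplace ergonomics", "telerehabilitation", "postural control",
)
_DESIGNS = (
    "randomized controlled trial", "cohort study", "case-control study",
    "pragmatic trial", "pilot study", "cross-sectional survey",
)


def generate_review(config: SimulationConfig) -> ReviewDataset:
    """Draw a synthetic review corpus with known truth labels.

    Each record's ``human_screen1`` is an independent Bernoulli(π) draw;
    titles and abstracts are templated English text, and every abstract
    embeds its record id (the hook the simulated judge backend uses to
    recover ground truth). A draw that lands all records in one class is
    resampled (default) or raises, per ``config.on_degenerate``.
    """
    rng = np.random.default_rng(config.seed)
    for _ in range(100):
        labels = rng.random(config.n_records) < config.prevalence
        if 0 < labels.sum() < config.n_records:
            break
        if config.on_degenerate == "error":
            raise ValueError("degenerate draw: a single class in the sample")
    else:
        raise ValueError("could not draw a two-class sample in 100 attempts")

    topics = rng.integers(0, len(_TOPICS), size=config.n_records)
    designs = rng.integers(0, len(_DESIGNS), size=config.n_records)
    sizes = rng.integers(20, 500, size=config.n_records)

    records = []
    for i in range(config.n_records):
        record_id = f"rec-{i:05d}"
        title = (
            f"A {_DESIGNS[designs[i]]} of {_TOPICS[topics[i]]} "
            f"in adults (synthetic record {i:05d})"
        )
        abstract = (
            f"Background: this synthetic abstract describes corpus entry {record_id}. "
            f"Methods: a {_DESIGNS[designs[i]]} enrolling {sizes[i]} participants "
            f"evaluated {_TOPICS[topics[i]]} against usual care. "
            f"Results: outcomes were recorded for the full follow-up period. "
            f"Conclusion: generated text for screening-pipeline evaluation only."
        )
        records.append(
            ScreeningRecord(
                record_id=record_id,
                title=title,
                abstract=abstract,
                record_text=build_record_text(title, abstract),
                human_screen1=bool(labels[i]),
            )
        )
    return ReviewDataset(
        review_name=f"synthetic-seed{config.seed}",
        records=records,
        original_total=config.n_records,
        counts={"original_total": config.n_records, "preprocessed_total": config.n_records},
    )


def simulate_verdicts(
    dataset: ReviewDataset,
    profiles: Sequence[CriterionProfile],
    failure_rate: float = 0.0,
    seed: int = 28,
):
    """Draw a records x criteria Boolean verdict matrix with statuses.

    Returns a :class:`~abscreen.decide.CriteriaMatrix`. Per ok record and
    criterion the verdict is true with probability s (includable) or f
    (excludable), independently across criteria; a record fails outright
    with probability ``failure_rate`` and gets an all-false row with
    status "failed".
    """
    from .decide import CriteriaMatrix  # local import to avoid a cycle

    if not profiles:
        raise ValueError("profiles must be non-empty")
    rng = np.random.default_rng(seed)
    n = len(dataset.records)
    c = len(profiles)
    labels = np.array([r.human_screen1 for r in dataset.records], dtype=bool)
    failed = rng.random(n) < failure_rate

    s = np.array([p.sensitivity for p in profiles])
    f = np.array([p.false_positive_rate for p in profiles])
    p_true = np.where(labels[:, None], s[None, :], f[None, :])
    values = rng.random((n, c)) < p_true
    values[failed] = False

    return CriteriaMatrix(
        record_ids=dataset.ids(),
        criterion_keys=[p.key for p in profiles],
        values=values,
        status=["failed" if x else "ok" for x in failed],
    )


def expected_operating_point(
    profiles: Sequence[CriterionProfile],
) -> tuple[float, float]:
    """Closed-form (recall, specificity) of the all-criteria-true rule.

    Under conditional independence of criteria given the true label:
    recall = Π s_c (every criterion must fire on an includable record) and
    specificity = 1 − Π f_c (an excludable record survives unless every
    criterion false-fires).
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    recall = float(np.prod([p.sensitivity for p in profiles]))
    specificity = 1.0 - float(np.prod([p.false_positive_rate for p in profiles]))
    return recall, specificity
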