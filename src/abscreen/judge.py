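"""Criterion-wise judging of records with robust parsing and bookkeeping.

A *judge backend* is any callable mapping a prompt string to a response
string; it raises :class:`~abscreen.errors.RateLimitError` when throttled
(the only retriable failure class) and :class:`~abscreen.errors.BackendError`
for anything else. The prompt asks for a JSON object keyed by criterion,
each entry holding a Boolean value and a brief justification. Responses in
the wild are messy — prose prefixes before the JSON, string-typed
Booleans, missing criteria — so the parser recovers the first JSON object
it can find, normalizes values, and defaults absent criteria to False
(conservative: an unjudged criterion pushes a record toward exclusion,
which only adds second-reviewer workload, never silently includes).

Corpus screening runs with a bounded number of in-flight judgments,
persists progress atomically after every batch, keeps succeeded and
failed ("missing") records in provably disjoint sets, and can resume from
its checkpoint without re-judging succeeded records.
"""

from __future__ import annotations

import json
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Protocol, Sequence

from .criteria import Criterion, validate_criteria
from .errors import (
    BackendError,
    CheckpointError,
    ConfigurationError,
    RateLimitError,
    VerdictParseError,
)
from .records import ReviewDataset
from .store import EmbeddedIndex

__all__ = [
    "CriterionVerdict",
    "VerdictSet",
    "JudgeConfig",
    "RetryPolicy",
    "ScreenRunConfig",
    "ScreenResult",
    "build_prompt",
    "parse_verdicts",
    "screen_record",
    "screen_corpus",
    "read_verdicts_jsonl",
    "write_verdicts_jsonl",
]

MISSING_JUSTIFICATION = "missing — defaulted"
FAILED_JUSTIFICATION = "processing failed — defaulted"


@dataclass
class CriterionVerdict:
    value: bool
    justification: str = MISSING_JUSTIFICATION


@dataclass
class VerdictSet:
    """All criterion verdicts for one record, plus processing status.

    A failed record still carries a complete all-False verdict map so that
    decision rules can consume it uniformly, but ``status`` stays
    ``"failed"`` so evaluation can count it as residual human workload.
    """

    record_id: str
    verdicts: dict[str, CriterionVerdict]
    status: str = "ok"  # "ok" | "failed"
    attempts: int = 1
    failure_class: str | None = None  # "rate_limit" | "parse" | "other"

    def __post_init__(self) -> None:
        if self.status not in ("ok", "failed"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "failed" and self.failure_class is None:
            raise ValueError("failed VerdictSet requires a failure_class")

    def values(self, criterion_keys: Sequence[str]) -> list[bool]:
        return [self.verdicts[k].value for k in criterion_keys]

    def to_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "status": self.status,
            "attempts": self.attempts,
            "failure_class": self.failure_class,
            "verdicts": {
                k: {"value": v.value, "justification": v.justification}
                for k, v in self.verdicts.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "VerdictSet":
        return cls(
            record_id=d["record_id"],
            status=d["status"],
            attempts=d["attempts"],
            failure_class=d.get("failure_class"),
            verdicts={
                k: CriterionVerdict(value=bool(v["value"]), justification=v["justification"])
                for k, v in d["verdicts"].items()
            },
        )


@dataclass
class JudgeConfig:
    """Sampling/decoding parameters passed to live backends.

    Deterministic decoding (temperature 0) with a fixed seed, a context
    window large enough for any title+abstract, and no cap on response
    length so JSON outputs are never truncated mid-object.
    """

    temperature: float = 0.0
    top_p: float = 0.95
    seed: int = 28
    context_window: int = 25_000
    response_length_limit: int | None = None  # None = unlimited

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ConfigurationError("temperature must be >= 0")
        if not (0 < self.top_p <= 1):
            raise ConfigurationError("top_p must be in (0, 1]")


@dataclass
class RetryPolicy:
    """Exponential backoff: wait 2^attempt seconds, at most five attempts.

    Only rate-limit failures are retried; after attempt k fails the judge
    sleeps ``delay(k)`` seconds, so the schedule is 2, 4, 8, 16 s for
    retries 1–4.
    """

    max_attempts: int = 5
    retriable_classes: frozenset[str] = frozenset({"rate_limit"})

    def delay(self, attempt: int) -> float:
        return float(2**attempt)


@dataclass
class ScreenRunConfig:
    concurrency_limit: int = 5
    checkpoint_every: int = 20  # records per batch between checkpoints
    checkpoint_path: str | Path | None = None

    def __post_init__(self) -> None:
        if self.concurrency_limit < 1:
            raise ConfigurationError("concurrency_limit must be >= 1")
        if self.checkpoint_every < 1:
            raise ConfigurationError("checkpoint_every must be >= 1")


@dataclass
class ScreenResult:
    succeeded: dict[str, VerdictSet] = field(default_factory=dict)
    missing: dict[str, VerdictSet] = field(default_factory=dict)


class Clock(Protocol):
    def sleep(self, seconds: float) -> None: ...


class _RealClock:
    def sleep(self, seconds: float) -> None:
        time.sleep(seconds)


DEFAULT_TEMPLATE = """You are assisting with study selection for a systematic review.
Analyze the provided scientific article and determine, for each screening
criterion below, whether the article meets it.

Article:
{record_text}

Criteria:
{criteria_block}

Respond with ONLY a JSON object, no other text. The object must have one
entry per criterion, keyed exactly by the criterion name, and each entry
must be an object with a Boolean "value" (true or false) and a brief
"justification" string. Example shape:
{{"<criterion>": {{"value": true, "justification": "..."}}}}
"""


def build_prompt(
    record_text: str,
    criteria: Sequence[Criterion],
    template: str | None = None,
) -> str:
    """Render the screening prompt for one record.

    The prompt contains the record text once, every criterion's key and
    instruction in order, and an explicit JSON-only response directive.
    """
    validate_criteria(criteria)
    template = template or DEFAULT_TEMPLATE
    criteria_block = "\n".join(f"- {c.key}: {c.instruction}" for c in criteria)
    return template.format(record_text=record_text, criteria_block=criteria_block)


def _first_json_object(text: str) -> dict | None:
    """First decodable JSON object in ``text``, skipping any prose around it."""
    decoder = json.JSONDecoder()
    idx = text.find("{")
    while idx != -1:
        try:
            obj, _ = decoder.raw_decode(text, idx)
        except json.JSONDecodeError:
            idx = text.find("{", idx + 1)
            continue
        if isinstance(obj, dict):
            return obj
        idx = text.find("{", idx + 1)
    return None


_STR_TRUE = {"true", "yes", "1"}
_STR_FALSE = {"false", "no", "0"}


def _coerce_bool(value: object) -> bool | None:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and value in (0, 1):
        return bool(value)
    if isinstance(value, str):
        v = value.strip().lower()
        if v in _STR_TRUE:
            return True
        if v in _STR_FALSE:
            return False
    return None


def parse_verdicts(
    raw_response: str, criteria: Sequence[Criterion]
) -> dict[str, CriterionVerdict]:
    """Recover a complete verdict map from a possibly messy response.

    Total on its domain: either returns exactly one verdict per criterion
    or raises :class:`~abscreen.errors.VerdictParseError` — never a partial
    map. String Booleans ("True"/"false"/...) are normalized; criteria
    absent or uninterpretable in the response default to False with a
    placeholder justification.
    """
    obj = _first_json_object(raw_response)
    if obj is None:
        raise VerdictParseError("no JSON object found in response")
    lowered = {str(k).strip().lower(): v for k, v in obj.items()}
    out: dict[str, CriterionVerdict] = {}
    for criterion in criteria:
        entry = obj.get(criterion.key, lowered.get(criterion.key.lower()))
        value: bool | None = None
        justification = MISSING_JUSTIFICATION
        if isinstance(entry, Mapping):
            value = _coerce_bool(entry.get("value"))
            j = entry.get("justification")
            if isinstance(j, str) and j.strip():
                justification = j.strip()
        else:
            value = _coerce_bool(entry)
        if value is None:
            out[criterion.key] = CriterionVerdict(False, MISSING_JUSTIFICATION)
        else:
            out[criterion.key] = CriterionVerdict(value, justification)
    return out


def _all_false(criteria: Sequence[Criterion]) -> dict[str, CriterionVerdict]:
    return {c.key: CriterionVerdict(False, FAILED_JUSTIFICATION) for c in criteria}


def screen_record(
    record_id: str,
    source: str | EmbeddedIndex,
    criteria: Sequence[Criterion],
    backend: Callable[[str], str],
    retry: RetryPolicy | None = None,
    clock: Clock | None = None,
    template: str | None = None,
) -> VerdictSet:
    """Judge one record against every criterion, with backoff on rate limits.

    ``source`` is either the record text itself or an
    :class:`~abscreen.store.EmbeddedIndex` to fetch it from by exact id.
    Rate-limit failures are retried up to ``retry.max_attempts`` with
    delays of 2^attempt seconds (injectable ``clock``); any other backend
    error, or an unparseable response, fails the record immediately.
    """
    retry = retry or RetryPolicy()
    clock = clock or _RealClock()
    record_text = source.fetch(record_id) if isinstance(source, EmbeddedIndex) else source
    prompt = build_prompt(record_text, criteria, template)

    attempt = 0
    while True:
        attempt += 1
        try:
            raw = backend(prompt)
        except RateLimitError:
            if attempt >= retry.max_attempts:
                return VerdictSet(
                    record_id=record_id,
                    verdicts=_all_false(criteria),
                    status="failed",
                    attempts=attempt,
                    failure_class="rate_limit",
                )
            clock.sleep(retry.delay(attempt))
            continue
        except Exception:  # noqa: BLE001 — backend adapters own the taxonomy
            return VerdictSet(
                record_id=record_id,
                verdicts=_all_false(criteria),
                status="failed",
                attempts=attempt,
                failure_class="other",
            )
        try:
            verdicts = parse_verdicts(raw, criteria)
        except VerdictParseError:
            return VerdictSet(
                record_id=record_id,
                verdicts=_all_false(criteria),
                status="failed",
                attempts=attempt,
                failure_class="parse",
            )
        return VerdictSet(
            record_id=record_id, verdicts=verdicts, status="ok", attempts=attempt
        )


def _write_checkpoint(path: Path, result: ScreenResult) -> None:
    payload = json.dumps(
        {
            "succeeded": {k: v.to_dict() for k, v in result.succeeded.items()},
            "missing": {k: v.to_dict() for k, v in result.missing.items()},
        }
    )
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(payload, encoding="utf-8")
    tmp.replace(path)


def _load_checkpoint(path: Path) -> ScreenResult:
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
        return ScreenResult(
            succeeded={k: VerdictSet.from_dict(v) for k, v in doc["succeeded"].items()},
            missing={k: VerdictSet.from_dict(v) for k, v in doc["missing"].items()},
        )
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise CheckpointError(f"corrupt checkpoint, refusing to resume: {path}") from exc


def _assert_disjoint(result: ScreenResult) -> None:
    overlap = result.succeeded.keys() & result.missing.keys()
    if overlap:
        raise AssertionError(f"succeeded/missing sets overlap: {sorted(overlap)[:5]}")


def screen_corpus(
    dataset: ReviewDataset,
    criteria: Sequence[Criterion],
    backend: Callable[[str], str],
    run: ScreenRunConfig | None = None,
    retry: RetryPolicy | None = None,
    clock: Clock | None = None,
    resume: bool = True,
) -> ScreenResult:
    """Judge a whole dataset with bounded concurrency and atomic checkpoints.

    Records are processed in batches of ``run.checkpoint_every``, with at
    most ``run.concurrency_limit`` judgments in flight. After every batch
    the succeeded/missing dictionaries are verified disjoint and persisted
    atomically, so an interrupted run can resume: records already in the
    succeeded set are never re-judged, while previously failed records get
    a fresh attempt.
    """
    run = run or ScreenRunConfig()
    result = ScreenResult()
    checkpoint = Path(run.checkpoint_path) if run.checkpoint_path else None
    if checkpoint and resume and checkpoint.exists():
        result = _load_checkpoint(checkpoint)
        _assert_disjoint(result)

    pending = [
        r for r in dataset.records
        if r.record_id not in result.succeeded
    ]
    # failed records get re-attempted on resume
    for r in pending:
        result.missing.pop(r.record_id, None)

    for start in range(0, len(pending), run.checkpoint_every):
        batch = pending[start : start + run.checkpoint_every]
        with ThreadPoolExecutor(max_workers=run.concurrency_limit) as pool:
            verdict_sets = list(
                pool.map(
                    lambda rec: screen_record(
                        rec.record_id, rec.record_text, criteria, backend, retry, clock
                    ),
                    batch,
                )
            )
        for vs in verdict_sets:
            (result.succeeded if vs.status == "ok" else result.missing)[vs.record_id] = vs
        _assert_disjoint(result)
        if checkpoint:
            _write_checkpoint(checkpoint, result)
    return result


def write_verdicts_jsonl(
    verdict_sets: Iterable[VerdictSet], path: str | Path
) -> None:
    """Persist verdict sets as JSON-lines, one record per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for vs in verdict_sets:
            fh.write(json.dumps(vs.to_dict()) + "\n")


def read_verdicts_jsonl(path: str | Path) -> list[VerdictSet]:
    with open(path, encoding="utf-8") as fh:
        return [VerdictSet.from_dict(json.loads(line)) for line in fh if line.strip()]
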