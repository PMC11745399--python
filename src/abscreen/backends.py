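"""Judge backends: a deterministic simulated judge plus thin live adapters.

A backend is a callable ``prompt -> response text`` raising
:class:`~abscreen.errors.RateLimitError` for throttling and
:class:`~abscreen.errors.BackendError` otherwise. The simulated judge is
first-class: given the true labels and per-criterion operating
characteristics (sensitivity / false-positive rate) it emits well-formed
— or deliberately messy — JSON verdicts, deterministically per
(seed, record, criterion), so every downstream stage can be exercised
offline with known ground truth.

Live adapters for OpenAI-compatible and Ollama HTTP APIs are intentionally
thin and are not part of the offline test matrix.
"""

from __future__ import annotations

import hashlib
import json
import re
import urllib.request
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from .criteria import Criterion
from .errors import BackendError, RateLimitError
from .judge import JudgeConfig
from .simulate import CriterionProfile

__all__ = [
    "RECORD_ID_PATTERN",
    "extract_record_id",
    "SimulatedJudgeBackend",
    "ScriptedBackend",
    "FlakyBackend",
    "OpenAICompatBackend",
    "OllamaBackend",
]

# Synthetic abstracts embed their record id; the simulated judge recovers it
# from the prompt to look up the record's true label.
RECORD_ID_PATTERN = re.compile(r"corpus entry (rec-\d+)")


def extract_record_id(prompt: str) -> str:
    m = RECORD_ID_PATTERN.search(prompt)
    if m is None:
        raise BackendError("prompt does not reference a simulated corpus entry")
    return m.group(1)


def _unit_uniform(*parts: object) -> float:
    """Deterministic pseudo-uniform in [0, 1) from a tuple of values."""
    digest = hashlib.blake2b(
        "\x1f".join(str(p) for p in parts).encode("utf-8"), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") / 2.0**64


@dataclass
class SimulatedJudgeBackend:
    """Emulates an LLM judge over a synthetic corpus.

    For a truly includable record each criterion comes back true with
    probability ``sensitivity``; for an excludable record, with probability
    ``false_positive_rate``. Verdicts are a pure function of
    (seed, record_id, criterion key), so runs are exactly reproducible.

    ``prose_preface_rate`` and ``string_boolean_rate`` inject the two
    response pathologies real judges exhibit (chatty prefixes before the
    JSON, string-typed Booleans) to exercise the parser.
    ``hard_fail_ids`` simulates records a backend simply cannot process.
    """

    truth: Mapping[str, bool]
    profiles: Sequence[CriterionProfile]
    seed: int = 28
    failure_rate: float = 0.0
    prose_preface_rate: float = 0.0
    string_boolean_rate: float = 0.0
    hard_fail_ids: frozenset[str] = frozenset()
    calls: list[str] = field(default_factory=list)

    def __call__(self, prompt: str) -> str:
        record_id = extract_record_id(prompt)
        self.calls.append(record_id)
        if record_id in self.hard_fail_ids:
            raise BackendError(f"simulated hard failure for {record_id}")
        if self.failure_rate and _unit_uniform(self.seed, record_id, "fail") < self.failure_rate:
            raise BackendError(f"simulated processing failure for {record_id}")
        try:
            includable = self.truth[record_id]
        except KeyError:
            raise BackendError(f"unknown record id {record_id}") from None

        verdicts = {}
        for profile in self.profiles:
            p_true = profile.sensitivity if includable else profile.false_positive_rate
            value = _unit_uniform(self.seed, record_id, profile.key) < p_true
            if _unit_uniform(self.seed, record_id, profile.key, "str") < self.string_boolean_rate:
                value_out: object = "True" if value else "False"
            else:
                value_out = value
            verdicts[profile.key] = {
                "value": value_out,
                "justification": f"simulated assessment of {profile.key}",
            }
        body = json.dumps(verdicts)
        if _unit_uniform(self.seed, record_id, "prose") < self.prose_preface_rate:
            return "Here is the output in the requested format: " + body
        return body


@dataclass
class ScriptedBackend:
    """Returns canned responses keyed by record id; for tests and demos."""

    responses: Mapping[str, str]
    default: str | None = None

    def __call__(self, prompt: str) -> str:
        record_id = extract_record_id(prompt)
        if record_id in self.responses:
            return self.responses[record_id]
        if self.default is not None:
            return self.default
        raise BackendError(f"no scripted response for {record_id}")


class FlakyBackend:
    """Wraps a backend, rate-limiting the first ``failures`` calls per prompt."""

    def __init__(self, inner: Callable[[str], str], failures: int) -> None:
        self.inner = inner
        self.failures = failures
        self._seen: dict[str, int] = {}

    def __call__(self, prompt: str) -> str:
        n = self._seen.get(prompt, 0)
        self._seen[prompt] = n + 1
        if n < self.failures:
            raise RateLimitError("simulated rate limit")
        return self.inner(prompt)


def _post_json(url: str, payload: dict, headers: dict[str, str], timeout: float) -> dict:
    req = urllib.request.Request(
        url,
        data=json.dumps(payload).encode("utf-8"),
        headers={"Content-Type": "application/json", **headers},
    )
    try:
        with urllib.request.urlopen(req, timeout=timeout) as resp:
            return json.loads(resp.read().decode("utf-8"))
    except urllib.error.HTTPError as exc:  # pragma: no cover - live only
        if exc.code == 429:
            raise RateLimitError(f"rate limited by {url}") from exc
        raise BackendError(f"HTTP {exc.code} from {url}") from exc
    except Exception as exc:  # pragma: no cover - live only
        raise BackendError(str(exc)) from exc


class OpenAICompatBackend:  # pragma: no cover - requires a live endpoint
    """Chat-completions adapter for OpenAI-compatible HTTP APIs."""

    def __init__(
        self,
        model: str,
        api_key: str,
        base_url: str = "https://api.openai.com/v1",
        config: JudgeConfig | None = None,
        timeout: float = 120.0,
    ) -> None:
        self.model = model
        self.api_key = api_key
        self.base_url = base_url.rstrip("/")
        self.config = config or JudgeConfig()
        self.timeout = timeout

    def __call__(self, prompt: str) -> str:
        doc = _post_json(
            f"{self.base_url}/chat/completions",
            {
                "model": self.model,
                "messages": [{"role": "user", "content": prompt}],
                "temperature": self.config.temperature,
                "top_p": self.config.top_p,
                "seed": self.config.seed,
                "response_format": {"type": "json_object"},
            },
            {"Authorization": f"Bearer {self.api_key}"},
            self.timeout,
        )
        return doc["choices"][0]["message"]["content"]


class OllamaBackend:  # pragma: no cover - requires a live endpoint
    """Generate-API adapter for locally served open models."""

    def __init__(
        self,
        model: str,
        base_url: str = "http://localhost:11434",
        config: JudgeConfig | None = None,
        timeout: float = 600.0,
    ) -> None:
        self.model = model
        self.base_url = base_url.rstrip("/")
        self.config = config or JudgeConfig()
        self.timeout = timeout

    def __call__(self, prompt: str) -> str:
        cfg = self.config
        doc = _post_json(
            f"{self.base_url}/api/generate",
            {
                "model": self.model,
                "prompt": prompt,
                "format": "json",
                "stream": False,
                "options": {
                    "temperature": cfg.temperature,
                    "top_p": cfg.top_p,
                    "seed": cfg.seed,
                    "num_ctx": cfg.context_window,
                    "num_predict": -1 if cfg.response_length_limit is None else cfg.response_length_limit,
                },
            },
            {},
            self.timeout,
        )
        return doc["response"]
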