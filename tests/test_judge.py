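"""Prompt contract, verdict parsing, retry/backoff, corpus bookkeeping."""

import json

import numpy as np
import pytest

from abscreen import Criterion, CriterionProfile, SimulationConfig, generate_review
from abscreen.backends import FlakyBackend, SimulatedJudgeBackend
from abscreen.errors import (
    BackendError,
    CheckpointError,
    ConfigurationError,
    RateLimitError,
    VerdictParseError,
)
from abscreen.judge import (
    MISSING_JUSTIFICATION,
    RetryPolicy,
    ScreenRunConfig,
    build_prompt,
    parse_verdicts,
    screen_corpus,
    screen_record,
)


class FakeClock:
    def __init__(self):
        self.delays = []

    def sleep(self, seconds):
        self.delays.append(seconds)


class TestBuildPrompt:
    def test_contains_record_once_criteria_and_json_directive(self, two_criteria):
        prompt = build_prompt("UNIQUE-RECORD-TEXT", two_criteria)
        assert prompt.count("UNIQUE-RECORD-TEXT") == 1
        for c in two_criteria:
            assert c.key in prompt and c.instruction in prompt
        assert "JSON" in prompt

    def test_reordering_criteria_changes_only_order(self, two_criteria):
        a = build_prompt("R", two_criteria)
        b = build_prompt("R", list(reversed(two_criteria)))
        assert a != b
        assert sorted(a.splitlines()) == sorted(b.splitlines())

    def test_empty_criteria_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            build_prompt("R", [])

    def test_bundled_physio_set_lists_seven_keys(self):
        from abscreen import bundled_criteria

        crits = bundled_criteria("physio")
        prompt = build_prompt("R", crits)
        assert len(crits) == 7
        assert all(c.key in prompt for c in crits)


class TestParseVerdicts:
    def test_prose_prefix_before_json_recovered(self, two_criteria):
        raw = (
            "Here is the output in the requested format: "
            '{"population": {"value": true, "justification": "ok"}, '
            '"outcome": {"value": false, "justification": "no"}}'
        )
        verdicts = parse_verdicts(raw, two_criteria)
        assert verdicts["population"].value is True
        assert verdicts["outcome"].value is False

    @pytest.mark.parametrize("encoded,expected", [
        ('"True"', True), ('"true"', True), ("true", True),
        ('"False"', False), ('"no"', False), ("1", True), ("0", False),
    ])
    def test_string_boolean_normalization(self, encoded, expected, two_criteria):
        raw = (
            f'{{"population": {{"value": {encoded}, "justification": "x"}}, '
            '"outcome": {"value": true, "justification": "y"}}'
        )
        assert parse_verdicts(raw, two_criteria)["population"].value is expected

    def test_missing_criterion_defaulted_false(self, three_criteria):
        raw = '{"population": true, "outcome": {"value": "True", "justification": "j"}}'
        verdicts = parse_verdicts(raw, three_criteria)
        assert set(verdicts) == {"population", "outcome", "design"}
        assert verdicts["design"].value is False
        assert verdicts["design"].justification == MISSING_JUSTIFICATION

    def test_no_json_raises_parse_error(self, two_criteria):
        with pytest.raises(VerdictParseError):
            parse_verdicts("The model refused to answer.", two_criteria)

    def test_braces_in_prose_do_not_confuse_scanner(self, two_criteria):
        raw = 'Note {not json} ... {"population": true, "outcome": false}'
        verdicts = parse_verdicts(raw, two_criteria)
        assert verdicts["population"].value is True

    def test_parser_totality_on_mutilated_responses(self, three_criteria):
        """100 randomly mutilated valid responses: complete map or parse error."""
        rng = np.random.default_rng(0)
        keys = [c.key for c in three_criteria]
        for _ in range(100):
            obj = {}
            for k in keys:
                if rng.random() < 0.3:
                    continue  # drop the criterion entirely
                value = bool(rng.random() < 0.5)
                if rng.random() < 0.5:
                    obj[k] = {"value": str(value) if rng.random() < 0.5 else value,
                              "justification": "j"}
                else:
                    obj[k] = value
            raw = json.dumps(obj)
            if rng.random() < 0.5:
                raw = "Sure! Here you go: " + raw
            if rng.random() < 0.3:
                raw = raw + " Hope this helps."
            try:
                verdicts = parse_verdicts(raw, three_criteria)
            except VerdictParseError:
                continue
            assert set(verdicts) == set(keys)


class TestScreenRecord:
    def ok_backend(self, two_criteria):
        return lambda prompt: json.dumps(
            {c.key: {"value": True, "justification": "j"} for c in two_criteria}
        )

    def test_first_try_success(self, two_criteria):
        vs = screen_record("r1", "text", two_criteria, self.ok_backend(two_criteria))
        assert vs.status == "ok" and vs.attempts == 1
        assert set(vs.verdicts) == {"population", "outcome"}

    def test_rate_limit_backoff_schedule(self, two_criteria):
        backend = FlakyBackend(self.ok_backend(two_criteria), failures=4)
        clock = FakeClock()
        vs = screen_record("r1", "text", two_criteria, backend, RetryPolicy(), clock)
        assert vs.status == "ok" and vs.attempts == 5
        assert clock.delays == [2, 4, 8, 16]

    def test_exhausted_retries_fail_as_rate_limit(self, two_criteria):
        def always_limited(prompt):
            raise RateLimitError("429")

        clock = FakeClock()
        vs = screen_record("r1", "text", two_criteria, always_limited, RetryPolicy(), clock)
        assert vs.status == "failed" and vs.failure_class == "rate_limit"
        assert vs.attempts == 5
        assert clock.delays == [2, 4, 8, 16]

    def test_non_retriable_error_fails_immediately(self, two_criteria):
        def broken(prompt):
            raise BackendError("boom")

        clock = FakeClock()
        vs = screen_record("r1", "text", two_criteria, broken, RetryPolicy(), clock)
        assert vs.status == "failed" and vs.failure_class == "other"
        assert vs.attempts == 1 and clock.delays == []

    def test_unparseable_response_fails_as_parse(self, two_criteria):
        vs = screen_record("r1", "text", two_criteria, lambda p: "no json here")
        assert vs.status == "failed" and vs.failure_class == "parse"
        # failed record still carries a complete all-false map
        assert all(v.value is False for v in vs.verdicts.values())

    def test_fetches_record_text_from_index_by_exact_id(self, two_criteria):
        from abscreen.records import Label, RawRecordRow, preprocess
        from abscreen.store import embed_corpus

        ds = preprocess([RawRecordRow(title="t", abstract="a", screening1=Label.INCLUDED)])
        index = embed_corpus(ds)
        seen = {}

        def backend(prompt):
            seen["prompt"] = prompt
            return self.ok_backend(two_criteria)(prompt)

        screen_record(ds.ids()[0], index, two_criteria, backend)
        assert ds.records[0].record_text in seen["prompt"]


def sim_setup(n=30, failure_rate=0.0, seed=5, hard_fail=()):
    profiles = [
        CriterionProfile("population", 0.9, 0.1),
        CriterionProfile("outcome", 0.95, 0.2),
    ]
    criteria = [Criterion(p.key, f"check {p.key}") for p in profiles]
    ds = generate_review(SimulationConfig(n_records=n, prevalence=0.3,
                                          profiles=profiles, seed=seed))
    backend = SimulatedJudgeBackend(
        truth=ds.labels(), profiles=profiles, seed=seed,
        failure_rate=failure_rate, hard_fail_ids=frozenset(hard_fail),
    )
    return ds, criteria, backend


class TestScreenCorpus:
    def test_all_succeed(self):
        ds, criteria, backend = sim_setup(10)
        result = screen_corpus(ds, criteria, backend)
        assert len(result.succeeded) == 10 and not result.missing

    def test_hard_failures_split_disjointly(self):
        ds, criteria, backend = sim_setup(10, hard_fail=["rec-00002", "rec-00007"])
        result = screen_corpus(ds, criteria, backend)
        assert len(result.succeeded) == 8 and len(result.missing) == 2
        assert not (result.succeeded.keys() & result.missing.keys())
        assert set(result.succeeded) | set(result.missing) == set(ds.ids())

    def test_determinism_with_fixed_seed(self):
        ds, criteria, backend1 = sim_setup(20)
        _, _, backend2 = sim_setup(20)
        r1 = screen_corpus(ds, criteria, backend1)
        r2 = screen_corpus(ds, criteria, backend2)
        assert {k: v.to_dict() for k, v in r1.succeeded.items()} == {
            k: v.to_dict() for k, v in r2.succeeded.items()
        }

    def test_checkpoint_resume_matches_single_pass(self, tmp_path):
        ds, criteria, backend = sim_setup(50, hard_fail=["rec-00013"])
        ckpt = tmp_path / "ckpt.json"

        # interrupted run: only the first 20 records processed
        import dataclasses
        partial = dataclasses.replace(ds)
        partial.records = ds.records[:20]
        run = ScreenRunConfig(checkpoint_path=ckpt, checkpoint_every=10)
        screen_corpus(partial, criteria, backend, run=run)

        # resume over the full corpus; succeeded records are not re-judged
        _, _, fresh_backend = sim_setup(50, hard_fail=["rec-00013"])
        resumed = screen_corpus(ds, criteria, fresh_backend, run=run)
        assert set(fresh_backend.calls).isdisjoint(
            {r.record_id for r in ds.records[:20]} - {"rec-00013"}
        )

        _, _, oracle_backend = sim_setup(50, hard_fail=["rec-00013"])
        single = screen_corpus(ds, criteria, oracle_backend)
        assert {k: v.to_dict() for k, v in resumed.succeeded.items()} == {
            k: v.to_dict() for k, v in single.succeeded.items()
        }
        assert set(resumed.missing) == set(single.missing) == {"rec-00013"}

    def test_corrupt_checkpoint_refused_with_path(self, tmp_path):
        ds, criteria, backend = sim_setup(10)
        ckpt = tmp_path / "ckpt.json"
        ckpt.write_text("{not json", encoding="utf-8")
        with pytest.raises(CheckpointError, match="ckpt.json"):
            screen_corpus(ds, criteria, backend,
                          run=ScreenRunConfig(checkpoint_path=ckpt))

    def test_concurrency_limit_respected(self):
        import threading

        ds, criteria, _ = sim_setup(30)
        lock = threading.Lock()
        state = {"now": 0, "peak": 0}

        def backend(prompt):
            with lock:
                state["now"] += 1
                state["peak"] = max(state["peak"], state["now"])
            import time
            time.sleep(0.002)
            with lock:
                state["now"] -= 1
            return json.dumps({c.key: True for c in criteria})

        screen_corpus(ds, criteria, backend,
                      run=ScreenRunConfig(concurrency_limit=3, checkpoint_every=30))
        assert state["peak"] <= 3
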