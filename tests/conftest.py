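import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from abscreen import (
    Criterion,
    CriterionProfile,
    SimulationConfig,
    generate_review,
    simulate_verdicts,
)


@pytest.fixture
def two_criteria():
    return [
        Criterion("population", "Return true if the population matches."),
        Criterion("outcome", "Return true if the outcome is reported."),
    ]


@pytest.fixture
def three_criteria(two_criteria):
    return two_criteria + [Criterion("design", "Return true if the design qualifies.")]


@pytest.fixture
def profiles():
    return [
        CriterionProfile("population", sensitivity=0.9, false_positive_rate=0.1),
        CriterionProfile("outcome", sensitivity=0.95, false_positive_rate=0.2),
    ]


@pytest.fixture
def small_corpus(profiles):
    config = SimulationConfig(
        n_records=60, prevalence=0.3, profiles=profiles, seed=11
    )
    dataset = generate_review(config)
    matrix = simulate_verdicts(dataset, profiles, failure_rate=0.0, seed=11)
    return dataset, matrix


def write_csv(path, rows, header="title,abstract,screening1"):
    """Write a tiny delimited fixture file."""
    lines = [header] + rows
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
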