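from __future__ import annotations

import numpy as np
import pytest

from arnet.instruments import MiniRqlqResult, QolCategory, SeverityCategory, bin_qol
from arnet.model import Participant, Placement, aggregate_cohort
from arnet.naming import default_taxonomy
from arnet.synth import default_study_params, generate_participants


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture(scope="session")
def make_participant(taxonomy):
    """Factory for hand-built participants from (alter code, circle) pairs."""

    def _make(pid, placements, rqlq_mean=1.0, severity=SeverityCategory.MILD_INTERMITTENT):
        return Participant(
            id=pid,
            severity=severity,
            qol=bin_qol(rqlq_mean),
            rqlq=MiniRqlqResult(mean_score=rqlq_mean),
            placements=tuple(
                Placement(participant_id=pid, alter=taxonomy.by_code(code), circle=circle)
                for code, circle in placements
            ),
        )

    return _make


@pytest.fixture(scope="session")
def make_random_cohort(taxonomy, make_participant):
    """Random small cohorts for oracle-equivalence and round-trip suites."""
    codes = [c.code for c in taxonomy]

    def _make(rng: np.random.Generator, max_egos: int = 6):
        n = int(rng.integers(1, max_egos + 1))
        egos = []
        for i in range(n):
            k = int(rng.integers(1, 8))
            chosen = rng.choice(len(codes), size=k, replace=False)
            placements = [(codes[j], int(rng.integers(1, 5))) for j in chosen]
            mean = float(rng.uniform(0, 6))
            egos.append(make_participant(f"e{i:03d}", placements, rqlq_mean=mean))
        return aggregate_cohort(egos)

    return _make


@pytest.fixture(scope="session")
def small_cohort(make_participant):
    """Three hand-built egos spanning several QOL categories."""
    egos = [
        make_participant("p1", [("gp", 1), ("own_experience", 1), ("internet", 3)], rqlq_mean=1.5),
        make_participant("p2", [("gp", 2), ("pharmacist", 1)], rqlq_mean=3.0),
        make_participant("p3", [("media", 4)], rqlq_mean=5.5),
    ]
    return aggregate_cohort(egos)


@pytest.fixture(scope="session")
def calibrated_participants():
    """A study-sized synthetic cohort from the default parameters."""
    return generate_participants(default_study_params(seed=7, n_participants=41))


@pytest.fixture(scope="session")
def large_participants():
    """Large synthetic cohort for law-of-large-numbers checks (shared)."""
    return generate_participants(default_study_params(seed=1, n_participants=5000))
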