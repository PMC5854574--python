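"""Shared fixtures.

The heavy simulated-population fixtures are session-scoped so the delay
and hidden-cursor studies are computed once and shared between the
population tests and the acceptance suite.

Two cell populations are used deliberately: the position-error-dominant
sampler (the documented recovery-floor regime) for every check about
position-error peak *timing*, and the default multiplexed sampler —
whose kinematic couplings are strong enough to yield significant
position/velocity encoding — for the kinematic-invariance checks.
"""
from __future__ import annotations

import numpy as np
import pytest

from tracklag.experiments import preprocess_session, run_delay_study, run_hidden_study
from tracklag.simulate import generate_session, sample_strong_pe_truth
from tracklag.task import Condition

N_CELLS = 20
N_TRIALS = 50


def _delay_fixture(label: str, seed: int, ana_seed: int):
    session = generate_session(
        N_CELLS,
        N_TRIALS,
        Condition.from_label(label),
        seed=seed,
        truth_factory=sample_strong_pe_truth,
    )
    pre = preprocess_session(session)
    study = run_delay_study(
        session,
        pairs=("PE",),
        n_shuffles=100,
        seed=ana_seed,
        behavioral_checks=False,
        preprocessed=pre,
    )
    return session, pre, study


@pytest.fixture(scope="session")
def delay200_study():
    """20 PE-encoding cells, paired 50-trial baseline / 200-ms-delay
    blocks, full position-error pipeline with the 100-shuffle null."""
    return _delay_fixture("delay200", seed=1200, ana_seed=12)


@pytest.fixture(scope="session")
def delay100_study():
    return _delay_fixture("delay100", seed=1100, ana_seed=11)


@pytest.fixture(scope="session")
def hidden_study():
    """20 gated PE-encoding cells under the hidden-cursor manipulation,
    analyzed inside the target in both blocks."""
    session = generate_session(
        N_CELLS,
        N_TRIALS,
        Condition.from_label("hidden"),
        seed=1999,
        truth_factory=sample_strong_pe_truth,
    )
    pre = preprocess_session(session)
    study = run_hidden_study(
        session,
        pairs=("PE",),
        n_shuffles=100,
        seed=19,
        behavioral_checks=False,
        preprocessed=pre,
    )
    return session, pre, study


@pytest.fixture(scope="session")
def baseline_resplit_study():
    """Null manipulation: both blocks are baseline tracking."""
    session = generate_session(
        8,
        25,
        Condition.from_label("baseline"),
        seed=3011,
        truth_factory=sample_strong_pe_truth,
    )
    pre = preprocess_session(session)
    study = run_delay_study(
        session,
        pairs=("PE",),
        n_shuffles=100,
        seed=30,
        behavioral_checks=False,
        preprocessed=pre,
    )
    return session, pre, study


@pytest.fixture(scope="session")
def kinematic_sessions():
    """Small multiplexed-cell sessions (default sampler, so kinematic
    couplings are substantial) under each manipulation, preprocessed."""
    out = {}
    for label, seed in (("delay200", 4200), ("hidden", 4999)):
        session = generate_session(
            8, 30, Condition.from_label(label), seed=seed
        )
        out[label] = (session, preprocess_session(session))
    return out


@pytest.fixture(scope="session")
def small_session():
    """A light two-cell baseline session for unit-level pipeline tests."""
    return generate_session(2, 8, Condition.from_label("baseline"), seed=77)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
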