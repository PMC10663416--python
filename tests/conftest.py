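"""Shared fixtures: one simulated examination reused across test modules."""

import pytest

from aifcount import SimConfig, simulate_examination, prepare_examination


@pytest.fixture(scope="session")
def poisson_exam():
    cfg = SimConfig(seed=3)
    exam, truth = simulate_examination(cfg, seed=3)
    return exam, truth


@pytest.fixture(scope="session")
def prepared(poisson_exam):
    exam, _ = poisson_exam
    work, offsets, aux = prepare_examination(exam)
    return work, offsets, aux
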