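"""Shared fixtures: synthetic presets, prepared cohorts, trained models.

Everything is generated programmatically at session scope so expensive
artefacts (cohort simulation, desk-scale training) are built once and
reused across test modules.
"""

from __future__ import annotations

import pytest

from lifecourse import (
    DiseaseTrajectoryModel,
    ModelConfig,
    OracleRateModel,
    TrainConfig,
    fixture_presets,
    prepare_cohort,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def presets():
    return fixture_presets()


@pytest.fixture(scope="session")
def tiny_preset(presets):
    return presets["tiny"]


@pytest.fixture(scope="session")
def tiny_vocab(tiny_preset):
    return tiny_preset.hazard_model.vocab


@pytest.fixture(scope="session")
def tiny_cohort(tiny_preset):
    return simulate_cohort(
        tiny_preset.n, tiny_preset.hazard_model, seed=tiny_preset.seed
    )


@pytest.fixture(scope="session")
def tiny_prepared(tiny_cohort, tiny_vocab, tiny_preset):
    return prepare_cohort(tiny_cohort, tiny_vocab, seed=tiny_preset.seed + 1)


@pytest.fixture(scope="session")
def recovery_preset(presets):
    return presets["recovery"]


@pytest.fixture(scope="session")
def recovery_vocab(recovery_preset):
    return recovery_preset.hazard_model.vocab


@pytest.fixture(scope="session")
def recovery_oracle(recovery_preset):
    return OracleRateModel(recovery_preset.hazard_model, exclude_occurred=False)


@pytest.fixture(scope="session")
def trained_tiny(tiny_prepared, tiny_vocab):
    """A briefly trained desk model on the tiny preset (smoke-quality)."""
    model = DiseaseTrajectoryModel(
        tiny_prepared, tiny_vocab, config=ModelConfig.desk_scale(len(tiny_vocab))
    )
    return model.fit(
        TrainConfig.desk_scale(total_iters=300, warmup_iters=30, seed=4)
    )


@pytest.fixture(scope="session")
def trained_recovery(recovery_preset, recovery_vocab):
    """The desk-scale parameter-recovery fit: 5,000-person cohort with
    planted interactions, 6,000 optimization steps at the desk profile."""
    pr = recovery_preset
    cohort = simulate_cohort(pr.n, pr.hazard_model, seed=pr.seed)
    prepared = prepare_cohort(cohort, recovery_vocab, seed=pr.seed + 1)
    model = DiseaseTrajectoryModel(
        prepared, recovery_vocab, config=ModelConfig.desk_scale(len(recovery_vocab))
    )
    return model.fit(TrainConfig.desk_scale(log_every=1000, seed=1))


@pytest.fixture(scope="session")
def recovery_heldout(recovery_preset):
    """Held-out ground-truth cohort (different seed) for evaluation."""
    return simulate_cohort(2000, recovery_preset.hazard_model, seed=999)
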