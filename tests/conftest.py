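"""Shared fixtures: oracle-labeled peptides, calibrated PWM, toy backbones,
and a pretrained mini design model.

Everything is generated programmatically from seeds; the heavier artifacts
are session-scoped so the pretraining and PWM construction run once.
"""

from __future__ import annotations

import numpy as np
import pytest

from deimmune.alphabet import UNCLEAR, UNKNOWN
from deimmune.presentation import PWMClassifier
from deimmune.sequence_model import InverseFoldingModel, pretrain
from deimmune.synthetic import (
    MotifOracle,
    ToyBackboneSpec,
    generate_backbone,
    generate_labeled_set,
)

# Desk-scale study conditions (chosen once; see docs/methods.md).
N_CALIBRATION_PEPTIDES = 50_000
CALIBRATION_SEED = 11
N_TRAIN_STRUCTURES = 20
STRUCTURE_LENGTH = 60
PRETRAIN_EPOCHS = 150
PRETRAIN_LR = 1e-2


class SetPredictor:
    """Presentation predictor defined by an explicit presented-peptide set."""

    def __init__(self, presented, name="set-predictor"):
        self.presented = set(presented)
        self.name = name

    def __call__(self, peptide):
        if UNKNOWN in peptide:
            return UNCLEAR
        return peptide in self.presented


class ConstPredictor:
    """Predictor returning a constant call (X still yields UNCLEAR)."""

    def __init__(self, value, name=None):
        self.value = value
        self.name = name or f"const-{value}"

    def __call__(self, peptide):
        if UNKNOWN in peptide:
            return UNCLEAR
        return self.value


@pytest.fixture(scope="session")
def oracle() -> MotifOracle:
    return MotifOracle()


@pytest.fixture(scope="session")
def labeled_50k(oracle):
    return generate_labeled_set(oracle, N_CALIBRATION_PEPTIDES, seed=CALIBRATION_SEED)


@pytest.fixture(scope="session")
def pwm(labeled_50k) -> PWMClassifier:
    return PWMClassifier.fit(labeled_50k).calibrate(labeled_50k)


@pytest.fixture(scope="session")
def training_structures():
    topologies = ["helix", "strand", "mixed"]
    return [
        generate_backbone(
            ToyBackboneSpec(
                length=STRUCTURE_LENGTH,
                topology=topologies[i % 3],
                noise_sigma=0.1,
                seed=100 + i,
            )
        )
        for i in range(N_TRAIN_STRUCTURES)
    ]


@pytest.fixture(scope="session")
def base_model(training_structures) -> InverseFoldingModel:
    """Mini model after the supervised 'foundation' stage on native sequences."""
    model = InverseFoldingModel.initialize(seed=0)
    pretrain(
        model,
        training_structures,
        epochs=PRETRAIN_EPOCHS,
        learning_rate=PRETRAIN_LR,
        seed=1,
    )
    return model


@pytest.fixture(scope="session")
def helix60():
    return generate_backbone(ToyBackboneSpec(length=60, topology="helix", seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
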