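import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from amni import (
    CNNBranchConfig,
    SyntheticCohortConfig,
    TimeSeriesMatrix,
    TrainConfig,
    generate_cohort,
    pearson_fcn,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_connectivity(rng):
    """A well-conditioned random connectivity matrix with distinct strengths."""
    ts = TimeSeriesMatrix("toy", rng.standard_normal((40, 6)))
    return pearson_fcn(ts)


def desk_scale_train_config(variant: str = "amni", seed: int = 0, **overrides) -> TrainConfig:
    """The scaled-down training recipe used for synthetic-cohort experiments:
    30 epochs at learning rate 1e-3 with a narrow CNN, everything else per
    the default recipe."""
    kwargs = dict(
        learning_rate=1e-3,
        epochs=30,
        batch_size=16,
        seed=seed,
        variant=variant,
        cnn=CNNBranchConfig(conv_channels=[4, 8, 16, 32], fc_widths=(64, 64)),
    )
    kwargs.update(overrides)
    return TrainConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_cohort():
    """24 subjects, both modalities, strong effects; fast to train on."""
    cfg = SyntheticCohortConfig(n_class0=12, n_class1=12, seed=11)
    return generate_cohort(cfg)
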