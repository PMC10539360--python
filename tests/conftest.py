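import numpy as np
import pytest

from actiga import io as aio
from actiga.augment import AugmentationScheme
from actiga.clock import ClockConfig, GestationalAgeClock
from actiga.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """20 synthetic patients, one 8-day measurement each."""
    cfg = SimulationConfig(n_patients=20, measurements_per_patient=1, days=8, seed=42)
    recordings, metadata, truth = generate_cohort(cfg)
    return cfg, recordings, metadata, truth


@pytest.fixture(scope="session")
def tiny_samples(tiny_cohort):
    _, recordings, _, truth = tiny_cohort
    return [
        aio.make_sample(rec, meas.sample_id, meas.ga_weeks)
        for rec, meas in zip(recordings, truth.measurements.itertuples())
    ]


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cohort, tiny_samples):
    _, _, metadata, _ = tiny_cohort
    return aio.split_by_patient(tiny_samples, (0.6, 0.2, 0.2), seed=0, metadata=metadata)


@pytest.fixture(scope="session")
def small_clock(tiny_dataset):
    """A small clock trained briefly at reduced length (1,440 bins).

    Shared by attribution and augmentation tests that need a fitted,
    differentiable model; accuracy is irrelevant to them.
    """
    config = ClockConfig(
        n_blocks=2,
        embed_dim=32,
        bottleneck_dim=8,
        kernel_sizes=(9, 19, 39),
        learning_rate=0.02,
        min_epochs=5,
        max_epochs=40,
        batch_size=64,
        input_length=1440,
        seed=0,
    )
    model = GestationalAgeClock(tiny_dataset, config, AugmentationScheme(seed=0), downsample=7)
    results = model.fit()
    return model, results
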