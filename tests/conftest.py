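import numpy as np
import pandas as pd
import pytest

from soursentinel import GeneratorConfig, generate_experiment

DATA_DIR = __import__("pathlib").Path(__file__).parent / "data"


def small_config(seed: int = 7, **overrides) -> GeneratorConfig:
    """A scaled-down experiment used where the full design is not needed."""
    base = dict(
        n_columns=6,
        n_treated=3,
        duration_days=80,
        sampling_interval_days=2,
        nitrate_start_day=30,
        nitrate_stop_day=60,
        n_background_taxa=15,
        n_srb_taxa=3,
        harvest_days=(50, 56, 62, 78),
        seed=seed,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def default_experiment():
    """One full-design experiment shared by read-only tests."""
    return generate_experiment(GeneratorConfig(seed=11))


@pytest.fixture()
def small_experiment():
    return generate_experiment(small_config())


@pytest.fixture()
def minibundle_dir():
    return DATA_DIR / "minibundle"
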