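import numpy as np
import pandas as pd
import pytest

from surftens.data import Dataset, FluidRecord, NormalizationSpec
from surftens.network import MLPNetwork
from surftens.simulate import GeneratorConfig, generate_dataset

# Literature constants for acetic acid (DIPPR-style values), used as the
# reference fluid for the corresponding-states regression fixtures.
ACETIC = dict(name="acetic_acid", family="carboxylic",
              Tc=591.95, Tb=391.05, omega=0.4665, Pc=57.86, Mw=60.052)


@pytest.fixture
def acetic():
    return FluidRecord(**ACETIC)


@pytest.fixture
def small_dataset():
    """~400-point noisy synthetic corpus over 12 fluids (fixed seed)."""
    cfg = GeneratorConfig(n_fluids=12, points_per_fluid=(8, 60), seed=101)
    ds, _ = generate_dataset(cfg)
    return ds


def make_teacher(seed: int = 12345, n_hidden: int = 5) -> MLPNetwork:
    """Frozen random (3, n_hidden, 1) teacher with a physical (positive,
    order-0.02-N/m) output surface over the generator's input ranges."""
    rng = np.random.default_rng(seed)
    return MLPNetwork(
        input_names=("Tr", "Tb", "omega"),
        hidden_weights=rng.uniform(-2, 2, (n_hidden, 3)),
        hidden_biases=rng.uniform(-1, 1, n_hidden),
        output_weights=rng.uniform(0.05, 0.18, n_hidden),
        output_bias=0.08,
        input_norms=(NormalizationSpec("Tr", 0.25, 0.92),
                     NormalizationSpec("Tb", 300.0, 680.0),
                     NormalizationSpec("omega", 0.3, 1.1)),
        output_norm=NormalizationSpec("sigma", 0.0, 0.08),
    )


def teacher_dataset(noise_sd: float, seed: int = 7, n_fluids: int = 40,
                    n_hidden: int = 5) -> Dataset:
    """Corpus generated by the frozen teacher network (~1900 points)."""
    teacher = make_teacher(n_hidden=n_hidden)
    cfg = GeneratorConfig(
        n_fluids=n_fluids, points_per_fluid=(40, 60), noise_sd=noise_sd,
        duplicate_prob=0.0, seed=seed, teacher="frozen_network",
        frozen_network=teacher)
    ds, _ = generate_dataset(cfg)
    return ds


def toy_dataset(rows, fluids=None):
    """Dataset from explicit (fluid, T, sigma) tuples; one default fluid."""
    if fluids is None:
        fluids = [FluidRecord(**ACETIC)]
    df = pd.DataFrame(rows, columns=["fluid", "T", "sigma"])
    return Dataset(fluids, df)
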