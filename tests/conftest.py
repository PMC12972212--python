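import warnings
from contextlib import contextmanager

import numpy as np
import pandas as pd
import pytest

from betaclock import ClockConfig, MethylationDataset, SimConfig, simulate_dataset
from betaclock.simulate import simulate_like
from betaclock.two_stage import train_two_stage


@contextmanager
def quiet():
    """Suppress expected pipeline warnings (short site lists etc.)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def linear_cohort():
    """A small linear-trend cohort with its ground truth and a test draw."""
    ds, truth = simulate_dataset(
        SimConfig(
            n_samples=400,
            n_sites=40,
            n_informative=16,
            curve_family="linear",
            noise_scale=0.02,
            seed=42,
        )
    )
    test = simulate_like(truth, 80, seed=43)
    return ds, truth, test


@pytest.fixture(scope="session")
def trained_linear_model(linear_cohort):
    ds, _, _ = linear_cohort
    with quiet():
        model, _ = train_two_stage(ds, ClockConfig(), cutoff=25)
    return model


def make_dataset(beta, ages=None, sex=None, samples=None, sites=None):
    """Hand-rolled MethylationDataset from plain arrays."""
    beta = np.asarray(beta, dtype=float)
    samples = samples or [f"s{i}" for i in range(beta.shape[0])]
    sites = sites or [f"cg{j:08d}" for j in range(beta.shape[1])]
    frame = pd.DataFrame(beta, index=samples, columns=sites)
    ages_s = pd.Series(np.asarray(ages, dtype=float), index=samples) if ages is not None else None
    sex_s = pd.Series(sex, index=samples) if sex is not None else None
    return MethylationDataset(beta=frame, ages=ages_s, sex=sex_s)
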