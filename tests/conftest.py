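import numpy as np
import pandas as pd
import pytest

from precision_pathways import (
    CohortDataset,
    EnsemblePredictions,
    PlatformAssay,
    PlatformSpec,
    RunConfig,
    SyntheticSpec,
    generate_cohort,
)


def make_predictions(platform, votes_per_patient, classes=("neg", "pos"), tie_seed=0):
    """EnsemblePredictions built directly from a {patient: vote list} map."""
    votes = pd.DataFrame.from_dict(
        {pid: list(v) for pid, v in votes_per_patient.items()}, orient="index"
    )
    votes.columns = [f"rep{i}" for i in range(votes.shape[1])]
    return EnsemblePredictions(
        platform=platform, votes=votes, classes=tuple(classes), tie_seed=tie_seed
    )


def gaussian_assay(name, n_per_class, n_features, delta, seed, cost=0.0, classes=("neg", "pos")):
    """Two-class Gaussian assay: informative feature 0 shifted by delta."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.normal(size=(n, n_features))
    y = np.array([classes[0]] * n_per_class + [classes[1]] * n_per_class, dtype=object)
    X[:, 0] += np.where(y == classes[1], delta / 2.0, -delta / 2.0)
    samples = pd.Index([f"S{i:03d}" for i in range(n)])
    matrix = pd.DataFrame(X, index=samples, columns=[f"{name}_f{j}" for j in range(n_features)])
    labels = pd.Series(y, index=samples, name="class")
    return PlatformAssay(name=name, matrix=matrix, cost=cost), labels


@pytest.fixture
def small_config():
    """Light-weight run configuration for fast unit tests."""
    return RunConfig(repeats=5, feature_counts=(5,), seed=7)


@pytest.fixture
def two_platform_cohort():
    """60 patients, two platforms resolving disjoint 50/50 subpopulations."""
    spec = SyntheticSpec(
        platforms=(
            PlatformSpec("alpha", n_features=30, n_informative=3, effect_size=8.0,
                         cost=30.0, subpop_fraction=0.5),
            PlatformSpec("beta", n_features=40, n_informative=3, effect_size=8.0,
                         cost=50.0, subpop_fraction=0.5),
        ),
        n_patients=60,
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture
def separable_cohort():
    """Small cohort where every platform separates every patient (Δ=10)."""
    spec = SyntheticSpec(
        platforms=(
            PlatformSpec("first", n_features=20, n_informative=3, effect_size=10.0,
                         cost=10.0, subpop_fraction=1.0),
        ),
        n_patients=40,
        seed=5,
    )
    return generate_cohort(spec)
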