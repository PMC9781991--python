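import numpy as np
import pandas as pd
import pytest

from emgselect import DatabaseSpec, generate_database
from emgselect.features import FeatureMatrix


@pytest.fixture(scope="session")
def tiny_spec():
    """A small but structurally complete database: 2 subjects, 2 movements +
    rest, 4 repetitions, 4 channels, 2 s at 1 kHz with 0.3 s rest lead."""
    return DatabaseSpec(
        n_subjects=2,
        movement_names=("A", "B", "RR"),
        n_reps=4,
        n_channels=4,
        fs=1000.0,
        duration=2.0,
        rest_lead=0.3,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_db(tiny_spec):
    return generate_database(tiny_spec)


def make_blob_matrix(
    n_informative: int,
    n_noise: int,
    n_classes: int = 3,
    n_per_class: int = 30,
    separation: float = 3.0,
    seed: int = 0,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Labelled matrix whose first ``n_informative`` columns carry
    class-dependent means (Gaussian blobs) and whose remaining columns are
    pure noise.  Returns (matrix, informative_column_mask)."""
    rng = np.random.default_rng(seed)
    n_cols = n_informative + n_noise
    X = rng.standard_normal((n_classes * n_per_class, n_cols))
    y = np.repeat([f"C{k}" for k in range(n_classes)], n_per_class)
    for k in range(n_classes):
        centers = rng.standard_normal(n_informative) * separation
        X[k * n_per_class:(k + 1) * n_per_class, :n_informative] += centers
    rows = pd.DataFrame(
        {
            "subject": 0,
            "movement": y,
            "repetition": np.arange(len(y)),
            "window": -1,
        }
    )
    columns = pd.MultiIndex.from_tuples(
        [("ch1", f"F{i}") for i in range(n_cols)], names=["channel", "predictor"]
    )
    informative = np.zeros(n_cols, dtype=bool)
    informative[:n_informative] = True
    return FeatureMatrix(values=X, rows=rows, columns=columns), informative


@pytest.fixture(scope="session")
def blob6():
    """6-column instance (2 informative, 4 noise) for exhaustive-search
    comparisons."""
    return make_blob_matrix(2, 4, n_classes=3, n_per_class=30, separation=3.0, seed=5)
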