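import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from vitalsentry import (
    Autoencoder,
    CohortConfig,
    GruAutoencoder,
    chronological_split,
    cohort_windows,
    fit_normalizer,
    generate_cohort,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    """6 subjects, 2 weeks (1 train + 1 test), 2 episode subjects."""
    cfg = CohortConfig(
        n_subjects=6,
        n_weeks=2,
        train_weeks=1,
        n_unhealthy_subjects=2,
        n_male=3,
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_split(tiny_cohort):
    return chronological_split(tiny_cohort)


@pytest.fixture(scope="session")
def tiny_scaler(tiny_split):
    return fit_normalizer(tiny_split[0])


@pytest.fixture(scope="session")
def tiny_trained(tiny_split, tiny_scaler):
    """Small GRU-AE + AE trained briefly on the tiny cohort's healthy weeks."""
    train, _ = tiny_split
    wb = cohort_windows(train, tiny_scaler, window_length=168)
    gru = GruAutoencoder(
        hidden_sizes=(8, 4, 8), n_epochs=300, random_state=0
    ).fit(wb.windows)
    X = np.concatenate([tiny_scaler.transform(s.values()) for s in train.series])
    ae = Autoencoder(hidden_sizes=(8, 4, 8), n_epochs=120, random_state=0).fit(X)
    return gru, ae, wb
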