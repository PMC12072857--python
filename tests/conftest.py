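import numpy as np
import pandas as pd
import pytest

from rsig_triage import GeneratorConfig, apply_exclusions, generate_cohort


@pytest.fixture(scope="session")
def midsize_clean() -> pd.DataFrame:
    """Cleaned cohort with enough deaths for band-level fits (1% mortality)."""
    cfg = GeneratorConfig(n_patients=30_000, mortality_rate=0.01, seed=202)
    clean, _ = apply_exclusions(generate_cohort(cfg))
    return clean


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_scores_labels(rng: np.random.Generator, n: int, signal: float = 1.0):
    """Small two-class score set: deaths shifted low by `signal` score units."""
    n_pos = int(rng.integers(1, max(2, n // 4)))
    n_neg = n - n_pos
    pos = rng.normal(10.0 - 3.0 * signal, 3.0, n_pos)
    neg = rng.normal(15.0, 4.0, n_neg)
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(n_pos, dtype=np.int64),
                             np.zeros(n_neg, dtype=np.int64)])
    perm = rng.permutation(n)
    return scores[perm], labels[perm]
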