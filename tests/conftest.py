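import dataclasses

import numpy as np
import pandas as pd
import pytest

from orbigrow.cohort import replicate_study_structure


@pytest.fixture
def study_config():
    """Cohort preset mirroring the study: 65 patients, 146 scans."""
    return replicate_study_structure()


@pytest.fixture
def noise_free_config(study_config):
    """Same structure with every noise source switched off."""
    return dataclasses.replace(
        study_config,
        sd_individual=0.0,
        sd_walk_per_year=0.0,
        sd_measurement=0.0,
        asymmetry_log_ratio=0.0,
    )


def random_pair_instance(rng, max_pairs=10, base_age=12):
    """Small random pair table whose age-class graph is connected to base.

    Ages are chained (consecutive shuffled ages share an edge) so every
    coefficient is identified; growths are standard normal; patients are
    assigned at random from a pool of three.
    """
    n_ages = rng.integers(2, 6)
    ages = list(
        rng.choice(np.arange(7, 19), size=n_ages, replace=False)
    )
    if base_age not in ages:
        ages[0] = base_age
    order = rng.permutation(len(ages))
    chain = [ages[i] for i in order]
    edges = [tuple(sorted((chain[i], chain[i + 1]))) for i in range(len(chain) - 1)]
    n_extra = int(rng.integers(0, max_pairs - len(edges) + 1))
    for _ in range(n_extra):
        j, k = rng.choice(ages, size=2, replace=False)
        edges.append(tuple(sorted((int(j), int(k)))))
    rows = []
    for j, k in edges:
        rows.append(
            (
                f"P{rng.integers(1, 4)}",
                int(j),
                int(k),
                int(k - j),
                float(rng.normal()),
            )
        )
    return pd.DataFrame(rows, columns=["patient_id", "j", "k", "interval", "growth"])
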