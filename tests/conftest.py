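"""Shared fixtures.

The expensive fixture is ``replicate_table``: MPA-tuned vs default
holdout accuracy for all four classifiers on ten independently seeded
synthetic datasets.  It backs both the improvement-direction check and
the classifier-ranking check, so it is computed once per session.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ecgmpa import features, mpa, synthetic, tuning

N_REPLICATES = 10
REPLICATE_BEATS = 120
REPLICATE_MPA = dict(n=10, tmax=15)


@pytest.fixture(scope="session")
def clean_record():
    """A noise-free, jitter-free record: every beat window equals its template."""
    cfg = synthetic.SimConfig(
        n_beats=40,
        base_rr=1.2,
        rr_jitter_sd=0.0,
        noise_sd=0.0,
        wander_amplitude=0.0,
        powerline_amplitude=0.0,
        class_proportions={"N": 0.4, "S": 0.2, "VEB": 0.25, "F": 0.15},
        seed=2,
    )
    return synthetic.generate_record(cfg)


@pytest.fixture(scope="session")
def small_record():
    """A well-separated 150-beat record with mild noise."""
    return synthetic.generate_record(
        synthetic.well_separated_config(n_beats=150, seed=1)
    )


@pytest.fixture(scope="session")
def small_features(small_record):
    df = features.extract_all(small_record)
    X = df.drop(columns="label").to_numpy()
    y = df["label"].to_numpy()
    return X, y


@pytest.fixture(scope="session")
def replicate_table():
    """Tuned vs default holdout accuracy over 10 seeded synthetic datasets."""
    rows = []
    for seed in range(N_REPLICATES):
        record = synthetic.generate_record(
            synthetic.well_separated_config(n_beats=REPLICATE_BEATS, seed=100 + seed)
        )
        df = features.extract_all(record)
        X = df.drop(columns="label").to_numpy()
        y = df["label"].to_numpy()
        for clf in tuning.CLASSIFIERS:
            tuned = tuning.tune(
                clf,
                X,
                y,
                mpa_params=mpa.MPAParams(seed=seed, **REPLICATE_MPA),
                split_seed=seed,
            )
            default_acc = tuning.default_holdout_accuracy(clf, X, y, split_seed=seed)
            rows.append(
                {
                    "replicate": seed,
                    "classifier": clf,
                    "tuned": tuned.holdout_accuracy,
                    "default": default_acc,
                }
            )
    return pd.DataFrame(rows)
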