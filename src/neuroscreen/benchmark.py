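"""Reproducible synthetic-cohort evaluation of the screening ensemble.

Since the patient cohort is unavailable, the ensemble's operating point is
characterized on synthetic feature cohorts generated from the published
per-group means and SDs of the twelve most discriminative features (two
per exercise). One replicate runs the full pipeline — simulate, KDE
augmentation, per-exercise feature selection, grid-searched model, 70:30
stratified split, mean aggregation — and scores the held-out test split;
:func:`screening_benchmark` repeats this over independent seeds and
reports the per-seed metrics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .augmentation import augment_dataset
from .classification import ExerciseEnsembleClassifier, evaluate, split_dataset
from .synthetic_data import CohortSimSpec, simulate_feature_cohort


def run_screening_replicate(
    seed: int,
    n_per_group: int = 100,
    model_kind: str = "svm",
    n_negative: int = 200,
    n_positive: int = 200,
    train_fraction: float = 0.7,
    threshold: float = 0.5,
) -> dict:
    """One full simulate → augment → select → train → aggregate → score run."""
    spec = CohortSimSpec(
        n_no_dn=n_per_group,
        n_dn=n_per_group,
        include_edx=False,
        include_demographics=False,
        seed=seed,
    )
    cohort = simulate_feature_cohort(spec)
    augmented = augment_dataset(cohort, n_negative, n_positive, seed=seed)
    train, test = split_dataset(augmented, train_fraction, seed=seed)
    model = ExerciseEnsembleClassifier(
        model_kind=model_kind, threshold=threshold, random_state=seed
    )
    model.fit(train.X, train.y)
    scores = model.predict_proba(test.X)[:, 1]
    report = evaluate(test.y, scores, threshold=threshold)
    return {
        "seed": seed,
        "n_test": len(test),
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
        "accuracy": report.accuracy,
        "auc": report.auc,
    }


def screening_benchmark(
    n_seeds: int = 20,
    base_seed: int = 0,
    n_per_group: int = 100,
    model_kind: str = "svm",
    **replicate_kwargs,
) -> pd.DataFrame:
    """Per-seed metrics over ``n_seeds`` independent replicates.

    Replicate seeds are spawned from ``base_seed`` and stay below 2**31.
    """
    ss = np.random.SeedSequence(base_seed)
    seeds = [int(s) % (2**31) for s in ss.generate_state(n_seeds)]
    rows = [
        run_screening_replicate(
            seed, n_per_group=n_per_group, model_kind=model_kind, **replicate_kwargs
        )
        for seed in seeds
    ]
    return pd.DataFrame(rows)
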