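"""Shared fixtures: small synthetic studies reused across test modules.

The multi-seed simulation batches are session-scoped because several
tests read different aspects of the same runs (e.g. the zero-
separability runs feed both the verification null check and the
identification chance-level check).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from emgid.config import PopulationConfig
from emgid.experiment import make_cv_plan
from emgid.features import extract_dataset_features
from emgid.identification import evaluate_identification
from emgid.matching import score_cv_folds
from emgid.synthetic import generate_dataset
from emgid.verification import evaluate_verification


def run_pipeline(cfg, scenarios, vote_sizes, shrinkage="auto"):
    """Dataset -> features -> CV fold scores -> verification + identification."""
    ds = generate_dataset(cfg)
    feats = extract_dataset_features(ds)
    plan = make_cv_plan(cfg.n_repetitions, n_folds=cfg.n_repetitions)
    folds = score_cv_folds(feats, plan.test_rep_by_fold, shrinkage)
    ver = evaluate_verification(folds, scenarios, vote_sizes)
    ident, _ = evaluate_identification(folds, vote_sizes)
    return ds, feats, folds, ver, ident


@pytest.fixture(scope="session")
def small_dataset():
    """3 subjects x 2 gestures x 7 reps at default spreads."""
    cfg = PopulationConfig(n_subjects=3, n_gestures=2, seed=42)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    return extract_dataset_features(small_dataset)


@pytest.fixture(scope="session")
def small_fold_scores(small_features, small_dataset):
    plan = make_cv_plan(small_dataset.config.n_repetitions)
    return score_cv_folds(small_features, plan.test_rep_by_fold, "auto")


@pytest.fixture(scope="session")
def separability_sweep():
    """Leaked-test EER and rank-1 (m=1) at subject separability 0 / 0.5 / 2.

    4 subjects x 2 gestures, 5 seeds per setting.  The within-class
    repetition jitter is held at 1.2 so the middle setting sits clearly
    off the zero-EER floor and the ordering across settings is a real
    prediction rather than a floor artifact.
    """
    out = {}
    for sep in (0.0, 0.5, 2.0):
        rows = []
        for seed in range(5):
            cfg = PopulationConfig(
                n_subjects=4, n_gestures=2, seed=100 + seed,
                subject_separability=sep, within_class_variability=1.2,
            )
            _, _, _, ver, ident = run_pipeline(cfg, ("leaked",), (1,))
            rows.append(
                dict(seed=seed, eer=ver.eer.mean(), rank1=ident.rank1.mean())
            )
        out[sep] = pd.DataFrame(rows)
    return out


@pytest.fixture(scope="session")
def trend_runs():
    """Default-separability runs for the vote-size and scenario trends.

    4 subjects x 4 gestures (the reduced evaluation scale), 5 seeds;
    normal and leaked scenarios at all four vote sizes.
    """
    records = []
    for seed in range(5):
        cfg = PopulationConfig(n_subjects=4, n_gestures=4, seed=200 + seed)
        _, _, _, ver, ident = run_pipeline(cfg, ("normal", "leaked"), (1, 5, 9, 13))
        ver = ver.assign(seed=seed)
        ident = ident.assign(seed=seed)
        records.append((ver, ident))
    ver = pd.concat([v for v, _ in records], ignore_index=True)
    ident = pd.concat([i for _, i in records], ignore_index=True)
    return ver, ident
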