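"""Class templates and the Mahalanobis matching score.

A template summarizes the training windows of one (subject, gesture)
class by its centroid mu and a regularized covariance Sigma.  The
matching score of a probe feature vector p against a template is half
its squared Mahalanobis distance to the centroid:

    Score(p) = 1/2 (p - mu)^T Sigma^{-1} (p - mu)

(lower = more similar).  With 48 feature dimensions and a few hundred
training windows per class the sample covariance is noisy, so Sigma is
shrunk toward a scaled identity,

    Sigma = (1 - lambda) S + lambda (tr S / p) I,

with S the unbiased sample covariance and lambda either fixed or chosen
by the Ledoit-Wolf analytic rule.  Scores are computed through a
Cholesky solve, never an explicit inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from sklearn.covariance import ledoit_wolf_shrinkage

__all__ = [
    "Template",
    "fit_template",
    "match_score",
    "match_scores",
    "score_probe_set",
    "FoldScores",
    "score_cv_folds",
]

_DEGENERATE_RIDGE = 1e-12


@dataclass
class Template:
    """Enrolled model of one (subject, gesture) class."""

    subject_id: int
    gesture_id: int
    mu: np.ndarray
    sigma: np.ndarray
    shrinkage: float
    n_train: int
    _chol: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not np.all(np.isfinite(self.mu)):
            raise ValueError("template centroid contains non-finite values")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("template covariance is not symmetric")
        if self._chol is None:
            self._chol = cho_factor(self.sigma, lower=True)

    @classmethod
    def from_moments(
        cls, mu, sigma, subject_id: int = 0, gesture_id: int = 0,
        shrinkage: float = 0.0, n_train: int = 2,
    ) -> "Template":
        return cls(subject_id, gesture_id, np.asarray(mu, float),
                   np.asarray(sigma, float), shrinkage, n_train)

    @property
    def dim(self) -> int:
        return self.mu.size


def fit_template(
    train_features: np.ndarray,
    subject_id: int = 0,
    gesture_id: int = 0,
    shrinkage: float | str = "auto",
) -> Template:
    """Estimate a class template from its training windows.

    ``shrinkage`` is either a fixed lambda in [0, 1] or ``"auto"`` for the
    Ledoit-Wolf analytic intensity.  A class with zero total variance
    (identical training vectors) falls back to a tiny identity ridge so
    the template stays positive definite.
    """
    X = np.asarray(train_features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError(
            f"template for (subject={subject_id}, gesture={gesture_id}) needs at "
            f"least 2 training windows, got shape {X.shape}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("training features contain non-finite values")
    n, p = X.shape
    mu = X.mean(axis=0)
    S = np.cov(X, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    mean_var = np.trace(S) / p
    if shrinkage == "auto":
        lam = float(ledoit_wolf_shrinkage(X, assume_centered=False))
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrinkage must lie in [0, 1]")
    if mean_var <= 0.0:
        sigma = _DEGENERATE_RIDGE * np.eye(p)
    else:
        sigma = (1.0 - lam) * S + lam * mean_var * np.eye(p)
    sigma = 0.5 * (sigma + sigma.T)
    chol = _safe_cholesky(sigma, mean_var)
    return Template(subject_id, gesture_id, mu, sigma, lam, n, _chol=chol)


def _safe_cholesky(sigma: np.ndarray, scale: float):
    ridge = max(scale, 1.0) * 1e-12
    for _ in range(4):
        try:
            return cho_factor(sigma, lower=True)
        except np.linalg.LinAlgError:
            sigma += ridge * np.eye(sigma.shape[0])
            ridge *= 100.0
    raise np.linalg.LinAlgError("covariance not positive definite after ridging")


def match_score(p: np.ndarray, t: Template) -> float:
    """Half squared Mahalanobis distance of one probe to a template."""
    return float(match_scores(np.asarray(p, float)[None, :], t)[0])


def match_scores(P: np.ndarray, t: Template) -> np.ndarray:
    """Vectorized scores of probes (n x dim) against one template."""
    P = np.asarray(P, dtype=float)
    if P.shape[1] != t.dim:
        raise ValueError(f"probe dimension {P.shape[1]} != template dimension {t.dim}")
    d = P - t.mu[None, :]
    z = cho_solve(t._chol, d.T)
    return 0.5 * np.einsum("ij,ji->i", d, z)


def score_probe_set(
    probes: pd.DataFrame,
    templates: Mapping[tuple[int, int], Template],
    template_keys: Sequence[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Dense score table: one row per probe window, one column per template.

    ``probes`` is a feature table (rows in stream order); columns of the
    result are a (subject, gesture) MultiIndex.  Row order is preserved.
    """
    keys = list(template_keys) if template_keys is not None else sorted(templates)
    missing = [k for k in keys if k not in templates]
    if missing:
        raise KeyError(f"missing templates for (subject, gesture) classes: {missing}")
    fcols = [c for c in probes.columns if c.startswith("f")]
    P = probes[fcols].to_numpy(dtype=float)
    out = np.empty((len(probes), len(keys)))
    for j, k in enumerate(keys):
        out[:, j] = match_scores(P, templates[k])
    cols = pd.MultiIndex.from_tuples(keys, names=["subject", "gesture"])
    return pd.DataFrame(out, index=probes.index, columns=cols)


@dataclass
class FoldScores:
    """Everything one CV fold contributes to the evaluations.

    ``probes`` holds the identity columns of the fold's test windows in
    stream order; ``scores`` is the dense probe x template table aligned
    with it.  ``train_repetitions`` / ``test_repetition`` carry the
    provenance needed to assert that no test window reached a template.
    """

    fold: int
    train_repetitions: tuple[int, ...]
    test_repetition: int
    templates: dict[tuple[int, int], Template]
    probes: pd.DataFrame
    scores: pd.DataFrame


def score_cv_folds(
    features: pd.DataFrame,
    test_rep_by_fold: Mapping[int, int],
    shrinkage: float | str = "auto",
) -> dict[int, FoldScores]:
    """Fit per-class templates and score all test windows, per CV fold.

    For each fold, templates are fit from all repetitions except the
    fold's test repetition, then every test window of every class is
    scored against every template.
    """
    reps = sorted(int(r) for r in features["repetition"].unique())
    id_cols = ["subject", "gesture", "repetition", "window"]
    fcols = [c for c in features.columns if c.startswith("f")]
    out: dict[int, FoldScores] = {}
    for fold, test_rep in sorted(test_rep_by_fold.items()):
        train = features[features["repetition"] != test_rep]
        test = features[features["repetition"] == test_rep].reset_index(drop=True)
        templates: dict[tuple[int, int], Template] = {}
        for (s, g), grp in train.groupby(["subject", "gesture"], sort=True):
            templates[(int(s), int(g))] = fit_template(
                grp[fcols].to_numpy(dtype=float), int(s), int(g), shrinkage
            )
        scores = score_probe_set(test, templates)
        out[fold] = FoldScores(
            fold=fold,
            train_repetitions=tuple(r for r in reps if r != test_rep),
            test_repetition=test_rep,
            templates=templates,
            probes=test[id_cols].copy(),
            scores=scores,
        )
    return out
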