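"""Template estimation and the half squared Mahalanobis matching score."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from emgid.config import PopulationConfig
from emgid.features import extract_dataset_features
from emgid.matching import (
    Template,
    fit_template,
    match_score,
    match_scores,
    score_probe_set,
)
from emgid.synthetic import generate_dataset


class TestFitTemplate:
    def test_hand_computed_moments_without_shrinkage(self):
        X = np.array([[0, 0], [2, 0], [0, 2], [2, 2]], dtype=float)
        t = fit_template(X, shrinkage=0.0)
        assert np.allclose(t.mu, [1, 1])
        assert np.allclose(t.sigma, [[4 / 3, 0], [0, 4 / 3]])
        assert t.n_train == 4

    def test_full_shrinkage_gives_scaled_identity(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 5))
        t = fit_template(X, shrinkage=1.0)
        S = np.cov(X, rowvar=False, ddof=1)
        assert np.allclose(t.sigma, (np.trace(S) / 5) * np.eye(5))

    def test_identical_vectors_stay_positive_definite(self):
        X = np.tile([1.0, 2.0, 3.0], (6, 1))
        t = fit_template(X, shrinkage=1.0)
        assert np.allclose(t.mu, [1, 2, 3])
        assert np.all(np.linalg.eigvalsh(t.sigma) > 0)

    def test_auto_shrinkage_in_unit_interval(self):
        rng = np.random.default_rng(1)
        t = fit_template(rng.normal(size=(30, 8)), shrinkage="auto")
        assert 0.0 <= t.shrinkage <= 1.0
        assert np.all(np.linalg.eigvalsh(t.sigma) > 0)

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_template(np.zeros((1, 4)))
        with pytest.raises(ValueError, match="non-finite"):
            fit_template(np.array([[1.0, np.nan], [0.0, 1.0]]))


class TestMatchScore:
    def test_centroid_scores_zero(self):
        t = Template.from_moments([1.0, -2.0], np.eye(2))
        assert match_score([1.0, -2.0], t) == 0.0

    def test_euclidean_reduction_identity_covariance(self):
        t = Template.from_moments([0.0, 0.0], np.eye(2))
        assert match_score([3.0, 4.0], t) == pytest.approx(12.5)

    def test_diagonal_closed_form(self):
        t = Template.from_moments([0.0, 0.0], np.diag([2.0, 0.5]))
        assert match_score([1.0, 2.0], t) == pytest.approx(4.25)

    def test_covariance_scale_divides_scores(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(4, 4))
        sigma = A @ A.T + 4 * np.eye(4)
        P = rng.normal(size=(10, 4))
        base = match_scores(P, Template.from_moments(np.zeros(4), sigma))
        for c in (0.25, 3.0):
            scaled = match_scores(P, Template.from_moments(np.zeros(4), c * sigma))
            assert np.allclose(scaled, base / c, rtol=1e-12)

    def test_dimension_mismatch(self):
        t = Template.from_moments([0.0, 0.0], np.eye(2))
        with pytest.raises(ValueError, match="dimension"):
            match_score([1.0, 2.0, 3.0], t)

    def test_affine_invariance_without_shrinkage(self):
        """Mahalanobis scores are invariant under invertible affine maps of
        the feature space when the template is refit on mapped data."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 3))
        P = rng.normal(size=(10, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        A = q @ np.diag([1.5, 0.7, 1.1])  # well-conditioned
        b = rng.normal(size=3)
        t0 = fit_template(X, shrinkage=0.0)
        t1 = fit_template(X @ A.T + b, shrinkage=0.0)
        s0 = match_scores(P, t0)
        s1 = match_scores(P @ A.T + b, t1)
        assert np.allclose(s0, s1, rtol=1e-6)


class TestScoreProbeSet:
    def test_cardinality_and_zero_diagonal(self, small_features, small_fold_scores):
        fs = small_fold_scores[1]
        n_templates = len(fs.scores.columns)
        assert fs.scores.shape == (len(fs.probes), n_templates)
        # probes equal to their own template centroid score zero
        t = fs.templates[(1, 1)]
        assert match_score(t.mu, t) == 0.0

    def test_missing_template_listed(self, small_features):
        sub = small_features[small_features.repetition == 1].head(5)
        t = fit_template(np.zeros((3, 48)) + np.arange(48), 1, 1, shrinkage=1.0)
        with pytest.raises(KeyError, match=r"\(2, 1\)"):
            score_probe_set(sub, {(1, 1): t}, template_keys=[(1, 1), (2, 1)])

    def test_template_order_independence(self, small_features, small_fold_scores):
        fs = small_fold_scores[1]
        keys = list(fs.templates)
        probes = small_features[small_features.repetition == 1].reset_index(drop=True)
        fwd = score_probe_set(probes, fs.templates, keys)
        rev = score_probe_set(probes, fs.templates, keys[::-1])
        assert np.array_equal(fwd[keys].to_numpy(), rev[keys].to_numpy())

    def test_own_class_scores_stochastically_smaller(self):
        """Across seeds, genuine (own-template) scores rank below scores
        against other classes' templates on separable synthetic data."""
        for seed in range(5):
            cfg = PopulationConfig(
                n_subjects=2, n_gestures=2, n_repetitions=3, duration=1.5, seed=300 + seed
            )
            ds = generate_dataset(cfg)
            feats = extract_dataset_features(ds)
            train = feats[feats.repetition < 3]
            test = feats[feats.repetition == 3].reset_index(drop=True)
            fcols = [c for c in feats.columns if c.startswith("f")]
            templates = {
                (int(s), int(g)): fit_template(grp[fcols].to_numpy(), int(s), int(g))
                for (s, g), grp in train.groupby(["subject", "gesture"])
            }
            scores = score_probe_set(test, templates)
            own, other = [], []
            for i, row in test.iterrows():
                key = (int(row.subject), int(row.gesture))
                for col in scores.columns:
                    (own if col == key else other).append(scores.iloc[i][col])
            assert mannwhitneyu(own, other, alternative="less").pvalue < 1e-4
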