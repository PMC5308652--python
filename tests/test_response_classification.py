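import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import apoptopredict as ap
from apoptopredict.response_classification import (
    ClassificationError,
    ResponseClass,
)


class TestAssignResponseClass:
    @pytest.mark.parametrize(
        "survival, expected",
        [
            (0.25, ResponseClass.HIGH),
            (0.30, ResponseClass.HIGH),  # boundary inclusive
            (0.31, ResponseClass.LOW),
            (0.80, ResponseClass.LOW),  # boundary inclusive
            (0.85, ResponseClass.RESISTANT),
            (1.05, ResponseClass.RESISTANT),  # above-control assay noise
            (0.0, ResponseClass.HIGH),
        ],
    )
    def test_binning(self, survival, expected):
        assert ap.assign_response_class(survival) is expected

    def test_negative_survival_rejected(self):
        with pytest.raises(ClassificationError):
            ap.assign_response_class(-0.1)

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ap.assign_response_class(0.5, thresholds=(0.8, 0.3))

    @given(
        a=st.floats(min_value=0, max_value=1.1),
        b=st.floats(min_value=0, max_value=1.1),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_survival(self, a, b):
        if a > b:
            a, b = b, a
        assert ap.assign_response_class(a) <= ap.assign_response_class(b)


H, L, R = ResponseClass.HIGH, ResponseClass.LOW, ResponseClass.RESISTANT


class TestPooling:
    def test_singleton_high_pools_into_low(self):
        labels = [H] + [L] * 5 + [R] * 5
        pooled = ap.pool_singleton_classes(labels)
        assert pooled == [L] * 6 + [R] * 5

    def test_no_singleton_unchanged(self):
        labels = [H] * 3 + [L] * 4 + [R] * 4
        assert ap.pool_singleton_classes(labels) == [int(x) for x in labels]

    def test_cascading_pooling(self):
        labels = [H] + [L] + [R] * 9
        assert ap.pool_singleton_classes(labels) == [L, L] + [R] * 9

    def test_singleton_resistant_pools_upward(self):
        labels = [H] * 5 + [L] * 5 + [R]
        assert ap.pool_singleton_classes(labels) == [H] * 5 + [L] * 6

    def test_all_singletons_rejected(self):
        with pytest.raises(ClassificationError, match="coarser"):
            ap.pool_singleton_classes([H, L, R])

    @given(
        labels=st.lists(st.sampled_from([0, 1, 2]), min_size=2, max_size=20)
    )
    @settings(max_examples=200, deadline=None)
    def test_pooling_properties(self, labels):
        from collections import Counter

        counts = Counter(labels)
        if all(v == 1 for v in counts.values()):
            with pytest.raises(ClassificationError):
                ap.pool_singleton_classes(labels)
            return
        pooled = ap.pool_singleton_classes(labels)
        out = Counter(pooled)
        assert len(out) <= len(counts)  # never increases class count
        if len(out) > 1:
            assert all(v >= 2 for v in out.values())  # no singleton left


def spherical_two_class_coords(k=4, offset=3.0):
    """Two classes whose sample pooled covariance is exactly spherical."""
    mu0 = np.zeros(k)
    mu0[0] = -offset
    mu1 = -mu0
    pts0 = [mu0 + e for e in np.eye(k)] + [mu0 - e for e in np.eye(k)]
    pts1 = [mu1 + e for e in np.eye(k)] + [mu1 - e for e in np.eye(k)]
    coords = np.vstack(pts0 + pts1)
    labels = [0] * len(pts0) + [1] * len(pts1)
    return coords, labels


class TestLDA:
    def test_two_class_spherical_boundary_is_midplane(self):
        """With symmetric spherical classes at (-3,0,..) and (+3,0,..) the
        separating hyperplane is x1 = 0."""
        coords, labels = spherical_two_class_coords()
        model = ap.fit_class_regions(coords, labels)
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.normal(size=4)
            scores = model.discriminant_scores(x)
            assert (scores[1] > scores[0]) == (x[0] > 0) or abs(x[0]) < 1e-12
        # decision value vanishes on the plane
        on_plane = np.array([0.0, 1.3, -0.7, 2.0])
        s = model.discriminant_scores(on_plane)
        assert abs(s[0] - s[1]) < 1e-10

    def test_closed_form_discriminant_scores(self, rng):
        """Scores match the textbook formula computed independently."""
        coords = rng.normal(size=(30, 3))
        labels = rng.integers(0, 2, size=30)
        labels[:2], labels[2:4] = 0, 1  # ensure both classes populated
        model = ap.fit_class_regions(coords, labels, ridge=1e-9)
        x = rng.normal(size=3)
        scores = model.discriminant_scores(x)
        for idx, c in enumerate(model.classes):
            mu = coords[labels == c].mean(axis=0)
            inv = np.linalg.inv(model.covariance)
            expected = mu @ inv @ x - 0.5 * mu @ inv @ mu + np.log(0.5)
            assert scores[idx] == pytest.approx(expected, abs=1e-8)

    def test_point_at_class_mean_classified_to_class(self, rng):
        coords = np.vstack(
            [rng.normal(size=(10, 2)) - 4, rng.normal(size=(10, 2)) + 4]
        )
        labels = [0] * 10 + [1] * 10
        model = ap.fit_class_regions(coords, labels)
        for idx, c in enumerate(model.classes):
            assert ap.classify(model, model.means[idx]) == c

    def test_collinear_three_class_ordinal_regions(self):
        """Well-separated collinear means give ordinal regions along the line."""
        rng = np.random.default_rng(3)
        means = [-10.0, 0.0, 10.0]
        coords = np.vstack(
            [m + 0.5 * rng.normal(size=(8, 1)) for m in means]
        )
        labels = [0] * 8 + [1] * 8 + [2] * 8
        model = ap.fit_class_regions(coords, labels)
        for x, expected in [(-10, 0), (-6, 0), (0, 1), (4, 1), (9, 2)]:
            assert ap.classify(model, np.array([float(x)])) == expected

    def test_identical_coordinates_singular(self):
        coords = np.ones((8, 3))
        with pytest.raises(ClassificationError, match="singular"):
            ap.fit_class_regions(coords, [0] * 4 + [1] * 4)

    def test_dimension_mismatch(self):
        coords, labels = spherical_two_class_coords()
        model = ap.fit_class_regions(coords, labels)
        with pytest.raises(ClassificationError):
            ap.classify(model, np.zeros(2))

    def test_single_class_rejected(self):
        with pytest.raises(ClassificationError):
            ap.fit_class_regions(np.random.default_rng(0).normal(size=(6, 2)), [1] * 6)

    def test_agrees_with_sklearn_lda(self, rng):
        """Independent cross-check against scikit-learn's LDA predictions."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        coords = np.vstack(
            [rng.normal(size=(15, 4)) + mu for mu in ([-2, 0, 0, 0], [2, 1, 0, 0], [0, -2, 1, 0])]
        )
        labels = np.repeat([0, 1, 2], 15)
        model = ap.fit_class_regions(coords, labels, ridge=1e-10)
        sk = LinearDiscriminantAnalysis(priors=[1 / 3] * 3).fit(coords, labels)
        test = rng.normal(size=(100, 4)) * 2
        ours = np.array([ap.classify(model, x) for x in test])
        theirs = sk.predict(test)
        assert (ours == theirs).mean() >= 0.99

    def test_affine_invariance_of_decisions(self, rng):
        """Decisions are unchanged by an invertible affine map of all coords."""
        coords = np.vstack(
            [rng.normal(size=(12, 3)) - 2, rng.normal(size=(12, 3)) + 2]
        )
        labels = [0] * 12 + [1] * 12
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        b = rng.normal(size=3)
        test = rng.normal(size=(40, 3)) * 3
        m1 = ap.fit_class_regions(coords, labels, ridge=1e-12)
        m2 = ap.fit_class_regions(coords @ A.T + b, labels, ridge=1e-12)
        p1 = [ap.classify(m1, x) for x in test]
        p2 = [ap.classify(m2, x @ A.T + b) for x in test]
        assert p1 == p2


class TestResubstitution:
    def test_separable_classes_perfect(self):
        coords, labels = spherical_two_class_coords(offset=5.0)
        model = ap.fit_class_regions(coords, labels)
        assert ap.resubstitution_accuracy(model, coords, labels) == 1.0

    def test_permuted_labels_near_chance(self, rng):
        coords = rng.normal(size=(40, 3))
        accs = []
        for _ in range(100):
            labels = rng.permutation([0] * 20 + [1] * 20)
            model = ap.fit_class_regions(coords, labels)
            accs.append(ap.resubstitution_accuracy(model, coords, labels))
        # resubstitution overfits slightly above the 0.5 majority prior
        assert 0.45 < np.mean(accs) < 0.75

    def test_bayes_rate_approached_at_large_n(self, rng):
        """Known 1-D Gaussian mixture: accuracy approaches the analytic
        Bayes rate as n grows."""
        from scipy.stats import norm

        delta = 2.0  # class means at 0 and 2, unit SD
        bayes = norm.cdf(delta / 2)
        n = 4000
        coords = np.concatenate(
            [rng.normal(0, 1, n), rng.normal(delta, 1, n)]
        ).reshape(-1, 1)
        labels = [0] * n + [1] * n
        model = ap.fit_class_regions(coords, labels)
        acc = ap.resubstitution_accuracy(model, coords, labels)
        assert acc == pytest.approx(bayes, abs=0.02)
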