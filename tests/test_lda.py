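import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import subspace_angles

from serslda import (
    ConfigurationError,
    DegenerateInputError,
    LDScores,
    PreprocessParams,
    augment_gaussian,
    classify,
    default_profiles,
    evaluate,
    fit_lda,
    generate_dataset,
    preprocess_pipeline,
    project,
    scatter_matrices,
    split_train_test,
)
from serslda.synth import WavenumberAxis
from tests.conftest import make_matrix, simple_profiles


def random_matrix(rng, n_per_class, p, sep=3.0):
    """Gaussian blobs with distinct means, one blob per class name."""
    names = ["heart", "lung", "seminal"][: len(n_per_class)]
    rows, labels = [], []
    for i, (name, n) in enumerate(zip(names, n_per_class)):
        mean = np.zeros(p)
        mean[i % p] = sep * (i + 1)
        rows.append(rng.normal(0.0, 1.0, (n, p)) + mean)
        labels.extend([name] * n)
    return make_matrix(np.vstack(rows), labels)


class TestSplit:
    def test_even_split_per_class(self):
        M = random_matrix(np.random.default_rng(0), (10, 10, 10), 4)
        train, test = split_train_test(M, 0.5, seed=0)
        for c in M.classes:
            assert train.class_indices(c).size == 5
            assert test.class_indices(c).size == 5

    def test_partition_is_exact(self):
        M = random_matrix(np.random.default_rng(1), (7, 9, 8), 4)
        train, test = split_train_test(M, 0.5, seed=1)
        assert train.n + test.n == M.n
        assert np.allclose(np.sort(np.vstack([train.X, test.X]), axis=0),
                           np.sort(M.X, axis=0))

    def test_degenerate_ratios_rejected(self):
        M = random_matrix(np.random.default_rng(2), (4, 4, 4), 3)
        for ratio in (0.0, 1.0):
            with pytest.raises(ConfigurationError):
                split_train_test(M, ratio, seed=0)

    def test_single_member_class_rejected(self):
        M = make_matrix(np.eye(3), ["heart", "lung", "seminal"])
        with pytest.raises(DegenerateInputError):
            split_train_test(M, 0.5, seed=0)

    def test_same_seed_same_partition(self):
        M = random_matrix(np.random.default_rng(3), (8, 8, 8), 5)
        a = split_train_test(M, 0.5, seed=42)
        b = split_train_test(M, 0.5, seed=42)
        assert np.array_equal(a[0].X, b[0].X) and np.array_equal(a[1].X, b[1].X)


class TestAugment:
    def test_zero_copies_is_identity(self):
        M = random_matrix(np.random.default_rng(4), (5, 5), 3)
        out = augment_gaussian(M, copies=0, seed=0)
        assert np.array_equal(out.X, M.X)

    def test_zero_sigma_stacks_identical_copies(self):
        M = random_matrix(np.random.default_rng(5), (4, 4), 3)
        out = augment_gaussian(M, sigma_rel=0.0, copies=2, seed=0)
        assert out.n == 3 * M.n
        assert np.array_equal(out.X[: M.n], M.X)
        assert np.array_equal(out.X[M.n : 2 * M.n], M.X)
        assert np.array_equal(out.labels, np.tile(M.labels, 3))

    def test_row_count_contract(self):
        M = random_matrix(np.random.default_rng(6), (48, 48), 6)
        assert augment_gaussian(M, copies=2, seed=0).n == 288


class TestScatter:
    def test_two_dimensional_toy_exact(self):
        """Direct-summation oracle on four points in the plane."""
        M = make_matrix(
            [[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]],
            ["a", "a", "b", "b"],
        )
        sp = scatter_matrices(M)
        assert np.allclose(sp.S_W, [[4.0, 0.0], [0.0, 0.0]])
        assert np.allclose(sp.S_B, [[0.0, 0.0], [0.0, 2.0]])

    def test_single_point_classes_have_zero_within_scatter(self):
        M = make_matrix([[1.0, 2.0], [3.0, 4.0]], ["a", "b"])
        assert np.allclose(scatter_matrices(M).S_W, 0.0)

    def test_single_class_rejected(self):
        M = make_matrix(np.random.default_rng(7).normal(size=(4, 3)), ["a"] * 4)
        with pytest.raises(DegenerateInputError):
            scatter_matrices(M)

    @given(shift=st.lists(st.floats(-50.0, 50.0), min_size=3, max_size=3))
    @settings(max_examples=20, deadline=None)
    def test_translation_invariance(self, shift):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(12, 3))
        labels = ["a"] * 6 + ["b"] * 6
        a = scatter_matrices(make_matrix(X, labels))
        b = scatter_matrices(make_matrix(X + np.asarray(shift), labels))
        assert np.allclose(a.S_W, b.S_W, atol=1e-6)
        assert np.allclose(a.S_B, b.S_B, atol=1e-6)

    def test_between_scatter_rank_bound_is_exact(self):
        # sum_i w_i (m_i - grand) == 0 under both conventions, so the
        # c-class between-scatter has rank exactly c - 1
        rng = np.random.default_rng(9)
        M = random_matrix(rng, (5, 7, 6), 6)
        for weighted in (False, True):
            sp = scatter_matrices(M, weighted=weighted)
            evals = np.linalg.eigvalsh(sp.S_B)
            nonzero = (evals > 1e-9 * evals.max()).sum()
            assert nonzero <= 2


def brute_force_subspace(sp, k):
    """Dense eigendecomposition of S_W^{-1} S_B, the textbook route."""
    evals, evecs = np.linalg.eig(np.linalg.inv(sp.S_W) @ sp.S_B)
    order = np.argsort(evals.real)[::-1]
    return evecs[:, order[:k]].real


class TestFitLDA:
    def test_component_count_capped_at_c_minus_1(self):
        M = random_matrix(np.random.default_rng(10), (6, 6, 6), 4)
        with pytest.raises(ConfigurationError):
            fit_lda(M, n_components=3)

    def test_three_classes_two_nonzero_eigenvalues(self):
        M = random_matrix(np.random.default_rng(11), (8, 8, 8), 5)
        model = fit_lda(M, n_components=2)
        lam = model.eigenvalues_all
        assert (lam > 1e-9 * lam[0]).sum() == 2
        assert lam[0] >= lam[1] >= 0.0

    def test_two_class_fisher_closed_form(self):
        """With nonsingular S_W the leading direction is parallel to
        S_W^{-1}(m1 - m2) (Fisher's discriminant)."""
        rng = np.random.default_rng(12)
        M = random_matrix(rng, (40, 40), 6)
        model = fit_lda(M, n_components=1, shrinkage=0.0)
        sp = model.scatter
        fisher = np.linalg.solve(sp.S_W, sp.class_means[0] - sp.class_means[1])
        fisher /= np.linalg.norm(fisher)
        v = model.V[:, 0]
        # sine of the angle, well-conditioned near zero
        angle = np.linalg.norm(fisher - (fisher @ v) * v)
        assert angle < 1e-8

    def test_three_class_toy_matches_dense_eigensolver(self):
        rng = np.random.default_rng(13)
        M = random_matrix(rng, (20, 20, 20), 2)
        model = fit_lda(M, n_components=2, shrinkage=0.0)
        oracle = brute_force_subspace(model.scatter, 2)
        assert np.max(subspace_angles(model.V, oracle)) < 1e-6

    @pytest.mark.parametrize("seed", range(20))
    def test_subspace_matches_brute_force_oracle(self, seed):
        """On small nonsingular instances the fitted plane coincides with
        the dense eigendecomposition of S_W^{-1} S_B."""
        rng = np.random.default_rng(seed)
        p = int(rng.integers(3, 11))
        n = int(rng.integers(p + 3, 21))
        M = random_matrix(rng, (n, n, n), p, sep=float(rng.uniform(1.0, 4.0)))
        model = fit_lda(M, n_components=2, shrinkage=0.0)
        oracle = brute_force_subspace(model.scatter, 2)
        assert np.max(subspace_angles(model.V, oracle)) < 1e-6

    def test_singular_within_scatter_requires_shrinkage(self):
        rng = np.random.default_rng(14)
        M = random_matrix(rng, (3, 3), 10)  # p > n: singular S_W
        with pytest.raises(DegenerateInputError, match="shrinkage"):
            fit_lda(M, n_components=1, shrinkage=0.0)
        model = fit_lda(M, n_components=1, shrinkage=1e-3)
        assert model.V.shape == (10, 1)

    def test_columns_unit_norm_and_sign_fixed(self):
        M = random_matrix(np.random.default_rng(15), (10, 10, 10), 5)
        model = fit_lda(M)
        assert np.allclose(np.linalg.norm(model.V, axis=0), 1.0)
        for j in range(model.V.shape[1]):
            k = int(np.argmax(np.abs(model.V[:, j])))
            assert model.V[k, j] > 0


class TestProjectClassify:
    def test_class_means_project_to_centroids(self):
        M = random_matrix(np.random.default_rng(16), (9, 9, 9), 4)
        model = fit_lda(M)
        scores = project(model, model.scatter.class_means)
        assert np.allclose(scores.Z, model.centroids, atol=1e-10)

    def test_grand_mean_projects_to_origin(self):
        M = random_matrix(np.random.default_rng(17), (6, 6, 6), 4)
        model = fit_lda(M)
        assert np.allclose(project(model, model.grand_mean).Z, 0.0, atol=1e-12)

    def test_toy_projection_is_matrix_product(self):
        M = random_matrix(np.random.default_rng(18), (5, 5, 5), 3)
        model = fit_lda(M)
        X = np.random.default_rng(19).normal(size=(4, 3))
        assert np.allclose(project(model, X).Z, (X - model.grand_mean) @ model.V)

    def test_dimension_mismatch_rejected(self):
        M = random_matrix(np.random.default_rng(20), (5, 5, 5), 3)
        model = fit_lda(M)
        with pytest.raises(ConfigurationError):
            project(model, np.zeros((2, 7)))

    def test_point_at_centroid_gets_that_class(self):
        M = random_matrix(np.random.default_rng(21), (6, 6, 6), 4)
        model = fit_lda(M)
        pred = classify(model, LDScores(Z=model.centroids))
        assert list(pred) == list(model.classes)

    def test_equidistant_tie_goes_to_lexicographically_smaller(self):
        M = random_matrix(np.random.default_rng(22), (6, 6, 6), 4)
        model = fit_lda(M)
        midpoint = 0.5 * (model.centroids[0] + model.centroids[1])
        pred = classify(model, LDScores(Z=midpoint[None, :]))
        assert pred[0] == min(model.classes[0], model.classes[1])

    def test_matches_exhaustive_distance_oracle(self):
        M = random_matrix(np.random.default_rng(23), (6, 6, 6), 4)
        model = fit_lda(M)
        Z = np.random.default_rng(24).normal(0.0, 5.0, (200, 2))
        pred = classify(model, LDScores(Z=Z))
        for row, label in zip(Z, pred):
            dists = {c: np.linalg.norm(row - model.centroids[i])
                     for i, c in enumerate(model.classes)}
            assert dists[label] == min(dists.values())


class TestEvaluate:
    def test_all_correct_single_class_block(self):
        pred = ["lung"] * 33
        m = evaluate(pred, pred)
        stats = m.per_class["lung"]
        assert stats["precision"] == stats["sensitivity"] == stats["f_score"] == 1.0
        assert stats["support"] == 33

    def test_all_wrong_gives_zero_accuracy(self):
        m = evaluate(["a", "a"], ["b", "b"])
        assert m.accuracy == 0.0

    def test_hand_computed_counts(self):
        truth = ["a"] * 4 + ["b"] * 2
        pred = ["a", "a", "a", "b", "a", "b"]  # a: TP=3 FP=1 FN=1
        stats = evaluate(pred, truth).per_class["a"]
        assert stats["precision"] == 0.75
        assert stats["sensitivity"] == 0.75
        assert stats["f_score"] == 0.75

    def test_matches_sklearn_report(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(25)
        truth = rng.choice(["a", "b", "c"], 200)
        pred = rng.choice(["a", "b", "c"], 200)
        ours = evaluate(pred, truth)
        p, r, f, s = sklearn.precision_recall_fscore_support(
            truth, pred, labels=list(ours.classes), zero_division=np.nan
        )
        for i, c in enumerate(ours.classes):
            assert np.isclose(ours.per_class[c]["precision"], p[i])
            assert np.isclose(ours.per_class[c]["sensitivity"], r[i])
            assert np.isclose(ours.per_class[c]["f_score"], f[i])
            assert ours.per_class[c]["support"] == s[i]
        assert np.isclose(ours.accuracy, sklearn.accuracy_score(truth, pred))

    def test_absent_class_flagged_not_zeroed(self):
        m = evaluate(["a", "c"], ["a", "a"])
        assert "c" in m.undefined
        assert np.isnan(m.per_class["c"]["sensitivity"])


def test_separation_monotone_in_planted_amplitude(small_axis):
    """Mean test accuracy is non-decreasing in the class-exclusive band
    amplitude (up to one misclassified spectrum of sampling noise)."""
    amplitudes = (0.0, 0.05, 0.1, 0.2, 0.4)
    means = []
    for amp in amplitudes:
        accs = []
        for seed in range(6):
            ds = generate_dataset(
                default_profiles(exclusive_amplitude=amp),
                (20, 20, 20),
                seed=seed,
                axis=small_axis,
            )
            M = preprocess_pipeline(ds, PreprocessParams())
            train, test = split_train_test(M, 0.5, seed=seed + 100)
            train = augment_gaussian(train, seed=seed + 200)
            model = fit_lda(train)
            pred = classify(model, project(model, test.X))
            accs.append(float((pred == test.labels).mean()))
        means.append(np.mean(accs))
    n_test = 30
    for lo, hi in zip(means, means[1:]):
        assert hi >= lo - 1.0 / n_test
    assert means[-1] > means[0]
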