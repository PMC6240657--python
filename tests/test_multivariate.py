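import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from spectranote import (
    NSAFMatrix,
    cluster_profile_plot_data,
    kmeans_fit,
    loading_sum_profile,
    nsaf,
    pca_fit,
    presence_filter,
    profile_normalize,
    treatment_means,
)

from conftest import make_counts


def _matrix(values: np.ndarray, treatments, n_replicates) -> NSAFMatrix:
    design = pd.DataFrame(
        [
            {"sample_id": f"{t}_r{r}", "treatment": t, "replicate": r}
            for t in treatments
            for r in range(1, n_replicates + 1)
        ]
    )
    vals = pd.DataFrame(values, columns=design["sample_id"])
    vals.index = [f"P{i}" for i in range(len(vals))]
    return NSAFMatrix(values=vals, scale_factor=1.0, design=design)


class TestPCA:
    def test_duplicated_samples_identical_scores(self):
        rng = np.random.default_rng(0)
        base = rng.random((20, 3))
        vals = np.column_stack([base, base])  # samples 4-6 duplicate 1-3
        m = _matrix(vals, ("A", "B"), 3)
        model = pca_fit(m)
        np.testing.assert_allclose(
            model.scores.iloc[:3].to_numpy(), model.scores.iloc[3:].to_numpy(),
            atol=1e-9,
        )

    def test_two_variable_closed_form_eigenvectors(self):
        # 2 proteins (variables) x many samples with known covariance
        rng = np.random.default_rng(7)
        cov = np.array([[2.0, 0.8], [0.8, 1.0]])
        X = rng.multivariate_normal([0, 0], cov, size=500)  # samples x 2
        m = _matrix(np.abs(X).T, tuple(f"T{i}" for i in range(250)), 2)
        model = pca_fit(m, n_components=2)
        S = np.cov(np.abs(X).T)
        evals, evecs = np.linalg.eigh(S)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for j in range(2):
            v = evecs[:, j]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(
                model.loadings.iloc[:, j].to_numpy(), v, atol=1e-9
            )
        np.testing.assert_allclose(model.explained_variance, evals, rtol=1e-9)

    def test_full_reconstruction(self):
        cm = make_counts(30, seed=3)
        m = nsaf(cm)
        model = pca_fit(m)
        X = m.values.T.to_numpy()
        recon = model.scores.to_numpy() @ model.loadings.to_numpy().T + model.mean.to_numpy()
        np.testing.assert_allclose(recon, X, atol=1e-9)

    def test_scores_covariance_diagonal(self):
        cm = make_counts(40, seed=9)
        model = pca_fit(nsaf(cm), n_components=5)
        S = np.cov(model.scores.to_numpy().T)
        np.testing.assert_allclose(
            S, np.diag(model.explained_variance), atol=1e-9
        )

    def test_too_many_components_rejected(self):
        cm = make_counts(10, seed=1)
        with pytest.raises(ValueError, match="components"):
            pca_fit(nsaf(cm), n_components=13)


class TestLoadingSums:
    def test_both_sides_partition_total_mass(self):
        cm = make_counts(24, seed=5)
        m = nsaf(cm)
        model = pca_fit(m)
        n = len(m.accessions)
        hi = loading_sum_profile(model, m, "PC1", n, "high")
        # taking all proteins from either side must give the total mean NSAF
        total = treatment_means(m).sum(axis=0)
        np.testing.assert_allclose(hi, total, rtol=1e-9)

    def test_n_one_is_single_extreme_protein(self):
        cm = make_counts(15, seed=6)
        m = nsaf(cm)
        model = pca_fit(m)
        top = model.loadings["PC1"].idxmax()
        prof = loading_sum_profile(model, m, "PC1", 1, "high")
        np.testing.assert_allclose(prof, treatment_means(m).loc[top], rtol=1e-12)

    def test_matches_sort_and_sum_oracle(self):
        cm = make_counts(60, seed=8)
        m = nsaf(cm)
        model = pca_fit(m)
        load = model.loadings["PC1"]
        chosen = load.sort_values(ascending=False, kind="stable").index[:10]
        expected = treatment_means(m).loc[chosen].sum(axis=0)
        got = loading_sum_profile(model, m, "PC1", 10, "high")
        np.testing.assert_allclose(got, expected, rtol=1e-12)


class TestProfiles:
    def test_uniform_means(self):
        means = pd.DataFrame([[1.0, 1, 1, 1]], index=["P1"], columns=list("ABCD"))
        assert profile_normalize(means).iloc[0].tolist() == [0.25] * 4

    def test_arithmetic(self):
        means = pd.DataFrame([[3.0, 0, 0, 1]], index=["P1"], columns=list("ABCD"))
        assert profile_normalize(means).iloc[0].tolist() == [0.75, 0, 0, 0.25]

    @given(
        arrays(np.float64, (7, 4), elements=st.floats(0, 100, allow_nan=False))
    )
    @settings(max_examples=100, derandomize=True)
    def test_rows_sum_to_one(self, vals):
        means = pd.DataFrame(vals, index=[f"P{i}" for i in range(7)],
                             columns=list("ABCD"))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = profile_normalize(means)
        if len(prof):
            np.testing.assert_allclose(prof.sum(axis=1), 1.0, atol=1e-12)

    def test_all_zero_row_dropped_with_warning(self):
        means = pd.DataFrame([[0.0, 0, 0, 0], [1.0, 1, 1, 1]],
                             index=["P0", "P1"], columns=list("ABCD"))
        with pytest.warns(UserWarning, match="all-zero"):
            prof = profile_normalize(means)
        assert list(prof.index) == ["P1"]


def _blobs(seed=0, n_per=30, spread=0.01):
    rng = np.random.default_rng(seed)
    centers = np.array(
        [[0.7, 0.1, 0.1, 0.1], [0.1, 0.7, 0.1, 0.1], [0.1, 0.1, 0.1, 0.7]]
    )
    rows, labels = [], []
    for i, c in enumerate(centers):
        pts = np.abs(c + rng.normal(0, spread, size=(n_per, 4)))
        pts /= pts.sum(axis=1, keepdims=True)
        rows.append(pts)
        labels += [i] * n_per
    X = np.vstack(rows)
    idx = [f"P{i:03d}" for i in range(len(X))]
    return pd.DataFrame(X, index=idx, columns=list("ABCD")), np.array(labels)


class TestKMeans:
    def test_k1_centroid_is_grand_mean(self):
        prof, _ = _blobs()
        model = kmeans_fit(prof, k=1, seed=0, n_restarts=3)
        np.testing.assert_allclose(
            model.centroids.iloc[0], prof.mean(axis=0), atol=1e-12
        )

    def test_recovers_three_blobs(self):
        prof, labels = _blobs(seed=2)
        model = kmeans_fit(prof, k=3, seed=0, n_restarts=10)
        # each true blob maps to exactly one cluster
        found = {
            tuple(sorted(set(model.assignments[labels == i]))) for i in range(3)
        }
        assert all(len(f) == 1 for f in found)
        assert len({f[0] for f in found}) == 3

    def test_assignments_are_nearest_centroid(self):
        prof, _ = _blobs(seed=4, spread=0.1)
        model = kmeans_fit(prof, k=3, seed=1, n_restarts=5)
        X = model.profiles.to_numpy()
        C = model.centroids.to_numpy()
        d = ((X[:, None, :] - C[None]) ** 2).sum(axis=2)
        np.testing.assert_array_equal(model.assignments.to_numpy(), d.argmin(axis=1))

    def test_more_restarts_never_worse(self):
        prof, _ = _blobs(seed=6, spread=0.15)
        one = kmeans_fit(prof, k=4, seed=3, n_restarts=1).inertia
        many = kmeans_fit(prof, k=4, seed=3, n_restarts=10).inertia
        assert many <= one + 1e-12

    def test_row_order_invariance(self):
        prof, _ = _blobs(seed=5, spread=0.05)
        shuffled = prof.sample(frac=1, random_state=9)
        a = kmeans_fit(prof, k=3, seed=2, n_restarts=5).assignments
        b = kmeans_fit(shuffled, k=3, seed=2, n_restarts=5).assignments
        pd.testing.assert_series_equal(a, b)

    def test_k_exceeding_proteins_rejected(self):
        prof, _ = _blobs(n_per=2)
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_fit(prof, k=10)


class TestClusterProfiles:
    def test_singleton_cluster_mean_is_member(self):
        prof, _ = _blobs(seed=1)
        model = kmeans_fit(prof, k=3, seed=0, n_restarts=5)
        table = cluster_profile_plot_data(model)
        for _, row in table.iterrows():
            members = row["members"].split(";")
            np.testing.assert_allclose(
                row[list("ABCD")].to_numpy(float),
                prof.loc[members].mean(axis=0).to_numpy(),
                atol=1e-12,
            )

    def test_unknown_cluster_id(self):
        prof, _ = _blobs()
        model = kmeans_fit(prof, k=3, seed=0, n_restarts=2)
        with pytest.raises(KeyError):
            cluster_profile_plot_data(model, clusters=[99])
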