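"""Batch metrics: PCA embedding, silhouette, PCR, sample correlation."""

import numpy as np
import pandas as pd
import pytest

from omicsqc import (
    EvaluationConfig,
    FixtureSpec,
    ValidationError,
    assess_batch_effect,
    average_silhouette_width,
    generate_dataset,
    pca_embed,
    principal_component_regression,
    sample_correlation_matrix,
)
from omicsqc.batch import PcaEmbedding
from conftest import make_annotation, make_table


def brute_force_asw(X, labels):
    """Independent silhouette implementation: explicit loops."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    n = len(labels)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    svals = []
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        if same.sum() == 0:
            svals.append(0.0)
            continue
        a = D[i, same].mean()
        b = min(
            D[i, labels == other].mean()
            for other in np.unique(labels)
            if other != labels[i]
        )
        svals.append((b - a) / max(a, b))
    return float(np.mean(svals))


class TestPcaEmbed:
    def test_two_cluster_structure_matches_eigendecomposition(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 12))
        X[:, 6:] += 4.0  # constant offset on half the samples
        t = make_table(X)
        emb = pca_embed(t, EvaluationConfig(n_pca_components=5))
        # oracle: eigendecomposition of the sample covariance of centered data
        C = X - X.mean(axis=1, keepdims=True)
        cov = C.T @ C
        w = np.sort(np.linalg.eigvalsh(cov))[::-1]
        frac = w / w.sum()
        assert np.allclose(emb.variance_fractions, frac[:5], atol=1e-8)
        # PC1 separates the clusters and dominates
        pc1 = emb.coords["PC1"].to_numpy()
        assert (pc1[:6] < pc1[6:].min()).all() or (pc1[:6] > pc1[6:].max()).all()
        assert emb.variance_fractions[0] > emb.variance_fractions[1:].max()

    def test_near_degenerate_table(self):
        rng = np.random.default_rng(2)
        col = rng.normal(size=20)
        X = np.tile(col[:, None], (1, 6)) + rng.normal(scale=1e-9, size=(20, 6))
        emb = pca_embed(make_table(X), EvaluationConfig(n_pca_components=3))
        assert np.abs(emb.coords.to_numpy()).max() < 1e-6

    def test_exactly_degenerate_table_errors(self):
        X = np.tile(np.arange(5.0)[:, None], (1, 4))
        with pytest.raises(ValidationError, match="usable"):
            pca_embed(make_table(X), EvaluationConfig())

    def test_sample_permutation_equivariance(self, dataset, config):
        t = dataset.table
        emb = pca_embed(t, config)
        perm = list(reversed(t.sample_ids))
        emb_p = pca_embed(t.subset_samples(perm), config)
        pd.testing.assert_frame_equal(
            emb_p.coords, emb.coords.loc[perm], atol=1e-8, rtol=0
        )

    def test_too_few_samples(self):
        with pytest.raises(ValidationError, match="3 samples"):
            pca_embed(make_table(np.ones((4, 2))), EvaluationConfig())


class TestSilhouette:
    def test_four_point_hand_computation(self):
        # points 0,1 labeled A and 10,11 labeled B
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = ["A", "A", "B", "B"]
        # outer points: a=1, b=10.5 -> s=9.5/10.5; inner: a=1, b=9.5 -> s=8.5/9.5
        expected = (2 * (9.5 / 10.5) + 2 * (8.5 / 9.5)) / 4
        assert average_silhouette_width(X, y) == pytest.approx(expected, abs=1e-12)
        assert brute_force_asw(X, y) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            n = int(rng.integers(4, 13))
            X = rng.normal(size=(n, int(rng.integers(1, 4))))
            y = rng.choice(["A", "B", "C"][: int(rng.integers(2, 4))], size=n)
            if len(np.unique(y)) < 2:
                continue
            assert average_silhouette_width(X, y) == pytest.approx(
                brute_force_asw(X, y), abs=1e-12
            )

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(4)
        vals = []
        for _ in range(100):
            X = rng.normal(size=(30, 2))
            y = rng.choice(["A", "B"], size=30)
            if len(np.unique(y)) < 2:
                continue
            vals.append(average_silhouette_width(X, y))
        assert abs(np.mean(vals)) < 0.05

    def test_single_level_errors(self):
        with pytest.raises(ValidationError):
            average_silhouette_width(np.zeros((4, 2)), ["A"] * 4)


class TestPcr:
    def _emb(self, scores, fracs):
        coords = pd.DataFrame(
            np.asarray(scores, float),
            columns=[f"PC{i + 1}" for i in range(np.shape(scores)[1])],
        )
        return PcaEmbedding(coords=coords, variance_fractions=np.asarray(fracs, float))

    def test_hand_anova_saturated(self):
        emb = self._emb([[-1], [-1], [-1], [1], [1], [1]], [1.0])
        r2 = principal_component_regression(emb, ["A", "A", "A", "B", "B", "B"])
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_hand_anova_partial(self):
        # PC1 scores {0,2,1,3}: between-SS = 1+1 = 2 over total-SS 5
        emb = self._emb([[0.0], [2.0], [1.0], [3.0]], [1.0])
        r2 = principal_component_regression(emb, ["A", "A", "B", "B"])
        assert r2 == pytest.approx(0.2, abs=1e-12)

    def test_random_grouping_expectation(self):
        # E[R^2] for a random g-level grouping of i.i.d. scores is (g-1)/(n-1)
        rng = np.random.default_rng(5)
        n, g = 60, 3
        vals = []
        for _ in range(400):
            emb = self._emb(rng.normal(size=(n, 1)), [1.0])
            y = rng.choice([f"G{i}" for i in range(g)], size=n)
            if len(np.unique(y)) < g:
                continue
            vals.append(principal_component_regression(emb, y))
        assert np.mean(vals) == pytest.approx((g - 1) / (n - 1), abs=0.01)

    def test_variance_weighting(self):
        # PC1 fully batch-driven (frac 0.6), PC2 independent of batch (frac 0.2)
        emb = self._emb(
            [[-1, 1], [-1, -1], [1, 1], [1, -1]], [0.6, 0.2]
        )
        r2 = principal_component_regression(emb, ["A", "A", "B", "B"], n_top=2)
        assert r2 == pytest.approx(0.6 / 0.8, abs=1e-12)

    def test_label_permutation_invariance(self, dataset, config):
        emb = pca_embed(dataset.table, config)
        batches = dataset.annotation.batches.loc[dataset.table.sample_ids]
        r2 = principal_component_regression(emb, batches)
        renamed = batches.map({"B1": "x", "B2": "y"})
        assert principal_component_regression(emb, renamed) == pytest.approx(r2)


class TestSampleCorrelation:
    def test_duplicate_and_anticorrelated_columns(self):
        col = np.array([1.0, 2, 3, 4, 5])
        t = make_table(np.column_stack([col, col, -col + 6]))
        C = sample_correlation_matrix(t)
        assert C.iloc[0, 1] == pytest.approx(1.0)
        assert C.iloc[0, 2] == pytest.approx(-1.0)

    def test_matches_pairwise_oracle(self, dataset):
        t = dataset.table
        C = sample_correlation_matrix(t)
        rng = np.random.default_rng(6)
        cols = rng.choice(t.n_samples, size=6, replace=False)
        for i in cols[:3]:
            for j in cols[3:]:
                x = t.values.iloc[:, i].to_numpy()
                y = t.values.iloc[:, j].to_numpy()
                ok = ~(np.isnan(x) | np.isnan(y))
                r = np.corrcoef(x[ok], y[ok])[0, 1]
                assert C.iloc[i, j] == pytest.approx(r, abs=1e-12)

    def test_sparse_pair_left_missing(self, caplog):
        vals = np.array(
            [[1.0, np.nan], [2.0, np.nan], [3.0, np.nan], [4.0, 1.0], [5.0, 2.0]]
        )
        with caplog.at_level("WARNING"):
            C = sample_correlation_matrix(make_table(vals))
        assert np.isnan(C.iloc[0, 1])


class TestBatchShiftRecovery:
    def test_injected_shift_monotonicity(self):
        cfg = EvaluationConfig(random_seed=0)
        shifts = [0.0, 0.5, 1.0, 2.0]
        asw_means, pcr_means = [], []
        for delta in shifts:
            asws, pcrs = [], []
            for seed in range(5):
                ds = generate_dataset(
                    FixtureSpec(seed=seed, batch_shift=delta, n_features=100,
                                n_samples=24, n_qc=0, missing_rate=0.0)
                )
                ba = assess_batch_effect(
                    ds.table, ds.annotation.batches, cfg
                )
                asws.append(ba.asw_batch)
                pcrs.append(ba.pcr_batch_r2)
            asw_means.append(np.mean(asws))
            pcr_means.append(np.mean(pcrs))
        assert abs(asw_means[0]) < 0.15 and abs(pcr_means[0]) < 0.15
        assert asw_means == sorted(asw_means)
        assert pcr_means == sorted(pcr_means)
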