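from itertools import combinations
from math import factorial

import numpy as np
import pytest

from methdeg.attribution import (
    AttributionMatrix,
    exact_shapley_attributions,
    export_heatmap_table,
    mean_attribution,
    read_heatmap_table,
    shapley_attributions,
)


def softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def toy_model(W):
    """Callable model: probs = softmax(Z @ W)."""
    return lambda Z: softmax(np.atleast_2d(Z) @ W)


def brute_force_shapley(f, x, baseline):
    """Independent oracle: direct coalition enumeration of the Shapley sum."""
    d = len(x)
    k = f(baseline[None, :]).shape[1]
    out = np.zeros((d, k))
    feats = list(range(d))
    for i in feats:
        rest = [j for j in feats if j != i]
        for r in range(d):
            w = factorial(r) * factorial(d - r - 1) / factorial(d)
            for S in combinations(rest, r):
                z0 = baseline.copy()
                z0[list(S)] = x[list(S)]
                z1 = z0.copy()
                z1[i] = x[i]
                out[i] += w * (f(z1[None, :])[0] - f(z0[None, :])[0])
    return out


@pytest.fixture(scope="module")
def three_feature_toy():
    rng = np.random.default_rng(8)
    W = rng.normal(size=(3, 4))
    f = toy_model(W)
    x = rng.uniform(0, 1, size=3)
    baseline = np.full(3, 0.5)
    return f, x, baseline


class TestSampledEstimator:
    def test_matches_brute_force(self, three_feature_toy):
        f, x, baseline = three_feature_toy
        oracle = brute_force_shapley(f, x, baseline)
        est = shapley_attributions(f, x[None, :], baseline, n_permutations=2048, seed=0)[0]
        assert np.abs(est - oracle).max() <= 0.02

    def test_additivity(self, three_feature_toy):
        f, x, baseline = three_feature_toy
        est = shapley_attributions(f, x[None, :], baseline, n_permutations=512, seed=1)[0]
        gap = f(x[None, :])[0] - f(baseline[None, :])[0]
        np.testing.assert_allclose(est.sum(axis=0), gap, atol=0.02)

    def test_dummy_axiom(self):
        # feature 2 has zero weight everywhere -> zero attribution
        W = np.array([[1.0, -1.0, 0.3], [0.5, 0.2, -0.4], [0.0, 0.0, 0.0]])
        f = toy_model(W)
        x = np.array([0.9, 0.1, 0.7])
        baseline = np.zeros(3)
        est = shapley_attributions(f, x[None, :], baseline, n_permutations=256, seed=2)[0]
        assert np.abs(est[2]).max() < 1e-12

    def test_symmetry_axiom(self):
        # two interchangeable features with identical weights and values
        W = np.array([[1.0, -0.5], [1.0, -0.5]])
        f = toy_model(W)
        x = np.array([0.8, 0.8])
        baseline = np.zeros(2)
        est = shapley_attributions(f, x[None, :], baseline, n_permutations=1024, seed=3)[0]
        np.testing.assert_allclose(est[0], est[1], atol=0.01)

    def test_convergence_with_more_permutations(self, three_feature_toy):
        f, x, baseline = three_feature_toy
        oracle = brute_force_shapley(f, x, baseline)
        errs = []
        for n_perm in (8, 64, 1024):
            est = shapley_attributions(f, x[None, :], baseline,
                                       n_permutations=n_perm, seed=4)[0]
            errs.append(np.abs(est - oracle).max())
        assert errs[2] < errs[0]

    def test_exact_mode_matches_oracle(self, three_feature_toy):
        f, x, baseline = three_feature_toy
        oracle = brute_force_shapley(f, x, baseline)
        exact = exact_shapley_attributions(f, x[None, :], baseline)[0]
        np.testing.assert_allclose(exact, oracle, atol=1e-10)

    def test_validation_errors(self, three_feature_toy):
        f, x, baseline = three_feature_toy
        with pytest.raises(ValueError, match="baseline"):
            shapley_attributions(f, x[None, :], np.zeros(5), n_permutations=4)
        with pytest.raises(ValueError, match="n_permutations"):
            shapley_attributions(f, x[None, :], baseline, n_permutations=0)


class TestMeanAttribution:
    def test_single_sample_identity(self):
        per = np.random.default_rng(0).normal(size=(1, 5, 4))
        m = mean_attribution(per, [f"cg{i}" for i in range(5)])
        np.testing.assert_array_equal(m.values, per[0])

    def test_opposite_samples_cancel(self):
        a = np.random.default_rng(1).normal(size=(5, 4))
        per = np.stack([a, -a])
        m = mean_attribution(per, [f"cg{i}" for i in range(5)])
        np.testing.assert_allclose(m.values, 0.0, atol=1e-15)

    def test_mean_equals_recomputation(self):
        per = np.random.default_rng(2).normal(size=(7, 3, 4))
        m = mean_attribution(per, ["a", "b", "c"])
        np.testing.assert_allclose(m.values, per.mean(axis=0))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_attribution(np.zeros((0, 3, 4)), ["a", "b", "c"])


class TestHeatmapTable:
    @pytest.fixture
    def matrix(self):
        rng = np.random.default_rng(5)
        return mean_attribution(rng.normal(size=(6, 110, 4)),
                                [f"cg{i:05d}" for i in range(110)])

    def test_shape(self, tmp_path, matrix):
        path = export_heatmap_table(matrix, tmp_path / "attr.tsv")
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 111  # header + 110 rows

    def test_round_trip(self, tmp_path, matrix):
        path = export_heatmap_table(matrix, tmp_path / "attr.tsv")
        back = read_heatmap_table(path)
        np.testing.assert_allclose(back.values, matrix.values, atol=1e-6)
        assert back.cpg_ids == matrix.cpg_ids

    def test_top_rank_is_argmax(self, tmp_path, matrix):
        import pandas as pd

        path = export_heatmap_table(matrix, tmp_path / "attr.tsv")
        df = pd.read_csv(path, sep="\t", index_col=0)
        for cls in matrix.classes:
            assert df[f"rank_{cls}"].idxmin() == df[cls].idxmax()

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            AttributionMatrix(np.full((2, 4), np.nan), ["a", "b"],
                              ("c1", "c2", "c3", "c4"), np.zeros(2), 0, 0)
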