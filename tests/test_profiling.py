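"""Normalization, PCA against an eigendecomposition oracle, family
contributions, and hierarchical clustering against brute-force agglomeration."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mitohicp.manifest import default_manifest
from mitohicp.profiling import (
    PcaResult,
    cluster_heatmap,
    pca_embed,
    rank_family_contributions,
    zscore_normalize,
)


class TestZscore:
    def test_constant_column_dropped_and_reported(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        norm, dropped = zscore_normalize(df)
        assert dropped == ["b"]
        assert list(norm.columns) == ["a"]

    def test_hand_formula_population_sd(self):
        norm, _ = zscore_normalize(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        assert norm["a"].tolist() == pytest.approx(
            [-1.2247449, 0.0, 1.2247449], abs=1e-6)

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        once, _ = zscore_normalize(df)
        twice, _ = zscore_normalize(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-9)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            zscore_normalize(pd.DataFrame({"a": [1.0]}))


class TestPca:
    def test_single_feature_explains_everything(self):
        df = pd.DataFrame({"a": [-1.0, 0.0, 1.0]})
        res = pca_embed(df, k=1)
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_collinear_points_align_pc1(self):
        df = pd.DataFrame({"x": [-2.0, -1.0, 1.0, 2.0],
                           "y": [-2.0, -1.0, 1.0, 2.0]})
        res = pca_embed(df, k=2)
        v = res.loadings["PC1"].to_numpy()
        assert np.allclose(np.abs(v), 1 / np.sqrt(2), atol=1e-9)
        assert v[np.argmax(np.abs(v))] > 0  # sign convention
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.normal(size=(6, 4)), columns=list("abcd"))
        res = pca_embed(df, k=4)
        X = df.to_numpy() - df.to_numpy().mean(axis=0)
        cov = X.T @ X / (len(df) - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for c in range(4):
            v = evecs[:, c]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            assert np.allclose(res.loadings.iloc[:, c].to_numpy(), v, atol=1e-8)
            assert np.allclose(res.scores.iloc[:, c].to_numpy(), X @ v, atol=1e-8)
        assert np.allclose(
            res.variance_explained_full, evals / evals.sum(), atol=1e-8)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(rng.normal(size=(8, 5)))
        norm, _ = zscore_normalize(df)
        res = pca_embed(norm, k=5)
        rec = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(rec, norm.to_numpy(), atol=1e-8)

    def test_k_beyond_rank_truncated_with_warning(self):
        df = pd.DataFrame(np.random.default_rng(1).normal(size=(3, 5)))
        with pytest.warns(UserWarning, match="truncating"):
            res = pca_embed(df, k=5)
        assert res.scores.shape[1] == 2

    def test_variance_fractions_sum_to_one(self):
        df = pd.DataFrame(np.random.default_rng(2).normal(size=(10, 4)))
        res = pca_embed(df, k=2)
        assert res.variance_explained_full.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(res.variance_explained_full) <= 1e-12)


class TestFamilyContributions:
    def _profiles(self, rng, signal_family=None, n=40, scale=20.0):
        m = default_manifest().subset(families=["intensity", "shape", "texture"])
        X = rng.normal(size=(n, len(m)))
        df = pd.DataFrame(X, columns=m.names)
        if signal_family:
            cols = m.table.loc[m.table.family == signal_family, "name"]
            latent = rng.normal(size=n)
            for c in cols:
                df[c] += scale * latent
        return df, m

    def test_injected_intensity_signal_ranks_first(self):
        rng = np.random.default_rng(21)
        df, m = self._profiles(rng, signal_family="intensity")
        norm, _ = zscore_normalize(df)
        res = pca_embed(norm, k=2)
        contrib = rank_family_contributions(res, m)
        assert contrib["family"].iloc[0] == "intensity"

    def test_contributions_sum_to_one(self):
        rng = np.random.default_rng(22)
        df, m = self._profiles(rng)
        res = pca_embed(df, k=2)
        contrib = rank_family_contributions(res, m)
        assert contrib["contribution"].sum() == pytest.approx(1.0)

    def test_uniform_loadings_give_size_proportional_shares(self):
        rng = np.random.default_rng(23)
        m = default_manifest()
        # isotropic loadings: shares should track family sizes
        reps = []
        for _ in range(30):
            v = rng.normal(size=(len(m), 2))
            v /= np.linalg.norm(v, axis=0)
            res = PcaResult(
                scores=pd.DataFrame(np.zeros((2, 2)), columns=["PC1", "PC2"]),
                loadings=pd.DataFrame(v, index=m.names, columns=["PC1", "PC2"]),
                variance_explained=np.array([0.5, 0.5]),
                variance_explained_full=np.array([0.5, 0.5]),
                dropped_features=[],
            )
            c = rank_family_contributions(res, m).set_index("family")["contribution"]
            reps.append(c)
        mean_share = pd.concat(reps, axis=1).mean(axis=1)
        sizes = m.family_counts() / len(m)
        for fam in sizes.index:
            assert mean_share[fam] == pytest.approx(sizes[fam], abs=0.02)

    def test_unknown_feature_rejected(self):
        m = default_manifest()
        res = pca_embed(pd.DataFrame(np.random.default_rng(3).normal(size=(4, 2)),
                                     columns=["zzz", "yyy"]), k=2)
        with pytest.raises(ValueError, match="absent"):
            rank_family_contributions(res, m)


def oracle_average_linkage(X, metric="correlation"):
    """Brute-force agglomerative average linkage: at each step merge the
    pair of clusters with the smallest mean pairwise distance."""
    def dist(a, b):
        if metric == "correlation":
            return 1 - np.corrcoef(a, b)[0, 1]
        return float(np.linalg.norm(a - b))

    n = len(X)
    D = {(i, j): dist(X[i], X[j]) for i, j in itertools.combinations(range(n), 2)}
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = min(
            (
                (np.mean([D[tuple(sorted((a, b)))] for a in clusters[ci]
                          for b in clusters[cj]]), ci, cj)
                for ci, cj in itertools.combinations(sorted(clusters), 2)
            ),
            key=lambda t: (t[0], t[1], t[2]),
        )
        h, ci, cj = best
        merges.append((ci, cj, h))
        clusters[next_id] = clusters.pop(ci) + clusters.pop(cj)
        next_id += 1
    return merges


class TestClusterHeatmap:
    def test_identical_rows_merge_first_at_zero(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                           [9.0, 1.0, 4.0], [0.0, 5.0, 5.0]])
        hm = cluster_heatmap(df)
        first = hm["linkage"][0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_merge_sequence_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(31)
        df = pd.DataFrame(rng.normal(size=(4, 3)))
        hm = cluster_heatmap(df)
        oracle = oracle_average_linkage(df.to_numpy())
        for z_row, (ci, cj, h) in zip(hm["linkage"], oracle):
            assert {int(z_row[0]), int(z_row[1])} == {ci, cj}
            assert z_row[2] == pytest.approx(h, abs=1e-10)

    def test_two_blocks_split_at_top(self):
        rng = np.random.default_rng(32)
        base_a = rng.normal(size=6)
        base_b = -base_a
        rows = [base_a + 0.01 * rng.normal(size=6) for _ in range(3)]
        rows += [base_b + 0.01 * rng.normal(size=6) for _ in range(3)]
        hm = cluster_heatmap(pd.DataFrame(rows))
        order = list(hm["order"])
        assert {tuple(sorted(order[:3])), tuple(sorted(order[3:]))} == {
            (0, 1, 2), (3, 4, 5)}

    def test_constant_row_rejected_under_correlation(self):
        df = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="euclidean"):
            cluster_heatmap(df)
        out = cluster_heatmap(df, metric="euclidean")
        assert len(out["linkage"]) == 1
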