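"""PCA against an eigendecomposition oracle; HCA against a naive
average-linkage oracle."""

import numpy as np
import pytest
from scipy.stats import rankdata, spearmanr

import metabodose as md
from metabodose.core_data import TableError
from metabodose.multivariate import Dendrogram

from conftest import make_table


def naive_average_linkage(d):
    """O(n^3) UPGMA on a dissimilarity matrix, scipy cluster numbering:
    merge the closest pair (ties by lowest indices), new cluster distance
    is the size-weighted average of member distances."""
    n = d.shape[0]
    active = {i: [i] for i in range(n)}      # cluster id -> leaf members
    dist = {
        frozenset((i, j)): float(d[i, j])
        for i in range(n) for j in range(i + 1, n)
    }
    merges = []
    next_id = n
    while len(active) > 1:
        best = min(
            dist.items(), key=lambda kv: (kv[1], tuple(sorted(kv[0])))
        )
        (a, b), h = sorted(best[0]), best[1]
        merges.append((a, b, h))
        members = active[a] + active[b]
        na, nb = len(active[a]), len(active[b])
        del active[a], active[b]
        for c in list(active):
            da = dist.pop(frozenset((a, c)))
            db = dist.pop(frozenset((b, c)))
            dist[frozenset((next_id, c))] = (na * da + nb * db) / (na + nb)
        dist.pop(frozenset((a, b)))
        active[next_id] = members
        next_id += 1
    return merges


class TestPca:
    def test_duplicated_samples_rank_one(self):
        values = np.array([[1.0, 2.0, 5.0], [3.0, 1.0, 0.5]])
        table = make_table(np.vstack([values, values]), ["a", "b", "a", "b"])
        result = md.run_pca(table, scaling="center")
        assert result.variance_fraction[0] == pytest.approx(1.0)

    def test_variance_fractions_match_covariance_eigenvalues(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            table = make_table(
                rng.lognormal(1, 0.6, (10, 8)), ["a"] * 5 + ["b"] * 5
            )
            result = md.run_pca(table, scaling="center")
            X = table.data.to_numpy()
            X = X - X.mean(axis=0)
            eig = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
            expected = eig[eig > 1e-12] / eig.sum()
            got = result.variance_fraction[: len(expected)]
            assert np.allclose(got, expected, atol=1e-10)

    def test_variance_fractions_non_increasing_and_bounded(self, preprocessed):
        table, _ = preprocessed
        vf = md.run_pca(table).variance_fraction
        assert (np.diff(vf) <= 1e-12).all()
        assert vf.sum() <= 1 + 1e-9

    def test_scores_orthogonal(self, preprocessed):
        table, _ = preprocessed
        scores = md.run_pca(table).scores.to_numpy()
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(gram)).max()

    def test_deterministic_sign_convention(self, preprocessed):
        table, _ = preprocessed
        result = md.run_pca(table)
        for k in range(result.n_components):
            loadings = result.loadings.iloc[:, k].to_numpy()
            assert loadings[np.argmax(np.abs(loadings))] > 0

    def test_zero_variance_metabolite_named_under_autoscale(self):
        table = make_table(
            [[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]], ["a", "a", "b"],
            ["ok", "flatline"],
        )
        with pytest.raises(TableError, match="flatline"):
            md.run_pca(table, scaling="autoscale")

    def test_planted_separation_along_pc1(self):
        """WT and hom centroids separate along PC1 by more than either
        group's internal spread when dosage effects are planted."""
        table, _ = md.generate(md.SimulationConfig(seed=15, cv=0.1))
        table = md.normalize_tic(table)
        result = md.run_pca(table)
        pc1 = result.scores.iloc[:, 0]
        wt = pc1[table.genotypes.to_numpy() == "WT"]
        hom = pc1[table.genotypes.to_numpy() == "hom"]
        gap = abs(wt.mean() - hom.mean())
        assert gap > max(wt.std(), hom.std())

    def test_het_centroid_between_wt_and_hom(self):
        table, _ = md.generate(md.SimulationConfig(seed=23, cv=0.1))
        table = md.normalize_tic(table)
        pc1 = md.run_pca(table).scores.iloc[:, 0]
        cent = {
            g: pc1[table.genotypes.to_numpy() == g].mean()
            for g in ("WT", "het", "hom")
        }
        lo, hi = sorted([cent["WT"], cent["hom"]])
        assert lo < cent["het"] < hi


class TestHca:
    def test_rank_identical_items_merge_first_at_zero(self):
        table = make_table(
            [[1, 2, 3, 4], [10, 20, 30, 40], [4, 3, 2, 1]],
            ["a", "a", "b"],
        )
        dendrogram = md.cluster_hca(table, axis="samples")
        a, b, h = dendrogram.merges[0]
        assert {a, b} == {0, 1}
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_merges_match_naive_oracle(self):
        rng = np.random.default_rng(33)
        for _ in range(50):
            raw = rng.random((8, 8))
            d = (raw + raw.T) / 2
            np.fill_diagonal(d, 0.0)
            from scipy.cluster import hierarchy
            from scipy.spatial.distance import squareform

            Z = hierarchy.linkage(squareform(d, checks=False),
                                  method="average")
            expected = naive_average_linkage(d)
            for (a, b, h, _), (ea, eb, eh) in zip(Z, expected):
                assert {int(a), int(b)} == {ea, eb}
                assert h == pytest.approx(eh, abs=1e-10)

    def test_pipeline_dendrogram_matches_oracle_on_spearman(self):
        # enough metabolites that pairwise Spearman distances are
        # distinct, so tie-break conventions cannot diverge
        table, _ = md.generate(md.SimulationConfig(seed=3))
        dendrogram = md.cluster_hca(table, axis="samples")
        ranks = np.apply_along_axis(
            rankdata, 1, table.data.to_numpy()
        )
        d = 1 - np.corrcoef(ranks)
        np.fill_diagonal(d, 0.0)
        expected = naive_average_linkage((d + d.T) / 2)
        for (a, b, h), (ea, eb, eh) in zip(dendrogram.merges, expected):
            assert {a, b} == {ea, eb}
            assert h == pytest.approx(eh, abs=1e-10)

    def test_monotone_transform_invariance(self, small_table):
        before = md.cluster_hca(small_table, axis="metabolites")
        transformed = small_table.with_data(np.exp(small_table.data / 50.0))
        after = md.cluster_hca(transformed, axis="metabolites")
        assert before.merges == pytest.approx(after.merges)

    def test_merge_heights_non_decreasing(self, preprocessed):
        table, _ = preprocessed
        heights = [h for _, _, h in md.cluster_hca(table).merges]
        assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))
        assert len(heights) == table.n_samples - 1

    def test_constant_item_named(self):
        table = make_table(
            [[1, 5, 5], [2, 5, 6], [3, 5, 4]], ["a", "b", "c"],
            ["ok", "flat", "ok2"],
        )
        with pytest.raises(TableError, match="flat"):
            md.cluster_hca(table, axis="metabolites")

    def test_spearman_distance_uses_midranks(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        table = make_table(
            np.vstack([x, y, 4.0 - x]), ["a", "b", "c"]
        )
        dendrogram = md.cluster_hca(table, axis="samples")
        rho = spearmanr(x, y).statistic
        assert dendrogram.merges[0][2] == pytest.approx(1 - rho, abs=1e-12)


def test_newick_export_parses_and_preserves_leaves(preprocessed):
    table, _ = preprocessed
    dendrogram = md.cluster_hca(table)
    text = dendrogram.to_newick()
    from io import StringIO

    from Bio import Phylo

    tree = Phylo.read(StringIO(text), "newick")
    leaves = {leaf.name for leaf in tree.get_terminals()}
    assert leaves == set(dendrogram.labels)
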