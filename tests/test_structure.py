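import numpy as np
import pandas as pd
import pytest

from mirqc import correlation_distance, hierarchical_cluster, pca
from mirqc.errors import DomainError, ValidationError

from conftest import make_matrix


def _frame(cols: dict) -> pd.DataFrame:
    n = len(next(iter(cols.values())))
    return pd.DataFrame(cols, index=[f"miR-{i}" for i in range(n)])


class TestCorrelationDistance:
    def test_identical_profiles_have_zero_distance(self):
        x = [25.0, 30.0, 35.0, 28.0]
        d = correlation_distance(make_matrix(_frame({"a": x, "b": list(x)})))
        assert d.at["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_profiles_have_distance_two(self):
        x = np.array([25.0, 30.0, 35.0, 28.0])
        y = (-x + 60).tolist()
        d = correlation_distance(make_matrix(_frame({"a": x.tolist(), "b": y})))
        assert d.at["a", "b"] == pytest.approx(2.0, abs=1e-12)

    def test_independent_profiles_near_one(self):
        rng = np.random.default_rng(11)
        cols = {f"s{i}": rng.uniform(22, 38, 2000).tolist() for i in range(3)}
        d = correlation_distance(make_matrix(_frame(cols)))
        off = d.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0, atol=0.1)

    def test_invariant_under_affine_increasing_rescaling(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(22, 38, 50)
        y = x + rng.normal(0, 1, 50)
        base = correlation_distance(
            make_matrix(_frame({"a": x.tolist(), "b": y.tolist()}))
        ).at["a", "b"]
        scaled = correlation_distance(
            make_matrix(_frame({"a": (0.5 * x + 3).tolist(), "b": y.tolist()}))
        ).at["a", "b"]
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_stratum_filter_restricts_assays(self, clinical_study):
        matrix, _ = clinical_study
        d_all = correlation_distance(matrix)
        d_high = correlation_distance(matrix, stratum_filter="high")
        assert d_all.shape == d_high.shape
        assert not np.allclose(d_all.to_numpy(), d_high.to_numpy())


class TestHierarchicalCluster:
    def _blob_distance(self):
        # two tight blobs: within-distance ~0, between ~1
        labels = ["a1", "a2", "a3", "b1", "b2", "b3"]
        d = np.ones((6, 6))
        d[:3, :3] = 0.01
        d[3:, 3:] = 0.01
        np.fill_diagonal(d, 0.0)
        return pd.DataFrame(d, index=labels, columns=labels)

    def test_cut_at_two_recovers_separated_blobs(self):
        dendro = hierarchical_cluster(self._blob_distance())
        cut = dendro.cut(2)
        assert len(set(cut[:3])) == 1
        assert len(set(cut[3:])) == 1
        assert cut["a1"] != cut["b1"]

    def test_singleton_input_gives_single_leaf(self):
        d = pd.DataFrame([[0.0]], index=["only"], columns=["only"])
        dendro = hierarchical_cluster(d)
        assert dendro.labels == ["only"]
        assert dendro.to_newick().startswith("only")

    def test_deterministic_for_fixed_input(self, clinical_study):
        matrix, _ = clinical_study
        d = correlation_distance(matrix)
        z1 = hierarchical_cluster(d).linkage_matrix
        z2 = hierarchical_cluster(d).linkage_matrix
        assert np.array_equal(z1, z2)

    def test_complete_linkage_heights_monotone(self):
        dendro = hierarchical_cluster(self._blob_distance(), "complete")
        heights = dendro.linkage_matrix[:, 2]
        assert all(a <= b for a, b in zip(heights, heights[1:]))

    def test_newick_contains_all_leaves(self, clinical_study):
        matrix, _ = clinical_study
        d = correlation_distance(matrix)
        newick = hierarchical_cluster(d).to_newick()
        assert newick.endswith(";")
        for cid in matrix.condition_ids:
            assert cid in newick

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame([[0.0, 1.0], [0.5, 0.0]], index=list("ab"),
                         columns=list("ab"))
        with pytest.raises(ValidationError):
            hierarchical_cluster(d)


class TestPCA:
    def test_rank_one_group_shift_loads_on_first_component(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(24, 36, 200)
        cols = {}
        for i in range(3):
            cols[f"g1-{i}"] = base.tolist()
            cols[f"g2-{i}"] = (base + 2.0).tolist()
        res = pca(make_matrix(_frame(cols)), n_components=2)
        assert res.variance_ratio[0] > 0.999
        pc1 = res.scores["PC1"]
        g1 = pc1[[c for c in pc1.index if c.startswith("g1")]]
        g2 = pc1[[c for c in pc1.index if c.startswith("g2")]]
        assert g1.max() < g2.min() or g2.max() < g1.min()

    def test_isotropic_noise_spreads_variance(self):
        rng = np.random.default_rng(6)
        cols = {f"s{i}": rng.normal(30, 1, 4000).tolist() for i in range(5)}
        res = pca(make_matrix(_frame(cols)), n_components=4)
        assert res.variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)
        assert res.variance_ratio.max() < 2.5 * res.variance_ratio.min()

    def test_sign_convention_is_deterministic(self, clinical_study):
        matrix, _ = clinical_study
        a = pca(matrix, n_components=2)
        b = pca(matrix, n_components=2)
        pd.testing.assert_frame_equal(a.scores, b.scores)
        first_loads = a.loadings.iloc[:, 0].to_numpy()
        nz = first_loads[np.abs(first_loads) > 1e-12]
        assert nz[0] > 0

    def test_scores_stable_under_condition_reordering(self, clinical_study):
        matrix, _ = clinical_study
        res = pca(matrix, n_components=2)
        reordered = matrix.subset_conditions(list(reversed(matrix.condition_ids)))
        res2 = pca(reordered, n_components=2)
        for cid in matrix.condition_ids:
            assert np.allclose(
                np.abs(res.scores.loc[cid]), np.abs(res2.scores.loc[cid]),
                atol=1e-8,
            )

    def test_zero_variance_input_raises(self):
        cols = {"a": [25.0, 30.0, 35.0], "b": [25.0, 30.0, 35.0],
                "c": [25.0, 30.0, 35.0]}
        with pytest.raises(DomainError):
            pca(make_matrix(_frame(cols)), n_components=1)

    def test_excessive_components_rejected(self, clinical_study):
        matrix, _ = clinical_study
        with pytest.raises(ValidationError):
            pca(matrix, n_components=len(matrix.conditions))
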