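import numpy as np
import pandas as pd
import pytest

from tempomics import hierarchical_cluster, label_cluster, pca_decompose


def naive_ward_heights(X):
    """Brute-force agglomerative Ward clustering (Lance-Williams update,
    ward.D2 convention: plain Euclidean distances, not squared). Returns the
    sorted sequence of merge heights."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    dist = {
        (i, j): np.linalg.norm(X[i] - X[j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    heights = []
    next_id = n
    while len(active) > 1:
        (i, j), d_ij = min(dist.items(), key=lambda kv: kv[1])
        heights.append(d_ij)
        ni, nj = sizes[i], sizes[j]
        new = {}
        for k in active - {i, j}:
            nk = sizes[k]
            d_ik = dist[tuple(sorted((i, k)))]
            d_jk = dist[tuple(sorted((j, k)))]
            d2 = (
                (ni + nk) * d_ik**2 + (nj + nk) * d_jk**2 - nk * d_ij**2
            ) / (ni + nj + nk)
            new[k] = np.sqrt(d2)
        active -= {i, j}
        dist = {
            (a, b): v
            for (a, b), v in dist.items()
            if a in active and b in active
        }
        for k, v in new.items():
            dist[tuple(sorted((k, next_id)))] = v
        sizes[next_id] = ni + nj
        active.add(next_id)
        next_id += 1
    return np.array(heights)


class TestHierarchicalCluster:
    def test_perfect_separation_two_templates(self):
        a = np.array([0, 1, 2, 1, 0], dtype=float)
        b = np.array([0, -2, -3, -2, -1], dtype=float)
        M = pd.DataFrame(
            [a, a + 1e-3, b, b - 1e-3],
            index=["a1", "a2", "b1", "b2"],
            columns=[0, 30, 60, 120, 240],
        )
        result = hierarchical_cluster(M, k=2)
        assign = result.assignment
        assert assign["a1"] == assign["a2"]
        assert assign["b1"] == assign["b2"]
        assert assign["a1"] != assign["b1"]

    def test_singleton_cut(self):
        rng = np.random.default_rng(1)
        M = pd.DataFrame(rng.normal(size=(5, 4)))
        result = hierarchical_cluster(M, k=5)
        assert sorted(result.assignment) == [1, 2, 3, 4, 5]

    def test_too_many_clusters_rejected(self):
        M = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError):
            hierarchical_cluster(M, k=4)

    def test_missing_entries_rejected(self):
        M = pd.DataFrame([[0.0, np.nan], [1.0, 2.0]], index=["x", "y"])
        with pytest.raises(ValueError, match="x"):
            hierarchical_cluster(M, k=1)

    def test_linkage_heights_match_naive_ward_oracle(self):
        rng = np.random.default_rng(42)
        M = pd.DataFrame(rng.normal(size=(10, 13)))
        result = hierarchical_cluster(M, k=3)
        np.testing.assert_allclose(
            np.sort(result.linkage[:, 2]), np.sort(naive_ward_heights(M)), atol=1e-9
        )

    def test_assignment_invariant_to_input_order(self):
        rng = np.random.default_rng(6)
        M = pd.DataFrame(
            rng.normal(size=(12, 5)), index=[f"m{i}" for i in range(12)]
        )
        perm = rng.permutation(12)
        a = hierarchical_cluster(M, k=4).assignment
        b = hierarchical_cluster(M.iloc[perm], k=4).assignment
        # same partition of molecule ids, regardless of label numbers
        part_a = {}
        part_b = {}
        for mol in M.index:
            part_a.setdefault(a[mol], set()).add(mol)
            part_b.setdefault(b[mol], set()).add(mol)
        assert set(map(frozenset, part_a.values())) == set(
            map(frozenset, part_b.values())
        )


class TestNewickExport:
    def test_tree_parses_with_correct_leaves_and_depth(self):
        from tempomics import linkage_to_newick

        rng = np.random.default_rng(2)
        M = pd.DataFrame(rng.normal(size=(6, 4)), index=[f"m{i}" for i in range(6)])
        result = hierarchical_cluster(M, k=2)
        newick = linkage_to_newick(result.linkage, list(M.index))
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
        assert leaves == sorted(M.index)
        # every leaf sits at the root merge height
        root_height = result.linkage[-1, 2]
        for leaf in tree.leaf_node_iter():
            assert leaf.distance_from_root() == pytest.approx(root_height, rel=1e-6)


class TestLabelCluster:
    @pytest.mark.parametrize(
        "trajectory,expected",
        [
            # peaks at +3.0 then falls to +0.5: large transient increase
            ([0, 1.5, 3.0, 2.0, 0.5], ("large", "transient", "increase")),
            # declines to -2.0 and stays near it: small sustained decrease
            ([0, -1.0, -2.0, -1.9, -1.9], ("small", "sustained", "decrease")),
            # everything inside (-1.5, 1.5): not clear
            ([0, 0.5, 1.0, 0.8, 0.2], ("not_clear", "not_clear", "increase")),
            ([0, -2.0, -3.0, -1.4, -0.5], ("large", "transient", "decrease")),
        ],
    )
    def test_threshold_labels(self, trajectory, expected):
        assert label_cluster(np.asarray(trajectory, dtype=float)) == expected


class TestPCA:
    def test_rank_one_input_single_component(self):
        template = np.array([0.0, 1.0, 2.0, 1.0])
        M = pd.DataFrame(
            np.outer([1.0, 2.0, 3.0, -1.0], template), columns=[0, 30, 60, 120]
        )
        result = pca_decompose(M)
        assert result.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(3)
        M = pd.DataFrame(rng.normal(size=(8, 5)), columns=[0, 30, 60, 120, 240])
        centred = M.to_numpy() - M.to_numpy().mean(axis=0)
        U, s, Vt = np.linalg.svd(centred, full_matrices=False)
        np.testing.assert_allclose((U * s) @ Vt, centred, atol=1e-9)

    def test_scores_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(9)
        M = pd.DataFrame(rng.normal(size=(5, 4)), columns=[0, 30, 90, 240])
        result = pca_decompose(M)
        centred = M.to_numpy() - M.to_numpy().mean(axis=0)
        cov = centred.T @ centred
        eigval, eigvec = np.linalg.eigh(cov)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        evr_oracle = eigval / eigval.sum()
        np.testing.assert_allclose(
            result.explained_variance_ratio, evr_oracle[: len(result.explained_variance_ratio)],
            atol=1e-9,
        )
        proj = centred @ eigvec
        for a in range(min(3, proj.shape[1])):
            got = result.scores.iloc[:, a].to_numpy()
            np.testing.assert_allclose(
                np.abs(got), np.abs(proj[:, a]), atol=1e-9
            )

    def test_explained_variance_non_increasing_and_sums_to_one(self):
        rng = np.random.default_rng(12)
        M = pd.DataFrame(rng.normal(size=(10, 6)), columns=[0, 10, 30, 60, 120, 240])
        evr = pca_decompose(M).explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() == pytest.approx(1.0)

    def test_loadings_are_correlations_in_unit_interval(self):
        rng = np.random.default_rng(30)
        M = pd.DataFrame(rng.normal(size=(12, 5)), columns=[0, 30, 60, 120, 240])
        result = pca_decompose(M)
        loads = result.loadings.to_numpy()
        assert np.nanmax(np.abs(loads)) <= 1 + 1e-12
        # check one loading against a direct correlation
        centred = M.to_numpy() - M.to_numpy().mean(axis=0)
        r = np.corrcoef(result.scores["PC1"], centred[:, 2])[0, 1]
        assert result.loadings.iloc[2, 0] == pytest.approx(r, abs=1e-9)

    def test_sign_convention_pc1_positive_near_90min(self, study_run):
        ds, _, cfg, _ = study_run
        scores = pd.read_csv(f"{cfg.output_dir}/pca_loadings.csv", index_col=0)
        times = scores.index.to_numpy(dtype=float)
        anchor = np.argmin(np.abs(times - 90.0))
        assert scores["PC1"].iloc[anchor] > 0

    def test_degenerate_shapes_rejected(self):
        with pytest.raises(ValueError):
            pca_decompose(pd.DataFrame([[1.0, 2.0]]))
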