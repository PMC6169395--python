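"""Kinship, structure covariates, clustering and differentiation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes

import spudgwas as sg
from spudgwas.panel import PanelError



def _panel(values, ids=None):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return sg.DosagePanel.from_values(
        [f"m{i}" for i in range(m)],
        ids or [f"s{i}" for i in range(n)],
        values,
    )


class TestGowerKinship:
    def test_identical_vectors_give_one(self):
        panel = _panel(np.tile([[1.0], [3.0]], (1, 3)))
        K = sg.gower_kinship(panel)
        assert np.allclose(K.S, 1.0)

    def test_opposite_fixed_vectors_give_zero(self):
        panel = _panel([[0, 4], [0, 4], [0, 4]])
        K = sg.gower_kinship(panel)
        assert K.S[0, 1] == 0.0

    def test_two_marker_example(self):
        panel = _panel([[0, 4], [2, 2]])  # x=[0,2], y=[4,2] -> (0 + 1)/2
        K = sg.gower_kinship(panel)
        assert K.S[0, 1] == pytest.approx(0.5)

    def test_pairwise_complete_with_missing(self):
        panel = _panel([[0, 4], [2, np.nan], [1, 1]])
        K = sg.gower_kinship(panel)
        # only markers 0 and 2 shared: mean(1-4/4, 1-0/4) = 0.5
        assert K.S[0, 1] == pytest.approx(0.5)

    def test_permutation_equivariance(self, sim_small):
        panel = sg.filter_markers(sim_small.panel)
        K = sg.gower_kinship(panel)
        perm = np.random.default_rng(0).permutation(panel.n_samples)
        shuffled = panel.subset_samples([panel.sample_ids[i] for i in perm])
        K2 = sg.gower_kinship(shuffled)
        assert np.allclose(K2.S, K.S[np.ix_(perm, perm)], equal_nan=True)


class TestPcaCovariates:
    def test_identity_relationship_centred_spectrum(self):
        K = sg.RelationshipMatrix(list("abcdef"), np.eye(6))
        cov, vals = sg.pca_covariates(K, n=3)
        # centring removes the constant direction; remaining eigenvalues equal
        assert np.allclose(vals[:-1], 1.0)
        assert np.allclose(cov.Q.T @ cov.Q, np.eye(3), atol=1e-10)

    def test_two_clan_block_matrix_first_axis_separates(self):
        S = np.full((6, 6), 0.2)
        S[:3, :3] = 0.9
        S[3:, 3:] = 0.9
        np.fill_diagonal(S, 1.0)
        K = sg.RelationshipMatrix(list("abcdef"), S)
        cov, vals = sg.pca_covariates(K, n=2)
        v1 = cov.Q[:, 0]
        assert len(set(np.sign(v1[:3]))) == 1
        assert len(set(np.sign(v1[3:]))) == 1
        assert np.sign(v1[0]) != np.sign(v1[3])
        # cross-check against a direct eigendecomposition of the centred matrix
        C = np.eye(6) - np.full((6, 6), 1 / 6)
        w, V = np.linalg.eigh(C @ S @ C)
        assert vals[0] == pytest.approx(w[-1])
        assert abs(np.dot(v1, V[:, -1])) == pytest.approx(1.0, abs=1e-10)

    def test_eigenvalues_sorted_non_increasing(self, sim_small):
        K = sg.gower_kinship(sg.filter_markers(sim_small.panel))
        _, vals = sg.pca_covariates(K, n=5)
        assert np.all(np.diff(vals) <= 1e-10)

    def test_rank_k_reconstruction_eckart_young(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(8, 3))
        S = A @ A.T  # rank 3, PSD
        S = S / np.abs(S).max()
        K = sg.RelationshipMatrix([f"s{i}" for i in range(8)], S)
        cov, vals = sg.pca_covariates(K, n=3, center=False)
        recon = cov.Q @ np.diag(vals[:3]) @ cov.Q.T
        assert np.allclose(recon, S, atol=1e-10)
        # rank-2 truncation error equals the optimal (dropped-eigenvalue) error
        cov2, _ = sg.pca_covariates(K, n=2, center=False)
        recon2 = cov2.Q @ np.diag(vals[:2]) @ cov2.Q.T
        assert np.linalg.norm(recon2 - S) == pytest.approx(abs(vals[2]), rel=1e-8)

    def test_asymmetric_matrix_rejected(self):
        S = np.eye(4)
        S[0, 1] = 0.5
        with pytest.raises(PanelError, match="symmetric"):
            sg.pca_covariates(sg.RelationshipMatrix(list("abcd"), S), n=2)


class TestDissimilarity:
    def test_all_equal_similarity_gives_zero(self):
        K = sg.RelationshipMatrix(list("abc"), np.ones((3, 3)))
        assert np.allclose(sg.similarity_to_dissimilarity(K), 0.0)

    def test_identity_gives_sqrt2_off_diagonal(self):
        K = sg.RelationshipMatrix(list("abc"), np.eye(3))
        D = sg.similarity_to_dissimilarity(K)
        off = D[np.triu_indices(3, 1)]
        assert np.allclose(off, np.sqrt(2))

    def test_triangle_inequality_on_psd_similarities(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            A = rng.normal(size=(8, 8))
            S = A @ A.T
            S = S / np.diag(S).max()
            K = sg.RelationshipMatrix([f"s{i}" for i in range(8)], S)
            D = sg.similarity_to_dissimilarity(K)
            for i, j, k in itertools.permutations(range(8), 3):
                assert D[i, j] <= D[i, k] + D[k, j] + 1e-9

    def test_one_minus_dialect(self):
        K = sg.RelationshipMatrix(list("ab"), np.array([[1.0, 0.25], [0.25, 1.0]]))
        D = sg.similarity_to_dissimilarity(K, kind="one_minus")
        assert D[0, 1] == pytest.approx(0.75)


class TestNmds:
    def test_recovers_planar_configuration(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 2))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        res = sg.nmds(D, k=2)
        assert res.stress < 0.01
        _, _, disparity = procrustes(X, res.configuration)
        assert disparity < 0.01

    def test_stress_non_increasing_in_k(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 4))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        table, _ = sg.nmds_scan(D, k_max=5)
        assert np.all(np.diff(table["stress"]) <= 1e-6)

    def test_degenerate_equal_dissimilarities(self):
        D = np.ones((6, 6)) - np.eye(6)
        r1 = sg.nmds(D, k=1)
        r2 = sg.nmds(D, k=1)
        assert np.isfinite(r1.stress)
        assert r1.stress == r2.stress  # deterministic

    def test_k_too_large_rejected(self):
        D = np.zeros((4, 4))
        with pytest.raises(PanelError):
            sg.nmds(D, k=4)

    def test_scan_suggests_cluster_dimension(self):
        rng = np.random.default_rng(5)
        centers = np.array([[0, 0], [8, 0], [4, 7]], dtype=float)
        X = np.vstack([c + rng.normal(scale=0.4, size=(6, 2)) for c in centers])
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        _, suggestion = sg.nmds_scan(D, k_max=6)
        assert suggestion in (2, 3)

    def test_stress_invariant_to_rigid_motion_of_input(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        D1 = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        X2 = X @ R + 5.0
        D2 = np.sqrt(((X2[:, None, :] - X2[None, :, :]) ** 2).sum(-1))
        assert sg.nmds(D1, 2).stress == pytest.approx(sg.nmds(D2, 2).stress, abs=1e-8)


class TestNeiDistance:
    def test_identical_frequencies_zero(self):
        p = np.array([0.2, 0.7, 0.5])
        assert sg.nei_distance(p, p) == pytest.approx(0.0)

    def test_fixed_alternative_alleles_infinite(self):
        with pytest.warns(UserWarning, match="infinite"):
            d = sg.nei_distance(np.array([1.0]), np.array([0.0]))
        assert np.isinf(d)

    def test_two_locus_hand_computation(self):
        pa = np.array([0.2, 0.8])
        pb = np.array([0.6, 0.4])
        jab = np.mean([0.2 * 0.6 + 0.8 * 0.4, 0.8 * 0.4 + 0.2 * 0.6])
        jaa = np.mean([0.2**2 + 0.8**2, 0.8**2 + 0.2**2])
        jbb = np.mean([0.6**2 + 0.4**2, 0.4**2 + 0.6**2])
        expected = -np.log(jab / np.sqrt(jaa * jbb))
        assert sg.nei_distance(pa, pb) == pytest.approx(expected)


def _ward_d2_oracle(D):
    """Exhaustive greedy Ward (ward.D2 convention) via Lance-Williams."""
    n = D.shape[0]
    d2 = {frozenset((i, j)): D[i, j] ** 2 for i in range(n) for j in range(i + 1, n)}
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    merges, heights = [], []
    nxt = n
    while len(active) > 1:
        best = min(
            ((d2[frozenset((a, b))], a, b) for a, b in itertools.combinations(active, 2)),
            key=lambda t: (t[0], t[1], t[2]),
        )
        val, a, b = best
        merges.append({a, b})
        heights.append(np.sqrt(val))
        na, nb = sizes[a], sizes[b]
        for c in active:
            if c in (a, b):
                continue
            nc = sizes[c]
            new = (
                (na + nc) * d2[frozenset((a, c))]
                + (nb + nc) * d2[frozenset((b, c))]
                - nc * val
            ) / (na + nb + nc)
            d2[frozenset((nxt, c))] = new
        sizes[nxt] = na + nb
        active = [c for c in active if c not in (a, b)] + [nxt]
        nxt += 1
    return merges, heights


class TestHierarchicalClusters:
    def test_two_tight_pairs_merge_first(self):
        pts = np.array([[0.0], [0.1], [10.0], [10.1], [30.0]])
        D = np.abs(pts - pts.T)
        dend = sg.hierarchical_clusters(D)
        first_two = [set(dend.merges[0]), set(dend.merges[1])]
        assert {0, 1} in first_two and {2, 3} in first_two

    def test_matches_exhaustive_greedy_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(5, 3))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        dend = sg.hierarchical_clusters(D)
        merges, heights = _ward_d2_oracle(D)
        for k in range(4):
            assert set(dend.merges[k]) == merges[k]
            assert dend.heights[k] == pytest.approx(heights[k])

    def test_heights_non_decreasing(self, sim_small):
        K = sg.gower_kinship(sg.filter_markers(sim_small.panel))
        D = sg.similarity_to_dissimilarity(K)
        dend = sg.hierarchical_clusters(D, labels=list(K.sample_ids))
        assert np.all(np.diff(dend.heights) >= -1e-12)

    def test_newick_roundtrips_labels(self):
        D = np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], dtype=float)
        dend = sg.hierarchical_clusters(D, labels=["x", "y", "z"])
        nwk = dend.to_newick()
        assert nwk.endswith(";")
        for lab in ("x", "y", "z"):
            assert lab in nwk


class TestFst:
    def test_identical_subpopulations_near_zero(self):
        rng = np.random.default_rng(8)
        block = rng.integers(0, 5, size=(300, 30)).astype(float)
        vals = np.hstack([block, block])
        panel = sg.DosagePanel.from_values(
            [f"m{i}" for i in range(300)], [f"s{i}" for i in range(60)], vals
        )
        assign = {f"s{i}": "A" if i < 30 else "B" for i in range(60)}
        fst = sg.fst_pairwise(panel, assign)
        assert abs(fst.loc["A", "B"]) < 0.02

    def test_alternatively_fixed_subpopulations_are_one(self):
        vals = np.hstack([np.zeros((50, 10)), np.full((50, 10), 4.0)])
        panel = sg.DosagePanel.from_values(
            [f"m{i}" for i in range(50)], [f"s{i}" for i in range(20)], vals
        )
        assign = {f"s{i}": "A" if i < 10 else "B" for i in range(20)}
        fst = sg.fst_pairwise(panel, assign)
        assert fst.loc["A", "B"] == pytest.approx(1.0)

    @pytest.mark.parametrize("target", [0.05, 0.10])
    def test_balding_nichols_recovery(self, target):
        cfg = sg.SimConfig(
            n_founders=200, n_samples=200, n_subpops=2, fst=target, families=[],
            n_chrom=2, markers_per_chrom=1000, seed=17,
        )
        sim = sg.simulate_panel(cfg)
        assign = {s: str(p) for s, p in sim.truth["subpop"].items()}
        fst = sg.fst_pairwise(sim.panel, assign)
        assert fst.iloc[0, 1] == pytest.approx(target, abs=0.02)


def test_zero_shared_markers_pair_reported_missing():
    vals = np.array([[0.0, np.nan], [np.nan, 2.0]])
    panel = sg.DosagePanel.from_values(["m0", "m1"], ["a", "b"], vals)
    with pytest.warns(UserWarning, match="zero shared markers"):
        K = sg.gower_kinship(panel)
    assert np.isnan(K.S[0, 1])
    assert K.S[0, 0] == 1.0 and K.S[1, 1] == 1.0
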