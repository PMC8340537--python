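import numpy as np
import pytest
from scipy.linalg import subspace_angles
from sklearn.base import clone

from ajivekit.ajive import (
    AJIVE,
    ajive,
    extract_individual,
    extract_joint,
    random_direction_bound,
    select_joint_rank,
    stacked_basis_svd,
    truncated_block_svd,
    variance_explained,
    wedin_bound,
)
from ajivekit.blocks import MultiOmicsCollection, OmicsBlock
from ajivekit.preprocess import center_features
from ajivekit.simulate import SyntheticConfig, generate_blocks
from conftest import make_block


def centered_block(values, name="b"):
    v = np.asarray(values, dtype=float)
    return make_block(v - v.mean(axis=1, keepdims=True), name=name)


def collection_of(mats, names=None):
    names = names or [f"block{k + 1}" for k in range(len(mats))]
    blocks = [
        OmicsBlock(
            values=np.asarray(m, dtype=float),
            feature_ids=[f"{nm}f{i}" for i in range(np.asarray(m).shape[0])],
            sample_ids=[f"s{j}" for j in range(np.asarray(m).shape[1])],
            name=nm,
        )
        for m, nm in zip(mats, names)
    ]
    return MultiOmicsCollection(blocks=blocks)


def planted_matrix(rng, p, n, row_basis, scale=1.0):
    """Noiseless matrix whose row space equals span(row_basis)."""
    r = row_basis.shape[1]
    return scale * rng.standard_normal((p, r)) @ row_basis.T


class TestTruncatedBlockSVD:
    def test_exact_rank_two(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((10, 2)) @ rng.standard_normal((2, 8))
        sv = truncated_block_svd(make_block(X), 2)
        approx = (sv.left_basis * sv.singular_values) @ sv.row_basis.T
        assert np.linalg.norm(X - approx) / np.linalg.norm(X) < 1e-12
        assert sv.noise_threshold == pytest.approx(0.0, abs=1e-10)

    def test_noise_threshold_is_next_singular_value(self):
        U = np.eye(3)
        X = U @ np.diag([5.0, 3.0, 1.0]) @ np.eye(3)
        sv = truncated_block_svd(make_block(X), 1)
        assert sv.noise_threshold == pytest.approx(3.0)

    def test_row_basis_orthonormal(self):
        rng = np.random.default_rng(1)
        sv = truncated_block_svd(make_block(rng.standard_normal((20, 15))), 5)
        np.testing.assert_allclose(sv.row_basis.T @ sv.row_basis, np.eye(5), atol=1e-12)

    def test_rank_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            truncated_block_svd(make_block(np.ones((3, 4))), 5)


class TestStackedBasisSVD:
    def test_identical_rank1_bases_reach_two(self):
        rng = np.random.default_rng(2)
        v = np.zeros(10)
        v[0] = 1.0
        basis = v[:, None]
        X1 = planted_matrix(rng, 6, 10, basis)
        X2 = planted_matrix(rng, 8, 10, basis)
        svds = [truncated_block_svd(make_block(X, name=f"b{i}"), 1) for i, X in enumerate((X1, X2))]
        sq, _ = stacked_basis_svd(svds)
        assert sq[0] == pytest.approx(2.0, abs=1e-10)

    @pytest.mark.parametrize("theta_deg,expected_top", [(90.0, 1.0), (60.0, 1.5)])
    def test_principal_angle_identity(self, theta_deg, expected_top):
        # two rank-1 row spaces at angle theta: the Gram matrix of the
        # stacked bases is [[1, cos(theta)], [cos(theta), 1]], so the top
        # squared singular value is 1 + cos(theta)
        rng = np.random.default_rng(3)
        n = 12
        theta = np.radians(theta_deg)
        v1 = np.zeros(n)
        v1[0] = 1.0
        v2 = np.zeros(n)
        v2[0], v2[1] = np.cos(theta), np.sin(theta)
        X1 = planted_matrix(rng, 7, n, v1[:, None])
        X2 = planted_matrix(rng, 9, n, v2[:, None])
        svds = [truncated_block_svd(make_block(X, name=f"b{i}"), 1) for i, X in enumerate((X1, X2))]
        sq, _ = stacked_basis_svd(svds)
        assert sq[0] == pytest.approx(expected_top, abs=1e-10)

    def test_mismatched_samples_rejected(self):
        rng = np.random.default_rng(4)
        s1 = truncated_block_svd(make_block(rng.standard_normal((5, 8)), name="a"), 2)
        s2 = truncated_block_svd(make_block(rng.standard_normal((5, 9)), name="b"), 2)
        with pytest.raises(ValueError, match="samples"):
            stacked_basis_svd([s1, s2])


class TestThresholds:
    def test_wedin_noiseless_equals_K(self):
        rng = np.random.default_rng(5)
        Q, _ = np.linalg.qr(rng.standard_normal((10, 2)))
        svds = [
            truncated_block_svd(make_block(planted_matrix(rng, p, 10, Q), name=f"b{p}"), 2)
            for p in (6, 7, 8)
        ]
        assert wedin_bound(svds, n_resample=50, seed=0) == pytest.approx(3.0, abs=1e-8)

    def test_wedin_noisy_block_lowers_threshold(self):
        rng = np.random.default_rng(6)
        Q, _ = np.linalg.qr(rng.standard_normal((20, 2)))
        clean = planted_matrix(rng, 30, 20, Q)
        noisy = rng.standard_normal((25, 20))  # pure noise block
        svds = [
            truncated_block_svd(make_block(clean, name="clean"), 2),
            truncated_block_svd(make_block(noisy, name="noise"), 2),
        ]
        t = wedin_bound(svds, n_resample=100, seed=1)
        assert t < 1.9

    def test_wedin_deterministic_and_validates(self):
        rng = np.random.default_rng(7)
        svds = [
            truncated_block_svd(make_block(rng.standard_normal((15, 10)), name=f"b{i}"), 3)
            for i in range(2)
        ]
        assert wedin_bound(svds, n_resample=50, seed=3) == wedin_bound(
            svds, n_resample=50, seed=3
        )
        with pytest.raises(ValueError, match="n_resample"):
            wedin_bound(svds, n_resample=1)

    def test_random_direction_near_one_in_high_dim(self):
        # two random directions in high dimension are nearly orthogonal:
        # top squared singular value is 1 + |cos(theta)| = 1 + O(n^{-1/2})
        t = random_direction_bound([1, 1], n=2000, n_draws=100, seed=0)
        assert 1.0 < t < 1.0 + 3.0 / np.sqrt(2000)

    def test_random_direction_forced_overlap_small_n(self):
        t = random_direction_bound([4, 4], n=5, n_draws=100, seed=0)
        assert t > 1.9

    def test_random_direction_deterministic(self):
        a = random_direction_bound([2, 3], n=30, n_draws=50, seed=9)
        b = random_direction_bound([2, 3], n=30, n_draws=50, seed=9)
        assert a == b
        with pytest.raises(ValueError, match="rank"):
            random_direction_bound([5], n=5, n_draws=10)


class TestSelectJointRank:
    def test_counts_exceedances(self):
        assert select_joint_rank(np.array([1.9, 1.2, 0.4]), 1.5, 1.1) == 1

    def test_all_below(self):
        assert select_joint_rank(np.array([1.0, 0.5]), 1.5, 1.2) == 0

    def test_noiseless_tie_escape(self):
        # wedin threshold exactly K: shared directions attain exactly K
        assert select_joint_rank(np.array([2.0, 2.0, 0.9]), 2.0, 1.3) == 2

    def test_rank_cap(self):
        assert select_joint_rank(np.array([1.9, 1.8, 1.7]), 1.0, 1.0, rank_cap=2) == 2


class TestExtraction:
    def test_joint_projection_matches_lstsq_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((12, 10))
        Q, _ = np.linalg.qr(rng.standard_normal((10, 3)))
        (J, loadings), = extract_joint([make_block(X)], Q)
        # oracle: row-wise least-squares projection onto span(Q)
        coefs, *_ = np.linalg.lstsq(Q, X.T, rcond=None)
        np.testing.assert_allclose(J, (Q @ coefs).T, atol=1e-10)
        np.testing.assert_allclose(loadings, X @ Q, atol=1e-12)

    def test_zero_joint_rank_gives_zero_matrices(self):
        X = np.random.default_rng(9).standard_normal((5, 6))
        (J, _), = extract_joint([make_block(X)], np.zeros((6, 0)))
        np.testing.assert_array_equal(J, np.zeros_like(X))

    def test_rows_in_joint_span_projected_exactly(self):
        rng = np.random.default_rng(10)
        Q, _ = np.linalg.qr(rng.standard_normal((8, 2)))
        X = planted_matrix(rng, 5, 8, Q)
        (J, _), = extract_joint([make_block(X)], Q)
        np.testing.assert_allclose(J, X, atol=1e-10)

    def test_individual_rank_by_threshold(self):
        # remainder with singular values (5, 2, 0.5) and threshold 1 -> rank 2
        rng = np.random.default_rng(11)
        U, _ = np.linalg.qr(rng.standard_normal((9, 3)))
        V, _ = np.linalg.qr(rng.standard_normal((7, 3)))
        R = U @ np.diag([5.0, 2.0, 0.5]) @ V.T
        I, r_i, scores, loadings = extract_individual(
            R, np.zeros_like(R), 1.0, np.zeros((7, 0))
        )
        assert r_i == 2
        assert scores.shape == (7, 2) and loadings.shape == (9, 2)
        np.testing.assert_allclose(
            np.linalg.svd(I, compute_uv=False)[:2], [5.0, 2.0], atol=1e-10
        )

    def test_fully_joint_block_has_zero_individual(self):
        rng = np.random.default_rng(12)
        Q, _ = np.linalg.qr(rng.standard_normal((8, 2)))
        X = planted_matrix(rng, 6, 8, Q)
        I, r_i, _, _ = extract_individual(X, X.copy(), 0.0, Q)
        assert r_i == 0
        np.testing.assert_array_equal(I, np.zeros_like(X))


class TestVarianceExplained:
    def test_constructed_split(self):
        # block built as orthogonal joint/individual signals with a 60/40
        # Frobenius-energy split and no noise
        rng = np.random.default_rng(13)
        n = 40
        Q, _ = np.linalg.qr(rng.standard_normal((n, 4)))
        J_basis, I_basis = Q[:, :2], Q[:, 2:]
        Jm = planted_matrix(rng, 30, n, J_basis)
        Im = planted_matrix(rng, 30, n, I_basis)
        Jm *= np.sqrt(0.6) / np.linalg.norm(Jm)
        Im *= np.sqrt(0.4) / np.linalg.norm(Im)
        X = Jm + Im
        other = planted_matrix(rng, 20, n, J_basis)
        coll = collection_of([X, other])
        res = ajive(coll, initial_ranks=[4, 2], seed=0)
        ve = res.variance_explained.loc["block1"]
        assert ve["joint"] == pytest.approx(0.6, abs=0.02)
        assert ve["individual"] == pytest.approx(0.4, abs=0.02)
        assert ve["residual"] == pytest.approx(0.0, abs=0.02)

    def test_zero_norm_block_rejected(self):
        from ajivekit.ajive import BlockDecomposition

        d = BlockDecomposition(
            name="z",
            joint=np.zeros((2, 2)),
            individual=np.zeros((2, 2)),
            residual=np.zeros((2, 2)),
            initial_rank=1,
            individual_rank=0,
            noise_threshold=0.0,
            joint_loadings=np.zeros((2, 0)),
            individual_scores=np.zeros((2, 0)),
            individual_loadings=np.zeros((2, 0)),
        )
        with pytest.raises(ValueError, match="zero norm"):
            variance_explained([d], [make_block(np.zeros((2, 2)), name="z")])


class TestAjiveDegenerateCases:
    def test_identical_noiseless_blocks_fully_joint(self):
        rng = np.random.default_rng(14)
        Q, _ = np.linalg.qr(rng.standard_normal((12, 2)))
        X1 = planted_matrix(rng, 8, 12, Q)
        X2 = planted_matrix(rng, 9, 12, Q)
        res = ajive(collection_of([X1, X2]), initial_ranks=[2, 2], seed=0)
        assert res.joint_rank == 2
        assert res.individual_ranks == [0, 0]
        for b in res.blocks:
            assert np.linalg.norm(b.residual) < 1e-8 * np.linalg.norm(b.joint)

    def test_orthogonal_planted_row_spaces_no_joint(self):
        rng = np.random.default_rng(15)
        n = 20
        Q, _ = np.linalg.qr(rng.standard_normal((n, 5)))
        res = ajive(
            collection_of(
                [planted_matrix(rng, 10, n, Q[:, :2]), planted_matrix(rng, 11, n, Q[:, 2:5])]
            ),
            initial_ranks=[2, 3],
            seed=0,
        )
        assert res.joint_rank == 0
        assert res.individual_ranks == [2, 3]

    def test_single_block_usage_error(self):
        coll = collection_of([np.random.default_rng(16).standard_normal((5, 6))])
        with pytest.raises(ValueError, match="single block"):
            ajive(coll, initial_ranks=[2])

    def test_missing_entries_rejected(self):
        v = np.random.default_rng(17).standard_normal((4, 5))
        v[0, 0] = np.nan
        coll = collection_of([v, np.random.default_rng(18).standard_normal((4, 5))])
        with pytest.raises(ValueError, match="missing"):
            ajive(coll, initial_ranks=[2, 2])


@pytest.fixture(scope="module")
def random_results():
    out = []
    for seed in range(6):
        rng = np.random.default_rng(200 + seed)
        K = int(rng.integers(2, 4))
        n = int(rng.integers(15, 30))
        mats, ranks = [], []
        for k in range(K):
            p = int(rng.integers(8, 40))
            r = int(rng.integers(1, min(p, n) // 2))
            X = rng.standard_normal((p, n))
            X -= X.mean(axis=1, keepdims=True)
            mats.append(X)
            ranks.append(r)
        coll = collection_of(mats)
        out.append((coll, ajive(coll, initial_ranks=ranks, seed=seed)))
    return out


class TestAjiveInvariants:

    def test_reconstruction(self, random_results):
        for coll, res in random_results:
            for b, d in zip(coll.blocks, res.blocks):
                rel = np.linalg.norm(b.values - d.joint - d.individual - d.residual)
                assert rel <= 1e-8 * np.linalg.norm(b.values)

    def test_joint_basis_orthonormal(self, random_results):
        for _, res in random_results:
            V = res.joint.joint_basis
            np.testing.assert_allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-10)

    def test_individual_orthogonal_to_joint(self, random_results):
        for _, res in random_results:
            V = res.joint.joint_basis
            for d in res.blocks:
                if np.linalg.norm(d.individual) > 0 and V.shape[1]:
                    assert (
                        np.linalg.norm(d.individual @ V)
                        < 1e-8 * np.linalg.norm(d.individual)
                    )

    def test_rank_bounds(self, random_results):
        for _, res in random_results:
            r_J = res.joint_rank
            assert r_J <= min(d.initial_rank for d in res.blocks)
            for d in res.blocks:
                assert np.linalg.matrix_rank(d.joint) <= r_J
                assert d.individual_rank <= d.initial_rank

    def test_variance_proportions_sum_to_one(self, random_results):
        for _, res in random_results:
            total = res.variance_explained.sum(axis=1)
            np.testing.assert_allclose(total, 1.0, atol=1e-10)


class TestScaleInsensitivity:
    @pytest.mark.parametrize("c", [1e-3, 1e3])
    def test_joint_basis_invariant_to_block_scaling(self, small_collection, c):
        coll, _ = small_collection
        ranks = [4, 4, 4]
        base = ajive(coll, initial_ranks=ranks, seed=0)
        scaled_blocks = [b for b in coll.blocks]
        scaled = collection_of(
            [coll.blocks[0].values * c] + [b.values for b in coll.blocks[1:]],
            names=[b.name for b in coll.blocks],
        )
        res = ajive(scaled, initial_ranks=ranks, seed=0)
        assert res.joint_rank == base.joint_rank
        ang = subspace_angles(res.joint.joint_basis, base.joint.joint_basis).max()
        assert ang < 1e-6


class TestPermutationEquivariance:
    def test_sample_permutation_permutes_scores(self):
        rng = np.random.default_rng(30)
        coll, _ = generate_blocks(
            SyntheticConfig(
                n_samples=40, block_dims=(80, 50), joint_rank=2, individual_ranks=(1, 1),
                block_scales=(1.0, 1.0), snr=(10.0, 10.0), seed=5,
            )
        )
        blocks = [center_features(b) for b in coll.blocks]
        perm = rng.permutation(40)
        base = ajive(collection_of([b.values for b in blocks]), initial_ranks=[3, 3], seed=0)
        permuted = ajive(
            collection_of([b.values[:, perm] for b in blocks]), initial_ranks=[3, 3], seed=0
        )
        assert permuted.joint_rank == base.joint_rank
        np.testing.assert_allclose(
            permuted.joint.joint_basis, base.joint.joint_basis[perm], atol=1e-8
        )

    def test_block_order_preserves_joint_span(self, small_collection):
        coll, _ = small_collection
        ranks = [4, 4, 4]
        a = ajive(coll, initial_ranks=ranks, seed=0)
        reordered = MultiOmicsCollection(blocks=coll.blocks[::-1])
        b = ajive(reordered, initial_ranks=ranks[::-1], seed=0)
        assert a.joint_rank == b.joint_rank
        ang = subspace_angles(a.joint.joint_basis, b.joint.joint_basis).max()
        assert ang < 1e-6


class TestRecovery:
    def test_synthetic_recovery_single_seed(self):
        coll, truth = generate_blocks(SyntheticConfig(seed=123))
        centered = collection_of(
            [center_features(b).values for b in coll.blocks],
            names=[b.name for b in coll.blocks],
        )
        res = ajive(centered, seed=123)
        assert res.joint_rank == 2
        ang = np.degrees(subspace_angles(res.joint.joint_basis, truth.joint_score_basis).max())
        assert ang < 10.0


class TestEstimatorAPI:
    def test_fit_attributes_and_clone(self):
        rng = np.random.default_rng(40)
        Q, _ = np.linalg.qr(rng.standard_normal((25, 2)))
        Xs = [
            (planted_matrix(rng, 15, 25, Q) + 0.01 * rng.standard_normal((15, 25))).T,
            (planted_matrix(rng, 12, 25, Q) + 0.01 * rng.standard_normal((12, 25))).T,
        ]
        est = AJIVE(initial_ranks=[2, 2], random_state=0)
        cloned = clone(est)
        assert cloned.get_params()["initial_ranks"] == [2, 2]
        est.fit(Xs)
        assert est.joint_rank_ == 2
        assert est.joint_scores_.shape == (25, 2)
        assert len(est.individual_scores_) == 2
        T = est.fit_transform(Xs)
        assert T.shape[0] == 25 and T.shape[1] >= 2

    def test_single_view_rejected(self):
        with pytest.raises(ValueError, match="single view"):
            AJIVE().fit([np.zeros((10, 4))])
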