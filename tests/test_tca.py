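"""Masked nonnegative CP decomposition: fitting, completion, similarity,
clustering, stability, factor shuffling."""

import numpy as np
import pytest

from ringdrift import tca
from ringdrift.preprocess import DffTensor
from ringdrift.tca import MaskedTensor, TCAModel


def planted_model(rng, n=20, t=30, k=15, rank=1):
    W = rng.random((n, rank)) + 0.1
    B = rng.random((t, rank)) + 0.1
    A = rng.random((k, rank)) + 0.1
    return TCAModel(W=W, B=B, A=A)


def full_mask(x):
    return MaskedTensor(values=x, mask=np.ones_like(x))


class TestMask:
    def test_mask_zero_exactly_at_negative_entries(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(4, 6, 5))
        t = DffTensor(values=vals, week_labels=np.zeros(5, dtype=int))
        masked = tca.build_mask(t)
        np.testing.assert_array_equal(masked.mask == 0, vals < 0)
        assert (masked.mask == 0).mean() == (vals < 0).mean()

    def test_all_nonnegative_gives_all_ones(self):
        t = DffTensor(values=np.ones((2, 3, 4)),
                      week_labels=np.zeros(4, dtype=int))
        assert tca.build_mask(t).mask.all()


class TestReconstruct:
    def test_unit_basis_vectors_give_single_entry(self):
        W = np.zeros((4, 1)); W[1] = 1
        B = np.zeros((5, 1)); B[2] = 1
        A = np.zeros((6, 1)); A[3] = 1
        out = tca.reconstruct(TCAModel(W=W, B=B, A=A))
        expected = np.zeros((4, 5, 6))
        expected[1, 2, 3] = 1
        np.testing.assert_array_equal(out, expected)

    def test_component_additivity_and_loop_oracle(self):
        rng = np.random.default_rng(1)
        m2 = planted_model(rng, rank=2)
        m_a = TCAModel(W=m2.W[:, :1], B=m2.B[:, :1], A=m2.A[:, :1])
        m_b = TCAModel(W=m2.W[:, 1:], B=m2.B[:, 1:], A=m2.A[:, 1:])
        np.testing.assert_allclose(
            tca.reconstruct(m2), tca.reconstruct(m_a) + tca.reconstruct(m_b),
            atol=1e-12,
        )
        # brute-force triple loop
        out = tca.reconstruct(m2)
        for n in (0, 3):
            for t in (0, 7):
                for k in (0, 5):
                    manual = sum(
                        m2.W[n, r] * m2.B[t, r] * m2.A[k, r] for r in range(2)
                    )
                    assert out[n, t, k] == pytest.approx(manual, abs=1e-12)


class TestNormalizedError:
    def test_perfect_and_null_reconstruction(self):
        rng = np.random.default_rng(2)
        m = planted_model(rng)
        x = tca.reconstruct(m)
        t = full_mask(x)
        assert tca.normalized_error(t, m) == pytest.approx(0.0, abs=1e-12)
        zero = TCAModel(W=np.zeros_like(m.W), B=m.B, A=m.A)
        assert tca.normalized_error(t, zero) == pytest.approx(1.0)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(3)
        m = planted_model(rng, n=5, t=6, k=4)
        x = rng.random((5, 6, 4))
        mask = (rng.random((5, 6, 4)) > 0.3).astype(float)
        t = MaskedTensor(values=x, mask=mask)
        xhat = tca.reconstruct(m)
        num = den = 0.0
        for n in range(5):
            for tt in range(6):
                for k in range(4):
                    num += mask[n, tt, k] * (x[n, tt, k] - xhat[n, tt, k]) ** 2
                    den += mask[n, tt, k] * x[n, tt, k] ** 2
        assert tca.normalized_error(t, m) == pytest.approx(num / den, abs=1e-12)


class TestFit:
    def test_rank1_planted_recovery(self):
        rng = np.random.default_rng(4)
        truth = planted_model(rng, rank=1)
        x = tca.reconstruct(truth)
        model = tca.fit(full_mask(x), 1, seed=0, max_iter=2000, tol=1e-12)
        assert tca.normalized_error(full_mask(x), model) < 1e-6
        # factors match up to scale: cosine similarity per mode
        for got, want in ((model.W, truth.W), (model.B, truth.B),
                          (model.A, truth.A)):
            cos = float(
                got[:, 0] @ want[:, 0]
                / (np.linalg.norm(got[:, 0]) * np.linalg.norm(want[:, 0]))
            )
            assert cos > 0.999

    def test_all_zero_tensor_flagged_degenerate(self):
        x = np.zeros((4, 5, 6))
        model = tca.fit(full_mask(x), 1, seed=0, max_iter=50)
        assert model.objective == pytest.approx(0.0, abs=1e-20)
        assert model.degenerate

    def test_masked_completion_of_rank1_tensor(self):
        rng = np.random.default_rng(5)
        truth = planted_model(rng, rank=1)
        x = tca.reconstruct(truth)
        holdout = rng.random(x.shape) < 0.2
        t = MaskedTensor(values=x, mask=(~holdout).astype(float))
        model = tca.fit(t, 1, seed=0, max_iter=2000, tol=1e-12)
        xhat = tca.reconstruct(model)
        masked_err = np.sum((x - xhat)[holdout] ** 2) / np.sum(x[holdout] ** 2)
        assert masked_err < 1e-3

    def test_objective_monotone_nonincreasing(self):
        # track the objective across iterations via single-iteration refits
        rng = np.random.default_rng(6)
        x = tca.reconstruct(planted_model(rng, rank=3))
        x += 0.05 * x.std() * rng.random(x.shape)
        t = full_mask(x)
        objs = [
            tca.fit(t, 2, seed=3, max_iter=iters, tol=0, n_restarts=1).objective
            for iters in (1, 3, 10, 30, 100)
        ]
        diffs = np.diff(objs)
        assert np.all(diffs <= 1e-8 * objs[0])

    def test_all_masked_rejected(self):
        t = MaskedTensor(values=np.ones((2, 2, 2)), mask=np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            tca.fit(t, 1)


class TestCrossValidation:
    def test_planted_rank_beats_rank_one(self):
        rng = np.random.default_rng(7)
        truth = planted_model(rng, n=25, t=30, k=20, rank=3)
        x = tca.reconstruct(truth)
        cv = tca.cross_validate(full_mask(x), [1, 3, 5], seed=0, max_iter=500)
        assert cv["test_error"][1] < cv["test_error"][0]
        assert cv["test_error"][2] < cv["test_error"][0]
        # train error non-increasing in rank (tolerance for optimizer noise)
        assert np.all(np.diff(cv["train_error"]) <= 1e-3)

    def test_different_seeds_different_splits(self):
        rng = np.random.default_rng(8)
        x = tca.reconstruct(planted_model(rng, rank=2)) \
            + 0.1 * rng.random((20, 30, 15))
        a = tca.cross_validate(full_mask(x), [2], seed=0, max_iter=100)
        b = tca.cross_validate(full_mask(x), [2], seed=1, max_iter=100)
        assert a["test_error"][0] != b["test_error"][0]
        assert abs(a["test_error"][0] - b["test_error"][0]) < 0.2

    def test_holdout_respects_fiber_coverage(self):
        rng = np.random.default_rng(9)
        mask = np.ones((6, 7, 8))
        holdout = tca.make_holdout_mask((6, 7, 8), mask, 0.5, seed=0)
        train = holdout * mask
        for axis in range(3):
            other = tuple(i for i in range(3) if i != axis)
            assert np.all(train.sum(axis=other) > 0)


class TestSimilarity:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(10)
        m = planted_model(rng, rank=4)
        assert tca.model_similarity(m, m) == pytest.approx(1.0)

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(11)
        m = planted_model(rng, rank=4)
        perm = np.array([2, 0, 3, 1])
        m2 = TCAModel(W=m.W[:, perm], B=m.B[:, perm], A=m.A[:, perm])
        assert tca.model_similarity(m, m2) == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(12)
        m = planted_model(rng, rank=3)
        m2 = TCAModel(W=2.0 * m.W, B=0.5 * m.B, A=3.0 * m.A)
        assert tca.model_similarity(m, m2) == pytest.approx(1.0)

    def test_independent_models_score_low(self):
        rng = np.random.default_rng(13)
        scores = [
            tca.model_similarity(
                planted_model(rng, n=50, t=50, k=50, rank=10),
                planted_model(rng, n=50, t=50, k=50, rank=10),
            )
            for _ in range(5)
        ]
        # random nonnegative factors still share the positive orthant, so
        # the expected cosine is well above 0 but below the matched regime
        assert max(scores) < 0.9


class TestClustering:
    def test_two_planted_groups_recovered(self):
        rng = np.random.default_rng(14)
        K, R = 40, 8
        pattern_a = np.r_[np.ones(20), np.zeros(20)]
        pattern_b = np.r_[np.zeros(20), np.ones(20)]
        A = np.stack(
            [pattern_a + 0.01 * rng.random(K) for _ in range(4)]
            + [pattern_b + 0.01 * rng.random(K) for _ in range(4)], axis=1
        )
        B = rng.random((30, R))
        m = TCAModel(W=rng.random((10, R)), B=B, A=A)
        order, labels = tca.cluster_trial_factors(m, k_clusters=2, seed=0)
        # perfect recovery: components 0-3 in one cluster, 4-7 in the other
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]
        # within each cluster, ordering is by temporal time-to-peak
        peaks = B.argmax(axis=0)
        for cluster in set(labels):
            members = [r for r in order if labels[r] == cluster]
            assert list(peaks[members]) == sorted(peaks[members])

    def test_same_seed_same_labels(self):
        rng = np.random.default_rng(15)
        m = planted_model(rng, rank=6)
        _, l1 = tca.cluster_trial_factors(m, k_clusters=3, seed=5)
        _, l2 = tca.cluster_trial_factors(m, k_clusters=3, seed=5)
        np.testing.assert_array_equal(l1, l2)


class TestTrialFactorStability:
    def test_identical_factors_score_one(self):
        A = np.tile(np.array([1.0, 2.0, 3.0]), (12, 1))
        m = TCAModel(W=np.ones((4, 3)), B=np.ones((5, 3)), A=A)
        within, across = tca.trial_factor_stability(
            m, np.repeat([0, 1], 6))
        assert within == pytest.approx(1.0)
        assert across == pytest.approx(1.0)

    def test_week_specific_orthogonal_patterns(self):
        # trial factors switch to an orthogonal pattern in week 2
        A = np.zeros((12, 4))
        A[:6, :2] = [2.0, 1.0]
        A[6:, 2:] = [1.0, 2.0]
        rng = np.random.default_rng(16)
        A += 0.01 * rng.random(A.shape)
        m = TCAModel(W=np.ones((4, 4)), B=np.ones((5, 4)), A=A)
        within, across = tca.trial_factor_stability(m, np.repeat([0, 1], 6))
        assert within > 0.9
        # across-week pairs compare disjoint patterns: far below within-week
        assert across < within - 0.5

    def test_matches_pair_loop_oracle(self):
        rng = np.random.default_rng(17)
        m = planted_model(rng, k=10, rank=3)
        weeks = np.repeat([0, 1], 5)
        within, across = tca.trial_factor_stability(m, weeks)
        from ringdrift._utils import pearson
        w_pairs, a_pairs = [], []
        for i in range(10):
            for j in range(i + 1, 10):
                c = pearson(m.A[i], m.A[j])
                (w_pairs if weeks[i] == weeks[j] else a_pairs).append(c)
        assert within == pytest.approx(np.mean(w_pairs))
        assert across == pytest.approx(np.mean(a_pairs))


class TestShuffleFactors:
    def test_multisets_and_energy_preserved(self):
        rng = np.random.default_rng(18)
        m = planted_model(rng, rank=3)
        shuf = tca.shuffle_factors(m, seed=0)
        for orig, new in ((m.W, shuf.W), (m.B, shuf.B), (m.A, shuf.A)):
            for r in range(3):
                np.testing.assert_allclose(
                    np.sort(orig[:, r]), np.sort(new[:, r]))
        # per-component reconstruction energy is a product of column norms,
        # all invariant under permutation / circular shift
        for r in range(3):
            orig_energy = (
                np.linalg.norm(m.W[:, r]) * np.linalg.norm(m.B[:, r])
                * np.linalg.norm(m.A[:, r])
            )
            new_energy = (
                np.linalg.norm(shuf.W[:, r]) * np.linalg.norm(shuf.B[:, r])
                * np.linalg.norm(shuf.A[:, r])
            )
            assert new_energy == pytest.approx(orig_energy)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(19)
        m = planted_model(rng, rank=2)
        a = tca.shuffle_factors(m, seed=7)
        b = tca.shuffle_factors(m, seed=7)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.B, b.B)
        np.testing.assert_array_equal(a.A, b.A)


class TestReproducibility:
    def test_two_seeds_agree_on_clean_low_rank_data(self):
        # the fit-to-fit health check: similarity between independent
        # seeded fits on well-posed synthetic data should be close to 1
        rng = np.random.default_rng(20)
        truth = planted_model(rng, n=40, t=50, k=30, rank=4)
        x = tca.reconstruct(truth)
        x += 0.05 * x.std() * rng.random(x.shape)
        t = full_mask(x)
        m1 = tca.fit(t, 4, seed=1, max_iter=800, tol=1e-10, n_restarts=2)
        m2 = tca.fit(t, 4, seed=2, max_iter=800, tol=1e-10, n_restarts=2)
        assert tca.model_similarity(m1, m2) >= 0.95
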