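"""Window feature families against independent brute-force oracles."""

import numpy as np
import pytest

from oracles import (
    brute_cokurt,
    brute_coskew,
    brute_cov,
    brute_error,
    brute_error_full,
    brute_mean,
    random_pileup,
)
from qvmeth.errors import (
    ContextUnencodableError,
    EmptyPileupError,
    InsufficientDepthError,
    LayoutError,
)
from qvmeth.features import (
    ALPHABET,
    FeatureLayout,
    WindowPileup,
    assemble_feature_vector,
    compute_moments,
    encode_context,
    extract_features,
    joint_error_rates,
    mean_qv,
    qv_cokurtosis,
    qv_coskewness,
    qv_covariance,
)

W = 21


def make_pileup(Q, R=None, T=None):
    Q = np.asarray(Q, dtype=float)
    if R is None:
        R = np.full(Q.shape, "A")
    if T is None:
        T = "A" * Q.shape[1]
    return WindowPileup(chrom="c", center=100, strand="+",
                        flank=(Q.shape[1] - 1) // 2, Q=Q, R=R, T=T)


class TestMoments:
    def test_constant_qvs_give_constant_mean(self):
        pile = make_pileup(np.full((4, W), 20.0))
        assert np.array_equal(mean_qv(pile), np.full(W, 20.0))

    def test_single_read_mean_is_identity(self):
        q = np.arange(W, dtype=float).reshape(1, W)
        assert np.array_equal(mean_qv(make_pileup(q)), q[0])

    def test_identical_rows_give_zero_covariance(self):
        q = np.tile(np.arange(W, dtype=float), (3, 1))
        assert np.allclose(qv_covariance(make_pileup(q)), 0.0)

    def test_two_reads_offset_by_two(self):
        # rows differ by +2 everywhere: deviations are ±1, so every
        # V_pq = (1*1 + (-1)(-1)) / (2-1) ... = 2 with divisor n-1
        base = np.linspace(5, 25, W)
        pile = make_pileup(np.vstack([base, base + 2.0]))
        assert np.allclose(qv_covariance(pile), 2.0)

    def test_symmetric_two_point_distribution_has_zero_coskew(self):
        q = np.vstack([np.full(W, 18.0), np.full(W, 22.0)])
        assert np.allclose(qv_coskewness(make_pileup(q)), 0.0)

    def test_constant_column_zeroes_coskew_row_and_col(self):
        rng = np.random.default_rng(1)
        q = rng.integers(1, 40, size=(6, W)).astype(float)
        q[:, 7] = 13.0
        S = qv_coskewness(make_pileup(q))
        assert np.all(S[7, :] == 0.0)
        assert np.all(S[:, 7] == 0.0)

    def test_cokurtosis_diagonal_is_classical_kurtosis(self):
        # two-point symmetric distribution has kurtosis exactly 1 with the
        # population-sigma divisor
        q = np.vstack([np.full(W, 10.0), np.full(W, 30.0)])
        K = qv_cokurtosis(make_pileup(q))
        assert np.allclose(np.diag(K), 1.0)

    def test_empty_and_single_read_errors(self):
        empty = make_pileup(np.empty((0, W)))
        with pytest.raises(EmptyPileupError):
            mean_qv(empty)
        single = make_pileup(np.ones((1, W)))
        with pytest.raises(InsufficientDepthError):
            qv_covariance(single)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_moments_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pile = random_pileup(rng, n=int(rng.integers(2, 31)))
        assert np.allclose(mean_qv(pile), brute_mean(pile.Q), atol=1e-9)
        assert np.allclose(qv_covariance(pile), brute_cov(pile.Q), atol=1e-9)
        assert np.allclose(qv_coskewness(pile), brute_coskew(pile.Q),
                           atol=1e-9)
        assert np.allclose(qv_cokurtosis(pile), brute_cokurt(pile.Q),
                           atol=1e-9)

    def test_qv_shift_invariance(self):
        # adding a constant shifts the mean and leaves co-moments unchanged
        rng = np.random.default_rng(5)
        pile = random_pileup(rng, n=9)
        shifted = make_pileup(pile.Q + 7.0, pile.R, pile.T)
        assert np.allclose(mean_qv(shifted), mean_qv(pile) + 7.0)
        for op in (qv_covariance, qv_coskewness, qv_cokurtosis):
            assert np.allclose(op(shifted), op(pile), atol=1e-9)

    def test_cov_and_cokurt_symmetric(self):
        rng = np.random.default_rng(9)
        pile = random_pileup(rng, n=12)
        V = qv_covariance(pile)
        K = qv_cokurtosis(pile)
        assert np.allclose(V, V.T, atol=1e-9)
        assert np.allclose(K, K.T, atol=1e-9)
        assert np.all(np.diag(V) >= 0)
        assert np.all(K >= 0)


class TestErrorTensor:
    def test_all_reads_match_reference(self):
        T = "ACGT" * 5 + "A"
        R = np.tile(np.array(list(T)), (4, 1))
        pile = make_pileup(np.full((4, W), 20.0), R, T)
        assert np.all(joint_error_rates(pile).E == 0.0)

    def test_single_mismatch_diagonal_entry(self):
        T = "A" * W
        R = np.full((2, W), "A")
        p0 = 4
        R[0, p0] = "C"  # read 1: lone A->C mismatch at p0
        pile = make_pileup(np.full((2, W), 20.0), R, T)
        E = joint_error_rates(pile).E
        c = ALPHABET.index("C")
        assert E[c, c, p0, p0] == 0.5
        # no other error pair exists anywhere
        assert E.sum() == 0.5

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_brute_force_exactly(self, seed):
        rng = np.random.default_rng(seed)
        pile = random_pileup(rng, n=int(rng.integers(2, 31)))
        E = joint_error_rates(pile).E
        assert np.array_equal(E, brute_error(pile.R, pile.T))

    def test_matches_fully_literal_five_loop_oracle(self):
        rng = np.random.default_rng(13)
        pile = random_pileup(rng, n=4)
        E = joint_error_rates(pile).E
        assert np.array_equal(E, brute_error_full(pile.R, pile.T))

    def test_swap_symmetry_and_structural_zeros(self):
        rng = np.random.default_rng(17)
        pile = random_pileup(rng, n=20)
        E = joint_error_rates(pile).E
        assert np.array_equal(E, np.transpose(E, (1, 0, 3, 2)))
        for p, base in enumerate(pile.T):
            assert np.all(E[ALPHABET.index(base), :, p, :] == 0.0)
            assert np.all(E[:, ALPHABET.index(base), :, p] == 0.0)

    def test_mass_bound_per_position_pair(self):
        rng = np.random.default_rng(21)
        pile = random_pileup(rng, n=25, match_prob=0.3)
        E = joint_error_rates(pile).E
        assert np.all(E.sum(axis=(0, 1)) <= 1.0 + 1e-12)


class TestContextEncoding:
    def test_all_a_gives_zeros(self):
        assert np.all(encode_context("A" * W) == 0)

    def test_all_t_gives_ones(self):
        assert np.all(encode_context("T" * W) == 1)

    def test_cyclic_acgt(self):
        bits = encode_context(("ACGT" * 6)[:W])
        assert list(bits[:8]) == [0, 0, 0, 1, 1, 0, 1, 1]
        assert len(bits) == 42

    def test_non_acgt_raises(self):
        with pytest.raises(ContextUnencodableError):
            encode_context("A" * 10 + "N" + "A" * 10)


class TestLayout:
    def test_default_total_length(self):
        layout = FeatureLayout()
        assert layout.total_length == 21 + 3 * 441 + 11025 + 42 == 12411

    def test_zero_inputs_give_zero_vector(self):
        from qvmeth.features import ErrorTensor, WindowMoments

        z = np.zeros((W, W))
        moments = WindowMoments(np.zeros(W), z, z.copy(), z.copy(),
                                np.zeros(W))
        tensor = ErrorTensor(np.zeros((5, 5, W, W)))
        fv = assemble_feature_vector(moments, tensor, np.zeros(2 * W))
        assert fv.values.shape == (12411,)
        assert np.all(fv.values == 0)

    def test_sentinel_positions(self):
        from qvmeth.features import ErrorTensor, WindowMoments

        z = np.zeros((W, W))
        cov = z.copy()
        cov[0, 1] = 7.0
        E = np.zeros((5, 5, W, W))
        E[1, 0, 0, 0] = 3.0
        moments = WindowMoments(np.zeros(W), cov, z.copy(), z.copy(),
                                np.zeros(W))
        fv = assemble_feature_vector(moments, ErrorTensor(E), np.zeros(2 * W))
        assert fv.values[21 + 0 * 21 + 1] == 7.0  # cov (p=0, q=1) -> 22
        assert fv.values[21 + 3 * 441 + 1 * (5 * 21 * 21)] == 3.0  # -> 3549

    def test_shape_mismatch_raises(self):
        from qvmeth.features import ErrorTensor, WindowMoments

        z = np.zeros((W, W))
        moments = WindowMoments(np.zeros(W - 1), z, z.copy(), z.copy(),
                                np.zeros(W))
        with pytest.raises(LayoutError):
            assemble_feature_vector(
                moments, ErrorTensor(np.zeros((5, 5, W, W))), np.zeros(2 * W)
            )

    def test_extract_features_end_to_end(self):
        rng = np.random.default_rng(23)
        pile = random_pileup(rng, n=8)
        fv = extract_features(pile)
        layout = FeatureLayout()
        assert fv.values.shape == (layout.total_length,)
        mom = compute_moments(pile)
        assert np.array_equal(fv.values[layout.segment_slice("mean")],
                              mom.mean)
        assert np.array_equal(
            fv.values[layout.segment_slice("context")],
            encode_context(pile.T).astype(float),
        )
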