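"""Affiliation matrices, binarization, coaffiliation, and exposure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from affilex import (
    EmptyNetworkError,
    affiliation_exposure,
    binarize,
    build_count_matrix,
    coaffiliation,
)
from affilex.network import AffiliationMatrix
from affilex.vocab import PUSH_IN, SpeechAct, Theme, speech_act_order

from conftest import msg


def exposure_oracle(C, y):
    """Naive double-loop computation of F_i = sum_j C_ij y_j / sum_j C_ij."""
    n = len(y)
    F = np.zeros(n)
    for i in range(n):
        num = den = 0.0
        for j in range(n):
            if j != i:
                num += C[i, j] * y[j]
                den += C[i, j]
        F[i] = num / den if den > 0 else 0.0
    return F


def coaff_oracle(A):
    """Pairwise shared-affiliation counts by explicit double loop."""
    n = A.shape[0]
    C = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            C[i, j] = int(sum(A[i, k] and A[j, k] for k in range(A.shape[1])))
    return C


class TestCountMatrix:
    def test_theme_rows_and_column_order(self, toy_corpus):
        m = build_count_matrix(toy_corpus, Theme.OBSTACLES)
        assert m.users == ["u1", "u3"]  # u2 has no obstacles message
        df = m.counts_frame()
        assert df.loc["u1", "assertion"] == 2
        assert df.loc["u3", "assertion"] == 1 and df.loc["u3", "stance"] == 1
        assert [a.value for a in m.speech_acts] == [a.value for a in SpeechAct]

    def test_multi_theme_message_feeds_both_matrices(self):
        corpus = [msg("m1", "u1", themes=["obstacles", "progress"], acts=["question"])]
        for theme in (Theme.OBSTACLES, Theme.PROGRESS):
            m = build_count_matrix(corpus, theme)
            assert m.counts_frame().loc["u1", "question"] == 1

    def test_style_subset_restricts_columns_but_not_users(self, toy_corpus):
        corpus = toy_corpus + [msg("m5", "u4", themes=["obstacles"], acts=["question"])]
        m = build_count_matrix(corpus, Theme.OBSTACLES, sa_subset=PUSH_IN)
        assert set(m.users) == {"u1", "u3", "u4"}
        assert len(m.speech_acts) == 5
        # u4 only used an interactive act: present with an all-zero row
        assert m.counts_frame().loc["u4"].sum() == 0

    def test_empty_theme_raises(self, toy_corpus):
        with pytest.raises(EmptyNetworkError, match="pharmacotherapy"):
            build_count_matrix(toy_corpus, Theme.PHARMACOTHERAPY)


class TestBinarize:
    def test_median_of_positive_counts(self):
        m = AffiliationMatrix(
            theme=Theme.OBSTACLES,
            users=["a", "b"],
            speech_acts=speech_act_order(PUSH_IN)[:2],
            counts=np.array([[0, 1], [2, 5]]),
        )
        binarize(m)
        assert m.threshold == 2.0  # median of (1, 2, 5)
        assert m.binary.tolist() == [[0, 0], [1, 1]]

    def test_uniform_positive_counts_all_become_one(self):
        m = AffiliationMatrix(
            theme=Theme.PROGRESS, users=["a", "b"],
            speech_acts=speech_act_order(PUSH_IN)[:2],
            counts=np.array([[3, 0], [3, 3]]),
        )
        binarize(m)
        assert m.binary.tolist() == [[1, 0], [1, 1]]

    def test_all_zero_matrix_raises(self):
        m = AffiliationMatrix(
            theme=Theme.PROGRESS, users=["a"],
            speech_acts=speech_act_order(PUSH_IN)[:2],
            counts=np.zeros((1, 2), dtype=int),
        )
        with pytest.raises(EmptyNetworkError):
            binarize(m)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_doubling_counts_never_clears_affiliation(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 6, size=(5, 4))
        if counts.max() == 0:
            counts[0, 0] = 1
        acts = speech_act_order()[:4]

        def bin_of(c):
            m = AffiliationMatrix(
                theme=Theme.PROGRESS, users=list("abcde"),
                speech_acts=acts, counts=c,
            )
            return binarize(m).binary

        before, after = bin_of(counts), bin_of(2 * counts)
        assert np.all(after >= before)


class TestCoaffiliation:
    def test_hand_multiplication(self):
        m = AffiliationMatrix(
            theme=Theme.OBSTACLES, users=["a", "b", "c"],
            speech_acts=speech_act_order(PUSH_IN)[:2],
            counts=np.array([[1, 0], [0, 1], [1, 1]]),
            binary=np.array([[1, 0], [0, 1], [1, 1]]),
        )
        co = coaffiliation(m)
        assert co.C.tolist() == [[1, 0, 1], [0, 1, 1], [1, 1, 2]]
        assert co.D.tolist() == [1, 1, 2]

    def test_zero_row_user_is_isolate(self):
        m = AffiliationMatrix(
            theme=Theme.OBSTACLES, users=["a", "b"],
            speech_acts=speech_act_order(PUSH_IN)[:2],
            counts=np.array([[0, 0], [1, 1]]),
            binary=np.array([[0, 0], [1, 1]]),
        )
        co = coaffiliation(m)
        assert co.D[0] == 0 and co.isolates()[0]
        # b shares no act with anyone either: nonzero diagonal, still an isolate
        assert co.D[1] == 2 and co.isolates()[1]
        assert co.C[0].tolist() == [0, 0]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_double_loop_and_invariants(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.integers(0, 2, size=(6, 5))
        m = AffiliationMatrix(
            theme=Theme.PROGRESS, users=[f"u{i}" for i in range(6)],
            speech_acts=speech_act_order()[:5], counts=A, binary=A,
        )
        C = coaffiliation(m).C
        assert np.array_equal(C, coaff_oracle(A))
        assert np.array_equal(C, C.T)
        assert np.all(np.diag(C) == A.sum(axis=1))
        mins = np.minimum.outer(np.diag(C), np.diag(C))
        assert np.all(C <= mins) and np.all(C >= 0)


class TestExposure:
    C = np.array([[1, 0, 1], [0, 1, 1], [1, 1, 2]])

    def test_hand_example(self):
        F = affiliation_exposure(self.C, np.array([10.0, 20.0, 30.0]))
        assert F.tolist() == [30.0, 30.0, 15.0]

    def test_constant_attribute_gives_constant_exposure(self):
        F = affiliation_exposure(self.C, np.full(3, 7.0))
        assert np.allclose(F, 7.0)

    def test_isolate_gets_zero_or_nan(self):
        C = np.diag([3, 2, 1])  # only diagonal: everyone isolated
        y = np.array([1.0, 2.0, 3.0])
        assert affiliation_exposure(C, y).eq(0).all()
        assert affiliation_exposure(C, y, isolate_policy="nan").isna().all()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 15))
        A = rng.integers(0, 2, size=(n, 6))
        C = A @ A.T
        y = rng.normal(size=n) * 10
        F = affiliation_exposure(C, y).to_numpy()
        assert np.max(np.abs(F - exposure_oracle(C, y))) < 1e-12

    def test_invariant_to_user_permutation(self, rng):
        A = rng.integers(0, 2, size=(8, 5))
        C = A @ A.T
        y = rng.normal(size=8)
        perm = rng.permutation(8)
        F = affiliation_exposure(C, y).to_numpy()
        Fp = affiliation_exposure(C[np.ix_(perm, perm)], y[perm]).to_numpy()
        assert np.allclose(F[perm], Fp)

    def test_invariant_to_offdiagonal_scaling(self, rng):
        A = rng.integers(0, 2, size=(8, 5))
        C = (A @ A.T).astype(float)
        y = rng.normal(size=8)
        scaled = C.copy()
        off = ~np.eye(8, dtype=bool)
        scaled[off] *= 17.0
        assert np.allclose(
            affiliation_exposure(C, y), affiliation_exposure(scaled, y)
        )

    def test_misaligned_user_order_rejected(self):
        from affilex.network import CoaffiliationMatrix

        co = CoaffiliationMatrix(users=["a", "b"], C=np.eye(2, dtype=int))
        y = pd.Series([1.0, 2.0], index=["b", "a"])
        with pytest.raises(ValueError, match="order"):
            affiliation_exposure(co, y)
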