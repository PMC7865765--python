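import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from popmatch import (
    DEFAULT_ADJUSTMENT,
    NormalizedProfile,
    WeightVector,
    combined_score,
    pairwise_matrix,
    similarity_score,
)
from popmatch.profiles import ProfileValidationError

from conftest import random_normalized


def scalar_reference(c, p, w, a, strict=False):
    """Independent term-by-term evaluation of the similarity formula."""
    denom = sum(
        (wj * (cj + pj + a) if not strict else (cj + pj + a))
        for cj, pj, wj in zip(c, p, w)
    )
    s = 0.0
    for ci, pi, wi in zip(c, p, w):
        prefactor = wi * (ci + pi + a) / denom
        agreement = 2.0 / (1.0 + abs(ci - pi)) - 1.0
        s += prefactor * agreement
    return s


normalized_vec = arrays(
    float, st.integers(2, 25),
    elements=st.floats(0.0, 1.0, allow_nan=False, width=64),
)


class TestSimilarityScore:
    def test_self_similarity_is_one(self, rng):
        for _ in range(20):
            v = random_normalized(rng)
            assert similarity_score(v, v) == pytest.approx(1.0, abs=1e-9)

    def test_self_similarity_is_one_under_focus_weights(self, rng):
        v = random_normalized(rng, 10)
        w = np.array([1, 0, 1, 0, 0, 1, 1, 0, 0, 1], dtype=float)
        assert similarity_score(v, v, w) == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_support_scores_zero(self):
        c = np.array([1.0, 0.0])
        p = np.array([0.0, 1.0])
        assert similarity_score(c, p) == pytest.approx(0.0, abs=1e-12)
        assert similarity_score(c, p, adjustment=5.0) == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_example(self):
        # c=(1, 0.5), p=(1, 0), unit weights, a=0.2566:
        # term 1: (2.2566/3.0132)*1, term 2: (0.7566/3.0132)*(1/3)
        expected = 2.2566 / 3.0132 + 0.7566 / 3.0132 / 3.0
        s = similarity_score(np.array([1.0, 0.5]), np.array([1.0, 0.0]))
        assert s == pytest.approx(expected, abs=1e-12)
        assert s == pytest.approx(0.8326, abs=5e-5)

    def test_all_censored_pair_scores_one(self):
        z = np.zeros(20)
        assert similarity_score(z, z) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_exact(self, rng):
        for _ in range(50):
            c, p = random_normalized(rng), random_normalized(rng)
            w = rng.uniform(0, 2, c.size)
            w[0] = 1.0
            assert similarity_score(c, p, w) == similarity_score(p, c, w)

    def test_matches_scalar_reference_loop(self, rng):
        for strict in (False, True):
            for _ in range(1000):
                n = int(rng.integers(2, 25))
                c, p = random_normalized(rng, n), random_normalized(rng, n)
                # strict (unweighted-denominator) mode is only bounded for
                # weights in [0, 1]
                w = rng.uniform(0, 1 if strict else 2, n)
                w[int(rng.integers(n))] = 1.0
                a = float(rng.uniform(0.01, 1.0))
                got = similarity_score(c, p, w, a, strict_denominator=strict)
                want = scalar_reference(c, p, w, a, strict)
                assert got == pytest.approx(want, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_bounds_hold_for_arbitrary_normalized_pairs(self, data):
        c = data.draw(normalized_vec)
        p = data.draw(
            arrays(float, c.size, elements=st.floats(0.0, 1.0, width=64))
        )
        s = similarity_score(c, p)
        assert 0.0 <= s <= 1.0

    def test_agreement_term_monotone_in_congener_difference(self):
        # with other congeners fixed, widening |c_i - p_i| never raises the score
        base = np.array([0.5, 0.5, 0.5])
        p = base.copy()
        prev = similarity_score(base, p)
        for delta in np.linspace(0.05, 0.5, 10):
            p2 = base.copy()
            p2[1] = 0.5 + delta
            s = similarity_score(base, p2)
            assert s <= prev + 1e-12
            prev = s

    def test_strict_denominator_caps_downweighted_self_similarity(self, rng):
        v = random_normalized(rng, 6)
        w = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        assert similarity_score(v, v, w, strict_denominator=True) < 1.0

    def test_validation_errors(self, rng):
        v = random_normalized(rng, 4)
        with pytest.raises(ProfileValidationError, match="zero"):
            similarity_score(v, v, np.zeros(4))
        with pytest.raises(ProfileValidationError, match=r"\[0, 1\]"):
            similarity_score(v, np.array([0.0, 0.5, 1.0, 1.5]))
        a = NormalizedProfile("a", ["X", "Y"], np.array([1.0, 0.0]))
        b = NormalizedProfile("b", ["Y", "X"], np.array([1.0, 0.0]))
        with pytest.raises(ProfileValidationError, match="order mismatch"):
            similarity_score(a, b)

    def test_weight_vector_resolved_by_congener_name(self):
        a = NormalizedProfile("a", ["X", "Y"], np.array([1.0, 0.2]))
        b = NormalizedProfile("b", ["X", "Y"], np.array([1.0, 0.9]))
        w = WeightVector({"Y": 0.0})
        # congener Y ignored -> only the perfectly matching X counts
        assert similarity_score(a, b, w) == pytest.approx(1.0, abs=1e-9)


class TestCombinedScore:
    def test_convex_combination_of_equal_scores_is_identity(self):
        assert combined_score(1.0, 1.0, 0.6, 0.4) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        assert combined_score(0.5, 1.0, 0.6, 0.4) == pytest.approx(0.7, abs=1e-12)

    def test_weights_are_normalized_to_sum_one(self):
        assert combined_score(0.5, 1.0, 6.0, 4.0) == pytest.approx(0.7, abs=1e-12)

    def test_negative_weight_rejected(self):
        with pytest.raises(ProfileValidationError):
            combined_score(0.5, 0.5, -0.1, 1.0)
        with pytest.raises(ProfileValidationError):
            combined_score(0.5, 0.5, 0.0, 0.0)


class TestPairwiseMatrix:
    @staticmethod
    def _norm(sid, values):
        return NormalizedProfile(sid, [f"C{i}" for i in range(len(values))],
                                 np.asarray(values, dtype=float))

    def test_identical_profiles_give_all_ones(self):
        p = self._norm("a", [1.0, 0.5, 0.0])
        q = self._norm("b", [1.0, 0.5, 0.0])
        m = pairwise_matrix([p, q])
        np.testing.assert_allclose(m.values, 1.0, atol=1e-12)

    def test_symmetric_unit_diagonal_bounded(self, rng):
        profs = [self._norm(f"s{i}", random_normalized(rng, 8)) for i in range(6)]
        m = pairwise_matrix(profs).values
        np.testing.assert_allclose(m, m.T, atol=0)
        np.testing.assert_allclose(np.diag(m), 1.0, atol=0)
        assert ((m >= 0) & (m <= 1 + 1e-12)).all()

    def test_fully_censored_pair_scores_one_off_diagonal(self):
        z1 = self._norm("low1", np.zeros(20))
        z2 = self._norm("low2", np.zeros(20))
        m = pairwise_matrix([z1, z2])
        assert m.loc["low1", "low2"] == pytest.approx(1.0, abs=1e-12)
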