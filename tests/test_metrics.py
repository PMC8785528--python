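"""Unit and property tests for the per-marker accuracy indices."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as npst

from iamhiq import metrics as m
from conftest import naive_marker, random_probs

# Q and Iam_chance by MAF: (f, Q_HWE at its printed precision, printed
# decimals, Iam_chance at its printed precision)
TABULATED_MAF = [
    (0.5, 0.625, 3, 0.0625),
    (0.4, 0.614, 3, 0.0784),
    (0.3, 0.575, 3, 0.1369),
    (0.2, 0.486, 3, 0.2704),
    (0.1, 0.311, 3, 0.5329),
    (0.05, 0.176, 3, 0.7353),
    (0.01, 0.039, 3, 0.9415),
    (0.001, 0.0040, 4, 0.9940),
    (0.0001, 0.0004, 4, 0.9994),
    (0.00001, 0.00004, 5, 0.9999),
    (0.000001, 0.000004, 6, 1.0000),
]


def normalized_triplets(n_min=1, n_max=40):
    return npst.arrays(
        float,
        st.tuples(st.integers(n_min, n_max), st.just(3)),
        elements=st.floats(1e-6, 1.0),
    ).map(lambda p: p / p.sum(axis=1, keepdims=True))


class TestAlleleFrequency:
    @pytest.mark.parametrize(
        "probs,expected",
        [
            ([[1, 0, 0]] * 4, 0.0),
            ([[0, 0, 1]] * 4, 1.0),
            ([[1, 0, 0], [0, 1, 0], [0, 0, 1]], 0.5),  # (0+1+2)/(2*3)
        ],
    )
    def test_known_values(self, probs, expected):
        assert m.estimate_allele_freq(np.array(probs, float)) == pytest.approx(expected)

    def test_missing_rows_excluded(self):
        probs = np.array([[0, 0, 1], [0, 0, 0], [0, 0, 1]], float)
        assert m.estimate_allele_freq(probs) == 1.0

    def test_all_missing_raises(self):
        with pytest.raises(ValueError, match="usable"):
            m.estimate_allele_freq(np.zeros((3, 3)))


class TestAntiConcentration:
    @pytest.mark.parametrize(
        "triplet,expected",
        [
            ((1, 0, 0), 0.0),
            ((1 / 3, 1 / 3, 1 / 3), 2 / 3),
            ((0.5, 0.5, 0), 0.5),
        ],
    )
    def test_known_values(self, triplet, expected):
        assert m.anti_concentration(triplet) == pytest.approx(expected, abs=1e-12)

    @given(normalized_triplets(n_min=1, n_max=1))
    @settings(derandomize=True, max_examples=50)
    def test_two_forms_agree(self, probs):
        """Σp(1−p) equals 1 − Σp² on normalized triplets."""
        t = probs[0]
        assert m.anti_concentration(t) == pytest.approx(
            1.0 - float((t**2).sum()), abs=1e-12
        )


class TestHweAnchor:
    @pytest.mark.parametrize("f,q_printed,ndp,iam_printed", TABULATED_MAF)
    def test_tabulated_maf_grid(self, f, q_printed, ndp, iam_printed):
        """Closed form reproduces the reference grid at printed precision."""
        q = m.q_hwe(f)
        assert round(q, ndp) == pytest.approx(q_printed, abs=10 ** -(ndp + 6))
        assert round(m.iam_chance(q), 4) == pytest.approx(iam_printed, abs=1e-9)

    def test_boundaries_and_symmetry(self):
        assert m.q_hwe(0.0) == 0.0
        assert m.q_hwe(1.0) == 0.0
        f = np.linspace(0, 1, 11)
        np.testing.assert_allclose(m.q_hwe(f), m.q_hwe(1 - f), atol=1e-15)
        assert m.q_hwe(0.5) == pytest.approx(0.625)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            m.q_hwe(-0.1)
        with pytest.raises(ValueError):
            m.q_hwe(1.5)


class TestIamRescalings:
    def test_iam_chance_endpoints(self):
        assert m.iam_chance(0.0) == 1.0
        assert m.iam_chance(2 / 3) == 0.0
        with pytest.raises(ValueError):
            m.iam_chance(0.7)

    def test_iam_hwe_values(self):
        assert m.iam_hwe(0.0, 0.3) == 1.0
        assert m.iam_hwe(m.q_hwe(0.3), 0.3) == pytest.approx(0.0, abs=1e-12)
        assert math.isnan(m.iam_hwe(0.1, 0.0))  # degenerate anchor
        # flatter than the HWE anchor -> negative, returned as-is
        assert m.iam_hwe(0.5, 0.01) < 0


class TestHiq:
    def test_worked_example_homogeneous(self):
        """Ten identical (0.6,0.3,0.1) triplets: hiQ = 1 − √(1 − √0.6)."""
        probs = np.tile([0.6, 0.3, 0.1], (10, 1))
        f_ad = m.average_dosage_dist(probs)
        f_bg = m.best_guess_dist(probs)
        np.testing.assert_allclose(f_ad, [0.6, 0.3, 0.1], atol=1e-12)
        np.testing.assert_allclose(f_bg, [1, 0, 0], atol=1e-12)
        value = m.hiq(f_ad, f_bg)
        assert value == pytest.approx(1.0 - math.sqrt(1.0 - math.sqrt(0.6)), abs=1e-12)
        assert round(value, 2) == 0.53

    def test_worked_example_heterogeneous(self):
        """Six (1,0,0), three (0,1,0), one (0,0,1): f_bg = f_ad, hiQ = 1."""
        probs = np.array([[1, 0, 0]] * 6 + [[0, 1, 0]] * 3 + [[0, 0, 1]], float)
        f_ad = m.average_dosage_dist(probs)
        f_bg = m.best_guess_dist(probs)
        np.testing.assert_allclose(f_ad, [0.6, 0.3, 0.1], atol=1e-12)
        np.testing.assert_allclose(f_bg, f_ad, atol=1e-12)
        assert m.hiq(f_ad, f_bg) == 1.0

    def test_perpendicular_distributions(self):
        assert m.hiq([1, 0, 0], [0, 1, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_tie_splitting(self):
        probs = np.array([[0.5, 0.5, 0.0]])
        np.testing.assert_allclose(m.best_guess_dist(probs), [0.5, 0.5, 0.0])

    def test_identity_dosages_give_uniform_average(self):
        probs = np.eye(3)
        np.testing.assert_allclose(m.average_dosage_dist(probs), np.full(3, 1 / 3))

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            m.hiq([0.5, 0.2, 0.1], [1, 0, 0])


class TestComputeMarker:
    def test_one_hot_marker_is_fully_informative(self, rng):
        g = rng.choice(3, size=50, p=[0.49, 0.42, 0.09])  # HWE at f=0.3
        probs = np.zeros((50, 3))
        probs[np.arange(50), g] = 1.0
        acc = m.compute_marker(probs)
        assert acc.iam_chance == 1.0
        assert acc.iam_hwe == pytest.approx(1.0)
        assert acc.hiq == 1.0

    def test_hwe_vector_marker_has_zero_iam_hwe(self):
        f = 0.3
        hwe = np.array([(1 - f) ** 2, 2 * f * (1 - f), f * f])
        acc = m.compute_marker(np.tile(hwe, (100, 1)))
        assert acc.iam_hwe == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_oracle(self, rng):
        """Vectorized path equals a loop-based re-implementation."""
        probs = random_probs(rng, 20)
        acc = m.compute_marker(probs)
        ref = naive_marker(probs)
        for field in ("maf_hat", "q_bar", "iam_chance", "iam_hwe", "hiq"):
            assert getattr(acc, field) == pytest.approx(ref[field], abs=1e-12)
        assert acc.n_used == ref["n_used"]

    def test_all_missing_is_flagged_undefined(self):
        acc = m.compute_marker(np.zeros((4, 3)))
        assert acc.n_used == 0
        assert m.FLAG_MISSING_EXCLUDED in acc.flags
        assert math.isnan(acc.maf_hat) and math.isnan(acc.hiq)

    def test_undefined_anchor_is_flagged(self):
        acc = m.compute_marker(np.tile([1.0, 0.0, 0.0], (5, 1)))
        assert m.FLAG_IAM_HWE_UNDEFINED in acc.flags
        assert math.isnan(acc.iam_hwe)

    def test_founder_mask_restricts_frequency_only(self):
        probs = np.array([[0, 0, 1]] * 2 + [[1, 0, 0]] * 2, float)
        mask = np.array([True, True, False, False])
        acc = m.compute_marker(probs, founder_mask=mask)
        assert acc.maf_hat == 1.0  # founders are hom-alt
        assert acc.n_used == 4  # but everyone contributes elsewhere


class TestInvariants:
    @given(normalized_triplets(n_min=2, n_max=30), st.randoms(use_true_random=False))
    @settings(derandomize=True, max_examples=40)
    def test_permutation_invariance(self, probs, rnd):
        order = list(range(len(probs)))
        rnd.shuffle(order)
        a = m.compute_marker(probs)
        b = m.compute_marker(probs[order])
        for field in ("maf_hat", "q_bar", "iam_chance", "iam_hwe", "hiq"):
            assert getattr(a, field) == pytest.approx(getattr(b, field), nan_ok=True)

    @given(normalized_triplets(n_min=2, n_max=30))
    @settings(derandomize=True, max_examples=40)
    def test_orientation_symmetry(self, probs):
        """Reversing triplets flips f̂ to 1−f̂ and fixes every index."""
        a = m.compute_marker(probs)
        b = m.compute_marker(probs[:, ::-1])
        assert b.maf_hat == pytest.approx(1.0 - a.maf_hat, abs=1e-9)
        for field in ("q_bar", "iam_chance", "iam_hwe", "hiq"):
            assert getattr(a, field) == pytest.approx(
                getattr(b, field), abs=1e-9, nan_ok=True
            )

    @given(normalized_triplets(n_min=1, n_max=30))
    @settings(derandomize=True, max_examples=40)
    def test_bounds(self, probs):
        acc = m.compute_marker(probs)
        assert 0.0 <= acc.q_bar <= 2 / 3
        assert 0.0 <= acc.iam_chance <= 1.0
        assert 0.0 <= acc.hiq <= 1.0
        if not math.isnan(acc.iam_hwe):
            assert acc.iam_hwe <= 1.0
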