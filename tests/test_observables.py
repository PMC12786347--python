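"""FC, sliding-window FCD, phase FCD, KS and L2 distances vs brute force."""

import numpy as np
import pytest

from wbsim import (fc_similarity, ks_distance, l2_distance, phase_fcd,
                   sliding_window_fcd, static_fc)
from wbsim.errors import ValidationError


def brute_force_fc(x):
    """Pearson correlation from the covariance/sigma-sigma definition."""
    n, T = x.shape
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
            out[i, j] = (xi * xj).sum() / np.sqrt((xi ** 2).sum()
                                                  * (xj ** 2).sum())
    return out


def brute_force_ks(a, b):
    """Sup of |ECDF_a - ECDF_b| evaluated at every breakpoint."""
    points = np.concatenate([a, b])
    best = 0.0
    for x in points:
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        best = max(best, abs(fa - fb))
    return best


def brute_force_analytic_phase(x):
    """FFT-based analytic signal, written independently of scipy."""
    T = x.shape[-1]
    X = np.fft.fft(x - x.mean(axis=-1, keepdims=True), axis=-1)
    h = np.zeros(T)
    h[0] = 1.0
    if T % 2 == 0:
        h[T // 2] = 1.0
        h[1:T // 2] = 2.0
    else:
        h[1:(T + 1) // 2] = 2.0
    return np.angle(np.fft.ifft(X * h, axis=-1))


class TestStaticFC:
    def test_identical_series_all_ones(self, rng):
        x = np.tile(rng.random(50), (4, 1))
        fc = static_fc(x)
        np.testing.assert_allclose(fc.values, 1.0, atol=1e-12)

    def test_sign_flip_gives_minus_one(self, rng):
        base = rng.random(60)
        x = np.stack([base, -base])
        fc = static_fc(x)
        assert fc.values[0, 1] == pytest.approx(-1.0)

    def test_matches_brute_force(self, rng):
        x = rng.random((3, 4))
        np.testing.assert_allclose(static_fc(x).values, brute_force_fc(x),
                                   rtol=1e-12)

    def test_affine_rescale_invariance(self, rng):
        x = rng.random((5, 80))
        scaled = 3.7 * x + np.arange(5)[:, None]
        np.testing.assert_allclose(static_fc(scaled).values,
                                   static_fc(x).values, atol=1e-12)

    def test_zero_variance_region_flagged(self, rng):
        x = rng.random((3, 40))
        x[1] = 2.0
        fc = static_fc(x)
        assert fc.n_undefined == 1
        assert np.isnan(fc.values[0, 1])
        assert fc.values[1, 1] == 1.0
        # flagged entries are excluded from the comparison vector
        assert fc.upper_triangle().size == 1


class TestFCSimilarity:
    def test_identical_matrices(self, rng):
        fc = static_fc(rng.random((4, 30)))
        assert fc_similarity(fc, fc) == pytest.approx(1.0)

    def test_negated_off_diagonal(self, rng):
        fc = static_fc(rng.random((4, 30)))
        from wbsim import FCMatrix
        neg = FCMatrix(values=-fc.values)
        assert fc_similarity(fc, neg) == pytest.approx(-1.0)

    def test_matches_direct_formula(self, rng):
        a = static_fc(rng.random((4, 25)))
        b = static_fc(rng.random((4, 25)))
        iu = np.triu_indices(4, k=1)
        expected = np.corrcoef(a.values[iu], b.values[iu])[0, 1]
        assert fc_similarity(a, b) == pytest.approx(expected, rel=1e-12)


class TestSlidingWindowFCD:
    def test_periodic_signal_all_ones(self):
        t = np.arange(40)
        x = np.stack([np.sin(2 * np.pi * t / 10),
                      np.cos(2 * np.pi * t / 10),
                      np.sin(2 * np.pi * t / 10 + 1.0)])
        fcd = sliding_window_fcd(x, window=10, step=10)
        np.testing.assert_allclose(fcd.values, 1.0, atol=1e-10)

    def test_two_windows_single_entry(self, rng):
        x = rng.random((3, 20))
        fcd = sliding_window_fcd(x, window=10, step=10)
        assert fcd.values.size == 1
        assert fcd.n_windows == 2

    def test_matches_brute_force_loops(self, rng):
        x = rng.random((5, 30))
        window, step = 10, 10
        fcd = sliding_window_fcd(x, window=window, step=step)
        starts = range(0, x.shape[1] - window + 1, step)
        iu = np.triu_indices(5, k=1)
        tri = [brute_force_fc(x[:, s:s + window])[iu] for s in starts]
        expected = []
        for i in range(len(tri)):
            for j in range(i + 1, len(tri)):
                expected.append(np.corrcoef(tri[i], tri[j])[0, 1])
        np.testing.assert_allclose(fcd.values, expected, rtol=1e-10)

    def test_disjoint_window_count(self, rng):
        x = rng.random((3, 95))
        fcd = sliding_window_fcd(x, window=30, step=30)
        w = fcd.n_windows
        assert w == 3
        assert fcd.values.size == w * (w - 1) // 2

    def test_single_window_rejected(self, rng):
        with pytest.raises(ValidationError, match="window"):
            sliding_window_fcd(rng.random((3, 10)), window=10, step=3)


class TestPhaseFCD:
    def test_common_sinusoid_all_ones(self):
        t = np.arange(200) * 0.1
        x = np.tile(np.sin(t), (4, 1))
        fcd = phase_fcd(x, window=50, step=50)
        np.testing.assert_allclose(fcd.values, 1.0, atol=1e-9)

    def test_antiphase_coherence_minus_one(self):
        t = np.arange(400) * 0.1
        x = np.stack([np.sin(t), np.sin(t + np.pi)])
        phases = brute_force_analytic_phase(x)
        coher = np.cos(phases[0] - phases[1])
        # away from the Hilbert edge artefacts the coherence is -1
        np.testing.assert_allclose(coher[50:-50], -1.0, atol=1e-3)

    def test_matches_brute_force_pipeline(self, rng):
        x = rng.random((4, 60))
        window, step = 20, 20
        fcd = phase_fcd(x, window=window, step=step)
        phases = brute_force_analytic_phase(x)
        n = 4
        starts = range(0, x.shape[1] - window + 1, step)
        vecs = []
        for s in starts:
            entries = []
            for i in range(n):
                for j in range(i + 1, n):
                    entries.append(np.mean(np.cos(
                        phases[i, s:s + window] - phases[j, s:s + window])))
            vecs.append(np.array(entries))
        expected = []
        for i in range(len(vecs)):
            for j in range(i + 1, len(vecs)):
                expected.append(
                    vecs[i] @ vecs[j]
                    / (np.linalg.norm(vecs[i]) * np.linalg.norm(vecs[j])))
        np.testing.assert_allclose(fcd.values, expected, rtol=1e-9)

    def test_similarities_bounded(self, rng):
        fcd = phase_fcd(rng.random((5, 120)), window=30, step=10)
        assert np.all(fcd.values >= -1.0) and np.all(fcd.values <= 1.0)

    def test_constant_region_flagged(self, rng):
        x = rng.random((3, 50))
        x[2] = 5.0
        with pytest.raises(ValidationError, match="constant"):
            phase_fcd(x, window=20, step=10)


class TestKSDistance:
    def test_identical_samples_zero(self, rng):
        a = rng.random(40)
        assert ks_distance(a, a) == 0.0

    def test_disjoint_supports_one(self):
        assert ks_distance([1.0, 2.0], [10.0, 20.0]) == 1.0

    def test_enumerated_example_one_third(self):
        """{1,2,3} vs {2,3,4}: brute-force ECDF enumeration gives 1/3."""
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
        assert brute_force_ks(a, b) == pytest.approx(1.0 / 3.0)
        assert ks_distance(a, b) == pytest.approx(1.0 / 3.0)

    def test_matches_brute_force_on_random_samples(self, rng):
        for _ in range(20):
            a = rng.standard_normal(rng.integers(3, 40))
            b = rng.standard_normal(rng.integers(3, 40)) + 0.3
            assert ks_distance(a, b) == pytest.approx(brute_force_ks(a, b),
                                                      abs=1e-12)

    def test_symmetry_and_monotone_invariance(self, rng):
        a, b = rng.random(25), rng.random(30)
        assert ks_distance(a, b) == ks_distance(b, a)
        assert ks_distance(np.exp(a), np.exp(b)) == pytest.approx(
            ks_distance(a, b), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            ks_distance([], [1.0])


class TestL2Distance:
    def test_zero_for_equal_and_one_for_unit_basis(self):
        a = np.arange(6.0).reshape(2, 3)
        assert l2_distance(a, a) == 0.0
        e = np.zeros((2, 3))
        e[1, 2] = 1.0
        assert l2_distance(a + e, a) == 1.0

    def test_matches_hand_formula(self, rng):
        a, b = rng.random((3, 4)), rng.random((3, 4))
        assert l2_distance(a, b) == pytest.approx(
            np.sqrt(((a - b) ** 2).sum()), rel=1e-14)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            l2_distance(np.zeros(3), np.zeros(4))
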