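"""Bias-current generators: quantile constructions and random draws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.special import erfinv

from gammaprc import (
    GaussianHeterogeneity,
    LorentzianHeterogeneity,
    gaussian_bias_quantiles,
    gaussian_bias_sample,
    lorentzian_bias_quantiles,
)


class TestGaussianQuantiles:
    def test_zero_cv_degenerate(self):
        out = gaussian_bias_quantiles(GaussianHeterogeneity(20.4, 0.0, 5))
        assert np.allclose(out, 20.4)

    def test_single_neuron_gets_the_mean(self):
        out = gaussian_bias_quantiles(GaussianHeterogeneity(7.3, 0.4, 1))
        assert out.shape == (1,) and out[0] == pytest.approx(7.3)

    def test_cv_recovery_against_quadrature_oracle(self):
        # oracle: moments of the quantile function integrated over rank
        # fractions i/(n+1) converge to the continuous quantile integrals
        mean, cv, n = 15.8, 0.1, 10_000
        out = gaussian_bias_quantiles(GaussianHeterogeneity(mean, cv, n))
        sample_cv = out.std(ddof=1) / out.mean()
        q = lambda p: mean * (1 + np.sqrt(2) * cv * erfinv(2 * p - 1))
        m1 = quad(q, 0, 1)[0]
        m2 = quad(lambda p: q(p) ** 2, 0, 1)[0]
        oracle_cv = np.sqrt(m2 - m1**2) / m1
        assert sample_cv == pytest.approx(oracle_cv, rel=0.02)
        assert sample_cv == pytest.approx(cv, rel=0.02)

    def test_negative_current_rejected(self):
        with pytest.raises(ValueError, match="negative bias current"):
            gaussian_bias_quantiles(GaussianHeterogeneity(1.0, 2.0, 99))

    @given(
        mean=st.floats(0.5, 50.0),
        cv=st.floats(0.0, 0.25),
        n=st.integers(1, 400),
    )
    @settings(max_examples=50, deadline=None)
    def test_sorted_symmetric_exact_mean(self, mean, cv, n):
        out = gaussian_bias_quantiles(GaussianHeterogeneity(mean, cv, n))
        assert len(out) == n
        assert np.all(np.diff(out) >= 0)
        # symmetry about the mean and exact mean by rank symmetry
        assert np.allclose(out + out[::-1], 2 * mean, rtol=1e-12, atol=1e-9)
        assert out.mean() == pytest.approx(mean, rel=1e-12, abs=1e-9)

    def test_determinism(self):
        h = GaussianHeterogeneity(10.0, 0.2, 100)
        a, b = gaussian_bias_quantiles(h), gaussian_bias_quantiles(h)
        assert np.array_equal(a, b)


class TestLorentzianQuantiles:
    def test_middle_entry_is_center(self):
        out = lorentzian_bias_quantiles(LorentzianHeterogeneity(20.0, 3.0, 5))
        assert out[2] == pytest.approx(20.0)

    def test_quartile_identity_n3(self):
        out = lorentzian_bias_quantiles(LorentzianHeterogeneity(20.0, 3.0, 3))
        assert np.allclose(out, [17.0, 20.0, 23.0])

    def test_interquartile_half_range_matches_half_width(self):
        # analytic Lorentzian quantiles: Q(3/4) - Q(1/4) = 2*Delta
        out = lorentzian_bias_quantiles(LorentzianHeterogeneity(-5.0, 1.0, 5000))
        iqr_half = (np.quantile(out, 0.75) - np.quantile(out, 0.25)) / 2
        assert iqr_half == pytest.approx(1.0, rel=0.02)

    def test_heavy_tail_grows_with_n(self):
        caps = [
            lorentzian_bias_quantiles(LorentzianHeterogeneity(0.0, 2.0, n)).max()
            for n in (11, 101, 1001)
        ]
        assert caps[0] < caps[1] < caps[2]

    @given(center=st.floats(-30, 30), hw=st.floats(0.1, 5.0), n=st.integers(1, 300))
    @settings(max_examples=50, deadline=None)
    def test_strictly_ascending(self, center, hw, n):
        out = lorentzian_bias_quantiles(LorentzianHeterogeneity(center, hw, n))
        assert np.all(np.diff(out) > 0) or n == 1


class TestGaussianSample:
    def test_seed_determinism(self):
        a = gaussian_bias_sample(3.6, 0.167, 200, seed=7)
        b = gaussian_bias_sample(3.6, 0.167, 200, seed=7)
        assert np.array_equal(a, b)
        c = gaussian_bias_sample(3.6, 0.167, 200, seed=8)
        assert not np.array_equal(a, c)

    def test_zero_cv(self):
        assert np.allclose(gaussian_bias_sample(3.6, 0.0, 200, seed=0), 3.6)

    def test_large_n_cv_recovery(self):
        out = gaussian_bias_sample(3.6, 0.167, 100_000, seed=1)
        assert out.std() / out.mean() == pytest.approx(0.167, rel=0.01)
        assert np.all(out >= 0)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            gaussian_bias_sample(3.6, 0.1, 0, seed=0)
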