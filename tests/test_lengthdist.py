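import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ncoinfer import ValidationError, convert_weights, invert_weights, mixture_mean
from ncoinfer.lengthdist import (
    NBComponent,
    NBMixture,
    detection_mass,
    size_from_variance,
    truncation_point,
)


def test_shifted_geometric_is_nested():
    c = NBComponent(mean=2.0, size=1.0)
    assert c.pmf([1, 2, 3]) == pytest.approx([0.5, 0.25, 0.125])
    # agrees with the geometric distribution on {1, 2, ...}
    xs = np.arange(1, 40)
    assert np.allclose(c.pmf(xs), stats.geom.pmf(xs, 0.5), rtol=1e-12)


@pytest.mark.parametrize("mean,size", [(2.0, 1.0), (50.0, 0.3), (300.0, 4.0), (1e5, 1e3)])
def test_pmf_normalised_with_correct_mean(mean, size):
    c = NBComponent(mean, size)
    x = np.arange(1, truncation_point(c, 1e-12) + 1)
    f = c.pmf(x)
    assert np.all(f >= 0.0) and np.all(np.isfinite(f))
    assert f.sum() == pytest.approx(1.0, abs=1e-9)
    assert float(x @ f) == pytest.approx(mean, rel=1e-6)


def test_pmf_matches_scipy_reference():
    c = NBComponent(137.0, 0.7)
    xs = np.arange(1, 5000, 13)
    ref = stats.nbinom.pmf(xs - 1, 0.7, 0.7 / (0.7 + 136.0))
    assert np.allclose(c.pmf(xs), ref, rtol=1e-9)
    assert np.allclose(c.sf(xs), stats.nbinom.sf(xs - 1, 0.7, 0.7 / (0.7 + 136.0)),
                       rtol=1e-9)


def test_pmf_stable_for_extreme_parameters():
    for mean, size in [(1e6, 1e-3), (1.0001, 1e-3), (1e6, 1e3)]:
        c = NBComponent(mean, size)
        f = c.pmf(np.array([1, 10, 1000, 100000]))
        assert np.all(np.isfinite(f)) and np.all(f >= 0.0)


def test_truncation_point_examples():
    # geometric m=2: smallest X with (1/2)^X < 1e-9 is 30
    assert truncation_point(NBComponent(2.0, 1.0), 1e-9) == 30
    # near point mass at 10: truncation collapses to about the mean
    tight = NBComponent(10.0, 5e4)
    assert truncation_point(tight, 1e-9) <= 40
    # mixtures take the max over components
    mix = NBMixture([NBComponent(2.0, 1.0), tight], np.array([0.5, 0.5]))
    assert truncation_point(mix, 1e-9) == max(
        truncation_point(c, 1e-9) for c in mix.components
    )
    c = NBComponent(350.0, 2.0)
    x = truncation_point(c, 1e-9)
    assert c.sf(x) < 1e-9 <= c.sf(x - 1)


def test_detection_mass_constant_and_staircase():
    c = NBComponent(20.0, 2.0)
    n = truncation_point(c) + 10
    assert detection_mass(c, np.ones(n)) == pytest.approx(1.0, abs=1e-9)
    assert detection_mass(c, np.full(n, 0.3)) == pytest.approx(0.3, abs=1e-9)
    d = np.where(np.arange(1, n + 1) >= 10, 1.0, 0.2)
    xs = np.arange(1, n + 1)
    assert detection_mass(c, d) == pytest.approx(float(d @ c.pmf(xs)), rel=1e-12)
    with pytest.raises(ValidationError, match="larger x_max"):
        detection_mass(c, np.ones(5))


def test_weight_conversion_examples():
    a = convert_weights(np.array([0.5, 0.5]), np.array([0.1, 0.3]))
    assert a == pytest.approx([0.25, 0.75])
    same = convert_weights(np.array([0.3, 0.7]), np.array([0.2, 0.2]))
    assert same == pytest.approx([0.3, 0.7])
    with pytest.raises(ValidationError, match="undetectable"):
        convert_weights(np.array([0.5, 0.5]), np.array([0.0, 0.3]))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=4),
       st.lists(st.floats(0.001, 1.0), min_size=4, max_size=4))
def test_weight_conversion_round_trip(raw_alpha, raw_d):
    alpha = np.asarray(raw_alpha)
    alpha = alpha / alpha.sum()
    d = np.asarray(raw_d[: alpha.size])
    there = convert_weights(alpha, d)
    back = invert_weights(there, d)
    assert np.max(np.abs(back - alpha)) < 1e-12


def test_mixture_mean_is_underlying_mean():
    mix = NBMixture(
        [NBComponent(100.0, 1.0), NBComponent(1000.0, 1.0)],
        alpha_hat=np.array([0.9, 0.1]),
        d=np.array([1.0, 1.0]),
        alpha=np.array([0.5, 0.5]),
    )
    assert mixture_mean(mix) == pytest.approx(550.0)
    single = NBMixture([NBComponent(300.0, 2.0)], np.array([1.0]),
                       d=np.array([1.0]), alpha=np.array([1.0]))
    assert mixture_mean(single) == pytest.approx(300.0)
    # brute-force moment of the mixture pmf
    xs = np.arange(1, truncation_point(mix, 1e-12) + 1)
    assert float(xs @ mix.pmf(xs)) == pytest.approx(550.0, rel=1e-6)


def test_size_from_variance_maps_k_scale():
    c = NBComponent(300.0, size_from_variance(300.0, 300.0**2 * 0.25))
    assert c.variance == pytest.approx(300.0**2 * 0.25)
    with pytest.raises(ValidationError, match="not attainable"):
        size_from_variance(100.0, 50.0)


def test_mixture_serialisation_round_trip(tmp_path):
    from ncoinfer.lengthdist import read_mixture, write_mixture

    mix = NBMixture(
        [NBComponent(42.0, 1.5), NBComponent(900.0, 0.4)],
        alpha_hat=np.array([0.3, 0.7]),
        d=np.array([0.2, 0.9]),
        alpha=np.array([0.65882353, 0.34117647]),
    )
    path = tmp_path / "mixture.tsv"
    write_mixture(mix, path)
    again = read_mixture(path)
    assert [c.mean for c in again.components] == pytest.approx([42.0, 900.0])
    assert again.alpha_hat == pytest.approx(mix.alpha_hat)
    assert again.alpha == pytest.approx(mix.alpha)
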