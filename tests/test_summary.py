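"""HDI, weighted grand mean, contrasts, variance decomposition and
ratio-scale back-transformation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phytomacro.summary import (hdi, pairwise_contrasts, summarize_ratios,
                                variance_decomposition, weighted_grand_mean)


def _brute_force_hdi(x, mass):
    """Independent O(n^2) oracle: scan every window of the sorted sample."""
    x = np.sort(np.asarray(x, float))
    n = len(x)
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    best = None
    for i in range(n - k + 1):
        width = x[i + k - 1] - x[i]
        if best is None or width < best[0]:
            best = (width, x[i], x[i + k - 1])
    return float(best[1]), float(best[2])


def test_hdi_known_window():
    samples = [0, 1, 1, 2, 3, 4, 5, 6, 7, 9, 50]
    # mass chosen so 9 of 11 sorted points are kept
    assert hdi(samples, mass=9 / 11 - 1e-9) == (0.0, 7.0)


def test_hdi_zero_width_on_constant_samples():
    assert hdi([5.0] * 30) == (5.0, 5.0)


def test_hdi_standard_normal_limit():
    rng = np.random.default_rng(0)
    lo, hi = hdi(rng.standard_normal(100_000), 0.95)
    assert lo == pytest.approx(-1.96, abs=0.03)
    assert hi == pytest.approx(1.96, abs=0.03)


@settings(derandomize=True, max_examples=50)
@given(st.integers(0, 10_000), st.integers(5, 300),
       st.sampled_from([0.5, 0.8, 0.9, 0.95]))
def test_hdi_matches_brute_force_and_beats_equal_tails(seed, n, mass):
    rng = np.random.default_rng(seed)
    x = rng.gamma(2.0, 2.0, n)  # skewed, ties unlikely but ordering matters
    assert hdi(x, mass) == _brute_force_hdi(x, mass)
    # the central (equal-tailed) window of the same sample count can never
    # be shorter than the minimum over all windows
    xs = np.sort(x)
    k = int(np.ceil(mass * n))
    i = (n - k) // 2
    lo, hi = hdi(x, mass)
    assert hi - lo <= xs[i + k - 1] - xs[i] + 1e-12


def test_hdi_argument_validation():
    with pytest.raises(ValueError):
        hdi([1.0], 0.95)
    with pytest.raises(ValueError):
        hdi([1.0, 2.0], 1.5)


def _draws_with(mean, var, n=4000, seed=0):
    """Samples with *exactly* the requested sample mean and variance."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + np.sqrt(var) * z


def test_weighted_grand_mean_hand_computed_cases():
    equal = np.column_stack([_draws_with(10, 2.0, seed=1), _draws_with(20, 2.0, seed=2)])
    assert np.mean(weighted_grand_mean(equal)) == pytest.approx(15.0, abs=1e-9)

    unequal = np.column_stack([_draws_with(10, 1.0, seed=3), _draws_with(20, 4.0, seed=4)])
    # weights 1 and 1/4: (1*10 + 0.25*20) / 1.25 = 12
    assert np.mean(weighted_grand_mean(unequal)) == pytest.approx(12.0, abs=1e-9)


def test_grand_mean_is_drawwise_convex_combination():
    rng = np.random.default_rng(5)
    draws = rng.normal([10, 15, 30], [1, 2, 3], size=(500, 3))
    g = weighted_grand_mean(draws)
    assert np.all(g >= draws.min(axis=1) - 1e-12)
    assert np.all(g <= draws.max(axis=1) + 1e-12)


def test_grand_mean_of_identical_phyla_returns_the_draws():
    d = _draws_with(7.0, 1.3, seed=6)
    out = weighted_grand_mean(np.column_stack([d, d]))
    np.testing.assert_allclose(out, d, rtol=1e-12)


def test_grand_mean_rejects_degenerate_draws():
    with pytest.raises(ValueError, match="degenerate|zero"):
        weighted_grand_mean(np.column_stack([np.full(100, 3.0), np.arange(100.0)]))


def test_contrasts_significance_and_symmetry():
    rng = np.random.default_rng(7)
    draws = np.column_stack([
        rng.normal(43, 1, 3000),
        rng.normal(27, 1, 3000),
        rng.normal(43, 1, 3000) + rng.normal(0, 0.01, 3000),
    ])
    cm = pairwise_contrasts(draws, ["high", "low", "high2"])
    idx = cm.set_index(["phylum_a", "phylum_b"])
    assert idx.loc[("high", "low"), "significant"]
    assert not idx.loc[("high", "high2"), "significant"]
    # antisymmetric differences, symmetric flags
    for (a, b), row in idx.iterrows():
        assert row["significant"] == idx.loc[(b, a), "significant"]
        assert row["difference_median"] == pytest.approx(
            -idx.loc[(b, a), "difference_median"])


def test_variance_decomposition_symmetry_and_limits():
    s = np.full(100, 2.0)
    vd = variance_decomposition(s, s, s)
    assert vd.as_tuple() == pytest.approx((100 / 3,) * 3)
    assert sum(vd.as_tuple()) == pytest.approx(100.0, abs=0.5)

    zero = np.full(100, 1e-12)
    vd = variance_decomposition(s, s, zero)
    assert vd.as_tuple() == pytest.approx((0.0, 50.0, 50.0), abs=1e-6)


def test_variance_decomposition_drawwise_also_sums_to_100():
    rng = np.random.default_rng(8)
    vd = variance_decomposition(rng.gamma(2, 1, 500), rng.gamma(3, 1, 500),
                                rng.gamma(4, 1, 500), draw_wise=True)
    assert sum(vd.as_tuple()) == pytest.approx(100.0, abs=0.5)


def test_ratio_backtransform_monotone_invariance():
    from phytomacro.model import PosteriorDraws

    rng = np.random.default_rng(9)
    lx = rng.normal(np.log(2), 0.1, (2, 400))
    phylum_mean = np.stack([lx, lx + rng.normal(0, 0.05, (2, 400))], axis=2)
    draws = PosteriorDraws(
        mu=lx, phylum_mean=phylum_mean,
        species_mean=lx[:, :, None], sigma_p=np.ones((2, 400)),
        sigma_s=np.ones((2, 400)), sigma_e=np.ones((2, 400)),
        phylum_names=["A", "B"], species_names=["s"],
        species_phylum=np.zeros(1, dtype=np.intp))
    out = summarize_ratios(draws).set_index("name")
    assert out.loc["A", "median"] == pytest.approx(
        np.exp(np.median(lx)), rel=1e-12)
    assert out.loc["A", "hdi_low"] < out.loc["A", "median"] < out.loc["A", "hdi_high"]
    # a degenerate draw set collapses to a zero-width interval on the
    # ratio scale: median and HDI all equal exp(log value)
    constant = np.zeros((2, 100)) + np.log(2.0)
    from phytomacro.summary import hdi as _hdi
    lo, hi = _hdi(constant.ravel())
    assert np.exp(lo) == np.exp(hi) == pytest.approx(2.0, rel=1e-15)
    # exp(median(log x)) == median(exp(log x)) for any odd-length draw set
    # (for even lengths the median averages two order statistics, which
    # does not commute with exp)
    odd = rng.normal(np.log(2), 0.2, 801)
    assert np.exp(np.median(odd)) == pytest.approx(np.median(np.exp(odd)), rel=1e-12)
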