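"""Chart statistic recursions: transforms, worked-example rows, resets,
nonnegativity and symmetry."""

import numpy as np
import pytest
from scipy import stats

from vpcharts import (
    ChartConfig,
    ProfileModel,
    Sample,
    ShiftSpec,
    combine_max,
    combine_ss,
    make_chart,
    normal_chisq_transform,
    simulate_sample,
)
from vpcharts.charts import CHART_NAMES


def test_transform_fixed_points():
    eps = 1e-12
    assert normal_chisq_transform(stats.chi2.median(8), 8) == pytest.approx(0, abs=1e-9)
    lo = normal_chisq_transform(0.0, 8, eps)
    assert lo == pytest.approx(stats.norm.ppf(eps))
    assert np.isfinite(lo) and lo < -6
    assert np.isfinite(normal_chisq_transform(1e12, 8, eps))


def test_transform_normalizes_chisquare_draws():
    """Probability-integral-transform oracle: transformed chi-square(np)
    draws are standard normal (this is also the in-control law of the
    SS-chart F statistic)."""
    rng = np.random.default_rng(5)
    x = rng.chisquare(8, size=100000)
    z = normal_chisq_transform(x, 8)
    assert stats.kstest(z, "norm").pvalue > 0.01


def test_transform_monotone_in_argument():
    x = np.linspace(0.01, 40, 200)
    y = normal_chisq_transform(x, 6)
    assert np.all(np.diff(y) > 0)


def _residual_direction(X):
    """A vector orthogonal to the columns of X (n - q - 1 = 1 dim here)."""
    u, s, vt = np.linalg.svd(X, full_matrices=True)
    return u[:, -1]


def _sample_with_known_parts(model, n, w_target):
    """Y with Bhat == B exactly and W == w_target: residuals lie in the
    orthogonal complement of the design columns."""
    X = model.design(n)
    u = _residual_direction(X)  # unit norm, X'u = 0, 1'u = 0
    a = np.array([1.0, 0.0]) @ np.linalg.cholesky(model.Sigma).T
    resid = np.outer(u, a)  # f = |u|^2 * a Sigma^-1 a' = 1
    resid *= np.sqrt(w_target)
    return Sample(Y=X @ model.B + resid, X=X)


def test_max_mewma_fresh_state_edge(p2, cfg):
    """Bhat = B and W at the chi-square(np) median: the mean statistic is
    forced to the clamp quantile and the variability EWMA stays zero."""
    chart = make_chart("max_mewma", p2.model, cfg)
    s = _sample_with_known_parts(p2.model, 4, stats.chi2.median(8))
    me = chart.update(s)
    assert chart.last_var_stat == pytest.approx(0, abs=1e-9)
    assert chart.last_mean_stat == pytest.approx(stats.norm.ppf(cfg.clamp_eps))
    assert me == pytest.approx(abs(stats.norm.ppf(cfg.clamp_eps)), rel=1e-6)


def test_max_mewma_worked_example_row():
    """Published decision-table row: mean/variability components -2.370 and
    -0.544 combine to ME = 2.370."""
    assert combine_max(-2.370, -0.544) == pytest.approx(2.370)


def test_max_mcusum_allowance_and_null_update(p2):
    cfg = ChartConfig(tau_design=1.1)
    assert cfg.cusum_v == pytest.approx(np.log(1.1) * 11, abs=1e-12)
    assert cfg.cusum_v == pytest.approx(1.0484, abs=2e-4)

    chart = make_chart("max_mcusum", p2.model, cfg)
    X = p2.model.design(4)
    mc = chart.update(Sample(Y=X @ p2.model.B, X=X))  # Bhat == beta_g
    assert mc == 0.0
    assert chart.U == 0.0 and chart.L == 0.0


def test_max_mcusum_worked_example_row():
    assert combine_max(1.8698, 0.0) == pytest.approx(1.8698)


def test_ss_ewmae_fresh_state_edge(p2, cfg):
    """ebar = 0 with f at the chi-square(np) median: P is lam times the
    clamp quantile, V stays zero."""
    chart = make_chart("ss_ewmae", p2.model, cfg)
    s = _sample_with_known_parts(p2.model, 4, stats.chi2.median(8))
    ewe = chart.update(s)
    assert chart.V == pytest.approx(0, abs=1e-9)
    assert chart.P == pytest.approx(cfg.lam * stats.norm.ppf(cfg.clamp_eps))
    assert ewe == pytest.approx(chart.P**2, rel=1e-6)


def test_ss_ewmae_worked_example_row():
    # P^2 + V^2 for the published first-row components
    assert combine_ss(-0.3005, -0.1815) == pytest.approx(0.1233, abs=1e-4)


def test_ss_cusume_accumulator_arithmetic(p2):
    chart = make_chart("ss_cusume", p2.model, ChartConfig(k1=1.0, k2=1.5))
    assert chart.step_transformed(0.5, -1.0) == 0.0  # inside both allowances
    chart.reset()
    cue = chart.step_transformed(2.0, 0.0)
    assert chart.Dplus == pytest.approx(1.0)
    assert cue == pytest.approx(1.0)


def test_ss_cusume_worked_example_row():
    assert combine_ss(0.5029, 0.0) == pytest.approx(0.2529, abs=1e-4)


@pytest.mark.parametrize("name", CHART_NAMES)
def test_statistics_nonnegative_and_replayable(p2, name):
    """Plotting statistics and CUSUM accumulators are nonnegative under
    arbitrary shifts, and resetting + replaying reproduces them exactly."""
    rng = np.random.default_rng(31)
    chart = make_chart(name, p2.model)
    delta = rng.standard_normal(p2.model.B.shape)
    samples = [
        simulate_sample(
            p2.model,
            shift=ShiftSpec(delta_B=delta, tau=1.7),
            n=int(rng.choice([4, 8])),
            rng=rng,
        )
        for _ in range(40)
    ]
    stats1 = [chart.update(s) for s in samples]
    assert all(v >= 0 for v in stats1)
    if name == "max_mcusum":
        assert chart.U >= 0 and chart.L >= 0
    if name == "ss_cusume":
        assert min(chart.Dminus, chart.Dplus, chart.Bminus, chart.Bplus) >= 0
    chart.reset()
    stats2 = [chart.update(s) for s in samples]
    np.testing.assert_array_equal(stats1, stats2)


@pytest.mark.parametrize("name", CHART_NAMES)
def test_response_relabeling_invariance(p2, name):
    """Swapping the two responses (consistently in B, Sigma and Y) leaves
    every plotting statistic unchanged."""
    m = p2.model
    perm = [1, 0]
    m_perm = ProfileModel(B=m.B[:, perm], Sigma=m.Sigma[np.ix_(perm, perm)],
                          designs=m.designs)
    rng = np.random.default_rng(77)
    c1 = make_chart(name, m)
    c2 = make_chart(name, m_perm)
    X = m.design(4)
    for _ in range(25):
        Y = simulate_sample(m, n=4, rng=rng).Y
        s1 = c1.update(Sample(Y=Y, X=X))
        s2 = c2.update(Sample(Y=Y[:, perm], X=X))
        assert s1 == pytest.approx(s2, rel=1e-9)
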