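import numpy as np
import pandas as pd
import pytest

from dyadsync.errors import (
    CollinearityError,
    UndefinedCorrelationError,
    ValidationError,
)
from dyadsync.stats import (
    build_stats_report,
    fit_distance_regression,
    kruskal_wallis,
    pearson_corr,
    pearson_p_from_r,
)


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def test_kw_hand_computed():
    """Ranks 1..4, R1 = 3, R2 = 7 -> H = 12/(4*5)*(9/2 + 49/2) - 15 = 2.4."""
    res = kruskal_wallis([np.array([1, 2]), np.array([3, 4])])
    assert res.H == pytest.approx(2.4)
    assert res.df == 1


def test_kw_identical_groups():
    res = kruskal_wallis([np.array([1, 2]), np.array([1, 2])])
    assert res.H == pytest.approx(0.0)
    with pytest.warns(UserWarning, match="identical"):
        degenerate = kruskal_wallis([np.array([5.0, 5.0]), np.array([5.0, 5.0])])
    assert degenerate.H == 0.0 and degenerate.p == 1.0


def test_kw_monotone_invariance(rng):
    groups = [rng.normal(size=12), rng.normal(size=10), rng.normal(size=15)]
    base = kruskal_wallis(groups)
    transformed = kruskal_wallis([np.exp(g) for g in groups])  # strictly monotone
    assert transformed.H == pytest.approx(base.H)
    assert transformed.p == pytest.approx(base.p)


def test_kw_two_groups_same_operation(rng):
    """The emotion-vs-baseline contrast is the same code path with df = 1."""
    res = kruskal_wallis([rng.normal(size=15), rng.normal(size=15)])
    assert res.df == 1
    assert res.group_sizes == (15, 15)


def test_kw_validation():
    with pytest.raises(ValidationError):
        kruskal_wallis([np.array([1.0])])
    with pytest.raises(ValidationError):
        kruskal_wallis([np.array([1.0]), np.array([])])


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

def _regression_frame(n_dyads=15, seed=0, beta=(2.0, 3.0, -1.0), noise=0.0):
    rng = np.random.default_rng(seed)
    ds = rng.uniform(0, 2, size=n_dyads)
    rows = []
    for d in range(n_dyads):
        for cond, dummy in (("positive", 1.0), ("negative", 0.0)):
            y = beta[0] + beta[1] * ds[d] + beta[2] * dummy + noise * rng.standard_normal()
            rows.append(
                {
                    "dyad_id": f"d{d}",
                    "condition": cond,
                    "index": y,
                    "satisfaction_difference": ds[d],
                }
            )
    return pd.DataFrame(rows)


def test_regression_exact_interpolation():
    res = fit_distance_regression(_regression_frame(noise=0.0))
    assert res.terms["intercept"].estimate == pytest.approx(2.0)
    assert res.terms["satisfaction_difference"].estimate == pytest.approx(3.0)
    assert res.terms["emotion_positive"].estimate == pytest.approx(-1.0)


def test_regression_residual_df():
    res = fit_distance_regression(_regression_frame(n_dyads=15, noise=0.1))
    assert res.n_rows == 30
    assert res.df_resid == 27  # 30 rows - 3 coefficients


def test_regression_matches_normal_equations(rng):
    df = _regression_frame(n_dyads=20, seed=3, noise=0.5)
    res = fit_distance_regression(df)
    X = np.column_stack(
        [
            np.ones(len(df)),
            df["satisfaction_difference"],
            (df["condition"] == "positive").astype(float),
        ]
    )
    y = df["index"].to_numpy()
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    estimates = [
        res.terms[k].estimate
        for k in ("intercept", "satisfaction_difference", "emotion_positive")
    ]
    np.testing.assert_allclose(estimates, beta, atol=1e-10)
    # residuals orthogonal to every design column
    resid = y - X @ beta
    assert np.all(np.abs(X.T @ resid) < 1e-8 * np.abs(X).sum(axis=0))


def test_regression_collinearity_and_validation():
    df = _regression_frame(n_dyads=5, noise=0.1)
    df["satisfaction_difference"] = 0.0  # constant column duplicates intercept
    with pytest.raises(CollinearityError):
        fit_distance_regression(df)
    with pytest.raises(ValidationError, match="positive/negative"):
        bad = _regression_frame(n_dyads=5)
        bad.loc[0, "condition"] = "baseline"
        fit_distance_regression(bad)


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

def test_pearson_perfect():
    x = np.arange(10.0)
    res = pearson_corr(x, x)
    assert res.r == pytest.approx(1.0)
    assert res.n == 10


def test_pearson_matches_covariance_formula():
    x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
    y = np.array([2.0, 1.0, 5.0, 3.0, 8.0])
    expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    assert pearson_corr(x, y).r == pytest.approx(expected, rel=1e-12)


def test_pearson_constant_rejected():
    with pytest.raises(UndefinedCorrelationError):
        pearson_corr(np.ones(5), np.arange(5.0))


def test_p_from_r_consistency():
    """The r -> p conversion is self-consistent with a printed (r, p) pair.

    At exactly r = -0.47, n = 15 the two-tailed p is 0.0771; a published
    pair (r = -0.47, p = 0.079) is mutually consistent because unrounded r
    values within [-0.475, -0.465] produce p values spanning 0.079.
    """
    assert pearson_p_from_r(-0.47, 15) == pytest.approx(0.0771, abs=5e-4)
    p_lo = pearson_p_from_r(-0.475, 15)
    p_hi = pearson_p_from_r(-0.465, 15)
    assert p_lo < 0.079 < p_hi
    # conversion agrees with scipy's pearsonr p on real data
    rng = np.random.default_rng(7)
    x, y = rng.normal(size=20), rng.normal(size=20)
    res = pearson_corr(x, y)
    assert pearson_p_from_r(res.r, res.n) == pytest.approx(res.p, rel=1e-9)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def test_build_stats_report_structure(rng):
    rows = []
    for d in range(15):
        ds = rng.uniform(0, 2)
        for roi in ("frontal_left", "frontal_right"):
            for cond in ("positive", "negative", "baseline"):
                rows.append(
                    {
                        "dyad_id": f"d{d:02d}",
                        "roi": roi,
                        "condition": cond,
                        "index": rng.uniform(0.1, 0.5),
                        "satisfaction_difference": ds,
                    }
                )
    report = build_stats_report(pd.DataFrame(rows))
    assert report.kw_three_way.df == 2
    assert report.kw_two_way.df == 1
    assert report.kw_three_way.group_sizes == (15, 15, 15)
    assert report.regression_right.df_resid == 27
    assert report.regression_left.n_rows == 30
    assert report.pearson.n == 15
    assert abs(report.pearson.r) <= 1
    d = report.to_dict()
    assert d["options"]["kw_roi"] == "frontal_right"
    assert report.to_json()  # serialisable
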