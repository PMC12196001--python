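"""Dyad-level statistics on the ROI x condition synchrony indexes.

Three analyses mirror the study's analytic plan:

* a Kruskal-Wallis rank test of the per-dyad indexes across the positive,
  negative and baseline conditions (and, with two groups, the emotion-
  combined vs. baseline contrast -- the same operation);
* an ordinary-least-squares regression per ROI of the index on the dyad's
  satisfaction difference and an emotion dummy (positive = 1), with the
  baseline condition excluded; and
* a Pearson correlation between the satisfaction difference and the
  frontal-right index averaged over the two emotion conditions.

The condition samples entering the Kruskal-Wallis are repeated measures on
the same dyads but are treated as independent groups, replicating the
original analysis; see the methods note for the caveat.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sst

from .errors import CollinearityError, UndefinedCorrelationError, ValidationError


@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    p: float
    group_sizes: tuple[int, ...]


@dataclass(frozen=True)
class TermStats:
    estimate: float
    se: float
    t: float
    p: float


@dataclass(frozen=True)
class RegressionResult:
    terms: dict[str, TermStats]
    df_resid: int
    n_rows: int


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p: float
    n: int


@dataclass
class StatsReport:
    """All statistics of one pipeline run, JSON-serialisable."""

    kw_three_way: KWResult
    kw_two_way: KWResult
    regression_right: RegressionResult
    regression_left: RegressionResult
    pearson: PearsonResult
    options: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)


def kruskal_wallis(groups: Sequence[np.ndarray]) -> KWResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square upper-tail p-value.

    ``df = len(groups) - 1``.  If every pooled value is identical the tie
    correction degenerates; H = 0 is returned with a warning.
    """
    if len(groups) < 2:
        raise ValidationError(f"need >= 2 groups, got {len(groups)}")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    sizes = tuple(a.size for a in arrays)
    if any(s == 0 for s in sizes):
        raise ValidationError("every group must be non-empty")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        warnings.warn("all pooled values identical; H = 0", stacklevel=2)
        return KWResult(H=0.0, df=df, p=1.0, group_sizes=sizes)
    H, p = sst.kruskal(*arrays)
    return KWResult(H=float(H), df=df, p=float(p), group_sizes=sizes)


def fit_distance_regression(data: pd.DataFrame) -> RegressionResult:
    """OLS of ``index ~ 1 + satisfaction_difference + emotion_dummy``.

    ``data`` must hold the emotion-condition rows only (baseline excluded),
    with columns ``index``, ``satisfaction_difference`` and either
    ``emotion_dummy`` (1 = positive) or ``condition`` in
    {positive, negative}.  Residual df = rows - 3.
    """
    df = data.copy()
    if "emotion_dummy" not in df.columns:
        if not set(df["condition"]).issubset({"positive", "negative"}):
            raise ValidationError(
                "regression rows must be positive/negative conditions only"
            )
        df["emotion_dummy"] = (df["condition"] == "positive").astype(float)
    if len(df) < 4:
        raise ValidationError(f"need >= 4 rows, got {len(df)}")
    X = np.column_stack(
        [
            np.ones(len(df)),
            df["satisfaction_difference"].to_numpy(float),
            df["emotion_dummy"].to_numpy(float),
        ]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("design matrix is rank deficient")
    y = df["index"].to_numpy(float)
    fit = sm.OLS(y, X).fit()
    names = ("intercept", "satisfaction_difference", "emotion_positive")
    terms = {
        name: TermStats(
            estimate=float(fit.params[i]),
            se=float(fit.bse[i]),
            t=float(fit.tvalues[i]),
            p=float(fit.pvalues[i]),
        )
        for i, name in enumerate(names)
    }
    return RegressionResult(terms=terms, df_resid=int(fit.df_resid), n_rows=len(df))


def pearson_corr(x: np.ndarray, y: np.ndarray) -> PearsonResult:
    """Pearson r with a two-tailed t-based p-value on n - 2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValidationError(f"need n >= 3, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("correlation undefined for constant input")
    r, p = sst.pearsonr(x, y)
    return PearsonResult(r=float(r), p=float(p), n=int(x.size))


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-tailed p for a given Pearson r at sample size n (t on n - 2 df)."""
    if not -1 < r < 1:
        raise ValidationError(f"|r| must be < 1, got {r}")
    if n < 3:
        raise ValidationError(f"need n >= 3, got {n}")
    t = abs(r) * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    return float(2 * sst.t.sf(t, n - 2))


def build_stats_report(
    roi_index: pd.DataFrame, kw_roi: str = "frontal_right"
) -> StatsReport:
    """Assemble the full report from the dyad x ROI x condition table.

    The Kruskal-Wallis contrasts use the ``kw_roi`` cluster (frontal right
    by default).  The two-group contrast compares each dyad's emotion index
    (mean of its positive and negative indexes) against its baseline index.
    The Pearson correlation relates the satisfaction difference to the
    frontal-right index averaged over the two emotion conditions.
    """
    required = {"dyad_id", "roi", "condition", "index", "satisfaction_difference"}
    missing = required - set(roi_index.columns)
    if missing:
        raise ValidationError(f"roi_index table lacks columns {sorted(missing)}")

    wide = roi_index.pivot_table(
        index=["dyad_id", "roi"], columns="condition", values="index", observed=True
    ).reset_index()
    ds = roi_index.groupby("dyad_id", observed=True)["satisfaction_difference"].first()

    cluster = wide[wide["roi"] == kw_roi].dropna(
        subset=["positive", "negative", "baseline"]
    )
    kw3 = kruskal_wallis(
        [cluster["positive"].to_numpy(), cluster["negative"].to_numpy(), cluster["baseline"].to_numpy()]
    )
    emotion = 0.5 * (cluster["positive"] + cluster["negative"])
    kw2 = kruskal_wallis([emotion.to_numpy(), cluster["baseline"].to_numpy()])

    regressions = {}
    for roi in ("frontal_right", "frontal_left"):
        rows = roi_index[
            (roi_index["roi"] == roi)
            & (roi_index["condition"].isin(["positive", "negative"]))
        ]
        regressions[roi] = fit_distance_regression(rows)

    right = cluster.set_index("dyad_id")
    pear = pearson_corr(
        ds.loc[right.index].to_numpy(),
        0.5 * (right["positive"] + right["negative"]).to_numpy(),
    )

    return StatsReport(
        kw_three_way=kw3,
        kw_two_way=kw2,
        regression_right=regressions["frontal_right"],
        regression_left=regressions["frontal_left"],
        pearson=pear,
        options={"kw_roi": kw_roi, "pearson_roi": "frontal_right"},
    )
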