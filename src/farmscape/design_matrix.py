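"""From metric tables to analysis-ready predictor matrices.

Proportional variables get the angular (arcsin-square-root) transform and
strictly continuous ones get ln(x + 1), stabilising the unit-sum constraint
and the influence of extreme values.  Spatial analyses model richness in one
period against that period's transformed variables; temporal analyses model
the change in richness (T1 - T0) against changes in the predictors.  By
default temporal deltas are differences of the *transformed* variables
(transform-then-difference keeps all deltas on comparable scales); raw-scale
differencing is available via ``delta_on_transformed=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import ALL_VARIABLES, DEFAULT_TRANSFORMS

__all__ = ["angular", "logtrans", "AnalysisMatrix", "build_matrix", "paired_t", "temporal_change_summary"]

MODES = ("spatial_T0", "spatial_T1", "temporal")


def angular(p):
    """Angular transform arcsin(sqrt(p)) of a proportion in [0, 1]."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        bad = p[(p < 0) | (p > 1)]
        raise ValueError(f"angular transform requires values in [0, 1], got {bad[:5]}")
    out = np.arcsin(np.sqrt(p))
    return float(out) if out.ndim == 0 else out


def logtrans(x, offset: float = 1.0):
    """ln(x + offset) for non-negative continuous variables (default offset 1)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError(f"logtrans requires non-negative values, got {x[x < 0][:5]}")
    out = np.log(x + offset)
    return float(out) if out.ndim == 0 else out


def _apply_transform(values: pd.Series, kind: str, log_offset: float) -> pd.Series:
    if kind == "angular_pct":
        if (values < 0).any() or (values > 100).any():
            raise ValueError(
                f"variable {values.name!r} declared a percentage but has values outside [0, 100]"
            )
        return pd.Series(angular(values / 100.0), index=values.index, name=values.name)
    if kind == "angular":
        return pd.Series(angular(values), index=values.index, name=values.name)
    if kind == "log":
        return pd.Series(logtrans(values, log_offset), index=values.index, name=values.name)
    if kind == "none":
        return values.astype(float)
    raise ValueError(f"unknown transform {kind!r} for variable {values.name!r}")


@dataclass
class AnalysisMatrix:
    """Response vector and transformed predictor matrix for one analysis.

    ``X`` is indexed by site_id with one column per landscape variable; ``y``
    is integer richness (spatial modes, Poisson/log models) or a real richness
    difference (temporal mode, Gaussian models).
    """

    X: pd.DataFrame
    y: pd.Series
    mode: str
    group: str

    @property
    def family(self) -> str:
        return "gaussian_identity" if self.mode == "temporal" else "poisson_log"

    @property
    def n(self) -> int:
        return len(self.y)


def build_matrix(
    metrics: pd.DataFrame,
    responses: pd.DataFrame,
    group: str = "all",
    mode: str = "spatial_T0",
    *,
    transforms: Mapping[str, str] | None = None,
    variables: Sequence[str] | None = None,
    delta_on_transformed: bool = True,
    log_offset: float = 1.0,
) -> AnalysisMatrix:
    """Assemble the analysis matrix for one habitat group and mode.

    Parameters
    ----------
    metrics
        Long table with columns ``site_id, period`` plus the landscape
        variables (as produced by :func:`~farmscape.landscape_metrics.metrics_table`).
    responses
        Richness table with columns ``site_id, period, group, richness``.
    mode
        ``spatial_T0`` / ``spatial_T1`` model one period; ``temporal`` models
        the change T1 - T0 in both response and predictors.

    Raises
    ------
    KeyError
        If a site/period required by the mode is missing in either table.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    transforms = DEFAULT_TRANSFORMS if transforms is None else transforms
    variables = [v for v in ALL_VARIABLES if v in metrics.columns] if variables is None else list(variables)

    resp = responses[responses["group"] == group]
    wide_y = resp.pivot(index="site_id", columns="period", values="richness")
    metric_p = {
        p: metrics[metrics["period"] == p].set_index("site_id")[variables]
        for p in metrics["period"].unique()
    }

    def _transformed(period: str) -> pd.DataFrame:
        tab = metric_p[period]
        return pd.DataFrame(
            {v: _apply_transform(tab[v], transforms.get(v, "none"), log_offset) for v in variables},
            index=tab.index,
        )

    if mode in ("spatial_T0", "spatial_T1"):
        period = mode.split("_")[1]
        if period not in metric_p:
            raise KeyError(f"metrics table has no rows for period {period!r}")
        X = _transformed(period)
        if period not in wide_y.columns:
            raise KeyError(f"responses have no rows for period {period!r}")
        y = wide_y[period]
    else:
        missing_p = {"T0", "T1"} - set(metric_p)
        if missing_p:
            raise KeyError(f"temporal mode requires both periods; missing {sorted(missing_p)}")
        if delta_on_transformed:
            X = _transformed("T1") - _transformed("T0")
        else:
            X = metric_p["T1"] - metric_p["T0"]
        y = wide_y["T1"] - wide_y["T0"]

    sites = X.index.intersection(y.dropna().index)
    missing = set(X.index).symmetric_difference(y.dropna().index)
    if missing:
        raise KeyError(f"sites missing from metrics or responses: {sorted(missing)[:10]}")
    X = X.loc[sites].sort_index()
    y = y.loc[sites].sort_index()
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing values in predictors {bad}")
    y = y.astype(float) if mode == "temporal" else y.astype(int)
    y.name = f"richness_{group}"
    return AnalysisMatrix(X=X, y=y, mode=mode, group=group)


def paired_t(x, y) -> dict[str, float]:
    """Two-sided paired t-test of ``y - x``.

    Returns ``{"t", "p", "mean_diff", "se"}`` with n-1 degrees of freedom.
    Raises ``ValueError`` when the differences have zero variance (the t
    statistic is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired_t requires two equal-length 1-D samples")
    if len(x) < 2:
        raise ValueError("paired_t requires n >= 2")
    d = y - x
    se = float(d.std(ddof=1) / math.sqrt(len(d)))
    if se == 0.0:
        raise ValueError("zero variance of paired differences: t statistic undefined")
    res = stats.ttest_rel(y, x)
    return {"t": float(res.statistic), "p": float(res.pvalue), "mean_diff": float(d.mean()), "se": se}


def temporal_change_summary(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-variable summary of temporal change between the two periods.

    For every landscape variable: mean +/- SE and min/max in each period, the
    mean +/- SE of the raw difference T1 - T0, and the paired t-test of that
    difference (NaN where the differences are constant).
    """
    variables = [v for v in ALL_VARIABLES if v in metrics.columns]
    t0 = metrics[metrics["period"] == "T0"].set_index("site_id")[variables].sort_index()
    t1 = metrics[metrics["period"] == "T1"].set_index("site_id")[variables].sort_index()
    if not t0.index.equals(t1.index):
        raise KeyError("temporal summary requires the same sites in both periods")
    n = len(t0)
    rows = []
    for v in variables:
        d = t1[v] - t0[v]
        try:
            test = paired_t(t0[v], t1[v])
        except ValueError:
            test = {"t": float("nan"), "p": float("nan")}
        rows.append(
            {
                "variable": v,
                "mean_T0": t0[v].mean(), "se_T0": t0[v].std(ddof=1) / math.sqrt(n),
                "min_T0": t0[v].min(), "max_T0": t0[v].max(),
                "mean_T1": t1[v].mean(), "se_T1": t1[v].std(ddof=1) / math.sqrt(n),
                "min_T1": t1[v].min(), "max_T1": t1[v].max(),
                "mean_delta": d.mean(), "se_delta": d.std(ddof=1) / math.sqrt(n),
                "t": test["t"], "p": test["p"],
            }
        )
    return pd.DataFrame(rows)
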