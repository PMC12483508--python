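"""Group-comparison statistics for neuron-level metrics.

Neuron-level metrics from multiple animals are nested observations: neurons
within an animal are not independent, and pooling them into a plain t-test
pseudoreplicates.  The primary comparison is therefore a linear mixed-effects
model, value ~ group with a random intercept per animal, reported with the
two-tailed t-statistic of the group fixed effect.  Classical two-sample tests
(Mann-Whitney U, Kolmogorov-Smirnov, unpaired t) are wrapped alongside for
non-nested comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

__all__ = [
    "ComparisonResult",
    "validate_metric_table",
    "lme_group_compare",
    "distribution_tests",
    "comparisons_frame",
]

REQUIRED_COLUMNS = ("neuron_id", "session_id", "animal_id", "group", "metric", "value")


@dataclass
class ComparisonResult:
    """A single standardized group comparison."""

    metric: str
    method: str
    estimate: float
    t_stat: float
    p_value: float
    n_per_group: dict
    df: float | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")


def comparisons_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Standardized report table, one row per comparison (CSV-ready)."""
    return pd.DataFrame(
        [
            dict(metric=r.metric, method=r.method, estimate=r.estimate,
                 t_stat=r.t_stat, p_value=r.p_value, df=r.df,
                 **{f"n_{k}": v for k, v in r.n_per_group.items()})
            for r in results
        ]
    )


def validate_metric_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format neuron metric table contract."""
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"metric table missing columns {sorted(missing)}")
    if not np.all(np.isfinite(table["value"].to_numpy(dtype=float))):
        raise ValueError("metric values must be finite")
    nested = table.groupby("neuron_id")[["session_id", "animal_id"]].nunique()
    if (nested > 1).any().any():
        raise ValueError("each neuron_id must belong to exactly one session and animal")
    return table


def lme_group_compare(
    table: pd.DataFrame,
    metric: str,
    grouping: str = "animal_id",
) -> ComparisonResult:
    """Mixed-effects group comparison of one neuron-level metric.

    Fits value ~ group with a random intercept per ``grouping`` unit
    (animal by default; pass ``session_id`` for session-level nesting) and
    reports the two-tailed t-statistic of the group fixed effect.  The
    p-value uses a t reference with df = (number of grouping units - 2) —
    the between-unit degrees of freedom — rather than the fitting library's
    normal approximation, which is anticonservative at the handful of
    animals typical of these designs; the df used is recorded on the result.
    Falls back to a plain OLS comparison with a warning when a group has a
    single grouping unit (no random-effect variance is estimable).
    """
    table = validate_metric_table(table)
    sub = table[table["metric"] == metric].copy()
    if sub.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    groups = sorted(sub["group"].unique())
    if len(groups) != 2:
        raise ValueError("expected exactly 2 groups")
    n_per = sub.groupby("group")["neuron_id"].nunique().to_dict()
    units = sub.groupby("group")[grouping].nunique()
    sub["__group"] = (sub["group"] == groups[1]).astype(float)
    if units.min() < 2:
        warnings.warn(
            "a group has a single grouping unit; falling back to OLS (no valid "
            "random-effect estimate)", stacklevel=2,
        )
        fit = smf.ols("value ~ __group", data=sub).fit()
        method = "ols_fallback"
        df = float(fit.df_resid)
        p = float(fit.pvalues["__group"])
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm("value ~ __group", data=sub, groups=sub[grouping]).fit(
                reml=True
            )
        method = "lme"
        df = float(sub[grouping].nunique() - 2)
        p = float(2.0 * stats.t.sf(abs(fit.tvalues["__group"]), df=df))
    return ComparisonResult(
        metric=metric,
        method=method,
        estimate=float(fit.params["__group"]),
        t_stat=float(fit.tvalues["__group"]),
        p_value=p,
        n_per_group=n_per,
        df=df,
    )


def distribution_tests(
    a: np.ndarray, b: np.ndarray, method: str = "mannwhitney", metric: str = ""
) -> ComparisonResult:
    """Two-sample distribution comparison (two-sided).

    method: ``mannwhitney`` (U statistic reported as t_stat), ``ks`` or ``t``.
    A fully tied Mann-Whitney comparison returns p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n_per = {"a": int(a.size), "b": int(b.size)}
    est = float(np.median(b) - np.median(a))
    if method == "mannwhitney":
        pooled = np.concatenate([a, b])
        if np.ptp(pooled) == 0:
            warnings.warn("all values tied: Mann-Whitney p set to 1", stacklevel=2)
            return ComparisonResult(metric, method, 0.0, a.size * b.size / 2, 1.0, n_per)
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return ComparisonResult(metric, method, est, float(res.statistic),
                                float(res.pvalue), n_per)
    if method == "ks":
        res = stats.ks_2samp(a, b)
        return ComparisonResult(metric, method, est, float(res.statistic),
                                float(res.pvalue), n_per)
    if method == "t":
        res = stats.ttest_ind(a, b)
        return ComparisonResult(metric, method, float(b.mean() - a.mean()),
                                float(res.statistic), float(res.pvalue), n_per)
    raise ValueError(f"unknown method {method!r}")
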