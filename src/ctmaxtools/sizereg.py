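"""Body-size regressions and per-group variance summaries.

CTmax is regressed on body size by ordinary least squares within each
day x treatment cell, with a two-sided t-test on the slope. Body-size units
are carried through opaquely ("size units"). Individuals without a size
measurement (e.g. an unphotographed replicate) are dropped from regression
with a logged count but are retained upstream for effect sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["RegressionResult", "fit_day_treatment", "fit_all", "variance_by_group"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegressionResult:
    day: int
    treatment: str
    slope: float
    intercept: float
    slope_se: float
    t_statistic: float
    p_value: float
    n: int
    group_variance: float
    fit_ok: bool


def _unfit(day: int, treatment: str, n: int, variance: float) -> RegressionResult:
    return RegressionResult(
        day=day,
        treatment=treatment,
        slope=np.nan,
        intercept=np.nan,
        slope_se=np.nan,
        t_statistic=np.nan,
        p_value=np.nan,
        n=n,
        group_variance=variance,
        fit_ok=False,
    )


def fit_day_treatment(
    records: pd.DataFrame, day: int | None = None, treatment: str | None = None
) -> RegressionResult:
    """OLS fit of ``ctmax_c`` on ``body_size`` for one day x treatment cell.

    Requires at least 3 records with both size and CTmax present; otherwise
    the result is flagged unfit (no slope test). ``group_variance`` is the
    unbiased sample variance of CTmax over the records used.
    """
    if day is None:
        day = int(records["day"].iloc[0]) if "day" in records else -1
    if treatment is None:
        treatment = str(records["treatment"].iloc[0]) if "treatment" in records else ""
    sub = records.dropna(subset=["body_size", "ctmax_c"])
    dropped = len(records) - len(sub)
    if dropped:
        logger.info(
            "day %s %s: dropped %d record(s) without body size", day, treatment, dropped
        )
    bad = sub[sub["body_size"] <= 0]
    if not bad.empty:
        raise ValueError(f"body_size must be > 0; {len(bad)} offending record(s)")
    n = len(sub)
    variance = float(sub["ctmax_c"].var(ddof=1)) if n >= 2 else np.nan
    if n < 3:
        return _unfit(day, treatment, n, variance)
    x = sub["body_size"].to_numpy(dtype=float)
    y = sub["ctmax_c"].to_numpy(dtype=float)
    if np.ptp(x) == 0.0:
        return _unfit(day, treatment, n, variance)
    res = sps.linregress(x, y)
    if res.stderr > 0:
        t_stat = res.slope / res.stderr
    else:
        t_stat = 0.0 if res.slope == 0 else np.inf
    return RegressionResult(
        day=day,
        treatment=treatment,
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        t_statistic=float(t_stat),
        p_value=float(res.pvalue),
        n=n,
        group_variance=variance,
        fit_ok=True,
    )


def fit_all(records: pd.DataFrame) -> pd.DataFrame:
    """Per-day, per-treatment OLS fits as a tidy frame (day ascending)."""
    rows = []
    for (day, treatment), sub in sorted(
        records.groupby(["day", "treatment"], sort=False).__iter__()
    ):
        rows.append(fit_day_treatment(sub, int(day), str(treatment)).__dict__)
    return pd.DataFrame(rows)


def variance_by_group(records: pd.DataFrame) -> pd.DataFrame:
    """Unbiased sample variance of CTmax per (day, treatment) cell.

    Cells with fewer than two values report an undefined (NaN) variance.
    """
    rows = []
    for (day, treatment), sub in sorted(
        records.groupby(["day", "treatment"], sort=False).__iter__()
    ):
        vals = sub["ctmax_c"].dropna()
        rows.append(
            {
                "day": int(day),
                "treatment": str(treatment),
                "variance_c2": float(vals.var(ddof=1)) if len(vals) >= 2 else np.nan,
                "n": int(len(vals)),
            }
        )
    return pd.DataFrame(rows)
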