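"""Mean-difference effect sizes with non-parametric bootstrap CIs.

Estimation-statistics style analysis: rather than null-hypothesis p-values,
treatment effects are reported as raw mean differences in degrees Celsius
with bootstrap confidence intervals. Two contrast schemes are supported:
each treatment group against the pre-treatment baseline on each day, and fed
against starved on each day.

The bootstrap resamples each group independently with replacement. For tiny
groups the percentile interval is computed from the *exhaustive* distribution
over all ``n_a**n_a * n_b**n_b`` equally likely resample pairs, which gives
exact, randomness-free endpoints; larger groups use seeded Monte Carlo.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "EffectSizeResult",
    "mean_difference",
    "bootstrap_ci",
    "contrast_table",
]

logger = logging.getLogger(__name__)

#: resample-space size below which percentile CIs are enumerated exactly
EXHAUSTIVE_LIMIT = 4096


@dataclass(frozen=True)
class GroupSample:
    """A group of CTmax values entering a contrast."""

    label: str
    day: int
    values: np.ndarray
    replicate: str = "pooled"
    replicates: np.ndarray | None = None  # per-value stratum labels

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.size == 0:
            raise ValueError(f"group {self.label} (day {self.day}): empty sample")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"group {self.label} (day {self.day}): non-finite values")
        if self.replicates is not None:
            reps = np.asarray(self.replicates)
            object.__setattr__(self, "replicates", reps)
            if reps.shape != values.shape:
                raise ValueError("replicates must align with values")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class EffectSizeResult:
    """Mean difference (group b minus group a) with its bootstrap CI."""

    group_a: str
    group_b: str
    day: int
    mean_diff: float
    ci_low: float
    ci_high: float
    ci_level: float
    n_a: int
    n_b: int
    n_boot: int
    seed: int
    method: str


def mean_difference(a: GroupSample, b: GroupSample) -> float:
    """Mean of group b minus mean of group a (negative = b lower)."""
    return float(np.mean(b.values) - np.mean(a.values))


def _resample_means(
    values: np.ndarray,
    strata: np.ndarray | None,
    n_boot: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bootstrap means of one group; optionally stratified by replicate."""
    n = values.size
    if strata is None:
        idx = rng.integers(0, n, size=(n_boot, n))
        return values[idx].mean(axis=1)
    total = np.zeros(n_boot)
    for label in pd.unique(strata):
        sub = values[strata == label]
        idx = rng.integers(0, sub.size, size=(n_boot, sub.size))
        total += sub[idx].sum(axis=1)
    return total / n


def _percentile(boots: np.ndarray, ci_level: float) -> tuple[float, float]:
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _exhaustive_diffs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All mean differences over the full product space of resamples.

    Every resample of a group of size n is an n-tuple of indices, each of the
    n**n tuples equally likely; only the multiset of drawn values matters for
    the mean, so we enumerate tuple means with their multiplicities via the
    cartesian product of index grids.
    """
    n_a, n_b = a.size, b.size
    grids_a = np.meshgrid(*([a] * n_a), indexing="ij")
    means_a = np.add.reduce(grids_a).ravel() / n_a
    grids_b = np.meshgrid(*([b] * n_b), indexing="ij")
    means_b = np.add.reduce(grids_b).ravel() / n_b
    return (means_b[None, :] - means_a[:, None]).ravel()


def _bca_interval(
    boots: np.ndarray,
    theta_hat: float,
    a_vals: np.ndarray,
    b_vals: np.ndarray,
    ci_level: float,
) -> tuple[float, float] | None:
    """Bias-corrected and accelerated interval; None if degenerate."""
    prop = np.mean(boots < theta_hat) + 0.5 * np.mean(boots == theta_hat)
    if prop <= 0.0 or prop >= 1.0:
        return None
    z0 = sps.norm.ppf(prop)
    # jackknife influence values over both groups
    jack = []
    mean_b = np.mean(b_vals)
    mean_a = np.mean(a_vals)
    for i in range(a_vals.size):
        jack.append(mean_b - np.mean(np.delete(a_vals, i)))
    for j in range(b_vals.size):
        jack.append(np.mean(np.delete(b_vals, j)) - mean_a)
    jack = np.asarray(jack)
    dev = jack.mean() - jack
    denom = 6.0 * np.sum(dev**2) ** 1.5
    if denom == 0.0:
        return None
    accel = np.sum(dev**3) / denom
    alpha = (1.0 - ci_level) / 2.0
    out = []
    for a_level in (alpha, 1.0 - alpha):
        z = sps.norm.ppf(a_level)
        adj = z0 + (z0 + z) / (1.0 - accel * (z0 + z))
        out.append(float(np.quantile(boots, sps.norm.cdf(adj))))
    return out[0], out[1]


def bootstrap_ci(
    a: GroupSample,
    b: GroupSample,
    n_boot: int = 5000,
    ci_level: float = 0.95,
    seed: int = 0,
    method: Literal["percentile", "bca"] = "bca",
    exhaustive: bool | Literal["auto"] = "auto",
) -> EffectSizeResult:
    """Mean difference b - a with a non-parametric bootstrap CI.

    Each group is resampled independently with replacement at its own size.
    ``method="bca"`` applies bias correction and acceleration (jackknife over
    both groups); zero-variance groups fall back to the percentile interval
    with a logged warning. When ``exhaustive`` is true (or "auto" and the
    resample space is small) the percentile interval is taken from the exact
    enumeration of all resample pairs.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must be in (0, 1)")
    if a.n < 2 or b.n < 2:
        raise ValueError(
            f"contrast {a.label} vs {b.label} (day {b.day}): "
            "each group needs >= 2 values"
        )
    theta_hat = mean_difference(a, b)
    space = a.n**a.n * b.n**b.n
    use_exhaustive = (
        method == "percentile"
        and a.replicates is None
        and b.replicates is None
        and (exhaustive is True or (exhaustive == "auto" and space <= EXHAUSTIVE_LIMIT))
    )
    if use_exhaustive:
        boots = _exhaustive_diffs(a.values, b.values)
        lo, hi = _percentile(boots, ci_level)
        used = "percentile-exhaustive"
    else:
        rng = np.random.default_rng(seed)
        means_a = _resample_means(a.values, a.replicates, n_boot, rng)
        means_b = _resample_means(b.values, b.replicates, n_boot, rng)
        boots = means_b - means_a
        used = method
        if method == "bca":
            interval = _bca_interval(boots, theta_hat, a.values, b.values, ci_level)
            if interval is None:
                logger.warning(
                    "BCa degenerate for %s vs %s (day %s); falling back to percentile",
                    a.label,
                    b.label,
                    b.day,
                )
                interval = _percentile(boots, ci_level)
                used = "percentile"
            lo, hi = interval
        else:
            lo, hi = _percentile(boots, ci_level)
    return EffectSizeResult(
        group_a=a.label,
        group_b=b.label,
        day=b.day,
        mean_diff=theta_hat,
        ci_low=lo,
        ci_high=hi,
        ci_level=ci_level,
        n_a=a.n,
        n_b=b.n,
        n_boot=int(boots.size) if use_exhaustive else n_boot,
        seed=seed,
        method=used,
    )


def _child_seeds(seed: int, n: int) -> list[int]:
    # 31-bit children so seeds remain portable small ints
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s & 0x7FFFFFFF) for s in state]


def contrast_table(
    data: pd.DataFrame,
    scheme: Literal["vs_baseline", "fed_vs_starved"],
    n_boot: int = 5000,
    ci_level: float = 0.95,
    seed: int = 0,
    method: Literal["percentile", "bca"] = "bca",
    stratify_by_replicate: bool = False,
    days: Sequence[int] | None = None,
) -> list[EffectSizeResult]:
    """Effect sizes for one contrast scheme across experimental days.

    ``data`` must carry columns ``ctmax_c``, ``day``, ``treatment`` and
    ``replicate``. Replicates are pooled within day x treatment by default;
    with ``stratify_by_replicate`` resampling is performed within replicate.
    Days with a missing group are skipped with a logged notice. Results are
    ordered by day ascending (then fed before starved for ``vs_baseline``).
    """
    required = {"ctmax_c", "day", "treatment", "replicate"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"data missing columns: {sorted(missing)}")

    def group(treatment: str, day: int) -> GroupSample | None:
        sel = data[(data["treatment"] == treatment) & (data["day"] == day)]
        if sel.empty:
            return None
        return GroupSample(
            label=treatment,
            day=day,
            values=sel["ctmax_c"].to_numpy(),
            replicates=sel["replicate"].to_numpy() if stratify_by_replicate else None,
        )

    if days is None:
        days = sorted(int(d) for d in data.loc[data["day"] > 0, "day"].unique())
    if scheme == "vs_baseline":
        baseline = group("baseline", 0)
        if baseline is None:
            raise ValueError("scheme vs_baseline requires a baseline (day 0) group")
        pairs = [
            (baseline, treatment, day)
            for day in days
            for treatment in ("fed", "starved")
        ]
    elif scheme == "fed_vs_starved":
        pairs = [(None, "starved", day) for day in days]
    else:
        raise ValueError(f"unknown scheme: {scheme}")

    seeds = _child_seeds(seed, len(pairs))
    results: list[EffectSizeResult] = []
    for (ref, treatment, day), child in zip(pairs, seeds):
        a = ref if ref is not None else group("fed", day)
        b = group(treatment, day)
        if a is None or b is None:
            logger.info(
                "skipping day %d contrast (%s): group missing", day, treatment
            )
            continue
        results.append(
            bootstrap_ci(
                a, b, n_boot=n_boot, ci_level=ci_level, seed=child, method=method
            )
        )
    return results


def results_to_frame(
    results: Sequence[EffectSizeResult], scheme: str
) -> pd.DataFrame:
    """Tidy data frame of effect-size results in the output CSV dialect."""
    return pd.DataFrame(
        {
            "scheme": scheme,
            "day": [r.day for r in results],
            "group_a": [r.group_a for r in results],
            "group_b": [r.group_b for r in results],
            "n_a": [r.n_a for r in results],
            "n_b": [r.n_b for r in results],
            "mean_diff_c": [r.mean_diff for r in results],
            "ci_low_c": [r.ci_low for r in results],
            "ci_high_c": [r.ci_high for r in results],
            "ci_level": [r.ci_level for r in results],
            "n_boot": [r.n_boot for r in results],
            "method": [r.method for r in results],
            "seed": [r.seed for r in results],
        }
    )
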