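"""Mean-difference effect sizes and bootstrap confidence intervals."""

import itertools
import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from ctmaxtools import GroupSample, bootstrap_ci, contrast_table, mean_difference
from ctmaxtools.effects import results_to_frame


def group(label, values, day=1, replicates=None):
    return GroupSample(label=label, day=day, values=np.asarray(values, float),
                       replicates=replicates)


def enumerate_percentile_ci(a, b, ci_level=0.95):
    """Independent oracle: percentile CI from the exact resample distribution.

    Enumerates every equally likely with-replacement resample pair via the
    cartesian product of index tuples and takes empirical quantiles with the
    standard linear-interpolation definition, computed by hand.
    """
    diffs = sorted(
        np.mean([b[j] for j in tb]) - np.mean([a[i] for i in ta])
        for ta in itertools.product(range(len(a)), repeat=len(a))
        for tb in itertools.product(range(len(b)), repeat=len(b))
    )
    out = []
    for q in ((1 - ci_level) / 2, 1 - (1 - ci_level) / 2):
        h = q * (len(diffs) - 1)
        k = int(np.floor(h))
        frac = h - k
        hi = diffs[min(k + 1, len(diffs) - 1)]
        out.append(diffs[k] + frac * (hi - diffs[k]))
    return tuple(out)


class TestMeanDifference:
    def test_identity(self):
        g = group("fed", [30.0, 31.0, 32.0])
        assert mean_difference(g, g) == 0.0

    def test_hand_arithmetic(self):
        a = group("fed", [30.0, 31.0])
        b = group("starved", [28.0, 29.0])
        assert mean_difference(a, b) == pytest.approx(-2.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            group("fed", [])


class TestBootstrapCI:
    def test_exhaustive_oracle_n2(self):
        """n=2 vs n=2: CI endpoints match full enumeration of 16 resample pairs."""
        a_vals, b_vals = [30.0, 31.0], [28.0, 29.0]
        res = bootstrap_ci(group("fed", a_vals), group("starved", b_vals),
                           method="percentile")
        lo, hi = enumerate_percentile_ci(a_vals, b_vals)
        assert res.ci_low == pytest.approx(lo, abs=1e-12)
        assert res.ci_high == pytest.approx(hi, abs=1e-12)
        assert res.method == "percentile-exhaustive"
        assert res.n_boot == 16

    def test_exhaustive_distribution_known_multiplicities(self):
        # resample means of each group give diffs {-3,-2.5,-2,-1.5,-1}
        # with binomial multiplicities {1,4,6,4,1}
        from ctmaxtools.effects import _exhaustive_diffs

        diffs = _exhaustive_diffs(np.array([30.0, 31.0]), np.array([28.0, 29.0]))
        values, counts = np.unique(diffs, return_counts=True)
        assert values.tolist() == [-3.0, -2.5, -2.0, -1.5, -1.0]
        assert counts.tolist() == [1, 4, 6, 4, 1]

    def test_exhaustive_oracle_n3(self):
        a_vals, b_vals = [30.0, 30.6, 31.4], [27.9, 29.1, 29.5]
        res = bootstrap_ci(group("fed", a_vals), group("starved", b_vals),
                           method="percentile")
        lo, hi = enumerate_percentile_ci(a_vals, b_vals)
        assert res.method == "percentile-exhaustive"
        assert res.ci_low == pytest.approx(lo, abs=1e-12)
        assert res.ci_high == pytest.approx(hi, abs=1e-12)

    def test_constant_equal_groups_degenerate_ci(self, caplog):
        a = group("fed", [30.0, 30.0])
        b = group("starved", [30.0, 30.0])
        res = bootstrap_ci(a, b, method="percentile")
        assert (res.ci_low, res.ci_high) == (0.0, 0.0)
        with caplog.at_level(logging.WARNING):
            res = bootstrap_ci(a, b, method="bca", exhaustive=False, n_boot=200)
        assert res.method == "percentile"  # BCa fell back
        assert (res.ci_low, res.ci_high) == (0.0, 0.0)
        assert any("falling back" in r.message for r in caplog.records)

    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        a = group("fed", rng.normal(35, 0.7, 40))
        b = group("starved", rng.normal(34, 1.0, 40))
        r1 = bootstrap_ci(a, b, seed=99, method="bca")
        r2 = bootstrap_ci(a, b, seed=99, method="bca")
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        r3 = bootstrap_ci(a, b, seed=100, method="bca")
        assert (r3.ci_low, r3.ci_high) != (r1.ci_low, r1.ci_high)

    @given(shift=st.floats(-10, 10), method=st.sampled_from(["percentile", "bca"]))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_translation_equivariance(self, shift, method):
        rng = np.random.default_rng(7)
        a_vals = rng.normal(35, 0.7, 15)
        b_vals = rng.normal(34, 1.2, 18)
        base = bootstrap_ci(group("fed", a_vals), group("starved", b_vals),
                            n_boot=500, seed=3, method=method)
        moved = bootstrap_ci(group("fed", a_vals), group("starved", b_vals + shift),
                             n_boot=500, seed=3, method=method)
        assert moved.mean_diff == pytest.approx(base.mean_diff + shift, abs=1e-9)
        assert moved.ci_low == pytest.approx(base.ci_low + shift, abs=1e-9)
        assert moved.ci_high == pytest.approx(base.ci_high + shift, abs=1e-9)

    def test_percentile_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(5)
        a = group("fed", rng.normal(35, 0.7, 30))
        b = group("starved", rng.normal(33, 1.5, 30))
        res = bootstrap_ci(a, b, method="percentile", n_boot=2000, seed=0)
        assert res.ci_low <= res.mean_diff <= res.ci_high

    def test_against_scipy_bootstrap(self):
        """Independent cross-check: scipy's percentile bootstrap agrees closely."""
        rng = np.random.default_rng(11)
        a_vals = rng.normal(35, 0.7, 60)
        b_vals = rng.normal(33.5, 1.4, 60)
        ours = bootstrap_ci(group("fed", a_vals), group("starved", b_vals),
                            method="percentile", n_boot=9999, seed=2)
        ref = sps.bootstrap(
            (b_vals, a_vals),
            lambda b, a, axis: np.mean(b, axis=axis) - np.mean(a, axis=axis),
            n_resamples=9999,
            method="percentile",
            confidence_level=0.95,
            random_state=np.random.default_rng(3),
        )
        assert ours.ci_low == pytest.approx(ref.confidence_interval.low, abs=0.08)
        assert ours.ci_high == pytest.approx(ref.confidence_interval.high, abs=0.08)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            bootstrap_ci(group("fed", [30.0]), group("starved", [28.0, 29.0]))


def make_table(days=5, n=12, delta_by_day=(0, 0, -1, -3, -5), seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for rep in (1, 2):
        for _ in range(n):
            rows.append(("baseline", 0, rep, rng.normal(35.0, 0.7)))
        for day in range(1, days + 1):
            for _ in range(n):
                rows.append(("fed", day, rep, rng.normal(35.0, 0.7)))
            for _ in range(n):
                rows.append(
                    ("starved", day, rep, rng.normal(35.0 + delta_by_day[day - 1], 0.7))
                )
    return pd.DataFrame(rows, columns=["treatment", "day", "replicate", "ctmax_c"])


class TestContrastTable:
    def test_fed_vs_starved_counts_and_order(self):
        df = make_table()
        results = contrast_table(df, "fed_vs_starved", n_boot=200, seed=1)
        assert len(results) == 5
        assert [r.day for r in results] == [1, 2, 3, 4, 5]
        assert all(r.group_a == "fed" and r.group_b == "starved" for r in results)

    def test_vs_baseline_counts(self):
        df = make_table()
        results = contrast_table(df, "vs_baseline", n_boot=200, seed=1)
        assert len(results) == 10  # fed and starved against baseline, days 1-5
        assert [(r.day, r.group_b) for r in results][:4] == [
            (1, "fed"), (1, "starved"), (2, "fed"), (2, "starved"),
        ]
        assert all(r.group_a == "baseline" for r in results)

    def test_missing_group_day_skipped(self, caplog):
        df = make_table()
        df = df[~((df["treatment"] == "starved") & (df["day"] > 3))]
        with caplog.at_level(logging.INFO, logger="ctmaxtools.effects"):
            results = contrast_table(df, "fed_vs_starved", n_boot=200, seed=1)
        assert [r.day for r in results] == [1, 2, 3]
        assert any("skipping" in r.message for r in caplog.records)

    def test_vs_baseline_requires_baseline(self):
        df = make_table()
        df = df[df["treatment"] != "baseline"]
        with pytest.raises(ValueError, match="baseline"):
            contrast_table(df, "vs_baseline", n_boot=100, seed=1)

    def test_results_frame_dialect(self):
        results = contrast_table(make_table(), "fed_vs_starved", n_boot=200, seed=1)
        frame = results_to_frame(results, "fed_vs_starved")
        assert list(frame.columns) == [
            "scheme", "day", "group_a", "group_b", "n_a", "n_b", "mean_diff_c",
            "ci_low_c", "ci_high_c", "ci_level", "n_boot", "method", "seed",
        ]

    def test_stratified_resampling_runs(self):
        df = make_table()
        res = contrast_table(df, "fed_vs_starved", n_boot=300, seed=4,
                             stratify_by_replicate=True, method="percentile")
        assert len(res) == 5
        assert all(r.ci_low <= r.mean_diff <= r.ci_high for r in res)
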