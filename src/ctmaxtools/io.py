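"""File validation, dataset assembly and the full analysis pipeline.

CSV dialects (UTF-8, header required):

* ``sensor_logs.csv`` -- trial_id, sensor_id, time_s, temp_c (one row per reading)
* ``trial_sheet.csv`` -- trial_id, individual_id, vial, replicate, day,
  treatment, stop_time_s, vials_remaining, excluded (0/1), exclusion_reason,
  body_size (optional)
* CTmax output -- trial_id, individual_id, ctmax_c, window_start_s,
  window_end_s, window_duration_s, sensor1_mean_c..sensor3_mean_c

Times are seconds from ramp start, temperatures degrees Celsius, day 0 is
the pre-treatment baseline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import effects, sizereg
from .estimation import SensorLog, StopRecord, estimate_trial

__all__ = [
    "SchemaError",
    "Dataset",
    "ExperimentManifest",
    "AnalysisSettings",
    "ReportBundle",
    "read_sensor_logs",
    "read_trial_sheet",
    "validate_and_load",
    "estimate_all",
    "run_full_analysis",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

LOG_COLUMNS = ["trial_id", "sensor_id", "time_s", "temp_c"]
SHEET_COLUMNS = [
    "trial_id",
    "individual_id",
    "replicate",
    "day",
    "treatment",
    "stop_time_s",
    "vials_remaining",
    "excluded",
]


class SchemaError(ValueError):
    """A file failed schema or referential-integrity validation."""


@dataclass(frozen=True)
class ExperimentManifest:
    """Paths making up one experiment's file set."""

    sensor_logs: Path
    trial_sheet: Path

    @classmethod
    def from_dir(cls, in_dir: str | Path) -> "ExperimentManifest":
        d = Path(in_dir)
        return cls(sensor_logs=d / "sensor_logs.csv", trial_sheet=d / "trial_sheet.csv")


@dataclass(frozen=True)
class Dataset:
    """Assembled experiment: per-trial sensor logs plus the trial sheet."""

    logs: Mapping[str, tuple[SensorLog, ...]]
    sheet: pd.DataFrame

    @property
    def n_excluded(self) -> int:
        return int(self.sheet["excluded"].sum())

    @property
    def n_individuals(self) -> int:
        return int(len(self.sheet))


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_sensor_logs(path: str | Path) -> dict[str, tuple[SensorLog, ...]]:
    """Read a sensor-log CSV into per-trial SensorLog triples."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, LOG_COLUMNS, str(path))
    out: dict[str, tuple[SensorLog, ...]] = {}
    for trial_id, trial_df in df.groupby("trial_id", sort=False):
        logs = []
        for sensor_id in sorted(trial_df["sensor_id"].unique()):
            sub = trial_df[trial_df["sensor_id"] == sensor_id].sort_values("time_s")
            logs.append(
                SensorLog(
                    str(sensor_id),
                    sub["time_s"].to_numpy(dtype=float),
                    sub["temp_c"].to_numpy(dtype=float),
                )
            )
        out[str(trial_id)] = tuple(logs)
    return out


def read_trial_sheet(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, SHEET_COLUMNS, str(path))
    df["excluded"] = df["excluded"].astype(int)
    bad = df[(~df["excluded"].astype(bool)) & (df["stop_time_s"].isna())]
    if not bad.empty:
        row = bad.index[0]
        raise SchemaError(
            f"{path}: row {row}: non-excluded individual without stop_time_s"
        )
    if "body_size" not in df.columns:
        df["body_size"] = np.nan
    return df


def validate_and_load(
    source: str | Path | ExperimentManifest,
) -> Dataset:
    """Load an experiment file set and check cross-file integrity.

    Every trial on the sheet must have exactly three sensor logs; every
    logged trial must be referenced by the sheet. Exclusion counts and
    fractions are logged.
    """
    manifest = (
        source
        if isinstance(source, ExperimentManifest)
        else ExperimentManifest.from_dir(source)
    )
    for p in (manifest.sensor_logs, manifest.trial_sheet):
        if not Path(p).exists():
            raise SchemaError(f"missing file: {p}")
    logs = read_sensor_logs(manifest.sensor_logs)
    sheet = read_trial_sheet(manifest.trial_sheet)
    sheet_trials = set(sheet["trial_id"].astype(str))
    unknown = sheet_trials - set(logs)
    if unknown:
        raise SchemaError(
            f"{manifest.trial_sheet}: stop records reference unknown trial(s): "
            f"{sorted(unknown)}"
        )
    orphans = set(logs) - sheet_trials
    if orphans:
        raise SchemaError(
            f"{manifest.sensor_logs}: trial(s) with no stop records: {sorted(orphans)}"
        )
    short = [t for t, ls in logs.items() if len(ls) != 3]
    if short:
        raise SchemaError(
            f"{manifest.sensor_logs}: trial(s) without exactly 3 sensors: {sorted(short)}"
        )
    ds = Dataset(logs=logs, sheet=sheet)
    total = ds.n_individuals
    n_exc = ds.n_excluded
    retained = total - n_exc
    logger.info(
        "loaded %d trials, %d individuals: %d retained, %d excluded "
        "(%.1f%% of all, %.1f%% of retained)",
        len(logs),
        total,
        retained,
        n_exc,
        100.0 * n_exc / total if total else 0.0,
        100.0 * n_exc / retained if retained else 0.0,
    )
    return ds


def estimate_all(
    dataset: Dataset, check_seconds: float = 5.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run CTmax estimation over every trial of a dataset.

    Returns the CTmax table (joined with day/treatment/replicate/body_size
    metadata) and an exclusions table.
    """
    est_rows, exc_rows = [], []
    meta_cols = ["individual_id", "replicate", "day", "treatment", "body_size"]
    for trial_id, trial_sheet in dataset.sheet.groupby("trial_id", sort=False):
        logs = dataset.logs[str(trial_id)]
        ordered = trial_sheet.sort_values(
            "stop_time_s", na_position="last", kind="mergesort"
        )
        stops = [
            StopRecord(
                individual_id=str(r.individual_id),
                stop_time=float(r.stop_time_s) if np.isfinite(r.stop_time_s) else np.nan,
                vials_remaining=int(r.vials_remaining)
                if np.isfinite(r.vials_remaining)
                else 0,
                excluded=bool(r.excluded),
                exclusion_reason=str(getattr(r, "exclusion_reason", "") or "") or None,
            )
            for r in ordered.itertuples()
        ]
        estimates, exclusions = estimate_trial(logs, stops, check_seconds)
        for est in estimates:
            est_rows.append(
                {
                    "trial_id": str(trial_id),
                    "individual_id": est.individual_id,
                    "ctmax_c": est.ctmax,
                    "window_start_s": est.window.t_start,
                    "window_end_s": est.window.t_end,
                    "window_duration_s": est.window.duration,
                    "sensor1_mean_c": est.per_sensor_means[0],
                    "sensor2_mean_c": est.per_sensor_means[1],
                    "sensor3_mean_c": est.per_sensor_means[2],
                }
            )
        for exc in exclusions:
            exc_rows.append(
                {
                    "trial_id": str(trial_id),
                    "individual_id": exc.individual_id,
                    "reason": exc.reason,
                }
            )
    est_df = pd.DataFrame(est_rows)
    meta = dataset.sheet[meta_cols].drop_duplicates("individual_id")
    if not est_df.empty:
        est_df = est_df.merge(meta, on="individual_id", how="left")
    exc_df = pd.DataFrame(exc_rows, columns=["trial_id", "individual_id", "reason"])
    return est_df, exc_df


@dataclass(frozen=True)
class AnalysisSettings:
    check_seconds: float = 5.0
    n_boot: int = 5000
    ci_level: float = 0.95
    ci_method: str = "bca"
    stratify_by_replicate: bool = False
    seed: int = 0


@dataclass(frozen=True)
class ReportBundle:
    ctmax: pd.DataFrame
    exclusions: pd.DataFrame
    effects_table: pd.DataFrame
    regressions: pd.DataFrame
    variances: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.ctmax.to_csv(out / "ctmax.csv", index=False)
        self.exclusions.to_csv(out / "exclusions.csv", index=False)
        self.effects_table.to_csv(out / "effects.csv", index=False)
        reg = self.regressions.copy()
        if "p_value" in reg.columns:
            reg["p_value"] = reg["p_value"].map(
                lambda p: f"{p:.2e}" if np.isfinite(p) else ""
            )
        reg.to_csv(out / "regressions.csv", index=False)
        self.variances.to_csv(out / "variances.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_full_analysis(
    source: str | Path | ExperimentManifest | Dataset,
    settings: AnalysisSettings = AnalysisSettings(),
) -> ReportBundle:
    """The complete pipeline: CTmax table, both contrast sets, regressions.

    Every random step is seeded from ``settings.seed``, so a rerun with the
    same inputs and settings reproduces the report bytes exactly.
    """
    try:
        dataset = (
            source if isinstance(source, Dataset) else validate_and_load(source)
        )
    except SchemaError as err:
        raise SchemaError(f"[load] {err}") from err

    try:
        ctmax_df, exc_df = estimate_all(dataset, settings.check_seconds)
    except Exception as err:
        raise RuntimeError(f"[estimate] {err}") from err

    seeds = effects._child_seeds(settings.seed, 2)
    tables = []
    try:
        for scheme, child in zip(("vs_baseline", "fed_vs_starved"), seeds):
            if scheme == "vs_baseline" and not (ctmax_df["treatment"] == "baseline").any():
                logger.info("no baseline group present; skipping vs_baseline contrasts")
                continue
            results = effects.contrast_table(
                ctmax_df,
                scheme,
                n_boot=settings.n_boot,
                ci_level=settings.ci_level,
                seed=child,
                method=settings.ci_method,
                stratify_by_replicate=settings.stratify_by_replicate,
            )
            tables.append(effects.results_to_frame(results, scheme))
    except Exception as err:
        raise RuntimeError(f"[effects] {err}") from err
    effects_df = (
        pd.concat(tables, ignore_index=True)
        if tables
        else effects.results_to_frame([], "none")
    )

    try:
        with_size = ctmax_df[ctmax_df["day"] > 0]
        regressions = sizereg.fit_all(with_size) if not with_size.empty else pd.DataFrame()
        variances = sizereg.variance_by_group(ctmax_df)
    except Exception as err:
        raise RuntimeError(f"[size_regression] {err}") from err

    total = dataset.n_individuals
    n_exc = dataset.n_excluded
    summary = {
        "schema_version": SCHEMA_VERSION,
        "n_trials": len(dataset.logs),
        "n_individuals": total,
        "n_excluded": n_exc,
        "exclusion_fraction_of_all": n_exc / total if total else 0.0,
        "exclusion_fraction_of_retained": n_exc / (total - n_exc) if total > n_exc else 0.0,
        "settings": {
            "check_seconds": settings.check_seconds,
            "n_boot": settings.n_boot,
            "ci_level": settings.ci_level,
            "ci_method": settings.ci_method,
            "stratify_by_replicate": settings.stratify_by_replicate,
            "seed": settings.seed,
        },
        "effect_sizes": effects_df.to_dict(orient="records"),
    }
    return ReportBundle(
        ctmax=ctmax_df,
        exclusions=exc_df,
        effects_table=effects_df,
        regressions=regressions,
        variances=variances,
        summary=summary,
    )
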