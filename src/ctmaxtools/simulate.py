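"""Synthetic CTmax ramping experiments.

Emulates a dynamic thermal-limit assay: a water bath warmed from 18 degrees C
by a fixed-output heater with imperfect insulation (so the ramp decelerates),
three temperature sensors with small offsets and read noise, ten vials per
assay each holding one individual, and a human observer cycling round-robin
through the vials at ~5 s per check. Individuals "die" (stop responding) when
the bath reaches their latent true CTmax; the observer records the stop time
and the number of vials spanning the final inter-check gap, which downstream
becomes the uncertainty window.

The default scenario reproduces the study design this package analyses: five
replicate experiments, a fed-baseline assay (day 0) then five daily assays
mixing fed controls and starved individuals, with the starved group's mean
CTmax dropping by {0, 0, -1, -3, -5} degrees C over days 1-5 and its
variance inflating. Absolute CTmax truth (35.0 +/- 0.7 degrees C) is a
configurable placeholder, not an empirical value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import SensorLog, StopRecord

__all__ = [
    "RampParams",
    "ScenarioConfig",
    "TrueIndividual",
    "TrialData",
    "ExperimentData",
    "mean_bath_path",
    "time_to_reach",
    "per_minute_rates",
    "simulate_ramp",
    "simulate_observer",
    "simulate_experiment",
]


@dataclass(frozen=True)
class RampParams:
    """Physics of one temperature ramp.

    The noiseless bath temperature solves the Newtonian-loss ODE
    ``dT/dt = heat_rate - loss_coeff * (T - t0)`` (rates per minute), i.e. a
    ramp that starts at ``heat_rate`` degrees C/min and decelerates as the
    bath warms -- the signature of a fixed-output heater in an imperfectly
    insulated reservoir. Defaults keep every per-minute average rate inside
    the 0.1-0.3 degrees C/min target envelope over the working range.
    """

    t0_c: float = 18.0
    heat_rate_c_per_min: float = 0.3
    loss_coeff_per_min: float = 0.008
    sensor_noise_sd_c: float = 0.05
    sensor_offsets_c: tuple[float, float, float] = (-0.1, 0.0, 0.1)
    log_interval_s: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 < self.heat_rate_c_per_min <= 1.0):
            raise ValueError("heat_rate_c_per_min must be in (0, 1]")
        if self.loss_coeff_per_min < 0:
            raise ValueError("loss_coeff_per_min must be >= 0 (non-monotone path rejected)")
        if self.sensor_noise_sd_c < 0 or self.log_interval_s <= 0:
            raise ValueError("invalid sensor noise or log interval")
        if len(self.sensor_offsets_c) != 3:
            raise ValueError("exactly 3 sensor offsets required")

    @property
    def asymptote_c(self) -> float:
        if self.loss_coeff_per_min == 0:
            return math.inf
        return self.t0_c + self.heat_rate_c_per_min / self.loss_coeff_per_min


def mean_bath_path(params: RampParams, t_s: np.ndarray | float) -> np.ndarray | float:
    """Noiseless bath temperature at time(s) ``t_s`` seconds after ramp start."""
    t_min = np.asarray(t_s, dtype=float) / 60.0
    r, k, t0 = params.heat_rate_c_per_min, params.loss_coeff_per_min, params.t0_c
    if k == 0:
        out = t0 + r * t_min
    else:
        out = t0 + (r / k) * (1.0 - np.exp(-k * t_min))
    return float(out) if np.isscalar(t_s) else out


def time_to_reach(params: RampParams, temp_c: float) -> float:
    """Seconds until the noiseless path first reaches ``temp_c`` (0 if below start)."""
    if temp_c <= params.t0_c:
        return 0.0
    if temp_c >= params.asymptote_c:
        raise ValueError(
            f"temperature {temp_c} degrees C unreachable (asymptote "
            f"{params.asymptote_c:.2f} degrees C)"
        )
    r, k = params.heat_rate_c_per_min, params.loss_coeff_per_min
    rise = temp_c - params.t0_c
    if k == 0:
        return 60.0 * rise / r
    return -60.0 * math.log(1.0 - k * rise / r) / k


def per_minute_rates(params: RampParams, duration_s: float) -> np.ndarray:
    """Average ramping rate (degrees C/min) over each whole minute of the ramp."""
    n_min = int(duration_s // 60)
    if n_min < 1:
        raise ValueError("duration shorter than one minute")
    edges = np.arange(n_min + 1) * 60.0
    temps = mean_bath_path(params, edges)
    return np.diff(temps)


def simulate_ramp(
    params: RampParams, duration_s: float, seed: int | np.random.Generator = 0
) -> list[SensorLog]:
    """Three sensor logs for one ramp: mean path + per-sensor offset + noise."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = np.arange(0.0, duration_s + 0.5 * params.log_interval_s, params.log_interval_s)
    base = mean_bath_path(params, times)
    logs = []
    for i, offset in enumerate(params.sensor_offsets_c, start=1):
        noise = rng.normal(0.0, params.sensor_noise_sd_c, size=times.size)
        logs.append(SensorLog(f"s{i}", times, base + offset + noise))
    return logs


@dataclass(frozen=True)
class TrueIndividual:
    """Latent truth for one simulated individual (tests-only downstream)."""

    individual_id: str
    true_ctmax_c: float
    body_size: float
    treatment: str
    day: int
    replicate: int
    excluded: bool = False


def simulate_observer(
    individuals: Sequence[TrueIndividual],
    params: RampParams,
    check_seconds: float = 5.0,
    t_max_s: float = math.inf,
) -> tuple[list[StopRecord], list[str]]:
    """Round-robin observer over the vials of one trial.

    The observer spends ``check_seconds`` per vial in a fixed cycle over the
    vials still in the bath. An individual is scored unresponsive at the
    first check ending strictly after its death time (the moment the
    noiseless bath path crosses its true CTmax); its vial is then removed.
    The recorded ``vials_remaining`` is the number of vials that were in the
    bath at the individual's previous check (itself included), so the
    uncertainty window ``vials_remaining * check_seconds`` reproduces the
    true inter-check gap exactly.

    Returns the stop records (in detection order) and the ids of individuals
    never detected before ``t_max_s`` (non-empty marks the trial incomplete).
    """
    active = [ind for ind in individuals if not ind.excluded]
    death = {ind.individual_id: time_to_reach(params, ind.true_ctmax_c) for ind in active}
    remaining = list(active)
    gap_count = {ind.individual_id: len(remaining) for ind in remaining}
    records: list[StopRecord] = []
    t = 0.0
    while remaining and t < t_max_s:
        for ind in list(remaining):
            t += check_seconds
            if t > t_max_s:
                break
            if death[ind.individual_id] < t:
                records.append(
                    StopRecord(
                        individual_id=ind.individual_id,
                        stop_time=t,
                        vials_remaining=gap_count[ind.individual_id],
                    )
                )
                remaining.remove(ind)
            else:
                gap_count[ind.individual_id] = len(remaining)
    return records, [ind.individual_id for ind in remaining]


@dataclass(frozen=True)
class ScenarioConfig:
    """Generator parameters for a full multi-replicate experiment.

    ``starved_delta_by_day_c`` is the per-day shift of the starved group's
    mean CTmax relative to fed (the study's effect trajectory);
    ``starved_sd_mult_by_day`` inflates the starved group's SD over days.
    ``terminations`` maps a replicate id to its last completed day (total
    starved mortality ends a replicate early). Replicates listed in
    ``unphotographed_replicates`` have body sizes withheld from the trial
    sheet (sizes enter analysis only through it).
    """

    n_replicates: int = 5
    n_days: int = 5
    n_per_assay: int = 10
    check_seconds: float = 5.0
    ramp: RampParams = field(default_factory=RampParams)
    fed_mean_c: float = 35.0  # placeholder truth, not an empirical value
    fed_sd_c: float = 0.7
    starved_delta_by_day_c: tuple[float, ...] = (0.0, 0.0, -1.0, -3.0, -5.0)
    starved_sd_mult_by_day: tuple[float, ...] = (1.0, 1.0, 1.5, 2.0, 3.0)
    exclusion_prob: float = 0.06
    size_mean: float = 0.9
    size_sd: float = 0.08
    size_slope_by_day: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0)
    group_size: int = 15
    terminations: dict[int, int] = field(default_factory=dict)
    unphotographed_replicates: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_assay < 1 or self.n_replicates < 1 or self.n_days < 1:
            raise ValueError("n_per_assay, n_replicates and n_days must be >= 1")
        if self.fed_sd_c <= 0 or self.size_sd <= 0:
            raise ValueError("standard deviations must be > 0")
        for name in ("starved_delta_by_day_c", "starved_sd_mult_by_day", "size_slope_by_day"):
            if len(getattr(self, name)) < self.n_days:
                raise ValueError(f"{name} must cover all {self.n_days} days")
        if not 0.0 <= self.exclusion_prob < 1.0:
            raise ValueError("exclusion_prob must be in [0, 1)")
        if self.check_seconds <= 0:
            raise ValueError("check_seconds must be > 0")

    def starved_sd_by_day_c(self) -> tuple[float, ...]:
        return tuple(self.fed_sd_c * m for m in self.starved_sd_mult_by_day)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["terminations"] = {str(k): v for k, v in self.terminations.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "ramp" in d and isinstance(d["ramp"], dict):
            ramp = dict(d["ramp"])
            if "sensor_offsets_c" in ramp:
                ramp["sensor_offsets_c"] = tuple(ramp["sensor_offsets_c"])
            d["ramp"] = RampParams(**ramp)
        for name in (
            "starved_delta_by_day_c",
            "starved_sd_mult_by_day",
            "size_slope_by_day",
            "unphotographed_replicates",
        ):
            if name in d and d[name] is not None:
                d[name] = tuple(d[name])
        if "terminations" in d and d["terminations"]:
            d["terminations"] = {int(k): int(v) for k, v in d["terminations"].items()}
        return cls(**d)


@dataclass(frozen=True)
class TrialData:
    """One assay: three sensor logs plus stop records and latent truth."""

    trial_id: str
    replicate: int
    day: int
    logs: tuple[SensorLog, SensorLog, SensorLog]
    stops: tuple[StopRecord, ...]
    individuals: tuple[TrueIndividual, ...]
    death_times: dict[str, float]


@dataclass(frozen=True)
class ExperimentData:
    """A complete simulated experiment, convertible to the CSV file set."""

    config: ScenarioConfig
    trials: tuple[TrialData, ...]

    def logs_frame(self) -> pd.DataFrame:
        parts = []
        for trial in self.trials:
            for log in trial.logs:
                parts.append(
                    pd.DataFrame(
                        {
                            "trial_id": trial.trial_id,
                            "sensor_id": log.sensor_id,
                            "time_s": log.times,
                            "temp_c": log.temps,
                        }
                    )
                )
        return pd.concat(parts, ignore_index=True)

    def sheet_frame(self) -> pd.DataFrame:
        rows = []
        for trial in self.trials:
            hide_size = trial.replicate in self.config.unphotographed_replicates
            stop_by_id = {s.individual_id: s for s in trial.stops}
            for vial, ind in enumerate(trial.individuals, start=1):
                stop = stop_by_id.get(ind.individual_id)
                rows.append(
                    {
                        "trial_id": trial.trial_id,
                        "individual_id": ind.individual_id,
                        "vial": vial,
                        "replicate": trial.replicate,
                        "day": trial.day,
                        "treatment": ind.treatment,
                        "stop_time_s": stop.stop_time if stop else np.nan,
                        "vials_remaining": stop.vials_remaining if stop else np.nan,
                        "excluded": int(ind.excluded),
                        "exclusion_reason": "abnormal behavior" if ind.excluded else "",
                        "body_size": np.nan if hide_size else ind.body_size,
                    }
                )
        return pd.DataFrame(rows)

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for trial in self.trials:
            for ind in trial.individuals:
                rows.append(
                    {
                        "trial_id": trial.trial_id,
                        "individual_id": ind.individual_id,
                        "true_ctmax_c": ind.true_ctmax_c,
                        "death_time_s": trial.death_times.get(ind.individual_id, np.nan),
                        "body_size": ind.body_size,
                        "treatment": ind.treatment,
                        "day": trial.day,
                        "replicate": trial.replicate,
                        "excluded": int(ind.excluded),
                    }
                )
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path, write_truth: bool = True) -> None:
        """Write the CSV file set (truth goes to a separate tests-only path)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.logs_frame().to_csv(out / "sensor_logs.csv", index=False)
        self.sheet_frame().to_csv(out / "trial_sheet.csv", index=False)
        if write_truth:
            truth_dir = out / "truth"
            truth_dir.mkdir(exist_ok=True)
            self.truth_frame().to_csv(
                truth_dir / "truth.csv", index=False
            )


def _draw_sizes(rng: np.random.Generator, n: int, cfg: ScenarioConfig) -> np.ndarray:
    sizes = rng.normal(cfg.size_mean, cfg.size_sd, size=n)
    return np.clip(sizes, 0.1 * cfg.size_mean, None)


def _simulate_trial(
    cfg: ScenarioConfig,
    replicate: int,
    day: int,
    individuals: list[TrueIndividual],
    rng: np.random.Generator,
) -> TrialData:
    included = [ind for ind in individuals if not ind.excluded]
    if not included:
        raise ValueError(f"trial r{replicate}d{day}: every individual excluded")
    hottest = max(ind.true_ctmax_c for ind in included)
    duration = time_to_reach(cfg.ramp, max(hottest, cfg.ramp.t0_c + 0.01)) + 120.0
    duration = math.ceil(duration / cfg.ramp.log_interval_s) * cfg.ramp.log_interval_s
    logs = simulate_ramp(cfg.ramp, duration, rng)
    stops, unreached = simulate_observer(included, cfg.ramp, cfg.check_seconds, duration)
    if unreached:
        raise RuntimeError(
            f"trial r{replicate}d{day} incomplete: {unreached} not detected by ramp end"
        )
    death_times = {
        ind.individual_id: time_to_reach(cfg.ramp, ind.true_ctmax_c) for ind in included
    }
    return TrialData(
        trial_id=f"r{replicate}d{day}",
        replicate=replicate,
        day=day,
        logs=tuple(logs),
        stops=tuple(stops),
        individuals=tuple(individuals),
        death_times=death_times,
    )


def simulate_experiment(config: ScenarioConfig) -> ExperimentData:
    """Simulate the full replicated design.

    Each replicate runs a fed baseline assay (day 0) and then one mixed assay
    per day, drawing half its individuals from three fed holding groups and
    half from three starved groups without replacement, in randomised vial
    order. True CTmax values are drawn at assay time from the day-dependent
    treatment distributions; exclusions (abnormal behaviour before the ramp)
    occur independently per individual. The whole experiment is a pure
    function of the config, including its seed.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    rep_seeds = root.spawn(cfg.n_replicates)
    trials: list[TrialData] = []
    deltas = cfg.starved_delta_by_day_c
    sds = cfg.starved_sd_by_day_c()
    slopes = cfg.size_slope_by_day
    counter = 0

    for rep_idx, rep_ss in enumerate(rep_seeds, start=1):
        rng = np.random.default_rng(rep_ss)
        last_day = cfg.terminations.get(rep_idx, cfg.n_days)

        # day 0: baseline assay, all recently fed
        base_inds = []
        for _ in range(cfg.n_per_assay):
            counter += 1
            base_inds.append(
                TrueIndividual(
                    individual_id=f"i{counter:05d}",
                    true_ctmax_c=float(rng.normal(cfg.fed_mean_c, cfg.fed_sd_c)),
                    body_size=float(_draw_sizes(rng, 1, cfg)[0]),
                    treatment="baseline",
                    day=0,
                    replicate=rep_idx,
                    excluded=bool(rng.random() < cfg.exclusion_prob),
                )
            )
        trials.append(_simulate_trial(cfg, rep_idx, 0, base_inds, rng))

        # six holding groups: three fed, three starved
        pools = {"fed": [], "starved": []}
        for treatment in ("fed", "starved"):
            for g in range(3):
                for m in range(cfg.group_size):
                    pools[treatment].append(f"{treatment[0]}{g + 1}m{m + 1}")
        for treatment in pools:
            rng.shuffle(pools[treatment])

        n_fed = cfg.n_per_assay // 2
        n_starved = cfg.n_per_assay - n_fed
        for day in range(1, last_day + 1):
            picks: list[TrueIndividual] = []
            for treatment, n_pick in (("fed", n_fed), ("starved", n_starved)):
                pool = pools[treatment]
                if len(pool) < n_pick:
                    raise ValueError(
                        f"replicate {rep_idx}: holding groups exhausted on day {day}; "
                        "increase group_size"
                    )
                chosen, pools[treatment] = pool[:n_pick], pool[n_pick:]
                for _ in chosen:
                    counter += 1
                    size = float(_draw_sizes(rng, 1, cfg)[0])
                    if treatment == "fed":
                        mu, sd = cfg.fed_mean_c, cfg.fed_sd_c
                        coupling = 0.0
                    else:
                        mu = cfg.fed_mean_c + deltas[day - 1]
                        sd = sds[day - 1]
                        coupling = slopes[day - 1] * (size - cfg.size_mean)
                    picks.append(
                        TrueIndividual(
                            individual_id=f"i{counter:05d}",
                            true_ctmax_c=float(rng.normal(mu, sd) + coupling),
                            body_size=size,
                            treatment=treatment,
                            day=day,
                            replicate=rep_idx,
                            excluded=bool(rng.random() < cfg.exclusion_prob),
                        )
                    )
            order = rng.permutation(len(picks))
            trials.append(
                _simulate_trial(cfg, rep_idx, day, [picks[i] for i in order], rng)
            )

    return ExperimentData(config=replace(cfg), trials=tuple(trials))
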