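"""Synthetic flock generator.

Emulates the statistical structure of a commercial broiler integration's
weekly performance table: two sexes, a latent two-group feed-efficiency
structure (HE/LE) with 35-d FCR means near 1.37–1.53, logistic-shaped mean
BW trajectories on the scale of real Ross 308 AP flocks, multiplicative
between-flock noise with CVs of roughly 3–7%, and positive right-skewed
weekly mortality.

Every flock's mean BW lies exactly on its group's growth curve; observation
noise is multiplicative lognormal (mean one) so that zero-CV datasets
reproduce the generating curve exactly and sample means converge to it.
Cumulative feed intake is derived as FI = FCR x BW, guaranteeing internal
consistency of the (BW, FI, FCR) triad the pipeline consumes.  All draws
flow from a single seeded generator, so a config replays bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import reference
from .models import LOGISTIC, MODEL_TAGS, Params, predict_bw
from .records import DEFAULT_AGES, EFFICIENCIES, FlockRecord, SEXES, WeeklySeries


class ConfigError(ValueError):
    """The generator configuration is incomplete or inconsistent."""


@dataclass
class GeneratorConfig:
    """Generating conditions for a synthetic flock dataset.

    Defaults reproduce the published group-level conditions: logistic group
    means per (sex, efficiency) cell, BW CVs of 3.4–6.5% by age, 35-d FCR
    means of 1.371–1.527 with a between-flock SD of 0.02, and mean weekly
    mortality of ~0.55%.
    """

    n_flocks_per_group: int = 50
    model: str = LOGISTIC
    group_params: Mapping[tuple[str, str], Params] = field(
        default_factory=lambda: dict(reference.LOGISTIC_GROUP_MEANS)
    )
    ages: tuple[int, ...] = DEFAULT_AGES
    bw_cv: Mapping[int, float] | float = field(
        default_factory=lambda: dict(reference.BW_CV_BY_AGE)
    )
    fcr35_means: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(reference.FCR35_GROUP_MEANS)
    )
    fcr35_sd: float = 0.02
    fcr_shape_cv: float = 2.0  # % noise on pre-35-d FCR points
    fcr_trajectories: Mapping[tuple[str, str], Mapping[int, float]] = field(
        default_factory=lambda: dict(reference.FCR_TRAJECTORIES)
    )
    mort_weekly_mean: float = reference.MORT_WEEKLY_MEAN
    mort_shape: float = 9.0  # gamma shape; CV = 1/sqrt(shape) ~ 33%
    seed: int = 0

    def validate(self) -> None:
        if self.n_flocks_per_group < 1:
            raise ConfigError("n_flocks_per_group must be >= 1")
        if self.model not in MODEL_TAGS:
            raise ConfigError(f"unknown generating model {self.model!r}")
        if self.fcr35_sd < 0 or self.fcr_shape_cv < 0:
            raise ConfigError("noise magnitudes must be >= 0")
        for m in self.fcr35_means.values():
            if m <= 1.0:
                raise ConfigError("35-d FCR means must exceed 1.0")
        if isinstance(self.bw_cv, (int, float)):
            if self.bw_cv < 0:
                raise ConfigError("bw_cv must be >= 0")
        elif any(v < 0 for v in self.bw_cv.values()):
            raise ConfigError("bw_cv must be >= 0")

    def cv_at(self, age: int) -> float:
        if isinstance(self.bw_cv, (int, float)):
            return float(self.bw_cv)
        return float(self.bw_cv[age])


def _lognormal_factor(rng: np.random.Generator, cv_pct: float, size: int) -> np.ndarray:
    """Mean-one multiplicative noise with the given CV in percent."""
    if cv_pct == 0.0:
        return np.ones(size)
    sigma2 = math.log1p((cv_pct / 100.0) ** 2)
    sigma = math.sqrt(sigma2)
    return np.exp(rng.normal(-sigma2 / 2.0, sigma, size=size))


def simulate_flock(
    sex: str,
    efficiency: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
    flock_id: str | None = None,
) -> FlockRecord:
    """Draw one flock from its (sex, efficiency) cell.

    BW at each age is the group growth curve times mean-one lognormal noise;
    35-d FCR is drawn around the group mean (truncated > 1); earlier FCR
    points rescale the group's trajectory template to that terminal value;
    FI = FCR x BW; weekly mortality is gamma-distributed and accumulated.
    """
    key = (sex, efficiency)
    if key not in config.group_params:
        raise ConfigError(f"no growth parameters configured for group {key}")
    if key not in config.fcr35_means or key not in config.fcr_trajectories:
        raise ConfigError(f"no FCR configuration for group {key}")
    params = config.group_params[key]
    ages = np.asarray(config.ages, dtype=float)

    bw_mean = np.asarray(predict_bw(config.model, params, ages), dtype=float)
    noise = np.array(
        [_lognormal_factor(rng, config.cv_at(int(a)), 1)[0] for a in config.ages]
    )
    bw = bw_mean * noise

    fcr35 = 0.0
    while fcr35 <= 1.0:
        fcr35 = rng.normal(config.fcr35_means[key], config.fcr35_sd)
    traj = config.fcr_trajectories[key]
    last_age = config.ages[-1]
    fcr = np.full(len(ages), np.nan)
    for j, a in enumerate(config.ages[1:], start=1):
        ratio = traj[a] / traj[last_age]
        if a == last_age:
            fcr[j] = fcr35
        else:
            fcr[j] = ratio * fcr35 * _lognormal_factor(rng, config.fcr_shape_cv, 1)[0]
    fi = fcr * bw  # cumulative feed intake, consistent by construction

    week_mort = np.full(len(ages), np.nan)
    n_weeks = len(ages) - 1
    if config.mort_weekly_mean > 0:
        draws = rng.gamma(
            config.mort_shape, config.mort_weekly_mean / config.mort_shape, size=n_weeks
        )
    else:
        draws = np.zeros(n_weeks)
    week_mort[1:] = draws
    cum_mort = np.full(len(ages), np.nan)
    cum_mort[1:] = np.cumsum(draws)

    series = WeeklySeries(
        ages=config.ages, bw=bw, fi=fi, fcr=fcr, week_mort=week_mort, cum_mort=cum_mort
    )
    if flock_id is None:
        flock_id = f"{sex[0].upper()}-{efficiency}-{rng.integers(10**9):09d}"
    return FlockRecord(flock_id=flock_id, sex=sex, series=series)


def simulate_dataset(
    config: GeneratorConfig,
) -> tuple[list[FlockRecord], pd.DataFrame]:
    """Simulate all (sex x efficiency) cells.

    Returns the records plus a ground-truth table (one row per flock) with
    the latent efficiency label, the generating parameters and the drawn
    noiseless 35-d FCR — the oracle for parameter- and partition-recovery
    tests.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[FlockRecord] = []
    truth_rows: list[dict[str, object]] = []
    for sex in SEXES:
        for eff in EFFICIENCIES:
            key = (sex, eff)
            if key not in config.group_params:
                continue
            params = config.group_params[key]
            for i in range(config.n_flocks_per_group):
                fid = f"{sex[0].upper()}-{eff}-{i:04d}"
                rec = simulate_flock(sex, eff, config, rng, flock_id=fid)
                records.append(rec)
                row: dict[str, object] = {
                    "flock_id": fid,
                    "sex": sex,
                    "efficiency": eff,
                    "model": config.model,
                    "fcr35": rec.fcr35,
                    "fcr35_group_mean": config.fcr35_means[key],
                }
                for name, value in zip(params.__dataclass_fields__, params.as_array()):
                    row[f"true_{name}"] = value
                truth_rows.append(row)
    return records, pd.DataFrame(truth_rows)
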