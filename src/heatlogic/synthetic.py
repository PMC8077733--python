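"""Synthetic meteorology and overdispersed daily counts with planted heat effects.

Real ED-visit series are protected health information, so every downstream
module is exercised on data from this generator instead.  It emulates the
relevant structure of a 20-year mid-latitude station record and of daily
ED-visit counts:

* hourly dry-bulb/dew-point temperature over full calendar years, built from
  a seasonal sinusoid peaking in mid-July plus an AR(1) daily anomaly (so
  extreme days cluster into multi-day runs) plus a diurnal cycle;
* daily counts drawn from a negative binomial with variance phi * mean, whose
  log-mean carries seasonal, day-of-week, holiday and secular year structure,
  a smooth temperature response, and a multiplicative extreme-heat effect
  exp(log RR) on days selected by a planted Boolean rule.

Three planted exposure scenarios over lagged indicators of daily minimum
apparent temperature (ATMN) exceeding its 98th percentile:

    E1 (same-day)            H = X1
    E2 (sustained 2-day)     H = X1 AND X2
    E3 (2-day lagged only)   H = NOT X1 AND X2 AND X3

With the default calibration the warm-season frequencies of E1/E2/E3 days
over 20 seasons land near 146/73/29, the regime the method is meant for.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import meteorology as met
from .meteorology import ExposureIndicatorMatrix, HeatMetricSpec, warm_season_mask

__all__ = [
    "WeatherGenConfig",
    "OutcomeProfile",
    "ScenarioSpec",
    "SimulatedDataset",
    "CIRC_PROFILE",
    "RENAL_PROFILE",
    "HEAT_PROFILE",
    "simulate_hourly_weather",
    "scenario_exposure",
    "baseline_mean_series",
    "simulate_counts",
    "holidays_frame",
    "simulate_dataset",
]


@dataclass(frozen=True)
class WeatherGenConfig:
    """Parameters of the synthetic station record (all temperatures degC)."""

    n_years: int = 20
    start_year: int = 1993
    annual_mean: float = 17.0          # yearly mean dry-bulb
    seasonal_amplitude: float = 10.5   # peak-to-mean seasonal swing
    peak_doy: int = 196                # mid-July
    rho: float = 0.75                  # AR(1) coefficient of daily anomalies
    anomaly_sd: float = 2.4            # marginal SD of daily anomalies
    diurnal_amplitude: float = 5.0     # half daily temperature range
    hourly_noise_sd: float = 0.4
    dewpoint_gap_mean: float = 6.0     # dry bulb minus dew point, daily
    dewpoint_gap_sd: float = 2.0
    dewpoint_gap_rho: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        for name in ("anomaly_sd", "hourly_noise_sd", "dewpoint_gap_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _ar1(n: int, rho: float, marginal_sd: float, rng) -> np.ndarray:
    """Stationary AR(1) series with the given marginal standard deviation."""
    innov_sd = marginal_sd * np.sqrt(1 - rho**2)
    x = np.empty(n)
    x[0] = rng.normal(0, marginal_sd)
    eps = rng.normal(0, innov_sd, size=n)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + eps[t]
    return x


def simulate_hourly_weather(config: WeatherGenConfig | None = None,
                            seed: int | None = None) -> pd.DataFrame:
    """Hourly dry-bulb and dew-point temperature over full calendar years.

    Daily mean = seasonal sinusoid + AR(1) anomaly; hourly values add a
    diurnal sinusoid (minimum near 05:00, maximum mid-afternoon) and small
    noise; dew point sits below dry bulb by a slowly varying positive gap.
    Deterministic given the seed.
    """
    cfg = config or WeatherGenConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)

    start = pd.Timestamp(year=cfg.start_year, month=1, day=1)
    end = pd.Timestamp(year=cfg.start_year + cfg.n_years - 1, month=12, day=31)
    days = pd.date_range(start, end, freq="D")
    n_days = len(days)

    doy = days.dayofyear.to_numpy().astype(float)
    seasonal = cfg.annual_mean + cfg.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - cfg.peak_doy) / 365.25
    )
    daily_mean = seasonal + _ar1(n_days, cfg.rho, cfg.anomaly_sd, rng)
    gap = cfg.dewpoint_gap_mean + _ar1(
        n_days, cfg.dewpoint_gap_rho, cfg.dewpoint_gap_sd, rng
    )
    gap = np.clip(gap, 0.5, None)

    hours = np.arange(24, dtype=float)
    diurnal = -cfg.diurnal_amplitude * np.cos(2 * np.pi * (hours - 17.0) / 24.0)
    dry = (
        daily_mean[:, None]
        + diurnal[None, :]
        + rng.normal(0, cfg.hourly_noise_sd, size=(n_days, 24))
    )
    dew = dry - gap[:, None] + rng.normal(0, 0.2, size=(n_days, 24))
    dew = np.minimum(dew, dry)  # dew point cannot exceed dry bulb

    timestamps = (
        days.to_numpy().repeat(24) + np.tile(hours, n_days).astype("timedelta64[h]")
    )
    return pd.DataFrame(
        {
            "timestamp": pd.DatetimeIndex(timestamps),
            "dry_bulb_c": dry.ravel(),
            "dew_point_c": dew.ravel(),
        }
    )


# ---------------------------------------------------------------------------
# Outcome profiles and scenarios


@dataclass(frozen=True)
class OutcomeProfile:
    """Log-linear mean structure of a synthetic daily outcome series.

    ``baseline_mean`` anchors the warm-season average daily count;
    ``phi`` is the negative-binomial overdispersion (variance = phi * mean).
    Effects are on the log scale.
    """

    name: str
    baseline_mean: float
    phi: float
    season_log_amp: float          # within-year sinusoidal swing
    year_log_range: float          # total secular trend, first to last year
    dow_log: tuple[float, ...]     # Monday..Sunday offsets
    holiday_log: float
    temp_slope: float              # per degC of truncated daily metric

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.phi < 1:
            raise ValueError("phi must be >= 1 (variance >= mean)")
        if len(self.dow_log) != 7:
            raise ValueError("dow_log must have 7 entries (Monday..Sunday)")


#: High-count profile: circulatory-disease-like (mean ~623/day).
CIRC_PROFILE = OutcomeProfile(
    name="CIRC", baseline_mean=623.0, phi=2.0, season_log_amp=0.05,
    year_log_range=1.0, dow_log=(0.10, 0.05, 0.03, 0.02, 0.04, -0.06, -0.10),
    holiday_log=-0.15, temp_slope=0.003,
)

#: Mid-count profile: renal-disease-like (mean ~139/day).
RENAL_PROFILE = OutcomeProfile(
    name="RENAL", baseline_mean=139.0, phi=1.5, season_log_amp=0.10,
    year_log_range=1.2, dow_log=(0.08, 0.04, 0.02, 0.02, 0.03, -0.05, -0.08),
    holiday_log=-0.12, temp_slope=0.010,
)

#: Low-count profile: heat-illness-like (mean ~2.5/day), strongly heat-driven.
HEAT_PROFILE = OutcomeProfile(
    name="HEAT", baseline_mean=2.5, phi=1.2, season_log_amp=0.9,
    year_log_range=0.4, dow_log=(0.0, 0.0, 0.0, 0.0, 0.05, 0.05, 0.0),
    holiday_log=0.0, temp_slope=0.08,
)

_PROFILES = {"CIRC": CIRC_PROFILE, "RENAL": RENAL_PROFILE, "HEAT": HEAT_PROFILE}

_SCENARIOS = ("E1", "E2", "E3")


@dataclass(frozen=True)
class ScenarioSpec:
    """A planted exposure rule, its true RR and the outcome profile."""

    scenario: str                      # "E1" | "E2" | "E3"
    true_rr: float = 1.05              # typically 1.01 or 1.05
    profile: OutcomeProfile = CIRC_PROFILE
    percentile: int = 98
    metric: HeatMetricSpec = HeatMetricSpec("AT", "MN")

    def __post_init__(self) -> None:
        if self.scenario not in _SCENARIOS:
            raise ValueError(f"scenario must be one of {_SCENARIOS}")
        if self.true_rr <= 0:
            raise ValueError("true_rr must be positive")


def scenario_exposure(indicators: ExposureIndicatorMatrix | pd.DataFrame,
                      scenario: str) -> pd.Series:
    """Evaluate the planted Boolean rule per day on the lagged indicator matrix."""
    X = indicators.X if isinstance(indicators, ExposureIndicatorMatrix) else indicators
    x1, x2, x3 = (X.iloc[:, j] for j in range(3))
    if scenario == "E1":
        h = x1
    elif scenario == "E2":
        h = x1 * x2
    elif scenario == "E3":
        h = (1 - x1) * x2 * x3
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return h.rename(f"H_{scenario}")


def holidays_frame(dates: pd.DatetimeIndex) -> pd.DataFrame:
    """Two warm-season holiday indicators: federal (Memorial Day, July 4,
    Labor Day) and a fixed synthetic state holiday (Aug 15)."""
    fed = np.zeros(len(dates))
    state = np.zeros(len(dates))
    for i, d in enumerate(dates):
        if d.month == 7 and d.day == 4:
            fed[i] = 1
        elif d.month == 5 and d.dayofweek == 0 and d.day > 24:  # last Monday of May
            fed[i] = 1
        elif d.month == 9 and d.dayofweek == 0 and d.day <= 7:  # first Monday of Sep
            fed[i] = 1
        if d.month == 8 and d.day == 15:
            state[i] = 1
    return pd.DataFrame({"holiday_fed": fed, "holiday_state": state}, index=dates)


def baseline_mean_series(dates: pd.DatetimeIndex, profile: OutcomeProfile,
                         temp_trunc: pd.Series | None = None) -> pd.Series:
    """Daily mean counts mu_t without the extreme-heat effect.

    Combines the profile's seasonal sinusoid, secular year trend, day-of-week
    and holiday offsets, and a linear response to the truncated daily heat
    metric; the intercept is set so the warm-season average equals
    ``baseline_mean``.
    """
    doy = dates.dayofyear.to_numpy().astype(float)
    log_mu = profile.season_log_amp * np.cos(2 * np.pi * (doy - 196.0) / 365.25)

    years = dates.year.to_numpy()
    uy = np.unique(years)
    if len(uy) > 1:
        frac = (years - uy[0]) / (uy[-1] - uy[0])
        log_mu = log_mu + profile.year_log_range * (frac - 0.5)

    dow = dates.dayofweek.to_numpy()
    log_mu = log_mu + np.asarray(profile.dow_log)[dow]

    hol = holidays_frame(dates)
    log_mu = log_mu + profile.holiday_log * (
        hol["holiday_fed"].to_numpy() + hol["holiday_state"].to_numpy()
    )

    if temp_trunc is not None:
        t = temp_trunc.reindex(dates).to_numpy()
        log_mu = log_mu + profile.temp_slope * (t - np.nanmean(t))

    mu = np.exp(log_mu)
    mu *= profile.baseline_mean / np.nanmean(mu)
    return pd.Series(mu, index=dates, name=f"mu_{profile.name}")


def simulate_counts(mu, H=None, log_rr: float = 0.0, phi: float = 1.0,
                    seed: int | np.random.Generator | None = 0) -> np.ndarray:
    """Negative-binomial counts with mean mu * exp(log_rr * H), variance phi * mean.

    Parameterized so the quasi-Poisson dispersion is recoverable: the NB size
    is mu / (phi - 1); phi = 1 degenerates to the Poisson.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or not np.all(np.isfinite(mu)):
        raise ValueError("means must be positive and finite")
    if phi < 1:
        raise ValueError("phi must be >= 1")
    if H is not None:
        mu = mu * np.exp(log_rr * np.asarray(H, dtype=float))
    if phi == 1.0:
        return rng.poisson(mu)
    size = mu / (phi - 1.0)
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


@dataclass
class SimulatedDataset:
    """One synthetic realisation: weather, counts and the full truth record."""

    hourly: pd.DataFrame
    counts: pd.Series                    # warm-season daily counts
    holidays: pd.DataFrame
    spec: ScenarioSpec
    true_H: pd.Series                    # warm-season planted exposure (0/1)
    mu0: pd.Series                       # baseline means (no heat effect)
    indicators: ExposureIndicatorMatrix  # truth-metric lag matrix, warm season
    daily_metric: pd.Series              # full-record daily truth metric
    threshold: met.ThresholdSpec


def simulate_dataset(
    spec: ScenarioSpec,
    weather_config: WeatherGenConfig | None = None,
    seed: int = 0,
    hourly: pd.DataFrame | None = None,
    max_lag: int = 3,
) -> SimulatedDataset:
    """Generate (or reuse) weather and draw one counts realisation.

    Weather and counts use independent seeded streams; pass a precomputed
    ``hourly`` frame to hold meteorology fixed across replicates, as when a
    single observed record is reused.
    """
    cfg = weather_config or WeatherGenConfig()
    if hourly is None:
        hourly = simulate_hourly_weather(cfg, seed=cfg.seed)

    daily = met.daily_metric(hourly, spec.metric)
    thr = met.percentile_threshold(daily, spec.percentile, metric=spec.metric)
    ind = met.extreme_indicator(daily, thr)
    lagm = met.lag_matrix(ind, max_lag=max_lag, metric=spec.metric, threshold=thr)

    season = warm_season_mask(pd.DatetimeIndex(lagm.X.index))
    Xw = lagm.X.loc[season].dropna()
    dates = pd.DatetimeIndex(Xw.index)
    lag_season = ExposureIndicatorMatrix(X=Xw, metric=spec.metric, threshold=thr)

    true_H = scenario_exposure(lag_season, spec.scenario)
    trunc = met.truncate_at_threshold(daily, thr)
    mu0 = baseline_mean_series(dates, spec.profile, temp_trunc=trunc)

    count_rng = np.random.default_rng(np.random.SeedSequence([seed, 1_000_003]))
    y = simulate_counts(
        mu0.to_numpy(), true_H.to_numpy(), np.log(spec.true_rr), spec.profile.phi,
        seed=count_rng,
    )
    counts = pd.Series(y, index=dates, name=spec.profile.name)
    return SimulatedDataset(
        hourly=hourly,
        counts=counts,
        holidays=holidays_frame(dates),
        spec=spec,
        true_H=true_H,
        mu0=mu0,
        indicators=lag_season,
        daily_metric=daily,
        threshold=thr,
    )
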