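"""Daily heat metrics, percentile thresholds and lagged extreme-heat indicators.

Hourly dry-bulb and dew-point temperature are reduced to six daily heat
metrics — the maximum (MX), minimum (MN) and average (Avg) of either
dry-bulb temperature (T) or apparent temperature (AT).  For a chosen metric
a percentile threshold over the station record defines a binary *extreme
indicator* (1 when the daily value strictly exceeds the threshold), which is
then lagged to form the predictor matrix for logic-tree learning.

Apparent temperature combines air temperature and humidity:

    AT = -1.3 + 0.92*T + 2.2*e

with T the dry-bulb temperature in degC and e the water vapor pressure in
kPa, derived here from dew point with the Magnus-Tetens formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HeatMetricSpec",
    "ThresholdSpec",
    "ExposureIndicatorMatrix",
    "water_vapor_pressure",
    "apparent_temperature",
    "daily_metric",
    "percentile_threshold",
    "extreme_indicator",
    "lag_matrix",
    "truncate_at_threshold",
    "lag123_mean",
    "warm_season_mask",
    "ALL_METRICS",
]

WARM_SEASON_START = (5, 1)   # May 1
WARM_SEASON_END = (9, 30)    # Sep 30

# Magnus-Tetens saturation vapor pressure over water (kPa)
_MAGNUS_A = 0.6112
_MAGNUS_B = 17.67
_MAGNUS_C = 243.5


@dataclass(frozen=True)
class HeatMetricSpec:
    """One of the six daily heat metrics: {T, AT} x {MX, MN, Avg}."""

    variable: str   # "T" (dry-bulb) or "AT" (apparent)
    statistic: str  # "MX", "MN", "Avg"

    def __post_init__(self) -> None:
        if self.variable not in ("T", "AT"):
            raise ValueError(f"unknown variable {self.variable!r}; expected 'T' or 'AT'")
        if self.statistic not in ("MX", "MN", "Avg"):
            raise ValueError(f"unknown statistic {self.statistic!r}; expected 'MX', 'MN' or 'Avg'")

    @property
    def name(self) -> str:
        """Field-conventional short name, e.g. 'ATMN' or 'TAvg'."""
        return f"{self.variable}{self.statistic}"

    @classmethod
    def from_name(cls, name: str) -> "HeatMetricSpec":
        for var in ("AT", "T"):
            if name.startswith(var):
                return cls(var, name[len(var):])
        raise ValueError(f"cannot parse heat metric name {name!r}")


#: All six valid metric specifications, in a fixed lexicographic order.
ALL_METRICS: tuple[HeatMetricSpec, ...] = tuple(
    HeatMetricSpec(v, s) for v in ("AT", "T") for s in ("Avg", "MN", "MX")
)


@dataclass(frozen=True)
class ThresholdSpec:
    """A percentile threshold of a daily metric over a basis date set."""

    percentile: int          # 95, 98 or 99
    value: float             # degC
    n_basis: int             # number of non-missing basis values
    metric: HeatMetricSpec | None = None

    def __post_init__(self) -> None:
        if self.percentile not in (95, 98, 99):
            raise ValueError("percentile must be one of 95, 98, 99")


@dataclass
class ExposureIndicatorMatrix:
    """Per-day binary indicators X_1..X_{L+1}: column ell is the lag-ell indicator.

    ``X.iloc[t, ell]`` equals the lag-0 indicator on day t-ell; the first
    ``max_lag`` dates carry NaN where the lagged value predates the record.
    """

    X: pd.DataFrame  # index: dates; columns: lag0..lagL; values 0/1/NaN
    metric: HeatMetricSpec
    threshold: ThresholdSpec

    @property
    def max_lag(self) -> int:
        return self.X.shape[1] - 1

    @property
    def labels(self) -> list[str]:
        return list(self.X.columns)


def water_vapor_pressure(dew_point):
    """Water vapor pressure (kPa) from dew-point temperature (degC).

    Saturation vapor pressure over water evaluated at the dew point, via the
    Magnus-Tetens approximation e = 0.6112 * exp(17.67*Td / (Td + 243.5)).
    """
    td = np.asarray(dew_point, dtype=float)
    if not np.all(np.isfinite(td)):
        raise ValueError("dew_point must be finite")
    e = _MAGNUS_A * np.exp(_MAGNUS_B * td / (td + _MAGNUS_C))
    return e if e.ndim else float(e)


def apparent_temperature(T, e):
    """Apparent temperature (degC) from dry-bulb T (degC) and vapor pressure e (kPa)."""
    T = np.asarray(T, dtype=float)
    e = np.asarray(e, dtype=float)
    if not (np.all(np.isfinite(T)) and np.all(np.isfinite(e))):
        raise ValueError("inputs to apparent_temperature must be finite")
    at = -1.3 + 0.92 * T + 2.2 * e
    return at if at.ndim else float(at)


def _hourly_variable(hourly: pd.DataFrame, variable: str) -> pd.Series:
    if variable == "T":
        return hourly["dry_bulb_c"]
    if "apparent_c" in hourly.columns:
        return hourly["apparent_c"]
    e = water_vapor_pressure(hourly["dew_point_c"].to_numpy())
    return pd.Series(
        apparent_temperature(hourly["dry_bulb_c"].to_numpy(), e),
        index=hourly.index,
        name="apparent_c",
    )


def validate_hourly(hourly: pd.DataFrame) -> pd.DataFrame:
    """Check an hourly weather frame; warn on physically suspect rows.

    Requires columns ``timestamp, dry_bulb_c, dew_point_c`` (optional
    ``apparent_c``) with strictly increasing timestamps.
    """
    required = {"timestamp", "dry_bulb_c", "dew_point_c"}
    missing = required - set(hourly.columns)
    if missing:
        raise ValueError(f"hourly weather missing columns: {sorted(missing)}")
    ts = pd.to_datetime(hourly["timestamp"])
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise ValueError("hourly timestamps must be strictly increasing")
    excess = hourly["dew_point_c"] > hourly["dry_bulb_c"] + 0.5
    if excess.any():
        warnings.warn(
            f"{int(excess.sum())} hourly rows have dew point above dry bulb "
            "(beyond 0.5 degC tolerance)",
            stacklevel=2,
        )
    out = hourly.copy()
    out["timestamp"] = ts
    return out


def daily_metric(
    hourly: pd.DataFrame,
    spec: HeatMetricSpec,
    min_hours: int = 18,
) -> pd.Series:
    """Aggregate hourly weather to a daily heat metric.

    Days with fewer than ``min_hours`` hourly observations are set missing.
    Returns a Series indexed by calendar date.
    """
    if not 1 <= min_hours <= 24:
        raise ValueError("min_hours must be in 1..24")
    if len(hourly) == 0:
        return pd.Series(dtype=float, name=spec.name)
    hourly = validate_hourly(hourly)
    values = _hourly_variable(hourly, spec.variable)
    date = hourly["timestamp"].dt.normalize()
    grouped = values.groupby(date.values)
    agg = {"MX": "max", "MN": "min", "Avg": "mean"}[spec.statistic]
    out = grouped.agg(agg)
    n = grouped.count()
    out[n < min_hours] = np.nan
    out.name = spec.name
    out.index = pd.DatetimeIndex(out.index, name="date")
    return out


def percentile_threshold(
    daily: pd.Series,
    percentile: int,
    basis_dates: pd.DatetimeIndex | None = None,
    metric: HeatMetricSpec | None = None,
    min_basis: int = 100,
) -> ThresholdSpec:
    """Percentile threshold of a daily metric over a basis date set.

    Uses linear interpolation between order statistics (quantile type 7),
    so thresholds are deterministic and bit-reproducible.  ``basis_dates``
    restricts the basis (default: every non-missing date in ``daily``).
    """
    basis = daily if basis_dates is None else daily.loc[daily.index.isin(basis_dates)]
    vals = basis.dropna().to_numpy()
    if vals.size < min_basis:
        raise ValueError(
            f"threshold basis has {vals.size} values; at least {min_basis} required"
        )
    value = float(np.quantile(vals, percentile / 100.0, method="linear"))
    return ThresholdSpec(percentile=percentile, value=value, n_basis=vals.size, metric=metric)


def extreme_indicator(daily: pd.Series, threshold: ThresholdSpec) -> pd.Series:
    """Binary extreme indicator: 1 iff the daily value strictly exceeds the threshold.

    Ties go to non-extreme; missing daily values stay missing.
    """
    out = (daily > threshold.value).astype(float)
    out[daily.isna()] = np.nan
    out.name = f"{daily.name}_gt_p{threshold.percentile}"
    return out


def lag_matrix(
    indicator: pd.Series,
    max_lag: int = 3,
    metric: HeatMetricSpec | None = None,
    threshold: ThresholdSpec | None = None,
) -> ExposureIndicatorMatrix:
    """Stack an indicator and its lags 1..max_lag into a predictor matrix.

    Column ``lag{l}`` at date t holds the indicator at date t-l, aligned on
    calendar dates (a gap in the record yields NaN rather than the previous
    row's value).
    """
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    idx = pd.DatetimeIndex(indicator.index)
    cols = {}
    for ell in range(max_lag + 1):
        cols[f"lag{ell}"] = indicator.reindex(idx - pd.Timedelta(days=ell)).to_numpy()
    X = pd.DataFrame(cols, index=idx)
    return ExposureIndicatorMatrix(X=X, metric=metric, threshold=threshold)


def truncate_at_threshold(daily: pd.Series, threshold: ThresholdSpec) -> pd.Series:
    """Cap the daily metric at the threshold value (values above become the threshold)."""
    out = daily.clip(upper=threshold.value)
    out.name = f"{daily.name}_trunc{threshold.percentile}"
    return out


def lag123_mean(daily: pd.Series) -> pd.Series:
    """Mean of the previous three days' values (lags 1-3); missing if any lag is.

    Alignment is by calendar date, so gaps in the record propagate missingness.
    """
    if len(daily) < 4:
        raise ValueError("need at least 4 days of data for a lag 1-3 mean")
    idx = pd.DatetimeIndex(daily.index)
    lags = np.column_stack(
        [daily.reindex(idx - pd.Timedelta(days=ell)).to_numpy() for ell in (1, 2, 3)]
    )
    out = pd.Series(lags.mean(axis=1), index=idx, name=f"{daily.name}_lag123mean")
    return out


def warm_season_mask(dates: pd.DatetimeIndex) -> np.ndarray:
    """Boolean mask selecting May 1 through Sep 30 dates."""
    m, d = dates.month, dates.day
    start = (m > WARM_SEASON_START[0]) | ((m == WARM_SEASON_START[0]) & (d >= WARM_SEASON_START[1]))
    end = (m < WARM_SEASON_END[0]) | ((m == WARM_SEASON_END[0]) & (d <= WARM_SEASON_END[1]))
    return np.asarray(start & end)
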