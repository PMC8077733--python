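"""Three-stage estimation of an extreme-heat exposure definition and its RR.

Stage 1 fits the quasi-Poisson time-series model *without* the exposure term,
adjusting for (truncated) continuous temperature, humidity, season, year,
day-of-week, holidays and hospital availability.  Stage 2 feeds the Pearson
residuals to logic regression over lagged extreme-heat indicators: 10-fold
cross-validation picks the tree size, simulated annealing finds the tree, and
the reference group is oriented so exposed days are the minority.  Stage 3
refits the full model with the learned binary exposure H(X_t) and reports
RR = exp(beta_H).

`run_grid` repeats the three stages over the heat-metric x percentile grid
(6 metrics x 3 thresholds by default) and selects the cell with the smallest
QAIC.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import logictree as lt
from . import meteorology as met
from . import tsmodel as ts
from .meteorology import ALL_METRICS, HeatMetricSpec, warm_season_mask

__all__ = [
    "LogicConfig",
    "GridSpec",
    "CellResult",
    "PipelineResult",
    "stage1_fit",
    "stage2_logic",
    "stage3_refit",
    "run_cell",
    "run_grid",
    "describe_exposure",
    "conventional_heatwave",
    "fill_gaps_alternative",
]

logger = logging.getLogger(__name__)


@dataclass
class LogicConfig:
    """Stage-2 learning configuration (tree sizes, annealing, CV)."""

    candidate_sizes: tuple[int, ...] = (0, 1, 2, 3)
    n_folds: int = 10
    cv_schedule: lt.AnnealingSchedule = field(
        default_factory=lambda: lt.AnnealingSchedule(n_iterations=2000)
    )
    final_schedule: lt.AnnealingSchedule = field(
        default_factory=lambda: lt.AnnealingSchedule(n_iterations=5000)
    )
    cv_restarts: int = 1
    final_restarts: int = 3
    cv_blocked: bool = False  # contiguous CV blocks instead of random days


@dataclass
class GridSpec:
    """The heat-metric x percentile search grid."""

    metrics: tuple[HeatMetricSpec, ...] = ALL_METRICS
    percentiles: tuple[int, ...] = (95, 98, 99)
    max_lag: int = 3
    truncation: bool = True
    threshold_basis: str = "full"  # "full" record or "warm_season"

    def __post_init__(self) -> None:
        if not self.metrics or not self.percentiles:
            raise ValueError("grid must contain at least one metric and one percentile")


def _cell_seed(master_seed: int, metric: HeatMetricSpec, percentile: int) -> int:
    tag = zlib.crc32(f"{metric.name}:{percentile}".encode())
    return int(np.random.SeedSequence([master_seed, tag]).generate_state(1)[0] % (2**31))


def _continuous_covariates(
    hourly: pd.DataFrame,
    metric: HeatMetricSpec,
    threshold: met.ThresholdSpec,
    truncation: bool,
    min_hours: int = 18,
) -> pd.DataFrame:
    """Same-day metric (optionally truncated), lag 1-3 mean, and max dew point."""
    daily = met.daily_metric(hourly, metric, min_hours=min_hours)
    base = met.truncate_at_threshold(daily, threshold) if truncation else daily
    out = pd.DataFrame({"t": base, "tbar": met.lag123_mean(base)})
    if metric.variable == "T":
        dpt = hourly.groupby(pd.to_datetime(hourly["timestamp"]).dt.normalize())[
            "dew_point_c"
        ].max()
        dpt.index = pd.DatetimeIndex(dpt.index)
        out["dpt"] = dpt.reindex(out.index)
    return out


def stage1_fit(
    counts: pd.Series,
    temps: pd.DataFrame,
    holidays: pd.DataFrame | None = None,
    hospitals: pd.DataFrame | None = None,
    include_dpt: bool = True,
) -> tuple[ts.QuasiPoissonFit, ts.CovariateDesign]:
    """Fit the base model without the exposure term; returns fit and design."""
    design = ts.build_design(
        counts, temps, H=None, holidays=holidays, hospitals=hospitals,
        include_dpt=include_dpt,
    )
    return ts.fit_quasipoisson(design), design


def stage2_logic(
    residuals: np.ndarray,
    indicators: pd.DataFrame,
    config: LogicConfig | None = None,
    seed: int = 0,
) -> lt.LogicTree | None:
    """Learn the Boolean exposure rule from stage-1 Pearson residuals.

    Returns None when cross-validation prefers the null (no-exposure) model
    or when the indicators carry no variation.
    """
    config = config or LogicConfig()
    X = np.asarray(indicators, dtype=float)
    r = np.asarray(residuals, dtype=float)
    keep = ~(np.isnan(X).any(axis=1) | np.isnan(r))
    X, r = X[keep], r[keep]
    if X.size == 0 or np.all(X == X[0, :]):  # constant indicators: nothing to learn
        return None
    rng = np.random.default_rng(seed)
    size = lt.select_tree_size(
        X, r, candidate_sizes=config.candidate_sizes, n_folds=config.n_folds,
        seed=rng, schedule=config.cv_schedule, n_restarts=config.cv_restarts,
        blocked=config.cv_blocked,
    )
    if size == 0:
        return None
    tree = lt.anneal(
        X, r, max_leaves=size, schedule=config.final_schedule,
        n_restarts=config.final_restarts, seed=rng,
    )
    return lt.orient_reference(tree, X)


def stage3_refit(
    design: ts.CovariateDesign, H: pd.Series
) -> tuple[ts.QuasiPoissonFit, ts.RiskEstimate | None]:
    """Refit the full model with the learned exposure; extract RR and 95% CI."""
    h = H.reindex(design.dates)
    if float(np.nansum(h.to_numpy())) == 0.0:
        logger.info("exposure column is all zero; reporting null finding")
        return ts.fit_quasipoisson(design), None
    full = design.with_exposure(H)
    fit = ts.fit_quasipoisson(full)
    return fit, ts.risk_estimate(fit)


@dataclass
class CellResult:
    """Outcome of the three stages for one metric x percentile grid cell."""

    metric: HeatMetricSpec
    percentile: int
    threshold: met.ThresholdSpec
    tree: lt.LogicTree | None
    exposure_text: str
    n_exposed: int
    n_days: int
    risk: ts.RiskEstimate | None
    qaic: float
    H: pd.Series | None
    stage1_fit: ts.QuasiPoissonFit | None = None
    stage3_fit: ts.QuasiPoissonFit | None = None

    @property
    def label(self) -> str:
        return f"{self.metric.name}{self.percentile}"


@dataclass
class PipelineResult:
    """All grid cells plus the QAIC-selected one."""

    cells: list[CellResult]
    selected: CellResult

    def table(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            rows.append(
                {
                    "metric": c.metric.name,
                    "percentile": c.percentile,
                    "qaic": c.qaic,
                    "exposure": c.exposure_text,
                    "frequency_days": c.n_exposed,
                    "rr": c.risk.rr if c.risk else np.nan,
                    "ci_low": c.risk.ci_low if c.risk else np.nan,
                    "ci_high": c.risk.ci_high if c.risk else np.nan,
                    "selected": c is self.selected,
                }
            )
        return pd.DataFrame(rows)


def run_cell(
    counts: pd.Series,
    hourly: pd.DataFrame,
    metric: HeatMetricSpec,
    percentile: int,
    grid: GridSpec | None = None,
    logic_config: LogicConfig | None = None,
    holidays: pd.DataFrame | None = None,
    hospitals: pd.DataFrame | None = None,
    seed: int = 0,
    keep_fits: bool = False,
    known_tree: lt.LogicTree | None = None,
) -> CellResult:
    """Run the three-stage algorithm for one heat metric and threshold.

    ``known_tree`` skips stage 2 and injects a fixed exposure rule (the
    known-H comparator of the simulation study).
    """
    grid = grid or GridSpec()
    daily = met.daily_metric(hourly, metric)
    if grid.threshold_basis == "warm_season":
        basis = daily.index[warm_season_mask(pd.DatetimeIndex(daily.index))]
        thr = met.percentile_threshold(daily, percentile, basis_dates=basis, metric=metric)
    else:
        thr = met.percentile_threshold(daily, percentile, metric=metric)
    indicator = met.extreme_indicator(daily, thr)
    lagm = met.lag_matrix(indicator, max_lag=grid.max_lag, metric=metric, threshold=thr)

    temps = _continuous_covariates(hourly, metric, thr, grid.truncation)
    fit1, design = stage1_fit(
        counts, temps, holidays=holidays, hospitals=hospitals,
        include_dpt=(metric.variable == "T"),
    )
    resid = ts.pearson_residuals(fit1, design.y)
    Xrows = lagm.X.reindex(design.dates)

    if known_tree is not None:
        tree = known_tree
    else:
        tree = stage2_logic(resid, Xrows, config=logic_config, seed=seed)

    n_days = len(design.dates)
    if tree is None:
        return CellResult(
            metric=metric, percentile=percentile, threshold=thr, tree=None,
            exposure_text="(none)", n_exposed=0, n_days=n_days, risk=None,
            qaic=ts.qaic(fit1), H=None,
            stage1_fit=fit1 if keep_fits else None,
        )

    Hvals = lt.evaluate_matrix(tree, Xrows.to_numpy(dtype=float))
    H = pd.Series(Hvals, index=design.dates, name="H")
    fit3, risk = stage3_refit(design, H)
    return CellResult(
        metric=metric, percentile=percentile, threshold=thr, tree=tree,
        exposure_text=describe_exposure(tree, lagm.labels),
        n_exposed=int(np.nansum(H.to_numpy())), n_days=n_days, risk=risk,
        qaic=ts.qaic(fit3), H=H,
        stage1_fit=fit1 if keep_fits else None,
        stage3_fit=fit3 if keep_fits else None,
    )


def run_grid(
    counts: pd.Series,
    hourly: pd.DataFrame,
    grid: GridSpec | None = None,
    logic_config: LogicConfig | None = None,
    holidays: pd.DataFrame | None = None,
    hospitals: pd.DataFrame | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Three-stage run per grid cell; the smallest-QAIC cell is selected.

    QAIC ties are broken toward fewer exposed days, then lexicographic metric
    order.  Failing cells are logged and skipped; if every cell fails a
    RuntimeError is raised.
    """
    grid = grid or GridSpec()
    cells: list[CellResult] = []
    for metric in grid.metrics:
        for pct in grid.percentiles:
            try:
                cells.append(
                    run_cell(
                        counts, hourly, metric, pct, grid=grid,
                        logic_config=logic_config, holidays=holidays,
                        hospitals=hospitals, seed=_cell_seed(seed, metric, pct),
                    )
                )
            except Exception:  # noqa: BLE001 - cell isolation is intentional
                logger.exception("grid cell %s%s failed; skipping", metric.name, pct)
    if not cells:
        raise RuntimeError("every grid cell failed")
    selected = min(cells, key=lambda c: (c.qaic, c.n_exposed, c.metric.name, c.percentile))
    return PipelineResult(cells=cells, selected=selected)


def describe_exposure(tree: lt.LogicTree, labels=None) -> str:
    """Canonical DNF rendering, e.g. ``(lag0 AND lag1) OR (lag1 AND lag3)``."""
    return lt.dnf_string(lt.to_dnf(tree), list(labels) if labels is not None else None)


def conventional_heatwave(indicator: pd.Series, min_consecutive: int = 2) -> pd.Series:
    """Conventional heat-wave flag: 1 when the current and the previous
    ``min_consecutive - 1`` days all exceed the threshold.

    Days whose lagged values predate the record cannot be asserted to be in
    a run and are flagged 0.
    """
    if min_consecutive < 1:
        raise ValueError("min_consecutive must be >= 1")
    idx = pd.DatetimeIndex(indicator.index)
    out = indicator.astype(float).copy()
    for ell in range(1, min_consecutive):
        lagged = indicator.reindex(idx - pd.Timedelta(days=ell)).to_numpy()
        out = out * np.nan_to_num(lagged, nan=0.0)
    out.name = f"heatwave_{min_consecutive}d"
    return out


def fill_gaps_alternative(tree: lt.LogicTree) -> lt.LogicTree:
    """Consecutive-day alternative exposure: per DNF clause drop the NOT
    literals, then include every lag between the clause's min and max lag.

    Clauses left empty (only complemented literals) are dropped with a
    warning.  The result is generally neither a subset nor a superset of the
    original exposure.
    """
    dnf = lt.to_dnf(tree)
    new_clauses = []
    for clause in dnf.clauses:
        plain = [idx for idx, comp in dnf.literals(clause) if not comp]
        if not plain:
            warnings.warn(
                "clause with only complemented literals dropped during gap filling",
                stacklevel=2,
            )
            continue
        filled = tuple(2 * i for i in range(min(plain), max(plain) + 1))
        new_clauses.append(filled)
    if not new_clauses:
        raise ValueError("no clause survives gap filling")
    # re-canonicalise (dedup + absorption) via a round trip through a tree
    rough = lt.dnf_to_tree(lt.DNFForm(tuple(sorted(set(new_clauses)))))
    return lt.dnf_to_tree(lt.to_dnf(rough))
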