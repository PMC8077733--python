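"""Quasi-Poisson log-linear time-series model for daily health counts.

The mean daily count mu_t is modelled on the log scale as

    ln(mu_t) = b0 + beta*H(X_t) + ns(T_t) + ns(Tbar_t) + ns(DPT_t)
               + year effects + seasonal spline x year + day-of-week
               + holidays + hospital availability

where H(X_t) is the binary extreme-heat exposure, T_t the (optionally
truncated) same-day heat metric, Tbar_t the mean of the metric over lags 1-3
and DPT_t the same-day maximum dew point (omitted when apparent temperature
is the exposure, since AT already incorporates humidity).  Variance is
var(Y_t) = phi * mu_t with dispersion phi estimated by Pearson chi-square.

Fitting is delegated to statsmodels' Poisson GLM with the Pearson-scale
(quasi-Poisson) covariance; this module owns the design construction, the
natural-cubic-spline bases, Pearson residuals, QAIC and relative-risk
extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .meteorology import WARM_SEASON_START

__all__ = [
    "natural_cubic_basis",
    "seasonal_spline_basis",
    "CovariateDesign",
    "build_design",
    "QuasiPoissonFit",
    "fit_quasipoisson",
    "pearson_residuals",
    "qaic",
    "RiskEstimate",
    "risk_estimate",
]

EXPOSURE_COL = "H"

# day-of-season offsets of Jun 1, Jul 1, Aug 1, Sep 1 from May 1
_MONTHLY_KNOTS = (31.0, 61.0, 92.0, 123.0)
_SEASON_LENGTH = 152.0  # May 1 -> Sep 30


def natural_cubic_basis(
    x,
    n_internal_knots: int = 2,
    internal_knots=None,
    boundary_knots=None,
) -> np.ndarray:
    """Natural cubic spline basis (linear beyond the boundary knots).

    With K = n_internal_knots + 2 total knots the basis has K - 1 columns
    (no intercept column): x itself plus K - 2 curvature terms of the
    truncated-power construction.  ``internal_knots=None`` places them
    equidistantly strictly inside the observed range (at interior
    (i/(m+1))-points of [min, max] for m internal knots).
    """
    x = np.asarray(x, dtype=float)
    finite = x[np.isfinite(x)]
    if boundary_knots is None:
        if finite.size == 0:
            raise ValueError("cannot place knots on an all-missing series")
        boundary_knots = (float(finite.min()), float(finite.max()))
    lo, hi = boundary_knots
    if internal_knots is None:
        m = n_internal_knots
        internal_knots = [lo + (hi - lo) * (i + 1) / (m + 1) for i in range(m)]
    knots = np.array([lo, *internal_knots, hi], dtype=float)
    if np.unique(knots).size != knots.size or knots.size < 3:
        raise ValueError("knots must be distinct and include at least one internal knot")
    K = knots.size

    def d(j):  # truncated-cubic difference ratio
        num = np.clip(x - knots[j], 0, None) ** 3 - np.clip(x - knots[K - 1], 0, None) ** 3
        return num / (knots[K - 1] - knots[j])

    cols = [x]
    dK2 = d(K - 2)
    for j in range(K - 2):
        cols.append(d(j) - dK2)
    return np.column_stack(cols)


def _day_of_season(dates: pd.DatetimeIndex) -> np.ndarray:
    season_start = pd.to_datetime(
        {"year": dates.year, "month": WARM_SEASON_START[0], "day": WARM_SEASON_START[1]}
    )
    return (dates - pd.DatetimeIndex(season_start)).days.to_numpy().astype(float)


def seasonal_spline_basis(dates: pd.DatetimeIndex) -> np.ndarray:
    """Within-season (May-Sep) natural cubic spline with monthly internal knots.

    Knots at Jun 1, Jul 1, Aug 1 and Sep 1; boundary knots at May 1 and
    Sep 30.  Five columns.
    """
    s = _day_of_season(dates)
    if (s < 0).any() or (s > _SEASON_LENGTH).any():
        raise ValueError("seasonal basis defined for warm-season dates only (May 1-Sep 30)")
    return natural_cubic_basis(
        s, internal_knots=list(_MONTHLY_KNOTS), boundary_knots=(0.0, _SEASON_LENGTH)
    )


@dataclass
class CovariateDesign:
    """Design matrix with named column blocks, aligned to analysis dates."""

    X: pd.DataFrame
    y: np.ndarray
    dates: pd.DatetimeIndex
    blocks: dict[str, list[str]]
    n_dropped: int = 0

    @property
    def has_exposure(self) -> bool:
        return EXPOSURE_COL in self.X.columns

    def with_exposure(self, H: pd.Series) -> "CovariateDesign":
        """Return a copy with the binary exposure column added (stage 3)."""
        h = H.reindex(self.dates)
        if h.isna().any():
            keep = ~h.isna().to_numpy()
            X = self.X.loc[keep].copy()
            y = self.y[keep]
            dates = self.dates[keep]
            h = h[keep]
            dropped = self.n_dropped + int((~keep).sum())
        else:
            X, y, dates, dropped = self.X.copy(), self.y, self.dates, self.n_dropped
        X.insert(1, EXPOSURE_COL, h.to_numpy().astype(float))
        blocks = dict(self.blocks)
        blocks["exposure"] = [EXPOSURE_COL]
        return CovariateDesign(X=X, y=y, dates=dates, blocks=blocks, n_dropped=dropped)


def build_design(
    counts: pd.Series,
    temps: pd.DataFrame,
    H: pd.Series | None = None,
    holidays: pd.DataFrame | None = None,
    hospitals: pd.DataFrame | None = None,
    include_dpt: bool = True,
    n_internal_knots: int = 2,
) -> CovariateDesign:
    """Assemble the block-structured design matrix for the count model.

    ``counts`` is the daily outcome indexed by warm-season dates.  ``temps``
    supplies columns ``t`` (same-day metric, truncated or raw) and ``tbar``
    (lag 1-3 mean), plus ``dpt`` when ``include_dpt`` (dry-bulb exposure
    runs).  Reference levels dropped: first year, Sunday.  Rows with any
    missing covariate are excluded; all-zero indicator columns are dropped
    with a warning.
    """
    dates = pd.DatetimeIndex(counts.index)
    df = pd.DataFrame({"_count": counts.to_numpy()}, index=dates)
    df["t"] = temps["t"].reindex(dates).to_numpy()
    df["tbar"] = temps["tbar"].reindex(dates).to_numpy()
    if include_dpt:
        if "dpt" not in temps.columns:
            raise ValueError("include_dpt=True but temps has no 'dpt' column")
        df["dpt"] = temps["dpt"].reindex(dates).to_numpy()
    if H is not None:
        df[EXPOSURE_COL] = H.reindex(dates).to_numpy()
    for extra, prefix in ((holidays, "holiday"), (hospitals, "hospital")):
        if extra is not None:
            for c in extra.columns:
                df[c] = extra[c].reindex(dates).to_numpy()

    keep = ~df.drop(columns=["_count"]).isna().any(axis=1) & ~df["_count"].isna()
    n_dropped = int((~keep).sum())
    df = df.loc[keep]
    dates = pd.DatetimeIndex(df.index)
    y = df["_count"].to_numpy(dtype=float)
    if (y < 0).any():
        raise ValueError("counts must be non-negative")

    blocks: dict[str, list[str]] = {}
    parts: list[pd.DataFrame] = []

    def add(name: str, arr: np.ndarray, colnames: list[str]):
        part = pd.DataFrame(arr, index=dates, columns=colnames)
        parts.append(part)
        blocks[name] = colnames

    add("intercept", np.ones((len(dates), 1)), ["const"])
    if H is not None:
        add("exposure", df[[EXPOSURE_COL]].to_numpy(), [EXPOSURE_COL])

    for var in ("t", "tbar") + (("dpt",) if include_dpt else ()):
        basis = natural_cubic_basis(df[var].to_numpy(), n_internal_knots=n_internal_knots)
        add(f"ns_{var}", basis, [f"ns_{var}_{j}" for j in range(basis.shape[1])])

    years = dates.year
    uyears = np.unique(years)
    if len(uyears) > 1:
        ydum = np.column_stack([(years == yv).astype(float) for yv in uyears[1:]])
        add("year", ydum, [f"year_{yv}" for yv in uyears[1:]])

    seas = seasonal_spline_basis(dates)
    seas_cols, seas_names = [], []
    for yv in uyears:
        mask = np.asarray(years == yv, dtype=float)[:, None]
        seas_cols.append(seas * mask)
        seas_names += [f"seas{j}_y{yv}" for j in range(seas.shape[1])]
    add("season_by_year", np.hstack(seas_cols), seas_names)

    dow = dates.dayofweek  # Monday=0 .. Sunday=6 (Sunday is the reference)
    dow_dum = np.column_stack([(dow == i).astype(float) for i in range(6)])
    add("dow", dow_dum, ["dow_mon", "dow_tue", "dow_wed", "dow_thu", "dow_fri", "dow_sat"])

    if holidays is not None and len(holidays.columns):
        add("holiday", df[list(holidays.columns)].to_numpy(dtype=float), list(holidays.columns))
    if hospitals is not None and len(hospitals.columns):
        add("hospital", df[list(hospitals.columns)].to_numpy(dtype=float), list(hospitals.columns))

    X = pd.concat(parts, axis=1)

    zero = [c for c in X.columns if c != "const" and not np.any(X[c].to_numpy())]
    if zero:
        warnings.warn(f"dropping all-zero design columns: {zero}", stacklevel=2)
        X = X.drop(columns=zero)
        blocks = {b: [c for c in cols if c not in zero] for b, cols in blocks.items()}

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"design is rank deficient (rank {rank} < {X.shape[1]} columns); "
            "check for collinear indicator blocks"
        )
    return CovariateDesign(X=X, y=y, dates=dates, blocks=blocks, n_dropped=n_dropped)


@dataclass
class QuasiPoissonFit:
    """A fitted quasi-Poisson log-linear model."""

    params: pd.Series
    cov: pd.DataFrame          # phi-scaled (quasi) covariance
    phi: float                 # Pearson chi-square / (n - p)
    mu: np.ndarray             # fitted means
    deviance: float
    n: int
    p: int
    dates: pd.DatetimeIndex | None = None

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    @property
    def qaic(self) -> float:
        return qaic(self)

    def report(self) -> dict:
        """Structured fit summary: coefficient table, dispersion, deviance, QAIC."""
        bse = self.bse
        return {
            "coefficients": {
                name: {"estimate": float(self.params[name]), "se": float(bse[name])}
                for name in self.params.index
            },
            "dispersion": self.phi,
            "deviance": self.deviance,
            "qaic": self.qaic,
            "n": self.n,
            "p": self.p,
        }


def fit_quasipoisson(design: CovariateDesign, counts: np.ndarray | None = None) -> QuasiPoissonFit:
    """Fit the log-link count model with Pearson-estimated dispersion."""
    y = design.y if counts is None else np.asarray(counts, dtype=float)
    X = design.X
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(scale="X2", maxiter=200, tol=1e-8)
    if not res.converged:
        raise RuntimeError("quasi-Poisson IRLS failed to converge")
    return QuasiPoissonFit(
        params=res.params,
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        phi=float(res.scale),
        mu=np.asarray(res.fittedvalues, dtype=float),
        deviance=float(res.deviance),
        n=len(y),
        p=X.shape[1],
        dates=design.dates,
    )


def pearson_residuals(fit: QuasiPoissonFit, counts) -> np.ndarray:
    """Pearson residuals r_t = (Y_t - mu_t) / sqrt(phi * mu_t)."""
    y = np.asarray(counts, dtype=float)
    mu = fit.mu
    if np.any(mu <= 0):
        raise ValueError("fitted means must be positive under the log link")
    return (y - mu) / np.sqrt(fit.phi * mu)


def qaic(fit: QuasiPoissonFit, phi: float | None = None) -> float:
    """Quasi-AIC: deviance / phi + 2 * (number of parameters).

    By default each model's own dispersion is used; pass a shared ``phi``
    (e.g. from the richest candidate) to compare on a common scale.
    """
    scale = fit.phi if phi is None else phi
    return fit.deviance / scale + 2 * fit.p


@dataclass(frozen=True)
class RiskEstimate:
    """Relative risk exp(beta) for the binary exposure, with 95% Wald CI."""

    rr: float
    ci_low: float
    ci_high: float
    beta_hat: float
    se: float


def risk_estimate(fit: QuasiPoissonFit, term: str = EXPOSURE_COL) -> RiskEstimate:
    """Extract RR = exp(beta_H) and its 95% CI from a stage-3 fit."""
    if term not in fit.params.index:
        raise KeyError(f"fit has no exposure term {term!r}")
    beta = float(fit.params[term])
    se = float(fit.bse[term])
    return RiskEstimate(
        rr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        beta_hat=beta,
        se=se,
    )
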