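"""Four-parameter sigmoidal concentration-response fitting and ECx derivation.

The mean model, fitted in log10-concentration space, is

    y(c) = bottom + (top - bottom) / (1 + 10**((log_ec50 - log10 c) * hill))

with y the percent inhibition relative to control (control = 0% by
construction).  Controls at concentration zero are not placed on the log
axis; they only define the inhibition baseline upstream.  ECx values are on
the absolute inhibition scale (x% of the control response), derived by
closed-form inversion of the fitted curve; confidence intervals come from a
within-concentration replicate bootstrap.  Assays with no detectable
response are routed to a one-way ANOVA and reported as censored
("> max tested concentration").
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .endpoints import EndpointTable

BOTTOM_BOUNDS = (-30.0, 40.0)  # percent inhibition
TOP_BOUNDS = (40.0, 120.0)
HILL_BOUNDS = (1e-6, 10.0)
LOG_EC50_PAD = 1.0  # decades beyond the tested range


def fourpl_curve(conc, bottom, top, log_ec50, hill):
    """Evaluate the 4PL inhibition curve at concentration(s) ``conc`` (> 0)."""
    logc = np.log10(np.asarray(conc, dtype=float))
    return _fourpl_logc(logc, bottom, top, log_ec50, hill)


def _fourpl_logc(logc, bottom, top, log_ec50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - logc) * hill))


@dataclass
class ECEstimate:
    """An effect concentration ECx with its interval and censoring state."""

    level: float
    value: float
    ci_low: float | None = None
    ci_high: float | None = None
    censored: bool = False

    def to_dict(self) -> dict:
        from .assay import display_value

        return {
            "level": self.level,
            "value": self.value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "censored": self.censored,
            "display": display_value(self.value, self.censored, self.value),
        }


@dataclass
class FourPLFit:
    """A fitted 4PL curve with derived ECx estimates."""

    bottom: float
    top: float
    log_ec50: float
    hill: float
    r_squared: float
    converged: bool
    n_points: int
    conc_min: float
    conc_max: float
    sse: float
    ec_estimates: dict[float, ECEstimate] = field(default_factory=dict)

    @property
    def ec50_param(self) -> float:
        """Curve midpoint 10**log_ec50 (the relative-scale EC50 parameter)."""
        return 10.0 ** self.log_ec50

    def predict(self, conc):
        return fourpl_curve(conc, self.bottom, self.top, self.log_ec50, self.hill)

    def to_dict(self) -> dict:
        return {
            "bottom": self.bottom,
            "top": self.top,
            "log_ec50": self.log_ec50,
            "hill": self.hill,
            "r_squared": self.r_squared,
            "converged": self.converged,
            "n_points": self.n_points,
            "conc_min": self.conc_min,
            "conc_max": self.conc_max,
            "ec_estimates": {str(int(k)): v.to_dict() for k, v in self.ec_estimates.items()},
        }


class FitError(RuntimeError):
    """Raised when no optimization start converges; carries the best residual."""

    def __init__(self, message: str, best_sse: float | None = None):
        super().__init__(message)
        self.best_sse = best_sse


class FourPLRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn style 4-parameter logistic concentration-response model.

    ``fit`` takes concentrations (ug/L, strictly positive; shape ``(n,)`` or
    ``(n, 1)``) and replicate-level percent inhibition.  The least-squares
    fit runs from ``n_starts`` deterministic starting points spread over the
    tested log-concentration range and keeps the best solution.

    Parameters
    ----------
    bottom_bounds, top_bounds, hill_bounds:
        Box constraints on the asymptotes and slope (percent inhibition /
        dimensionless).
    log_ec50_pad:
        Decades the midpoint may sit beyond the tested range.
    n_starts:
        Number of deterministic multi-start points (>= 2).

    Attributes
    ----------
    bottom_, top_, log_ec50_, hill_ : fitted parameters
    r_squared_ : 1 - SSE/SST on the replicate data
    conc_min_, conc_max_ : tested concentration range
    converged_ : whether any start converged
    """

    def __init__(
        self,
        bottom_bounds: tuple[float, float] = BOTTOM_BOUNDS,
        top_bounds: tuple[float, float] = TOP_BOUNDS,
        hill_bounds: tuple[float, float] = HILL_BOUNDS,
        log_ec50_pad: float = LOG_EC50_PAD,
        n_starts: int = 8,
    ):
        self.bottom_bounds = bottom_bounds
        self.top_bounds = top_bounds
        self.hill_bounds = hill_bounds
        self.log_ec50_pad = log_ec50_pad
        self.n_starts = n_starts

    # -- sklearn plumbing ---------------------------------------------------
    @staticmethod
    def _validate_conc(X) -> np.ndarray:
        conc = np.asarray(X, dtype=float)
        if conc.ndim == 2 and conc.shape[1] == 1:
            conc = conc[:, 0]
        if conc.ndim != 1:
            raise ValueError("X must be a 1-d array of concentrations or a single column")
        if np.any(~np.isfinite(conc)) or np.any(conc <= 0):
            raise ValueError("concentrations must be finite and > 0 (controls are not fitted)")
        return conc

    def fit(self, X, y):
        conc = self._validate_conc(X)
        y = np.asarray(y, dtype=float)
        if y.shape != conc.shape:
            raise ValueError("X and y must have the same length")
        if np.unique(conc).size < 4:
            raise ValueError(
                f"need >= 4 distinct positive concentrations, got {np.unique(conc).size}"
            )
        logc = np.log10(conc)
        lo, hi = logc.min(), logc.max()
        bounds_lo = [self.bottom_bounds[0], self.top_bounds[0], lo - self.log_ec50_pad, self.hill_bounds[0]]
        bounds_hi = [self.bottom_bounds[1], self.top_bounds[1], hi + self.log_ec50_pad, self.hill_bounds[1]]

        b0 = float(np.clip(y.min(), *self.bottom_bounds))
        t0 = float(np.clip(y.max(), *self.top_bounds))
        n_mid = max(2, self.n_starts // 2)
        mids = np.linspace(lo, hi, n_mid)
        hills = [0.7, 2.0]
        starts = [[b0, t0, m, h] for h in hills for m in mids][: max(2, self.n_starts)]

        best = None
        best_sse = np.inf
        for p0 in starts:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = curve_fit(
                        _fourpl_logc, logc, y, p0=p0, bounds=(bounds_lo, bounds_hi), maxfev=5000
                    )
            except (RuntimeError, ValueError):
                continue
            sse = float(np.sum((y - _fourpl_logc(logc, *popt)) ** 2))
            if sse < best_sse:
                best, best_sse = popt, sse
        if best is None:
            raise FitError("4PL fit failed to converge from every start", best_sse=None)

        self.bottom_, self.top_, self.log_ec50_, self.hill_ = (float(v) for v in best)
        sst = float(np.sum((y - y.mean()) ** 2))
        self.sse_ = best_sse
        self.r_squared_ = 1.0 - best_sse / sst if sst > 0 else 1.0
        self.n_points_ = int(conc.size)
        self.conc_min_ = float(conc.min())
        self.conc_max_ = float(conc.max())
        self.converged_ = True
        return self

    def predict(self, X):
        conc = self._validate_conc(X)
        return fourpl_curve(conc, self.bottom_, self.top_, self.log_ec50_, self.hill_)

    def ec_x(self, level: float) -> ECEstimate:
        """Invert the fitted curve at ``level`` % inhibition (absolute scale)."""
        return _invert_fourpl(
            self.bottom_, self.top_, self.log_ec50_, self.hill_, level, self.conc_max_
        )

    def to_fit(self, ec_levels: tuple[float, ...] = (10.0, 50.0)) -> FourPLFit:
        fit = FourPLFit(
            bottom=self.bottom_,
            top=self.top_,
            log_ec50=self.log_ec50_,
            hill=self.hill_,
            r_squared=self.r_squared_,
            converged=self.converged_,
            n_points=self.n_points_,
            conc_min=self.conc_min_,
            conc_max=self.conc_max_,
            sse=self.sse_,
        )
        for level in ec_levels:
            fit.ec_estimates[float(level)] = self.ec_x(level)
        return fit


def _invert_fourpl(
    bottom: float, top: float, log_ec50: float, hill: float, level: float, conc_max: float
) -> ECEstimate:
    lo_asym, hi_asym = min(bottom, top), max(bottom, top)
    if not (lo_asym < level < hi_asym):
        # level never reached by the curve: censor at the top tested conc
        return ECEstimate(level=level, value=conc_max, censored=True)
    u = (top - bottom) / (level - bottom) - 1.0
    logc = log_ec50 - math.log10(u) / hill
    conc = 10.0 ** logc
    if conc > conc_max:
        return ECEstimate(level=level, value=conc_max, censored=True)
    return ECEstimate(level=level, value=conc)


def fit_4pl(conc, inhibition, ec_levels: tuple[float, ...] = (10.0, 50.0), **kwargs) -> FourPLFit:
    """Fit the 4PL curve to replicate-level inhibition data.

    Thin wrapper over :class:`FourPLRegressor` returning a plain
    :class:`FourPLFit` record with ECx estimates at ``ec_levels``.
    """
    est = FourPLRegressor(**kwargs).fit(conc, inhibition)
    return est.to_fit(ec_levels)


def ec_x(fit: FourPLFit, level: float) -> ECEstimate:
    """Concentration inhibiting the endpoint by ``level`` % (absolute scale).

    Censored (value = highest tested concentration) when the curve never
    reaches ``level`` or the inversion lands above the tested range.
    """
    if not fit.converged:
        raise FitError("cannot derive ECx from a non-converged fit")
    return _invert_fourpl(fit.bottom, fit.top, fit.log_ec50, fit.hill, level, fit.conc_max)


@dataclass
class BootstrapCI:
    """Percentile bootstrap interval for an ECx estimate."""

    low: float
    high: float
    n_boot: int
    n_failed: int
    wide_warning: bool

    def to_dict(self) -> dict:
        return {
            "low": self.low,
            "high": self.high,
            "n_boot": self.n_boot,
            "n_failed": self.n_failed,
            "wide_warning": self.wide_warning,
        }


def bootstrap_ci(
    conc,
    inhibition,
    level: float = 50.0,
    n_boot: int = 2000,
    seed: int = 0,
    **fit_kwargs,
) -> BootstrapCI:
    """95% percentile bootstrap interval for ECx.

    Replicates are resampled with replacement *within* each concentration
    (the design is fixed; only replicate noise is resampled), the curve is
    refitted (warm-started at the full-data solution), and the 2.5/97.5
    percentiles of the resampled ECx values are returned.  Resampled
    deviations from each group mean are rescaled by sqrt(n/(n-1)): the plain
    within-group bootstrap deflates variance by (n-1)/n, which measurably
    undercovers at n = 5 replicates.  Deterministic given ``seed``.  If more
    than 20% of resample fits fail or censor, the interval is flagged with
    ``wide_warning``.
    """
    conc = FourPLRegressor._validate_conc(conc)
    y = np.asarray(inhibition, dtype=float)
    full = FourPLRegressor(**fit_kwargs).fit(conc, y)
    logc = np.log10(conc)
    lo, hi = logc.min(), logc.max()
    pad = fit_kwargs.get("log_ec50_pad", LOG_EC50_PAD)
    bounds = (
        [BOTTOM_BOUNDS[0], TOP_BOUNDS[0], lo - pad, HILL_BOUNDS[0]],
        [BOTTOM_BOUNDS[1], TOP_BOUNDS[1], hi + pad, HILL_BOUNDS[1]],
    )
    p_full = [full.bottom_, full.top_, full.log_ec50_, full.hill_]
    p_full = [float(np.clip(p, lo_b + 1e-9, hi_b - 1e-9)) for p, lo_b, hi_b in zip(p_full, *bounds)]

    rng = np.random.default_rng(seed)
    groups = [np.flatnonzero(conc == c) for c in np.unique(conc)]
    group_means = [float(y[g].mean()) for g in groups]
    inflation = [math.sqrt(g.size / (g.size - 1)) if g.size > 1 else 1.0 for g in groups]
    values = []
    n_failed = 0
    for _ in range(n_boot):
        logc_b = np.concatenate([logc[g] for g in groups])
        y_b = np.concatenate(
            [
                m + (y[rng.choice(g, size=g.size, replace=True)] - m) * infl
                for g, m, infl in zip(groups, group_means, inflation)
            ]
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _fourpl_logc, logc_b, y_b, p0=p_full, bounds=bounds, maxfev=2000
                )
        except (RuntimeError, ValueError):
            n_failed += 1
            continue
        est = _invert_fourpl(*(float(v) for v in popt), level, float(conc.max()))
        if est.censored:
            n_failed += 1
            continue
        values.append(est.value)
    if not values:
        raise FitError("every bootstrap resample failed to yield an ECx")
    low, high = np.percentile(values, [2.5, 97.5])
    return BootstrapCI(
        low=float(low),
        high=float(high),
        n_boot=n_boot,
        n_failed=n_failed,
        wide_warning=n_failed > 0.2 * n_boot,
    )


@dataclass
class AnovaResult:
    """Classical one-way fixed-effects ANOVA across treatments."""

    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    note: str | None = None

    def to_dict(self) -> dict:
        return {
            "f_statistic": self.f_statistic,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "p_value": self.p_value,
            "note": self.note,
        }


def nonresponse_anova(tbl: EndpointTable, endpoint: str = "sgr") -> AnovaResult:
    """One-way ANOVA on raw endpoint values across control + test treatments.

    Used for herbicides with no concentration response, where curve fitting
    is meaningless; the reference-toxicant treatment (a different chemical)
    is excluded.
    """
    if endpoint not in ("sgr", "yield"):
        raise ValueError("endpoint must be 'sgr' or 'yield'")
    data = tbl.data[tbl.data["role"] != "reference"]
    groups = [
        g[endpoint].dropna().to_numpy(dtype=float)
        for _, g in data.groupby("treatment_id", sort=False)
    ]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 treatments with >= 2 replicates each")
    n_total = sum(g.size for g in groups)
    df_between = len(groups) - 1
    df_within = n_total - len(groups)
    if all(np.ptp(g) == 0 for g in groups):
        # exact separation: no within-group variance anywhere
        means = [g.mean() for g in groups]
        if np.ptp(means) == 0:
            return AnovaResult(0.0, df_between, df_within, 1.0, note="all values identical")
        return AnovaResult(
            float("inf"), df_between, df_within, 0.0, note="exact separation: zero within-group variance"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p = stats.f_oneway(*groups)
    return AnovaResult(float(f_stat), df_between, df_within, float(p))


def classify_response(
    tbl: EndpointTable,
    endpoint: str = "sgr",
    alpha: float = 0.05,
    min_top_inhibition: float = 10.0,
) -> str:
    """Classify an assay as 'responsive' or 'nonresponsive'.

    Nonresponsive iff the treatment ANOVA is non-significant (p >= alpha)
    AND mean inhibition at the highest tested concentration is below
    ``min_top_inhibition`` %.  Nonresponsive assays are reported with
    censored thresholds ("> max tested") for ECx and NEC.
    """
    test = tbl.test_rows()
    if test["twa_conc"].nunique() < 4:
        raise ValueError("need >= 4 test concentrations to classify the response")
    anova = nonresponse_anova(tbl, endpoint)
    top_conc = test["twa_conc"].max()
    col = "sgr_inhibition" if endpoint == "sgr" else "yield_inhibition"
    top_inh = float(test.loc[test["twa_conc"] == top_conc, col].mean())
    if anova.p_value >= alpha and top_inh < min_top_inhibition:
        return "nonresponsive"
    return "responsive"
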