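"""Cross-herbicide and cross-endpoint potency comparisons.

Relative equivalent potency (ReP) expresses a test herbicide's EC50 on the
scale of the reference herbicide (diuron): ReP = EC50_reference /
EC50_test, so ReP < 1 means less potent than the reference.  The SGR:yield
EC50 ratio compares the two endpoints within one herbicide; values around 3
mean the 24-h quantum-yield endpoint responds at roughly threefold lower
concentrations than 3-day growth.  The endpoint-sensitivity regression
fits mean yield inhibition (response) against mean SGR inhibition
(predictor) by ordinary least squares: a slope above 1 means yield responds
more steeply per unit of growth inhibition, which coexists with a ~3x EC50
ratio because the two measures compare different aspects of the curves.

Censored EC50 inputs ("> max tested") make ReP and the endpoint ratio
undefined; they are reported as NA, never as a number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from ._format import format_sig


def _defined(value: float | None) -> bool:
    return value is not None and not (isinstance(value, float) and math.isnan(value))


def relative_potency(ec50_reference: float | None, ec50_test: float | None) -> float:
    """ReP = EC50 of the reference herbicide / EC50 of the test herbicide.

    Both EC50s must be positive, uncensored, and on the same endpoint.
    Censored or missing input yields NaN (rendered "NA" on display).
    """
    if not (_defined(ec50_reference) and _defined(ec50_test)):
        return float("nan")
    if ec50_reference <= 0 or ec50_test <= 0:
        raise ValueError("EC50 values must be > 0")
    return ec50_reference / ec50_test


def endpoint_ratio(ec50_sgr: float | None, ec50_yield: float | None) -> float:
    """SGR EC50 / quantum-yield EC50 for one herbicide (NaN when censored)."""
    if not (_defined(ec50_sgr) and _defined(ec50_yield)):
        return float("nan")
    if ec50_sgr <= 0 or ec50_yield <= 0:
        raise ValueError("EC50 values must be > 0")
    return ec50_sgr / ec50_yield


@dataclass
class PotencySummary:
    """ReP per endpoint plus the within-herbicide endpoint ratio."""

    herbicide_name: str
    reference_name: str
    rep_sgr: float
    rep_yield: float
    ec50_ratio: float

    def to_dict(self) -> dict:
        return {
            "herbicide_name": self.herbicide_name,
            "reference_name": self.reference_name,
            "rep_sgr": self.rep_sgr,
            "rep_yield": self.rep_yield,
            "ec50_ratio": self.ec50_ratio,
            "display": {
                "rep_sgr": format_sig(None if math.isnan(self.rep_sgr) else self.rep_sgr),
                "rep_yield": format_sig(None if math.isnan(self.rep_yield) else self.rep_yield),
                "ec50_ratio": format_sig(None if math.isnan(self.ec50_ratio) else self.ec50_ratio),
            },
        }


def potency_summary(
    herbicide_name: str,
    ec50_sgr: float | None,
    ec50_yield: float | None,
    reference_name: str = "diuron",
    reference_ec50_sgr: float | None = None,
    reference_ec50_yield: float | None = None,
) -> PotencySummary:
    """Assemble the potency block for one herbicide against a reference."""
    return PotencySummary(
        herbicide_name=herbicide_name,
        reference_name=reference_name,
        rep_sgr=relative_potency(reference_ec50_sgr, ec50_sgr),
        rep_yield=relative_potency(reference_ec50_yield, ec50_yield),
        ec50_ratio=endpoint_ratio(ec50_sgr, ec50_yield),
    )


@dataclass
class SensitivityRegression:
    """OLS of yield inhibition on SGR inhibition (per-treatment means)."""

    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    r_squared: float
    n: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "slope_ci": list(self.slope_ci),
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n": self.n,
        }


def sensitivity_regression(yield_inhibition, sgr_inhibition) -> SensitivityRegression:
    """Fit yield inhibition (response) vs SGR inhibition (predictor).

    Ordinary least squares with intercept on paired per-treatment mean
    inhibitions (replicate-level pairs are equally valid input).  Returns
    the slope with its 95% confidence interval and R^2.
    """
    y = np.asarray(yield_inhibition, dtype=float)
    x = np.asarray(sgr_inhibition, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("inputs must be paired 1-d arrays")
    if y.size < 3:
        raise ValueError("need >= 3 paired inhibition values")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the SGR-inhibition predictor")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return SensitivityRegression(
        slope=float(model.params[1]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        n=int(y.size),
    )
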