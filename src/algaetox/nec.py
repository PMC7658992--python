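"""Bayesian no-effect-concentration (NEC) threshold model.

The proportional response y (e.g. proportional decline in growth rate,
1 - inhibition/100) is modelled against natural-log concentration x as a
broken-stick exponential decay:

    E[y | x] = alpha * exp(-beta * (x - gamma) * I(x - gamma)) - delta

where I(z) = 1 for z > 0 and 0 otherwise.  Below the threshold gamma the
mean is constant at alpha - delta; above it the response decays at rate
beta per log-concentration unit.  gamma is the NEC on the log scale; the
NEC in ug/L is exp(gamma), summarized by its posterior median and central
95% credible interval.

The likelihood is gaussian, y ~ Normal(E[y|x], sigma).  Priors (weakly
informative, overridable):

    gamma ~ Uniform(min x - 0.5, max x)
    alpha ~ Normal(mean control y, 10 * sd control y), truncated > 0
    beta  ~ Gamma(1e-4, 1e-4)  (vague, positive)
    delta ~ Normal(0, 1)
    sigma ~ half-Cauchy(1)

Sampling uses the affine-invariant ensemble sampler (emcee); walkers are
folded into pseudo-chains for R-hat / effective-sample-size diagnostics.
Any correct MCMC scheme satisfies the module contract - correctness is
pinned by the likelihood cross-check and simulation-recovery tests, not by
the named algorithm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import emcee
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .endpoints import EndpointTable

PARAM_NAMES = ("alpha", "beta", "gamma", "delta", "sigma")

RHAT_LIMIT = 1.05
ESS_LIMIT = 400.0


class NonresponsiveAssayError(RuntimeError):
    """Raised when a censored (no-response) assay reaches the NEC fitter."""

    def __init__(self, max_conc: float):
        super().__init__(
            f"assay is nonresponsive; report the NEC as censored (> {max_conc:g} ug/L) instead of fitting"
        )
        self.max_conc = max_conc


@dataclass
class NECParams:
    """One point in the threshold-model parameter space."""

    alpha: float  # response at/below the threshold ("top"), plus delta
    beta: float   # decay rate per log-concentration unit, >= 0
    gamma: float  # NEC on the natural-log concentration scale
    delta: float  # additive offset
    sigma: float  # gaussian error sd, > 0

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma, self.delta, self.sigma])


@dataclass
class NECData:
    """Replicate-level design for the NEC model."""

    x: np.ndarray  # natural-log concentration per replicate
    y: np.ndarray  # proportional response per replicate
    max_conc: float  # highest tested concentration, ug/L
    control_x_policy: str = "unspecified"


def model_mean(params: NECParams | np.ndarray, x):
    """Threshold-model mean E[y|x]; constant at alpha - delta for x <= gamma.

    Continuous in x everywhere (exp(0) = 1 at the knot) and non-increasing
    for beta >= 0.
    """
    if isinstance(params, NECParams):
        alpha, beta, gamma, delta = params.alpha, params.beta, params.gamma, params.delta
    else:
        alpha, beta, gamma, delta = params[0], params[1], params[2], params[3]
    x = np.asarray(x, dtype=float)
    excess = np.where(x > gamma, x - gamma, 0.0)
    out = alpha * np.exp(-beta * excess) - delta
    return float(out) if out.ndim == 0 else out


def log_likelihood(params: NECParams | np.ndarray, x, y) -> float:
    """Gaussian log-likelihood of the threshold model (direct computation)."""
    if isinstance(params, NECParams):
        sigma = params.sigma
    else:
        sigma = params[4]
    if sigma <= 0:
        return -math.inf
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mu = model_mean(params, x)
    n = y.size
    return float(-0.5 * n * math.log(2 * math.pi * sigma**2) - np.sum((y - mu) ** 2) / (2 * sigma**2))


def nec_design_matrix(
    tbl: EndpointTable,
    endpoint: str = "sgr",
    control_decades: float = 1.0,
    check_response: bool = True,
) -> NECData:
    """Build the replicate-level (x, y) design from an endpoint table.

    y = 1 - inhibition/100 per replicate; x = ln(TWA concentration).
    Controls (concentration zero) cannot sit at ln 0, so they are placed
    ``control_decades`` decades below the lowest test concentration; the
    policy is recorded on the result.  The reference-toxicant treatment is
    excluded.  Nonresponsive assays short-circuit with
    :class:`NonresponsiveAssayError` so callers report a censored NEC.
    """
    col = "sgr_inhibition" if endpoint == "sgr" else "yield_inhibition"
    test = tbl.test_rows()
    if test.empty:
        raise ValueError("no test treatments in the endpoint table")
    max_conc = float(test["twa_conc"].max())
    if check_response:
        from .drc import classify_response

        if classify_response(tbl, endpoint) == "nonresponsive":
            raise NonresponsiveAssayError(max_conc)
    lowest = float(test["twa_conc"].min())
    control_conc = lowest / 10.0**control_decades
    controls = tbl.control_rows()
    x = np.concatenate(
        [np.full(len(controls), math.log(control_conc)), np.log(test["twa_conc"].to_numpy(float))]
    )
    y = np.concatenate(
        [
            1.0 - controls[col].to_numpy(float) / 100.0,
            1.0 - test[col].to_numpy(float) / 100.0,
        ]
    )
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("non-finite values in the NEC design")
    return NECData(
        x=x,
        y=y,
        max_conc=max_conc,
        control_x_policy=(
            f"controls at ln(lowest test TWA / 10^{control_decades:g}) = ln({control_conc:g})"
        ),
    )


@dataclass
class MCMCSettings:
    """Ensemble-sampler settings.

    ``walkers`` ensemble members run for ``iterations`` steps; the first
    ``burnin`` steps are discarded.  For diagnostics the walkers are folded
    into ``chains`` groups.  Defaults keep ~48,000 posterior draws.
    """

    walkers: int = 16
    iterations: int = 6000
    burnin: int = 3000
    chains: int = 4

    def __post_init__(self):
        if self.walkers < 2 * len(PARAM_NAMES):
            raise ValueError(f"need >= {2 * len(PARAM_NAMES)} walkers for a {len(PARAM_NAMES)}-d model")
        if not 0 <= self.burnin < self.iterations:
            raise ValueError("burnin must be in [0, iterations)")
        if self.walkers % self.chains != 0:
            raise ValueError("walkers must be divisible by chains for diagnostics")


@dataclass
class NECFit:
    """Posterior over the threshold-model parameters with the NEC summary."""

    posterior_draws: pd.DataFrame | None
    nec_value: float | None
    nec_ci: tuple[float, float] | None
    censored: bool
    max_conc: float
    diagnostics: dict[str, dict[str, float]] = field(default_factory=dict)
    converged: bool = True
    seed: int | None = None
    control_x_policy: str = "unspecified"

    def to_dict(self) -> dict:
        from .assay import display_value

        summary = {}
        if self.posterior_draws is not None:
            for name in PARAM_NAMES:
                d = self.posterior_draws[name].to_numpy()
                summary[name] = {
                    "median": float(np.median(d)),
                    "q2.5": float(np.percentile(d, 2.5)),
                    "q97.5": float(np.percentile(d, 97.5)),
                }
        return {
            "nec_value": self.nec_value,
            "nec_ci": list(self.nec_ci) if self.nec_ci else None,
            "censored": self.censored,
            "max_conc": self.max_conc,
            "display": display_value(self.nec_value, self.censored, self.max_conc),
            "diagnostics": self.diagnostics,
            "converged": self.converged,
            "seed": self.seed,
            "control_x_policy": self.control_x_policy,
            "posterior_summary": summary,
            "n_draws": 0 if self.posterior_draws is None else int(len(self.posterior_draws)),
        }


def censored_nec(max_conc: float) -> NECFit:
    """A censored NEC result: reported as "> max tested concentration"."""
    return NECFit(
        posterior_draws=None,
        nec_value=None,
        nec_ci=None,
        censored=True,
        max_conc=max_conc,
        converged=True,
    )


class NECThresholdRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn style Bayesian threshold (NEC) regressor.

    ``fit`` takes natural-log concentrations ``X`` (shape ``(n,)`` or
    ``(n, 1)``) and proportional responses ``y``, samples the posterior of
    (alpha, beta, gamma, delta, sigma) under the module's priors, and
    exposes the NEC summary.  Deterministic given ``random_state``.

    Attributes
    ----------
    posterior_ : DataFrame of kept draws, one column per parameter
    nec_draws_ : exp(gamma) draws (ug/L)
    nec_value_, nec_ci_ : posterior median and central 95% interval of exp(gamma)
    rhat_, ess_ : per-parameter convergence diagnostics
    converged_ : all R-hat <= 1.05 and ESS >= 400
    """

    def __init__(
        self,
        walkers: int = 16,
        iterations: int = 6000,
        burnin: int = 3000,
        chains: int = 4,
        gamma_pad: float = 0.5,
        alpha_prior_sd_factor: float = 10.0,
        random_state: int = 0,
    ):
        self.walkers = walkers
        self.iterations = iterations
        self.burnin = burnin
        self.chains = chains
        self.gamma_pad = gamma_pad
        self.alpha_prior_sd_factor = alpha_prior_sd_factor
        self.random_state = random_state

    # -- posterior ----------------------------------------------------------
    def _log_prob_fn(self, x: np.ndarray, y: np.ndarray):
        x_lo, x_hi = float(x.min()), float(x.max())
        g_lo, g_hi = x_lo - self.gamma_pad, x_hi
        control_y = y[x == x_lo]
        a_mu = float(np.mean(control_y))
        a_sd = max(float(np.std(control_y, ddof=1)) if control_y.size > 1 else 0.0, 1e-3)
        a_sd *= self.alpha_prior_sd_factor
        n = y.size

        def log_prob(theta: np.ndarray) -> np.ndarray:
            theta = np.atleast_2d(theta)
            alpha, beta, gamma, delta, sigma = theta.T
            ok = (alpha > 0) & (beta > 0) & (sigma > 0) & (gamma >= g_lo) & (gamma <= g_hi)
            a = np.where(ok, alpha, 1.0)
            b = np.where(ok, beta, 1.0)
            s = np.where(ok, sigma, 1.0)
            excess = np.clip(x[None, :] - gamma[:, None], 0.0, None)
            mu = a[:, None] * np.exp(-b[:, None] * excess) - delta[:, None]
            ll = -0.5 * n * np.log(2 * np.pi * s**2) - np.sum((y[None, :] - mu) ** 2, axis=1) / (
                2 * s**2
            )
            lp = (
                -0.5 * ((a - a_mu) / a_sd) ** 2          # alpha: truncated normal
                + (1e-4 - 1.0) * np.log(b) - 1e-4 * b    # beta: vague gamma
                - 0.5 * delta**2                          # delta: standard normal
                - np.log1p(s**2)                          # sigma: half-Cauchy(1)
            )
            return np.where(ok, ll + lp, -np.inf)

        return log_prob, (g_lo, g_hi, a_mu)

    def _initial_walkers(self, x, y, rs, g_lo, g_hi, a_mu) -> np.ndarray:
        resid_sd = max(float(np.std(y, ddof=1)) * 0.5, 1e-3)
        nw = self.walkers
        return np.column_stack(
            [
                np.abs(a_mu + rs.normal(0, max(0.05 * abs(a_mu), 0.01), nw)) + 1e-6,
                np.abs(rs.normal(1.0, 0.5, nw)) + 1e-3,
                rs.uniform(g_lo, g_hi, nw),
                rs.normal(0.0, 0.05, nw),
                np.abs(rs.normal(resid_sd, resid_sd / 4, nw)) + 1e-4,
            ]
        )

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("X and y must be 1-d arrays of equal length")
        MCMCSettings(self.walkers, self.iterations, self.burnin, self.chains)  # validate

        log_prob, (g_lo, g_hi, a_mu) = self._log_prob_fn(x, y)
        rs = np.random.RandomState(self.random_state)
        p0 = self._initial_walkers(x, y, rs, g_lo, g_hi, a_mu)
        # differential-evolution move mixture: mixes far better than the
        # default stretch move when a walker lands in a minor mode
        moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
        sampler = emcee.EnsembleSampler(
            self.walkers, len(PARAM_NAMES), log_prob, vectorize=True, moves=moves
        )
        sampler.random_state = rs.get_state()
        sampler.run_mcmc(p0, self.iterations, progress=False)
        chain = sampler.get_chain(discard=self.burnin)  # (steps, walkers, ndim)
        self.chain_ = chain
        self.acceptance_fraction_ = float(np.mean(sampler.acceptance_fraction))
        flat = chain.reshape(-1, len(PARAM_NAMES))
        self.posterior_ = pd.DataFrame(flat, columns=list(PARAM_NAMES))
        self.nec_draws_ = np.exp(self.posterior_["gamma"].to_numpy())
        self.nec_value_ = float(np.median(self.nec_draws_))
        self.nec_ci_ = (
            float(np.percentile(self.nec_draws_, 2.5)),
            float(np.percentile(self.nec_draws_, 97.5)),
        )
        self.rhat_, self.ess_ = self._diagnostics(chain)
        self.converged_ = all(r <= RHAT_LIMIT for r in self.rhat_.values()) and all(
            e >= ESS_LIMIT for e in self.ess_.values()
        )
        if not self.converged_:
            warnings.warn(
                "NEC sampler did not meet convergence targets "
                f"(max R-hat {max(self.rhat_.values()):.3f}, min ESS {min(self.ess_.values()):.0f}); "
                "consider longer chains",
                RuntimeWarning,
                stacklevel=2,
            )
        self.x_ = x
        self.y_ = y
        return self

    def _diagnostics(self, chain: np.ndarray) -> tuple[dict[str, float], dict[str, float]]:
        import arviz as az

        steps, walkers, ndim = chain.shape
        per = walkers // self.chains
        rhat: dict[str, float] = {}
        ess: dict[str, float] = {}
        for j, name in enumerate(PARAM_NAMES):
            # fold walkers into pseudo-chains: (chains, steps*per)
            folded = (
                chain[:, :, j].T.reshape(self.chains, per, steps).reshape(self.chains, -1)
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rhat[name] = float(az.rhat(folded))
                ess[name] = float(az.ess(folded))
        return rhat, ess

    def predict(self, X):
        """Posterior-mean response curve at log-concentrations ``X``."""
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        draws = self.posterior_.to_numpy()
        excess = np.clip(x[None, :] - draws[:, 2:3], 0.0, None)
        mu = draws[:, 0:1] * np.exp(-draws[:, 1:2] * excess) - draws[:, 3:4]
        return mu.mean(axis=0)


def fit_nec(data: NECData, settings: MCMCSettings | None = None, seed: int = 0) -> NECFit:
    """Sample the NEC-model posterior for a responsive assay.

    Thin wrapper over :class:`NECThresholdRegressor`; deterministic given
    ``seed``.  Non-convergence (any R-hat > 1.05 or ESS < 400) is flagged on
    the result and raised as a warning, never hidden.
    """
    settings = settings or MCMCSettings()
    est = NECThresholdRegressor(
        walkers=settings.walkers,
        iterations=settings.iterations,
        burnin=settings.burnin,
        chains=settings.chains,
        random_state=seed,
    ).fit(data.x, data.y)
    diagnostics = {
        name: {"rhat": est.rhat_[name], "ess": est.ess_[name]} for name in PARAM_NAMES
    }
    return NECFit(
        posterior_draws=est.posterior_,
        nec_value=est.nec_value_,
        nec_ci=est.nec_ci_,
        censored=False,
        max_conc=data.max_conc,
        diagnostics=diagnostics,
        converged=est.converged_,
        seed=seed,
        control_x_policy=data.control_x_policy,
    )


def nec_summary(fit: NECFit) -> tuple[float | None, tuple[float, float] | None, bool]:
    """(NEC median, 95% credible interval, censored flag) on the ug/L scale."""
    if fit.censored:
        return None, None, True
    draws = np.exp(fit.posterior_draws["gamma"].to_numpy())
    value = float(np.median(draws))
    ci = (float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5)))
    return value, ci, False
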