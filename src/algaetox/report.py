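"""Full-assay orchestration: endpoints -> QC -> ECx -> NEC -> potency.

``run_assay`` executes the whole analysis for one bioassay and returns a
:class:`RunSummary` that serializes to a stable JSON document: identical
(input, config, seed) reproduce the output byte for byte.  A failed QC
criterion warns and flags the summary but does not abort - the analyst
decides what a technically invalid assay is worth.  Nonresponsive assays
(no concentration dependence) skip the curve and threshold fits entirely
and report censored thresholds ("> max tested") with NA potency.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Any

from .assay import AssayDataset, validate_dataset
from .drc import (
    AnovaResult,
    ECEstimate,
    bootstrap_ci,
    classify_response,
    fit_4pl,
    nonresponse_anova,
)
from .endpoints import EndpointTable, endpoint_table
from .nec import MCMCSettings, NECFit, censored_nec, fit_nec, nec_design_matrix
from .potency import (
    PotencySummary,
    SensitivityRegression,
    potency_summary,
    sensitivity_regression,
)
from .qc import (
    DEFAULT_MAX_CONTROL_CV,
    DEFAULT_MAX_PH_INCREASE,
    DEFAULT_MIN_CONTROL_SGR,
    QCReport,
    check_validity,
    control_performance,
)


@dataclass
class RunConfig:
    """Everything an assay run depends on besides the data."""

    seed: int = 0
    ec_levels: tuple[float, ...] = (10.0, 50.0)
    n_boot: int = 2000
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    min_control_sgr: float = DEFAULT_MIN_CONTROL_SGR
    max_control_cv: float = DEFAULT_MAX_CONTROL_CV
    max_ph_increase: float = DEFAULT_MAX_PH_INCREASE
    pool_solvent_control: bool = False
    loq: float | None = None
    control_decades: float = 1.0  # NEC control-placement policy
    anova_alpha: float = 0.05
    min_top_inhibition: float = 10.0
    reference_name: str = "diuron"
    reference_ec50_sgr: float | None = None
    reference_ec50_yield: float | None = None

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        if "mcmc" in raw and isinstance(raw["mcmc"], dict):
            raw["mcmc"] = MCMCSettings(**raw["mcmc"])
        if "ec_levels" in raw:
            raw["ec_levels"] = tuple(float(v) for v in raw["ec_levels"])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["ec_levels"] = list(self.ec_levels)
        return d


@dataclass
class EndpointResult:
    """ECx block for one endpoint (growth or quantum yield)."""

    endpoint: str
    response_class: str
    anova: AnovaResult
    fit: Any | None  # FourPLFit when responsive
    ec_estimates: dict[float, ECEstimate]

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "response_class": self.response_class,
            "anova": self.anova.to_dict(),
            "fit": None if self.fit is None else self.fit.to_dict(),
            "ec_estimates": {str(int(k)): v.to_dict() for k, v in self.ec_estimates.items()},
        }


@dataclass
class RunSummary:
    """End-to-end result of one assay analysis."""

    herbicide: str
    validation_issues: list[str]
    qc: QCReport
    endpoints: dict[str, EndpointResult]
    nec: NECFit
    potency: PotencySummary | None
    sensitivity: SensitivityRegression | None
    provenance: dict[str, Any]

    def to_dict(self) -> dict:
        return {
            "herbicide": self.herbicide,
            "validation_issues": self.validation_issues,
            "qc": self.qc.to_dict(),
            "endpoints": {k: v.to_dict() for k, v in self.endpoints.items()},
            "nec": self.nec.to_dict(),
            "potency": None if self.potency is None else self.potency.to_dict(),
            "sensitivity": None if self.sensitivity is None else self.sensitivity.to_dict(),
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=True)


def _stage(name: str):
    """Decorate run stages so failures carry the stage name and context."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def _censored_estimates(levels, max_conc) -> dict[float, ECEstimate]:
    return {float(lv): ECEstimate(level=float(lv), value=max_conc, censored=True) for lv in levels}


def _analyze_endpoint(tbl: EndpointTable, endpoint: str, config: RunConfig, seed_base: int) -> EndpointResult:
    anova = nonresponse_anova(tbl, endpoint)
    response = classify_response(
        tbl, endpoint, alpha=config.anova_alpha, min_top_inhibition=config.min_top_inhibition
    )
    test = tbl.test_rows()
    col = "sgr_inhibition" if endpoint == "sgr" else "yield_inhibition"
    if response == "nonresponsive":
        return EndpointResult(
            endpoint=endpoint,
            response_class=response,
            anova=anova,
            fit=None,
            ec_estimates=_censored_estimates(config.ec_levels, tbl.max_test_conc),
        )
    conc = test["twa_conc"].to_numpy(float)
    inh = test[col].to_numpy(float)
    fit = fit_4pl(conc, inh, ec_levels=config.ec_levels)
    for k, level in enumerate(config.ec_levels):
        est = fit.ec_estimates[float(level)]
        if not est.censored and config.n_boot > 0:
            ci = bootstrap_ci(conc, inh, level=level, n_boot=config.n_boot, seed=seed_base + 17 * k)
            est.ci_low, est.ci_high = ci.low, ci.high
    return EndpointResult(
        endpoint=endpoint,
        response_class=response,
        anova=anova,
        fit=fit,
        ec_estimates=fit.ec_estimates,
    )


def run_assay(ds: AssayDataset, config: RunConfig | None = None) -> RunSummary:
    """Run the complete analysis chain on one bioassay.

    Stage order: structural validation, endpoint computation, QC, response
    classification + 4PL/ECx per endpoint (with bootstrap intervals),
    Bayesian NEC on the growth endpoint, potency summaries.  Nonresponsive
    assays take the censored path throughout.  Deterministic given
    (dataset, config); all seeds derive from ``config.seed``.
    """
    config = config or RunConfig()

    with _stage("validate"):
        issues = validate_dataset(ds)

    with _stage("endpoints"):
        tbl = endpoint_table(ds, pool_solvent_control=config.pool_solvent_control, loq=config.loq)

    with _stage("qc"):
        qc = check_validity(
            control_performance(tbl),
            ds.physicochem,
            min_control_sgr=config.min_control_sgr,
            max_control_cv=config.max_control_cv,
            max_ph_increase=config.max_ph_increase,
        )
        if not qc.valid:
            warnings.warn(
                f"assay {ds.herbicide_name!r} fails QC validity; results are reported but flagged",
                RuntimeWarning,
                stacklevel=2,
            )

    endpoints: dict[str, EndpointResult] = {}
    with _stage("drc:sgr"):
        endpoints["sgr"] = _analyze_endpoint(tbl, "sgr", config, seed_base=config.seed + 101)
    if tbl.has_yield:
        with _stage("drc:yield"):
            endpoints["yield"] = _analyze_endpoint(tbl, "yield", config, seed_base=config.seed + 211)

    with _stage("nec"):
        if endpoints["sgr"].response_class == "nonresponsive":
            nec = censored_nec(tbl.max_test_conc)
            nec.control_x_policy = "not applicable (censored)"
        else:
            data = nec_design_matrix(
                tbl, "sgr", control_decades=config.control_decades, check_response=False
            )
            nec = fit_nec(data, settings=config.mcmc, seed=config.seed + 307)

    with _stage("potency"):

        def _ec50(endpoint: str) -> float | None:
            res = endpoints.get(endpoint)
            if res is None:
                return None
            est = res.ec_estimates.get(50.0)
            if est is None or est.censored:
                return None
            return est.value

        potency = None
        if config.reference_ec50_sgr is not None or config.reference_ec50_yield is not None:
            potency = potency_summary(
                ds.herbicide_name,
                _ec50("sgr"),
                _ec50("yield"),
                reference_name=config.reference_name,
                reference_ec50_sgr=config.reference_ec50_sgr,
                reference_ec50_yield=config.reference_ec50_yield,
            )

        sensitivity = None
        if tbl.has_yield and endpoints["sgr"].response_class == "responsive":
            means = tbl.treatment_means()
            means = means[means["role"] == "test"]
            try:
                sensitivity = sensitivity_regression(
                    means["mean_yield_inhibition"].to_numpy(float),
                    means["mean_sgr_inhibition"].to_numpy(float),
                )
            except ValueError:
                sensitivity = None

    from . import __version__

    provenance = {
        "seed": config.seed,
        "config": config.to_dict(),
        "software_version": __version__,
        "control_mean_sgr": tbl.control_mean_sgr,
        "control_mean_yield": tbl.control_mean_yield,
        "max_test_conc": tbl.max_test_conc,
    }
    return RunSummary(
        herbicide=ds.herbicide_name,
        validation_issues=issues,
        qc=qc,
        endpoints=endpoints,
        nec=nec,
        potency=potency,
        sensitivity=sensitivity,
        provenance=provenance,
    )
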