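"""Synthetic bioassay generator.

Emulates the statistical structure of a 72-h static algal growth-inhibition
test: a seawater control, an optional reference-toxicant treatment
(diuron-like, 4 ug/L), and a geometric series of test concentrations, each
with n = 5 replicate vials started at 3e3 cells/mL.  Control growth sits in
the 1.4-1.7 day^-1 range and control quantum yield around 0.42-0.48, as in
healthy exponential-phase diatom cultures.  Herbicide dissipates first-order
between 0 h and 72 h (default 80% remaining), and analytical measurements of
start/end concentrations carry ~5% lognormal error, so the analysis-side TWA
(geometric mean) is exercised realistically.

Noise model: lognormal multiplicative error on cell densities (counting and
pipetting errors scale with the count; densities stay positive), additive
gaussian error on quantum yield (near-symmetric around ~0.45).  The yield
endpoint responds at lower concentrations than growth by a configurable
sensitivity factor (default 3: yield EC50 = growth EC50 / 3).  Hormesis is
not simulated; stimulation can still arise from noise and is preserved by
the analysis (no clipping of negative inhibition).

All outputs are reproducible from (design, truth, seed) alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .assay import AssayDataset, PhysicoChem, ReplicateRecord, TreatmentGroup
from .drc import fourpl_curve
from .nec import NECData, NECParams, model_mean


@dataclass
class FourPLCurve:
    """Ground-truth inhibition curve in 4PL form (percent inhibition)."""

    bottom: float = 0.0
    top: float = 100.0
    ec50: float = 20.0  # ug/L
    hill: float = 1.4

    def inhibition(self, conc) -> np.ndarray:
        return fourpl_curve(conc, self.bottom, self.top, math.log10(self.ec50), self.hill)

    def scaled(self, potency_factor: float) -> "FourPLCurve":
        """Same shape, EC50 divided by ``potency_factor`` (more potent)."""
        return replace(self, ec50=self.ec50 / potency_factor)


def truth_inhibition(curve, conc) -> np.ndarray:
    """Percent inhibition of ``curve`` (4PL, NEC-model, or None) at ``conc``."""
    conc = np.asarray(conc, dtype=float)
    if curve is None:
        return np.zeros_like(conc)
    if isinstance(curve, FourPLCurve):
        return np.asarray(curve.inhibition(conc))
    if isinstance(curve, NECParams):
        top = curve.alpha - curve.delta
        mu = model_mean(curve, np.log(conc))
        return 100.0 * (1.0 - np.asarray(mu) / top)
    raise TypeError(f"unsupported truth curve type {type(curve).__name__}")


@dataclass
class AssayDesign:
    """Treatment layout of one simulated bioassay."""

    concentrations: tuple[float, ...]  # nominal, ug/L, strictly increasing
    n_replicates: int = 5
    duration: float = 3.0  # days
    start_density: float = 3e3  # cells/mL
    include_reference: bool = True
    reference_conc: float = 4.0  # ug/L, diuron-like
    decay_fraction: float = 0.8  # fraction of nominal remaining at 72 h

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size == 0 or np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be positive and strictly increasing")
        if self.n_replicates < 2:
            raise ValueError("need n_replicates >= 2")


@dataclass
class TruthModel:
    """Ground truth the generator draws from.

    Defaults emulate the observed study conditions: control SGR 1.55 day^-1
    (mid of the 1.41-1.68 range), control yield 0.46, ~4% CV counting noise,
    0.01 absolute yield noise, reference-toxicant inhibition ~22% (SGR) /
    ~42% (yield), and a threefold more sensitive yield endpoint.
    """

    control_sgr: float = 1.55  # day^-1
    control_yield: float = 0.46
    inhibition_curve: FourPLCurve | NECParams | None = field(default_factory=FourPLCurve)
    endpoint_ratio_truth: float = 3.0  # yield EC50 = growth EC50 / ratio
    noise_cv_density: float = 4.0  # percent, lognormal on cell densities
    noise_sd_yield: float = 0.01  # absolute, gaussian on quantum yield
    conc_noise_cv: float = 5.0  # percent, lognormal on measured concentrations
    ref_inhibition_sgr: float = 22.0  # percent
    ref_inhibition_yield: float = 42.0  # percent
    fm_scale: float = 500.0  # instrument units for Fm'

    def yield_curve(self):
        if self.inhibition_curve is None:
            return None
        if isinstance(self.inhibition_curve, FourPLCurve):
            return self.inhibition_curve.scaled(self.endpoint_ratio_truth)
        shifted = replace(self.inhibition_curve)
        shifted.gamma = self.inhibition_curve.gamma - math.log(self.endpoint_ratio_truth)
        return shifted


def default_design(ec50: float = 20.0, n_replicates: int = 5) -> AssayDesign:
    """Seven geometric concentrations spanning two decades around ``ec50``."""
    conc = np.geomspace(ec50 / 10.0, ec50 * 10.0, 7)
    return AssayDesign(concentrations=tuple(float(c) for c in conc), n_replicates=n_replicates)


def flat_truth(**kwargs) -> TruthModel:
    """A no-effect (nonresponsive-herbicide) truth: zero inhibition everywhere."""
    return TruthModel(inhibition_curve=None, **kwargs)


def _lognoise(rng: np.random.Generator, cv_pct: float, size=None):
    if cv_pct == 0:
        return 1.0 if size is None else np.ones(size)
    return np.exp(rng.normal(0.0, cv_pct / 100.0, size))


def simulate_assay(
    design: AssayDesign,
    truth: TruthModel | None = None,
    seed: int = 0,
    herbicide_name: str = "synthetic",
) -> AssayDataset:
    """Generate one complete bioassay dataset.

    For each dosed treatment the measured start concentration is the nominal
    with lognormal analytical noise, the end concentration additionally
    carries the dissipation factor, and the biological effect is the truth
    curve evaluated at the geometric mean (TWA) of those simulated
    measurements - so a noiseless generator round-trips exactly through the
    analysis.  Deterministic given ``seed``.
    """
    truth = truth or TruthModel()
    rng = np.random.default_rng(seed)
    yield_curve = truth.yield_curve()

    groups: list[tuple[str, str, float, float, float]] = [("control", "control", 0.0, 0.0, 0.0)]
    if design.include_reference:
        groups.append(("reference", "reference", design.reference_conc, truth.ref_inhibition_sgr, truth.ref_inhibition_yield))
    for i, c in enumerate(design.concentrations, start=1):
        groups.append((f"T{i}", "test", float(c), np.nan, np.nan))

    treatments = []
    physicochem = {}
    for tid, role, nominal, i_sgr_fixed, i_qy_fixed in groups:
        if role == "control":
            start_meas = end_meas = None
            i_sgr, i_qy = 0.0, 0.0
        else:
            start_meas = nominal * float(_lognoise(rng, truth.conc_noise_cv))
            end_meas = nominal * design.decay_fraction * float(_lognoise(rng, truth.conc_noise_cv))
            twa = math.sqrt(start_meas * end_meas)
            if role == "reference":
                i_sgr, i_qy = i_sgr_fixed, i_qy_fixed
            else:
                i_sgr = float(truth_inhibition(truth.inhibition_curve, twa))
                i_qy = float(truth_inhibition(yield_curve, twa))
                if not np.isfinite(i_sgr) or not np.isfinite(i_qy):
                    raise ValueError(f"truth curve undefined at concentration {twa:g} ug/L")

        rate = truth.control_sgr * (1.0 - i_sgr / 100.0)
        qy_mean = truth.control_yield * (1.0 - i_qy / 100.0)
        replicates = []
        for r in range(design.n_replicates):
            t0 = design.start_density * float(_lognoise(rng, truth.noise_cv_density))
            t72 = t0 * math.exp(rate * design.duration) * float(_lognoise(rng, truth.noise_cv_density))
            qy = qy_mean + (rng.normal(0.0, truth.noise_sd_yield) if truth.noise_sd_yield else 0.0)
            qy = float(np.clip(qy, 0.0, 1.0))
            fm = truth.fm_scale
            replicates.append(
                ReplicateRecord(
                    replicate_id=f"r{r + 1}",
                    cell_density_t0=t0,
                    cell_density_t72=t72,
                    fluorescence_f=fm * (1.0 - qy),
                    fluorescence_fm=fm,
                )
            )
        treatments.append(
            TreatmentGroup(
                treatment_id=tid,
                role=role,
                nominal_conc=nominal,
                replicates=replicates,
                measured_conc_start=start_meas,
                measured_conc_end=end_meas,
            )
        )
        ph0 = 8.10 + float(rng.normal(0.0, 0.02))
        physicochem[tid] = PhysicoChem(
            ph_t0=round(ph0, 2),
            ph_t72=round(ph0 + 0.25 + float(rng.normal(0.0, 0.03)), 2),
            salinity=round(35.0 + float(rng.normal(0.0, 0.2)), 1),
            dissolved_oxygen=round(8.2 + float(rng.normal(0.0, 0.1)), 1),
            temperature=round(27.2 + float(rng.normal(0.0, 0.2)), 1),
        )

    return AssayDataset(
        herbicide_name=herbicide_name,
        treatments=treatments,
        physicochem=physicochem,
        duration=design.duration,
    )


def simulate_from_nec(
    params: NECParams,
    x_grid,
    n_replicates: int = 5,
    seed: int = 0,
) -> NECData:
    """Draw replicate responses directly from the NEC threshold model.

    y ~ Normal(model_mean(params, x), sigma) at each x in ``x_grid``,
    ``n_replicates`` per point.  The generative counterpart of the NEC
    likelihood, used for parameter-recovery studies.
    """
    if params.sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    x_grid = np.asarray(x_grid, dtype=float)
    x = np.repeat(x_grid, n_replicates)
    mu = model_mean(params, x)
    y = mu + (rng.normal(0.0, params.sigma, x.size) if params.sigma > 0 else 0.0)
    return NECData(
        x=x,
        y=np.asarray(y, dtype=float),
        max_conc=float(np.exp(x_grid.max())),
        control_x_policy="as generated (x grid supplied directly)",
    )
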