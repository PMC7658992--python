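"""Biological endpoints and the exposure metric.

* specific growth rate       SGR = (ln Xj - ln Xi) / (tj - ti)   [day^-1]
* effective quantum yield    dF/Fm' = (Fm' - F) / Fm'            [0, 1]
* percent inhibition         100 * (Xc - Xt) / Xc, Xc = control mean
* TWA exposure               geometric mean of measured start/end conc

Growth is scored over the full 3-day exposure; the quantum-yield endpoint is
the 24-h light-adapted PAM measurement (the data model carries the timing in
the column names).  Inhibition below zero (stimulation) is preserved, never
clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assay import AssayDataset


def specific_growth_rate(x_i, x_j, t_i: float = 0.0, t_j: float = 3.0):
    """Logarithmic increase in cell density per day between times ``t_i < t_j``.

    Accepts scalars or arrays; negative rates (population decline) are valid.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if np.any(x_i <= 0) or np.any(x_j <= 0):
        raise ValueError("cell densities must be > 0")
    if not t_j > t_i:
        raise ValueError(f"t_j must exceed t_i, got t_i={t_i}, t_j={t_j}")
    out = (np.log(x_j) - np.log(x_i)) / (t_j - t_i)
    return float(out) if out.ndim == 0 else out


def effective_quantum_yield(f, fm):
    """Light-adapted PSII efficiency (Fm' - F)/Fm', in [0, 1]."""
    f = np.asarray(f, dtype=float)
    fm = np.asarray(fm, dtype=float)
    if np.any(fm <= 0):
        raise ValueError("Fm' must be > 0")
    if np.any(f < 0) or np.any(f > fm):
        raise ValueError("F must satisfy 0 <= F <= Fm'")
    out = (fm - f) / fm
    return float(out) if out.ndim == 0 else out


def percent_inhibition(x_control: float, x_treatment):
    """Inhibition relative to the control mean, in percent.

    Negative values (treatment above control, i.e. stimulation) are
    preserved.  ``x_control`` is the arithmetic mean over control replicates.
    """
    if x_control == 0:
        raise ValueError("control mean must be nonzero")
    x_treatment = np.asarray(x_treatment, dtype=float)
    out = 100.0 * (x_control - x_treatment) / x_control
    return float(out) if out.ndim == 0 else out


def twa_concentration(c_start: float, c_end: float) -> float:
    """Time-weighted average exposure: geometric mean of start/end measurements.

    Suitable for first-order dissipation between 0 h and 72 h.  Non-positive
    inputs are a domain error: apply the below-quantitation policy (half-LOQ
    substitution or nominal fallback) before calling.
    """
    if c_start <= 0 or c_end <= 0:
        raise ValueError(
            "measured concentrations must be > 0; substitute LOQ/2 or fall back "
            "to nominal for below-quantitation values before computing the TWA"
        )
    return math.sqrt(c_start * c_end)


@dataclass
class EndpointTable:
    """Per-replicate endpoints plus per-treatment exposure.

    ``data`` columns: treatment_id, replicate_id, role, nominal_conc,
    twa_conc, conc_source, sgr, sgr_inhibition, yield, yield_inhibition
    (yield columns NaN for growth-only assays).
    """

    data: pd.DataFrame
    control_mean_sgr: float
    control_mean_yield: float | None
    herbicide_name: str
    duration: float
    max_test_conc: float

    @property
    def has_yield(self) -> bool:
        return self.control_mean_yield is not None

    def to_frame(self) -> pd.DataFrame:
        return self.data.copy()

    def to_dict(self) -> dict:
        return {
            "herbicide_name": self.herbicide_name,
            "control_mean_sgr": self.control_mean_sgr,
            "control_mean_yield": self.control_mean_yield,
            "duration": self.duration,
            "max_test_conc": self.max_test_conc,
            "rows": self.data.to_dict(orient="records"),
        }

    def test_rows(self) -> pd.DataFrame:
        return self.data[self.data["role"] == "test"]

    def control_rows(self) -> pd.DataFrame:
        return self.data[self.data["role"].isin(["control", "solvent_control"])]

    def treatment_means(self) -> pd.DataFrame:
        """Per-treatment mean inhibition (used for plots, regressions, QC)."""
        return (
            self.data.groupby(["treatment_id", "role"], sort=False, dropna=False)
            .agg(
                twa_conc=("twa_conc", "first"),
                nominal_conc=("nominal_conc", "first"),
                conc_source=("conc_source", "first"),
                mean_sgr=("sgr", "mean"),
                mean_sgr_inhibition=("sgr_inhibition", "mean"),
                mean_yield=("yield", "mean"),
                mean_yield_inhibition=("yield_inhibition", "mean"),
                n=("sgr", "size"),
            )
            .reset_index()
        )


def _treatment_exposure(t, loq: float | None) -> tuple[float, str]:
    """TWA exposure for one dosed treatment with the below-quantitation policy."""

    def usable(v):
        return v is not None and not (isinstance(v, float) and math.isnan(v)) and v > 0

    start, end = t.measured_conc_start, t.measured_conc_end
    if usable(start) and usable(end):
        return twa_concentration(start, end), "measured"
    if loq is not None and (start is not None or end is not None):
        # below-quantitation measurement present: substitute half the LOQ
        s = start if usable(start) else loq / 2.0
        e = end if usable(end) else loq / 2.0
        return twa_concentration(s, e), "half_loq"
    return float(t.nominal_conc), "nominal"


def endpoint_table(
    ds: AssayDataset,
    pool_solvent_control: bool = False,
    loq: float | None = None,
) -> EndpointTable:
    """Apply the endpoint equations per replicate and attach TWA exposure.

    The inhibition baseline is the arithmetic mean over seawater-control
    replicates (the solvent control is pooled into the baseline only when
    ``pool_solvent_control`` is set).  Control replicates keep their
    per-replicate inhibition values (mean 0 by construction) so downstream
    fits see control variance.
    """
    rows = []
    duration = ds.duration
    for t in ds.treatments:
        if t.is_control:
            conc, source = 0.0, "control"
        elif t.role == "reference":
            conc, source = _treatment_exposure(t, loq)
        else:
            conc, source = _treatment_exposure(t, loq)
        for r in t.replicates:
            try:
                sgr = specific_growth_rate(r.cell_density_t0, r.cell_density_t72, 0.0, duration)
            except ValueError as err:
                raise ValueError(
                    f"treatment {t.treatment_id!r}, replicate {r.replicate_id!r}: {err}"
                ) from err
            if r.has_fluorescence:
                try:
                    qy = effective_quantum_yield(r.fluorescence_f, r.fluorescence_fm)
                except ValueError as err:
                    raise ValueError(
                        f"treatment {t.treatment_id!r}, replicate {r.replicate_id!r}: {err}"
                    ) from err
            else:
                qy = np.nan
            rows.append(
                {
                    "treatment_id": t.treatment_id,
                    "replicate_id": r.replicate_id,
                    "role": t.role,
                    "nominal_conc": t.nominal_conc,
                    "twa_conc": conc,
                    "conc_source": source,
                    "sgr": sgr,
                    "yield": qy,
                }
            )
    data = pd.DataFrame(rows)

    baseline_roles = ["control", "solvent_control"] if pool_solvent_control else ["control"]
    base = data[data["role"].isin(baseline_roles)]
    if base.empty:
        raise ValueError("dataset has no control replicates for the inhibition baseline")
    control_mean_sgr = float(base["sgr"].mean())
    have_yield = base["yield"].notna().all() and data["yield"].notna().any()
    control_mean_yield = float(base["yield"].mean()) if have_yield else None

    data["sgr_inhibition"] = percent_inhibition(control_mean_sgr, data["sgr"].to_numpy())
    if control_mean_yield is not None:
        data["yield_inhibition"] = percent_inhibition(
            control_mean_yield, data["yield"].to_numpy()
        )
    else:
        data["yield_inhibition"] = np.nan

    test_concs = data.loc[data["role"] == "test", "twa_conc"]
    max_test_conc = float(test_concs.max()) if len(test_concs) else float("nan")
    return EndpointTable(
        data=data,
        control_mean_sgr=control_mean_sgr,
        control_mean_yield=control_mean_yield,
        herbicide_name=ds.herbicide_name,
        duration=duration,
        max_test_conc=max_test_conc,
    )
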