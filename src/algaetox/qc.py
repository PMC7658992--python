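"""Assay acceptability checks.

A 72-h test is considered valid when the control populations grew well
(mean control SGR >= 0.92 day^-1), control variability was low
(CV% <= 10), and the medium stayed chemically stable (pH increase over the
test <= 1 unit in every treatment).  The reference-toxicant inhibition is
reported as a between-assay consistency indicator but is not a hard gate.
QC only annotates; it never alters endpoint values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assay import PhysicoChem
from .endpoints import EndpointTable

DEFAULT_MIN_CONTROL_SGR = 0.92  # day^-1
DEFAULT_MAX_CONTROL_CV = 10.0  # percent
DEFAULT_MAX_PH_INCREASE = 1.0  # pH units


@dataclass
class QCReport:
    """Control performance, reference-toxicant response, and validity flags."""

    control_mean_sgr: float
    control_cv_pct: float
    control_mean_yield: float | None = None
    control_yield_cv_pct: float | None = None
    reference_sgr_inhibition_pct: float | None = None
    reference_yield_inhibition_pct: float | None = None
    ph_max_increase: float | None = None
    #: flag name -> (passed, message); empty until check_validity runs
    validity_flags: dict[str, tuple[bool, str]] = field(default_factory=dict)

    @property
    def valid(self) -> bool:
        return bool(self.validity_flags) and all(ok for ok, _ in self.validity_flags.values())

    def to_dict(self) -> dict:
        return {
            "control_mean_sgr": self.control_mean_sgr,
            "control_cv_pct": self.control_cv_pct,
            "control_mean_yield": self.control_mean_yield,
            "control_yield_cv_pct": self.control_yield_cv_pct,
            "reference_sgr_inhibition_pct": self.reference_sgr_inhibition_pct,
            "reference_yield_inhibition_pct": self.reference_yield_inhibition_pct,
            "ph_max_increase": self.ph_max_increase,
            "validity_flags": {k: {"passed": ok, "message": m} for k, (ok, m) in self.validity_flags.items()},
            "valid": self.valid if self.validity_flags else None,
        }


def _cv_pct(values: np.ndarray) -> float:
    """100 * sample sd (n-1) / mean."""
    mean = float(np.mean(values))
    if mean == 0:
        raise ValueError("cannot compute CV% around a zero mean")
    return 100.0 * float(np.std(values, ddof=1)) / mean


def control_performance(tbl: EndpointTable) -> QCReport:
    """Summarize control mean/CV and the reference-toxicant inhibition."""
    controls = tbl.data[tbl.data["role"] == "control"]
    if len(controls) < 2:
        raise ValueError(
            f"need >= 2 seawater-control replicates to assess performance, got {len(controls)}"
        )
    sgr = controls["sgr"].to_numpy(dtype=float)
    report = QCReport(
        control_mean_sgr=float(np.mean(sgr)),
        control_cv_pct=_cv_pct(sgr),
    )
    if controls["yield"].notna().all():
        qy = controls["yield"].to_numpy(dtype=float)
        report.control_mean_yield = float(np.mean(qy))
        report.control_yield_cv_pct = _cv_pct(qy)
    ref = tbl.data[tbl.data["role"] == "reference"]
    if len(ref):
        report.reference_sgr_inhibition_pct = float(ref["sgr_inhibition"].mean())
        if ref["yield_inhibition"].notna().all():
            report.reference_yield_inhibition_pct = float(ref["yield_inhibition"].mean())
    return report


def check_validity(
    qc: QCReport,
    physicochem: dict[str, PhysicoChem] | None = None,
    min_control_sgr: float = DEFAULT_MIN_CONTROL_SGR,
    max_control_cv: float = DEFAULT_MAX_CONTROL_CV,
    max_ph_increase: float = DEFAULT_MAX_PH_INCREASE,
) -> QCReport:
    """Complete a QC report with the three validity flags.

    The pH criterion uses the signed increase (t72 - t0), maximized over
    treatments; pH decreases never fail.  Flags are monotone in their
    inputs: worsening a metric can only turn a pass into a fail.
    """
    flags: dict[str, tuple[bool, str]] = {}
    ok = qc.control_mean_sgr >= min_control_sgr
    flags["valid_growth"] = (
        ok,
        f"control mean SGR {qc.control_mean_sgr:.3f} day^-1 "
        f"{'meets' if ok else 'below'} the >= {min_control_sgr} day^-1 criterion",
    )
    ok = qc.control_cv_pct <= max_control_cv
    flags["valid_cv"] = (
        ok,
        f"control SGR CV {qc.control_cv_pct:.2f}% "
        f"{'within' if ok else 'exceeds'} the <= {max_control_cv}% criterion",
    )
    increases = []
    for pc in (physicochem or {}).values():
        if pc.ph_t0 is not None and pc.ph_t72 is not None:
            increases.append(pc.ph_t72 - pc.ph_t0)
    if increases:
        ph_max = max(increases)
        ok = ph_max <= max_ph_increase
        msg = (
            f"max pH increase {ph_max:.2f} units "
            f"{'within' if ok else 'exceeds'} the <= {max_ph_increase}-unit criterion"
        )
    else:
        ph_max, ok, msg = None, True, "no paired pH measurements supplied; criterion not assessable"
    flags["valid_ph"] = (ok, msg)

    return QCReport(
        control_mean_sgr=qc.control_mean_sgr,
        control_cv_pct=qc.control_cv_pct,
        control_mean_yield=qc.control_mean_yield,
        control_yield_cv_pct=qc.control_yield_cv_pct,
        reference_sgr_inhibition_pct=qc.reference_sgr_inhibition_pct,
        reference_yield_inhibition_pct=qc.reference_yield_inhibition_pct,
        ph_max_increase=ph_max,
        validity_flags=flags,
    )
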