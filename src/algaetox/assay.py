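"""Bioassay domain types, long-format CSV I/O, and structural validation.

A dataset is one herbicide bioassay: a seawater control (optionally plus a
solvent control), a reference-toxicant treatment, and a series of test
concentrations, each with replicated vials.  Per replicate the assay records
cell densities at 0 h and 72 h (growth endpoint) and, optionally, a
light-adapted fluorescence pair (F, Fm') at 24 h (quantum-yield endpoint).

The on-disk format is one long-format CSV per assay, one row per replicate.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

from ._format import format_censored, format_sig

ROLES = ("control", "solvent_control", "reference", "test")

MANDATORY_COLUMNS = (
    "treatment",
    "role",
    "nominal_conc",
    "replicate",
    "cell_density_t0",
    "cell_density_t72",
)
REPLICATE_OPTIONAL_COLUMNS = (
    "fluorescence_f",
    "fluorescence_fm",
)
TREATMENT_OPTIONAL_COLUMNS = (
    "measured_conc_start",
    "measured_conc_end",
)
PHYSICOCHEM_COLUMNS = (
    "ph_t0",
    "ph_t72",
    "salinity",
    "dissolved_oxygen",
    "temperature",
)

#: multiplicative factors converting declared input units to ug/L
CONC_UNIT_FACTORS = {"ug/L": 1.0, "mg/L": 1000.0, "ng/L": 1e-3}


class AssayFormatError(ValueError):
    """Raised when an input file does not conform to the CSV contract."""


class AssayValidationError(ValueError):
    """Raised when a structurally parsed dataset violates a hard invariant."""


@dataclass
class ReplicateRecord:
    """One replicate vial: densities at 0/72 h and an optional (F, Fm') pair."""

    replicate_id: str
    cell_density_t0: float
    cell_density_t72: float
    fluorescence_f: float | None = None
    fluorescence_fm: float | None = None

    @property
    def has_fluorescence(self) -> bool:
        return self.fluorescence_f is not None and self.fluorescence_fm is not None


@dataclass
class TreatmentGroup:
    """A dosed treatment (or control) with its replicates.

    Concentrations are stored in ug/L throughout.  ``measured_conc_start`` /
    ``measured_conc_end`` are analytical measurements at 0 h and 72 h; they
    may be absent, in which case downstream exposure falls back to the
    nominal concentration (flagged).
    """

    treatment_id: str
    role: str
    nominal_conc: float
    replicates: list[ReplicateRecord] = field(default_factory=list)
    measured_conc_start: float | None = None
    measured_conc_end: float | None = None

    @property
    def is_control(self) -> bool:
        return self.role in ("control", "solvent_control")


@dataclass
class PhysicoChem:
    """Per-treatment physicochemical log (each field optional)."""

    ph_t0: float | None = None
    ph_t72: float | None = None
    salinity: float | None = None
    dissolved_oxygen: float | None = None
    temperature: float | None = None


@dataclass
class AssayDataset:
    """A complete bioassay: treatments x replicates plus physicochemistry."""

    herbicide_name: str
    treatments: list[TreatmentGroup]
    physicochem: dict[str, PhysicoChem] = field(default_factory=dict)
    duration: float = 3.0

    def treatment(self, treatment_id: str) -> TreatmentGroup:
        for t in self.treatments:
            if t.treatment_id == treatment_id:
                return t
        raise KeyError(treatment_id)

    @property
    def controls(self) -> list[TreatmentGroup]:
        return [t for t in self.treatments if t.is_control]

    @property
    def n_replicates(self) -> int:
        return sum(len(t.replicates) for t in self.treatments)


def _role_rank(role: str) -> int:
    return ROLES.index(role) if role in ROLES else len(ROLES)


def _sorted_treatments(treatments: Iterable[TreatmentGroup]) -> list[TreatmentGroup]:
    # canonical order so that input row order never affects results
    out = []
    for t in treatments:
        t.replicates = sorted(t.replicates, key=lambda r: r.replicate_id)
        out.append(t)
    return sorted(out, key=lambda t: (_role_rank(t.role), t.nominal_conc, t.treatment_id))


def read_assay_csv(
    path: str | Path,
    herbicide_name: str | None = None,
    conc_units: str = "ug/L",
    duration: float = 3.0,
) -> AssayDataset:
    """Read one long-format assay CSV into a validated :class:`AssayDataset`.

    Parameters
    ----------
    path:
        CSV with one row per replicate.  Mandatory columns:
        ``treatment, role, nominal_conc, replicate, cell_density_t0,
        cell_density_t72``.  Optional: fluorescence pair, measured start/end
        concentrations, physicochemistry, ``herbicide``, ``duration``.
    conc_units:
        Units of all concentration columns in the file; converted to ug/L
        at read time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"treatment": str, "replicate": str}, float_precision="round_trip")
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise AssayFormatError(f"missing mandatory column {col!r} in {path.name}")
    if conc_units not in CONC_UNIT_FACTORS:
        raise AssayFormatError(
            f"unknown concentration units {conc_units!r}; expected one of {sorted(CONC_UNIT_FACTORS)}"
        )
    factor = CONC_UNIT_FACTORS[conc_units]

    numeric_cols = [
        c
        for c in ("nominal_conc", "cell_density_t0", "cell_density_t72")
        + REPLICATE_OPTIONAL_COLUMNS
        + TREATMENT_OPTIONAL_COLUMNS
        + PHYSICOCHEM_COLUMNS
        if c in df.columns
    ]
    for col in numeric_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(df.index[bad][0]) + 2  # 1-based plus header line
            raise AssayFormatError(
                f"non-numeric value {df.loc[bad, col].iloc[0]!r} in column {col!r} at line {row}"
            )
        df[col] = converted

    conc_cols = ["nominal_conc"] + [c for c in TREATMENT_OPTIONAL_COLUMNS if c in df.columns]
    for col in conc_cols:
        df[col] = df[col] * factor

    if herbicide_name is None:
        if "herbicide" in df.columns and df["herbicide"].notna().any():
            herbicide_name = str(df["herbicide"].dropna().iloc[0])
        else:
            herbicide_name = path.stem
    if "duration" in df.columns and df["duration"].notna().any():
        duration = float(pd.to_numeric(df["duration"]).dropna().iloc[0])

    treatments: list[TreatmentGroup] = []
    physicochem: dict[str, PhysicoChem] = {}
    for tid, grp in df.groupby("treatment", sort=False):
        role = str(grp["role"].iloc[0])
        if role not in ROLES:
            raise AssayFormatError(
                f"unknown role {role!r} for treatment {tid!r}; expected one of {ROLES}"
            )

        def _opt(col: str) -> float | None:
            if col not in grp.columns:
                return None
            vals = grp[col].dropna()
            return float(vals.iloc[0]) if len(vals) else None

        replicates = []
        for _, row in grp.iterrows():
            f = row.get("fluorescence_f")
            fm = row.get("fluorescence_fm")
            replicates.append(
                ReplicateRecord(
                    replicate_id=str(row["replicate"]),
                    cell_density_t0=float(row["cell_density_t0"]),
                    cell_density_t72=float(row["cell_density_t72"]),
                    fluorescence_f=None if pd.isna(f) else float(f),
                    fluorescence_fm=None if pd.isna(fm) else float(fm),
                )
            )
        treatments.append(
            TreatmentGroup(
                treatment_id=str(tid),
                role=role,
                nominal_conc=float(grp["nominal_conc"].iloc[0]),
                replicates=replicates,
                measured_conc_start=_opt("measured_conc_start"),
                measured_conc_end=_opt("measured_conc_end"),
            )
        )
        pc = PhysicoChem(*[_opt(c) for c in PHYSICOCHEM_COLUMNS])
        if any(getattr(pc, f.name) is not None for f in dataclasses.fields(pc)):
            physicochem[str(tid)] = pc

    ds = AssayDataset(
        herbicide_name=herbicide_name,
        treatments=_sorted_treatments(treatments),
        physicochem=physicochem,
        duration=duration,
    )
    if not ds.controls:
        raise AssayValidationError(f"no control group in {path.name}")
    return ds


def write_assay_csv(ds: AssayDataset, path: str | Path) -> None:
    """Write an :class:`AssayDataset` back to the long-format CSV."""
    rows = []
    for t in _sorted_treatments(list(ds.treatments)):
        pc = ds.physicochem.get(t.treatment_id, PhysicoChem())
        for r in t.replicates:
            rows.append(
                {
                    "herbicide": ds.herbicide_name,
                    "treatment": t.treatment_id,
                    "role": t.role,
                    "nominal_conc": t.nominal_conc,
                    "replicate": r.replicate_id,
                    "cell_density_t0": r.cell_density_t0,
                    "cell_density_t72": r.cell_density_t72,
                    "fluorescence_f": r.fluorescence_f,
                    "fluorescence_fm": r.fluorescence_fm,
                    "measured_conc_start": t.measured_conc_start,
                    "measured_conc_end": t.measured_conc_end,
                    "duration": ds.duration,
                    **{c: getattr(pc, c) for c in PHYSICOCHEM_COLUMNS},
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def validate_dataset(ds: AssayDataset) -> list[str]:
    """Check every type invariant; return issue descriptions (empty iff valid).

    Issues are returned rather than raised so a whole dataset can be
    reviewed in one pass; each message names the treatment/replicate and the
    violated rule.
    """
    issues: list[str] = []
    seen_ids: set[str] = set()
    roles_seen: dict[str, int] = {}
    for t in ds.treatments:
        tag = f"treatment {t.treatment_id!r}"
        if t.treatment_id in seen_ids:
            issues.append(f"{tag}: duplicate treatment_id")
        seen_ids.add(t.treatment_id)
        roles_seen[t.role] = roles_seen.get(t.role, 0) + 1
        if t.role not in ROLES:
            issues.append(f"{tag}: unknown role {t.role!r}")
        if t.is_control and t.nominal_conc != 0:
            issues.append(f"{tag}: control must have nominal_conc = 0, got {t.nominal_conc}")
        if not t.is_control and t.nominal_conc <= 0:
            issues.append(f"{tag}: dosed treatment must have nominal_conc > 0")
        for name in ("measured_conc_start", "measured_conc_end"):
            v = getattr(t, name)
            if v is not None and v <= 0:
                issues.append(f"{tag}: {name} must be > 0 when present, got {v}")
        if len(t.replicates) < 2:
            issues.append(f"{tag}: fewer than 2 replicates")
        for r in t.replicates:
            rtag = f"{tag}, replicate {r.replicate_id!r}"
            if not (r.cell_density_t0 > 0 and r.cell_density_t72 > 0):
                issues.append(f"{rtag}: cell densities must be > 0")
            has_f = r.fluorescence_f is not None
            has_fm = r.fluorescence_fm is not None
            if has_f != has_fm:
                issues.append(f"{rtag}: fluorescence F and Fm' must be absent or present as a pair")
            if has_f and has_fm:
                if r.fluorescence_f < 0:
                    issues.append(f"{rtag}: fluorescence F must be >= 0")
                if r.fluorescence_fm < r.fluorescence_f:
                    issues.append(f"{rtag}: Fm' < F violates Fm' >= F >= 0")
    for role in ("control", "solvent_control"):
        if roles_seen.get(role, 0) > 1:
            issues.append(f"dataset: {roles_seen[role]} groups with role {role!r}; at most one allowed")
    if roles_seen.get("control", 0) == 0:
        issues.append("dataset: no seawater control group")
    for tid, pc in ds.physicochem.items():
        for name in ("ph_t0", "ph_t72"):
            v = getattr(pc, name)
            if v is not None and not (0 <= v <= 14):
                issues.append(f"treatment {tid!r}: {name} outside [0, 14]")
        if pc.salinity is not None and pc.salinity < 0:
            issues.append(f"treatment {tid!r}: salinity < 0")
    return issues


# ---------------------------------------------------------------------------
# result serialization


def _display(obj: Any) -> Any:
    """Recursively add 3-significant-figure display rendering to numbers."""
    if obj is None:
        return "NA"
    if isinstance(obj, bool):
        return obj
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        return format_sig(float(obj))
    if isinstance(obj, dict):
        return {k: _display(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_display(v) for v in obj]
    return obj


def _as_payload(report: Any) -> tuple[dict[str, Any] | list[dict[str, Any]], pd.DataFrame]:
    """Normalize any result type to (full-precision dict, display frame)."""
    if report is None:
        return {}, pd.DataFrame()
    if isinstance(report, pd.DataFrame):
        return report.to_dict(orient="records"), report
    if hasattr(report, "to_frame"):
        frame = report.to_frame()
    else:
        frame = None
    if hasattr(report, "to_dict"):
        data = report.to_dict()
    elif dataclasses.is_dataclass(report):
        data = dataclasses.asdict(report)
    else:
        raise TypeError(f"cannot serialize result of type {type(report).__name__}")
    if frame is None:
        flat = {k: v for k, v in data.items() if not isinstance(v, (dict, list))}
        frame = pd.DataFrame([flat]) if flat else pd.DataFrame()
    return data, frame


def write_results(report: Any, path: str | Path) -> None:
    """Serialize a result object to CSV or JSON (chosen by file suffix).

    JSON carries both full-precision values and a ``display`` block rounded
    to 3 significant figures (censored thresholds rendered as ``"> max"``).
    An empty report produces an empty file with header only.
    """
    path = Path(path)
    data, frame = _as_payload(report)
    if path.suffix.lower() == ".json":
        payload = {"values": data, "display": _display(data)}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default))
    else:
        frame.to_csv(path, index=False)


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj).__name__}")


def censored_display(max_conc: float) -> str:
    """Public alias for the "> max tested" reporting convention."""
    return format_censored(max_conc)


def display_value(x: float | None, censored: bool = False, max_conc: float | None = None) -> str:
    """Render a threshold for display: 3 sig figs, or "> max" when censored."""
    if censored:
        if max_conc is None or (isinstance(max_conc, float) and math.isnan(max_conc)):
            return "NA"
        return format_censored(max_conc)
    return format_sig(x)
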