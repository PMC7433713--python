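"""Non-compartmental pharmacokinetics over one 12-h tacrolimus dosing interval.

All parameters derive from a steady-state concentration-time profile sampled
on the nominal 0,1,2,3,4,6,8,10,12 h grid (actual times are used when they
deviate): linear-trapezoid AUC over 0-12 h and 0-4 h, the 12-h trough C12,
the observed peak Cmax/Tmax, apparent oral clearance CL/F = dose/AUC0-12,
and normalizations to a 1 mg dose equivalent and to body size (total and
lean body weight).

Units: concentrations ng/ml whole blood, times h, dose mg, clearance L/h.
CL/F = dose(mg) x 10^6 (ng/mg) / AUC(ng.h/ml) / 1000 (ml/L)
     = dose x 1000 / AUC  [L/h].

No terminal-slope extrapolation is performed: the analysis is confined to
the observed dosing interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ConcentrationProfile",
    "PkParameters",
    "auc_linear_trapezoid",
    "derive_pk_parameters",
    "lean_body_weight",
    "egfr_mdrd",
    "PK_PARAMETER_COLUMNS",
]

#: Nominal sampling grid, hours post-dose.
NOMINAL_TIMES = (0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 12.0)

#: Tolerance (h) for locating the 12-h trough sample (15 min).
C12_TOLERANCE_H = 0.25


@dataclass
class ConcentrationProfile:
    subject_id: str
    times: np.ndarray  # h post-dose, strictly increasing from 0
    concentrations: np.ndarray  # ng/ml
    dose: float  # mg per 12-h interval
    tbw: float | None = None  # kg
    lbw: float | None = None  # kg
    tau: float = 12.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape:
            raise ValueError(f"{self.subject_id}: times/concentrations length mismatch")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError(f"{self.subject_id}: times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError(f"{self.subject_id}: negative concentration")
        if not self.dose > 0:
            raise ValueError(f"{self.subject_id}: dose must be positive")


@dataclass
class PkParameters:
    subject_id: str
    dose: float  # mg
    auc_0_12: float  # ng.h/ml
    auc_0_4: float  # ng.h/ml
    auc_star: float  # ng.h/ml/mg, dose-normalized AUC0-12
    auc_0_4_norm: float  # ng.h/ml/mg
    c12: float  # ng/ml
    c12_per_dose: float  # ng/ml/mg
    cmax: float  # ng/ml
    cmax_per_dose: float  # ng/ml/mg
    tmax: float  # h
    cl_f: float  # L/h
    cl_per_lbw: float | None  # L/h/kg
    cl_per_tbw: float | None  # L/h/kg (extra; Table-2 set reports dose/TBW)
    dose_per_tbw: float | None  # mg/kg

    def as_dict(self) -> dict:
        return asdict(self)


#: Column order for per-subject PK output (the 13-parameter table set plus
#: the extra cl_per_tbw).
PK_PARAMETER_COLUMNS = [
    "subject_id",
    "dose",
    "dose_per_tbw",
    "c12",
    "c12_per_dose",
    "cmax",
    "cmax_per_dose",
    "tmax",
    "auc_0_12",
    "auc_star",
    "cl_f",
    "cl_per_lbw",
    "auc_0_4",
    "auc_0_4_norm",
    "cl_per_tbw",
]


def _interp_conc(times: np.ndarray, concs: np.ndarray, t: float) -> float:
    return float(np.interp(t, times, concs))


def auc_linear_trapezoid(
    profile: ConcentrationProfile, t_start: float, t_end: float
) -> float:
    """Linear-trapezoid AUC (ng.h/ml) between two times within the profile.

    Boundaries off the sampling grid are handled by linear interpolation
    between the bracketing samples, so the result is the exact integral of
    the piecewise-linear curve through the samples.
    """
    t, c = profile.times, profile.concentrations
    if not t_start < t_end:
        raise ValueError("t_start must be < t_end")
    if t_start < t[0] or t_end > t[-1]:
        raise ValueError(
            f"integration range [{t_start}, {t_end}] outside sampled "
            f"[{t[0]}, {t[-1]}]"
        )
    inside = (t > t_start) & (t < t_end)
    tt = np.concatenate([[t_start], t[inside], [t_end]])
    cc = np.concatenate(
        [[_interp_conc(t, c, t_start)], c[inside], [_interp_conc(t, c, t_end)]]
    )
    if tt.size < 2:
        raise ValueError("insufficient samples in range")
    return float(np.trapezoid(cc, tt))


def derive_pk_parameters(profile: ConcentrationProfile) -> PkParameters:
    """All interval PK parameters for one profile.

    C12 is the observed sample at 12 h (within +/-15 min), never an
    extrapolation.  Tmax ties break to the earliest time.  Every
    dose-normalized quantity is the raw value divided by the dose in mg.
    """
    t, c = profile.times, profile.concentrations
    if t.size < 2:
        raise ValueError(f"{profile.subject_id}: insufficient samples")

    auc12 = auc_linear_trapezoid(profile, 0.0, min(profile.tau, t[-1]))
    if auc12 <= 0:
        raise ValueError(f"{profile.subject_id}: degenerate profile (zero AUC)")
    auc4 = auc_linear_trapezoid(profile, 0.0, 4.0) if t[-1] >= 4.0 else np.nan

    near12 = np.abs(t - profile.tau) <= C12_TOLERANCE_H
    if not near12.any():
        raise ValueError(
            f"{profile.subject_id}: missing trough (no sample within "
            f"{C12_TOLERANCE_H} h of {profile.tau} h)"
        )
    c12 = float(c[near12][np.argmin(np.abs(t[near12] - profile.tau))])

    imax = int(np.argmax(c))  # argmax returns the first (earliest) maximum
    cmax, tmax = float(c[imax]), float(t[imax])

    dose = profile.dose
    cl_f = dose * 1000.0 / auc12  # L/h
    lbw, tbw = profile.lbw, profile.tbw
    return PkParameters(
        subject_id=profile.subject_id,
        dose=dose,
        auc_0_12=auc12,
        auc_0_4=auc4,
        auc_star=auc12 / dose,
        auc_0_4_norm=auc4 / dose,
        c12=c12,
        c12_per_dose=c12 / dose,
        cmax=cmax,
        cmax_per_dose=cmax / dose,
        tmax=tmax,
        cl_f=cl_f,
        cl_per_lbw=cl_f / lbw if lbw else None,
        cl_per_tbw=cl_f / tbw if tbw else None,
        dose_per_tbw=dose / tbw if tbw else None,
    )


def derive_pk_table(profiles) -> pd.DataFrame:
    """Per-subject PK parameter table in the canonical column order."""
    rows = [derive_pk_parameters(p).as_dict() for p in profiles]
    return pd.DataFrame(rows, columns=PK_PARAMETER_COLUMNS)


def lean_body_weight(sex: str, tbw: float, height: float) -> float:
    """Janmahasatian (2005) lean body weight, kg.

    male:   9270*TBW / (6680 + 216*BMI)
    female: 9270*TBW / (8780 + 244*BMI),  BMI = TBW / height^2 (kg/m^2).

    Always strictly below TBW for physiological inputs.  Non-physiological
    BMI (outside 10-100) triggers a warning but still returns the value.
    """
    if not (tbw > 0 and height > 0):
        raise ValueError("tbw and height must be positive")
    bmi = tbw / height**2
    if not 10.0 <= bmi <= 100.0:
        warnings.warn(f"BMI {bmi:.1f} outside 10-100; LBW may be unreliable")
    s = sex.strip().lower()
    if s in ("male", "m"):
        return 9270.0 * tbw / (6680.0 + 216.0 * bmi)
    if s in ("female", "f"):
        return 9270.0 * tbw / (8780.0 + 244.0 * bmi)
    raise ValueError(f"unknown sex {sex!r}")


def lean_body_weight_hume(sex: str, tbw: float, height: float) -> float:
    """Hume (1966) alternative LBW formula (height in m), kg."""
    h_cm = height * 100.0
    s = sex.strip().lower()
    if s in ("male", "m"):
        return 0.32810 * tbw + 0.33929 * h_cm - 29.5336
    if s in ("female", "f"):
        return 0.29569 * tbw + 0.41813 * h_cm - 43.2933
    raise ValueError(f"unknown sex {sex!r}")


def egfr_mdrd(scr: float, age: float, sex: str, race: str) -> float:
    """Four-variable MDRD estimated GFR, ml/min/1.73 m^2.

    175 * Scr^-1.154 * age^-0.203 * 0.742(if female) * 1.212(if Black).
    """
    if not (scr > 0 and age > 0):
        raise ValueError("scr and age must be positive")
    gfr = 175.0 * scr**-1.154 * age**-0.203
    if sex.strip().lower() in ("female", "f"):
        gfr *= 0.742
    if race.strip().lower() == "black":
        gfr *= 1.212
    return gfr
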