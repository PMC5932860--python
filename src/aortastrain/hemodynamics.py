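"""Derived echocardiographic and hemodynamic indices.

Per-subject measurements (Doppler velocities and VTIs, cuff pressures, LVOT
diameter, BSA) are turned into the standard derived indices of aortic
stenosis assessment: simplified-Bernoulli peak gradient, continuity-equation
stroke volume and valve area, mean arterial pressure, systemic vascular
resistance, systemic arterial compliance, arterial elastance and
valvulo-arterial impedance.  Every index is computed exactly by its textbook
formula; missing inputs yield absent (None) outputs rather than errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

__all__ = ["EchoRecord", "DerivedIndices", "derive_indices", "severity_flags",
           "derive_table"]


@dataclass
class EchoRecord:
    """Per-subject echo/hemodynamic measurements (None where not acquired).

    Units: heart_rate bpm; sbp/dbp/mean_gradient mmHg; lvot_diameter cm;
    vti_lvot/vti_av cm; peak_av_velocity m/s; bsa m^2; lvef %.
    """

    subject: str | None = None
    heart_rate: float | None = None
    sbp: float | None = None
    dbp: float | None = None
    lvot_diameter: float | None = None
    vti_lvot: float | None = None
    vti_av: float | None = None
    peak_av_velocity: float | None = None
    mean_gradient: float | None = None
    bsa: float | None = None
    lvef: float | None = None
    lv_edv: float | None = None
    lv_esv: float | None = None

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name != "subject" and v is not None and v <= 0:
                raise ValueError(f"{f.name} must be positive, got {v}")
        if self.sbp is not None and self.dbp is not None and self.sbp <= self.dbp:
            raise ValueError("systolic pressure must exceed diastolic pressure")
        if (self.vti_av is not None and self.vti_lvot is not None
                and self.vti_av < self.vti_lvot):
            warnings.warn("AV VTI below LVOT VTI: not consistent with a stenotic valve",
                          stacklevel=2)


@dataclass
class DerivedIndices:
    """Derived indices; None where inputs were missing.

    Units: pulse_pressure/map/peak_gradient mmHg; sv mL; svi mL/m^2;
    co L/min; ava cm^2; svr mmHg*min/L (Wood x 80); sac mL/mmHg/m^2;
    ea mmHg/mL; zva mmHg/mL/m^2.
    """

    pulse_pressure: float | None = None
    map: float | None = None
    peak_gradient: float | None = None
    sv: float | None = None
    svi: float | None = None
    co: float | None = None
    ava: float | None = None
    svr: float | None = None
    sac: float | None = None
    ea: float | None = None
    zva: float | None = None

    def to_dict(self) -> dict:
        return dict(vars(self))


def _warn_denominator(index: str, denom_name: str) -> None:
    warnings.warn(f"{index} not computed: {denom_name} is zero or missing", stacklevel=3)


def derive_indices(rec: EchoRecord) -> DerivedIndices:
    """Evaluate every derivable index by its printed clinical formula.

    peak gradient = 4 v^2 ; SV = D_LVOT^2 x 0.785 x VTI_LVOT ;
    AVA = D_LVOT^2 x 0.785 x (VTI_LVOT / VTI_AV) ; MAP = DBP + PP/3 ;
    SVR = 80 x MAP / CO with CO = SV x HR (L/min) ; SAC = SVi / PP ;
    Ea = 0.9 x SBP / SVi ; Zva = (SBP + MG) / SVi.
    """
    out = DerivedIndices()
    if rec.sbp is not None and rec.dbp is not None:
        out.pulse_pressure = rec.sbp - rec.dbp
        out.map = rec.dbp + out.pulse_pressure / 3.0
    if rec.peak_av_velocity is not None:
        out.peak_gradient = 4.0 * rec.peak_av_velocity**2
    if rec.lvot_diameter is not None and rec.vti_lvot is not None:
        out.sv = rec.lvot_diameter**2 * 0.785 * rec.vti_lvot  # mL (cm^3)
        if rec.vti_av is not None:
            out.ava = rec.lvot_diameter**2 * 0.785 * (rec.vti_lvot / rec.vti_av)
        if rec.bsa is not None:
            out.svi = out.sv / rec.bsa
        if rec.heart_rate is not None:
            out.co = out.sv * rec.heart_rate / 1000.0  # L/min
    if out.map is not None and out.co is not None:
        if out.co > 0:
            out.svr = 80.0 * out.map / out.co
        else:
            _warn_denominator("svr", "cardiac output")
    if out.svi is not None and out.pulse_pressure is not None:
        if out.pulse_pressure > 0:
            out.sac = out.svi / out.pulse_pressure
        else:
            _warn_denominator("sac", "pulse pressure")
    if out.svi is not None and out.svi > 0:
        if rec.sbp is not None:
            out.ea = rec.sbp * 0.9 / out.svi
            if rec.mean_gradient is not None:
                out.zva = (rec.sbp + rec.mean_gradient) / out.svi
    return out


def severity_flags(mean_gradient: float | None, svi: float | None) -> dict:
    """Flow/gradient phenotype flags.

    ``low_flow_low_gradient``: mean transvalvular gradient < 40 mmHg with a
    stroke volume index < 35 mL/m^2; None when either input is missing.
    """
    flag = None
    if mean_gradient is not None and svi is not None:
        flag = bool(mean_gradient < 40.0 and svi < 35.0)
    return {"low_flow_low_gradient": flag}


def derive_table(records: pd.DataFrame | str | Path) -> pd.DataFrame:
    """Apply ``derive_indices`` row-wise to a per-subject CSV or DataFrame."""
    if not isinstance(records, pd.DataFrame):
        records = pd.read_csv(records)
    known = {f.name for f in fields(EchoRecord)}
    rows = []
    for _, row in records.iterrows():
        kwargs = {k: (None if pd.isna(v) else v) for k, v in row.items() if k in known}
        rec = EchoRecord(**kwargs)
        idx = derive_indices(rec)
        flags = severity_flags(rec.mean_gradient, idx.svi)
        rows.append({**{k: kwargs.get(k) for k in known}, **idx.to_dict(), **flags})
    return pd.DataFrame(rows)
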