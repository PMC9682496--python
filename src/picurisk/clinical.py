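"""Flowsheet vitals, labs, derived indices and sample-and-hold merging.

Intermittent clinical observations (nurse-charted vitals, lab draws) are
carried forward onto the 30-minute window grid by sample-and-hold and
censored once stale: flowsheet vitals older than 24 h and labs older
than 48 h at query time are treated as missing.

Derived quantities: the estimated PO2/FiO2 ratio (ePFR) obtained by
inverting the oxyhemoglobin dissociation curve at the observed SpO2 and
dividing by an FiO2 estimate; the anion gap (Na - Cl - HCO3); and the
BUN to creatinine ratio.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from scipy.optimize import brentq

__all__ = [
    "FLOWSHEET_VARIABLES",
    "LAB_ANALYTES",
    "CLINICAL_FEATURES",
    "VITALS_HORIZON_S",
    "LABS_HORIZON_S",
    "flow_to_fio2",
    "severinghaus_po2",
    "epfr",
    "derived_labs",
    "sample_and_hold",
    "assemble_clinical",
]

#: flowsheet (nurse-charted) variables consumed from flowsheet.csv
FLOWSHEET_VARIABLES = [
    "HR", "RR", "SpO2", "SBP", "DBP", "temperature", "FiO2", "O2_flow",
]

#: the eleven frequently measured serum/blood analytes
LAB_ANALYTES = ["Na", "K", "Cl", "HCO3", "BUN", "Cr",
                "glucose", "Ca", "WBC", "Hct", "Plt"]

#: columns of the assembled per-window clinical feature row:
#: 8 vital-sign features (flowsheet vitals + ePFR) and 13 lab features
#: (11 analytes + anion gap + BUN/Cr), plus age appended downstream
VITAL_FEATURES = ["fs_HR", "fs_RR", "fs_SpO2", "fs_SBP", "fs_DBP",
                  "temperature", "FiO2", "ePFR"]
LAB_FEATURES = LAB_ANALYTES + ["anion_gap", "BUN_Cr_ratio"]
CLINICAL_FEATURES = VITAL_FEATURES + LAB_FEATURES

VITALS_HORIZON_S = 24 * 3600
LABS_HORIZON_S = 48 * 3600

#: assumed FiO2 increment per L/min of supplemental oxygen flow
FIO2_PER_LPM = 0.03
#: SpO2 cap before dissociation-curve inversion (flat portion of the curve)
SPO2_CAP = 0.96


def flow_to_fio2(o2_flow_lpm: float, recorded_fio2: float | None = None,
                 *, per_lpm: float = FIO2_PER_LPM) -> float:
    """Estimate FiO2 from supplemental oxygen flow.

    A charted FiO2 takes precedence.  Otherwise room air (0.21) plus
    ``per_lpm`` per L/min of flow, capped at 1.0; zero flow is room air.
    """
    if recorded_fio2 is not None and not (isinstance(recorded_fio2, float)
                                          and math.isnan(recorded_fio2)):
        return float(recorded_fio2)
    if o2_flow_lpm is None or (isinstance(o2_flow_lpm, float)
                               and math.isnan(o2_flow_lpm)):
        return math.nan
    if o2_flow_lpm < 0:
        raise ValueError(f"negative oxygen flow: {o2_flow_lpm} L/min")
    return min(1.0, 0.21 + per_lpm * float(o2_flow_lpm))


def _saturation(po2: float) -> float:
    """Oxyhemoglobin saturation at a given PO2 (Severinghaus 1979)."""
    return 1.0 / (23400.0 / (po2 ** 3 + 150.0 * po2) + 1.0)


def severinghaus_po2(spo2: float, *, cap: float = SPO2_CAP,
                     xtol: float = 0.01) -> float:
    """Invert the dissociation curve: PO2 (mmHg) at the observed SpO2.

    SpO2 is capped at ``cap`` before inversion because the curve is
    nearly flat above it and the inverse ill-conditioned.  The unique
    positive root of S(P) = SpO2 is bracketed and bisected to within
    ``xtol`` mmHg.
    """
    if isinstance(spo2, float) and math.isnan(spo2):
        return math.nan
    if spo2 <= 0 or spo2 > 1:
        raise ValueError(f"SpO2 must be in (0, 1], got {spo2}")
    s = min(float(spo2), cap)
    return float(brentq(lambda p: _saturation(p) - s, 1e-6, 700.0, xtol=xtol))


def epfr(spo2: float, fio2: float) -> float:
    """Estimated PO2/FiO2 ratio (mmHg): severinghaus_po2(SpO2) / FiO2."""
    if any(v is None or (isinstance(v, float) and math.isnan(v))
           for v in (spo2, fio2)):
        return math.nan
    if fio2 < 0.21:
        raise ValueError(f"FiO2 below room air: {fio2}")
    return severinghaus_po2(spo2) / float(fio2)


def derived_labs(na: float, cl: float, hco3: float,
                 bun: float, cr: float) -> tuple[float, float]:
    """Anion gap (mEq/L) and BUN/creatinine ratio.

    Each is missing when any component is missing; the ratio is missing
    when creatinine is zero.
    """
    def _nan(v):
        return v is None or (isinstance(v, float) and math.isnan(v))

    gap = math.nan if any(map(_nan, (na, cl, hco3))) else float(na - cl - hco3)
    if any(map(_nan, (bun, cr))) or cr == 0:
        ratio = math.nan
    else:
        ratio = float(bun) / float(cr)
    return gap, ratio


def sample_and_hold(times: np.ndarray, values: np.ndarray,
                    query_times: np.ndarray, horizon_s: float) -> np.ndarray:
    """Hold the last measurement at or before each query time.

    Causal by construction; a query with no prior measurement, or whose
    held value is strictly older than ``horizon_s``, is missing.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("measurement times must be sorted")
    q = np.asarray(query_times, dtype=float)
    out = np.full(q.shape, np.nan)
    if t.size == 0:
        return out
    idx = np.searchsorted(t, q, side="right") - 1
    has = idx >= 0
    stale = np.full(q.shape, np.inf)
    stale[has] = q[has] - t[idx[has]]
    keep = has & (stale <= horizon_s)
    out[keep] = v[idx[keep]]
    return out


def assemble_clinical(flowsheet: pd.DataFrame, labs: pd.DataFrame,
                      window_ends: np.ndarray, age_years: float,
                      *, vitals_horizon_s: float = VITALS_HORIZON_S,
                      labs_horizon_s: float = LABS_HORIZON_S) -> pd.DataFrame:
    """One clinical feature row per window end-time for one admission.

    ``flowsheet`` and ``labs`` are long tables with columns
    (time_s, variable|analyte, value).  Derived quantities (FiO2 from
    flow, ePFR, anion gap, BUN/Cr) are computed *after* holding, so a
    derived value is present exactly when all held components are fresh.
    """
    q = np.asarray(window_ends, dtype=float)
    out = pd.DataFrame(index=np.arange(q.size))
    out["t"] = q.astype(int)

    def _held(table: pd.DataFrame, key_col: str, key: str,
              horizon: float) -> np.ndarray:
        sub = table[table[key_col] == key].sort_values("time_s")
        return sample_and_hold(sub["time_s"].to_numpy(),
                               sub["value"].to_numpy(), q, horizon)

    fs = {v: _held(flowsheet, "variable", v, vitals_horizon_s)
          for v in FLOWSHEET_VARIABLES}
    for src, col in (("HR", "fs_HR"), ("RR", "fs_RR"), ("SpO2", "fs_SpO2"),
                     ("SBP", "fs_SBP"), ("DBP", "fs_DBP"),
                     ("temperature", "temperature")):
        out[col] = fs[src]

    fio2 = np.array([
        flow_to_fio2(flow, rec if math.isfinite(rec) else None)
        if (math.isfinite(flow) or math.isfinite(rec)) else math.nan
        for flow, rec in zip(fs["O2_flow"], fs["FiO2"])
    ])
    out["FiO2"] = fio2
    out["ePFR"] = np.array([
        epfr(s, f) if (math.isfinite(s) and math.isfinite(f)) else math.nan
        for s, f in zip(fs["SpO2"], fio2)
    ])

    lab = {a: _held(labs, "analyte", a, labs_horizon_s) for a in LAB_ANALYTES}
    for a in LAB_ANALYTES:
        out[a] = lab[a]
    gaps, ratios = zip(*(derived_labs(na, cl, h, b, c) for na, cl, h, b, c in
                         zip(lab["Na"], lab["Cl"], lab["HCO3"],
                             lab["BUN"], lab["Cr"]))) if q.size else ((), ())
    out["anion_gap"] = np.asarray(gaps, dtype=float)
    out["BUN_Cr_ratio"] = np.asarray(ratios, dtype=float)
    out["age_years"] = float(age_years)
    return out
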