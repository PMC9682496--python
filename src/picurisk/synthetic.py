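"""Seed-reproducible synthetic PICU cohorts.

No public dataset with continuous 0.5 Hz monitoring, inter-beat
intervals, flowsheet vitals, labs and airway events exists for this
problem, so the package ships a generator that emulates the statistical
structure the analysis assumes:

* admissions with a configurable mix of medical, cardiac-surgery and
  non-cardiac-surgery patients, cardiac-surgery ages skewed to infancy;
* age-dependent baseline vitals (piecewise-constant pediatric norms)
  with AR(1) noise on a 2-s grid;
* a configurable physiological prodrome — linear ramps in HR, RR, SpO2,
  blood pressure, oxygen flow, labs and inter-beat variability over the
  final 12 h before an unplanned intubation;
* sparse "sample-and-hold" non-invasive blood pressure, hourly
  flowsheet charting, irregular lab cadence;
* intubation/extubation events with indication and location, ventilator
  respiratory-rate runs, operating-room records consistent with patient
  type, and optional elective (operating-room) intubations so the
  chart-review vs computable-phenotype contrast is exercisable.

Time is seconds since hospital admission; continuous channels live on an
implicit 2-s grid starting at 0.  Everything is a pure function of the
configuration, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "CohortConfig",
    "ProdromeSpec",
    "AdmissionStreams",
    "CohortBundle",
    "ConfigError",
    "generate_cohort",
    "generate_rri_segment",
    "emit_cohort",
    "PATIENT_TYPES",
    "INDICATIONS",
]

PATIENT_TYPES = ["medical", "cardiac_surgery", "noncardiac_surgery"]
#: non-elective indication mix (respiratory failure 64%, both 14%,
#: hemodynamic instability 12%, other 10%)
INDICATIONS = ["respiratory_failure", "both", "hemodynamic_instability", "other"]
INDICATION_P = [0.64, 0.14, 0.12, 0.10]

GRID_DT_S = 2  # 0.5 Hz
PRODROME_S = 12 * 3600


class ConfigError(ValueError):
    """Invalid cohort configuration; the message names the field."""


@dataclass(frozen=True)
class ProdromeSpec:
    """Effect sizes of the pre-intubation prodrome, ramped linearly
    from zero at 12 h before the event to the full value at the event.

    Units: bpm, breaths/min, SpO2 fraction, mmHg, L/min; ``lab_shifts``
    are additive in each analyte's conventional units; ``rri_var_factor``
    multiplies the inter-beat noise SD at event time (values < 1 model
    the loss of heart-rate variability that accompanies deterioration).
    """

    d_hr: float = 25.0
    d_rr: float = 10.0
    d_spo2: float = -0.05
    d_sbp: float = -15.0
    d_flow: float = 4.0
    lab_shifts: dict = field(default_factory=lambda: {
        "HCO3": -5.0, "WBC": 6.0, "Plt": -60.0})
    rri_var_factor: float = 0.5


@dataclass(frozen=True)
class CohortConfig:
    n_admissions: int = 400
    #: proportions (medical, cardiac_surgery, noncardiac_surgery)
    patient_type_mix: tuple = (0.45, 0.24, 0.31)
    #: probability an admission has an unplanned intubation event
    event_rate: float = 0.033
    #: fraction of *surgical* admissions receiving a planned, elective,
    #: operating-room intubation (exercises the computable phenotype)
    elective_rate: float = 0.25
    #: optional (age_years, multiplier): admissions younger than the
    #: threshold have their event probability multiplied (capped at 1)
    age_risk: tuple | None = None
    prodrome: dict = field(default_factory=lambda: {
        t: ProdromeSpec() for t in PATIENT_TYPES})
    #: monitored-stay duration law, uniform in seconds
    duration_s: tuple = (20 * 3600, 32 * 3600)
    #: mean gap between lab draws, hours
    lab_interval_h: float = 12.0
    #: nurse charting cadence (q2h) and single-observation noise SD
    flowsheet_interval_s: int = 7200
    charting_noise: float = 2.0
    #: fraction of admissions on baseline supplemental oxygen
    baseline_o2_rate: float = 0.25
    #: ventilation duration after intubation, uniform in seconds
    vent_duration_s: tuple = (6 * 3600, 18 * 3600)
    #: probability a 2-s RRI sample is replaced by an implausible artifact
    artifact_rate: float = 2e-4
    seed: int = 0

    def validate(self) -> None:
        if self.n_admissions < 1:
            raise ConfigError("n_admissions must be >= 1")
        mix = np.asarray(self.patient_type_mix, dtype=float)
        if mix.size != 3 or np.any(mix < 0) or np.any(mix > 1) \
                or abs(mix.sum() - 1.0) > 1e-9:
            raise ConfigError(
                "patient_type_mix must be 3 proportions in [0,1] summing to 1")
        for name in ("event_rate", "elective_rate", "artifact_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        lo, hi = self.duration_s
        if not (0 < lo <= hi):
            raise ConfigError("duration_s must be a positive (lo, hi) pair")
        if lo < PRODROME_S + 2 * 3600:
            raise ConfigError(
                "duration_s lower bound must leave >= 12 h of pre-event "
                "monitoring plus baseline")


@dataclass
class AdmissionStreams:
    """Continuous monitoring for one admission on the 2-s grid."""

    start_s: int
    hr: np.ndarray
    rr: np.ndarray
    so2: np.ndarray
    ibp_sys: np.ndarray | None
    ibp_dia: np.ndarray | None
    nibp: pd.DataFrame  # time_s, sys, dia
    vent_rr_times: np.ndarray

    @property
    def end_s(self) -> int:
        return self.start_s + GRID_DT_S * len(self.hr)

    def grid(self) -> np.ndarray:
        return self.start_s + GRID_DT_S * np.arange(len(self.hr))


@dataclass
class CohortBundle:
    admissions: pd.DataFrame
    streams: dict
    rri: dict  # admission_id -> (beat times s, intervals ms)
    flowsheet: pd.DataFrame
    labs: pd.DataFrame
    events: pd.DataFrame
    or_records: pd.DataFrame
    config: CohortConfig | None = None

    @property
    def n_admissions(self) -> int:
        return len(self.admissions)


# --- age-dependent baseline norms (piecewise constant) -----------------

_AGE_EDGES = [1.0, 3.0, 6.0, 12.0]


def _by_age(age: float, values: list[float]) -> float:
    return values[int(np.searchsorted(_AGE_EDGES, age, side="right"))]


def _norms(age: float) -> dict[str, float]:
    return {
        "HR": _by_age(age, [130.0, 115.0, 100.0, 90.0, 80.0]),
        "RR": _by_age(age, [35.0, 28.0, 24.0, 20.0, 16.0]),
        "SO2": 0.97,
        "SBP": _by_age(age, [85.0, 95.0, 100.0, 105.0, 115.0]),
        "DBP": _by_age(age, [50.0, 55.0, 60.0, 62.0, 68.0]),
    }


_MARGINAL_SD = {"HR": 6.0, "RR": 4.0, "SO2": 0.01, "SBP": 8.0, "DBP": 6.0}
_BOUNDS = {"HR": (40.0, 250.0), "RR": (5.0, 100.0), "SO2": (0.5, 1.0),
           "SBP": (30.0, 250.0), "DBP": (15.0, 150.0)}

_LAB_NORMS = {  # (mean, sd) in conventional units
    "Na": (140.0, 3.0), "K": (4.2, 0.5), "Cl": (104.0, 3.0),
    "HCO3": (24.0, 3.0), "BUN": (12.0, 5.0), "Cr": (0.4, 0.15),
    "glucose": (100.0, 20.0), "Ca": (9.5, 0.6), "WBC": (9.0, 3.0),
    "Hct": (35.0, 4.0), "Plt": (250.0, 80.0),
}


def _ar1(rng: np.random.Generator, n: int, sd: float,
         phi: float = 0.995) -> np.ndarray:
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - phi * phi), size=n)
    return lfilter([1.0], [1.0, -phi], eps)


def _sample_age(rng: np.random.Generator, ptype: str) -> float:
    # cardiac surgery skews to infancy; others spread across 0-18 y
    if ptype == "cardiac_surgery":
        w, scale = 0.8, 1.0
    else:
        w, scale = 0.35, 1.5
    if rng.random() < w:
        age = rng.exponential(scale)
    else:
        age = rng.uniform(0.0, 18.0)
    return float(min(age, 18.0))


def _ramp(t: np.ndarray, event_s: float | None) -> np.ndarray:
    """Linear 0->1 ramp over the final 12 h before the event, 0 after."""
    if event_s is None:
        return np.zeros_like(t, dtype=float)
    r = np.clip((t - (event_s - PRODROME_S)) / PRODROME_S, 0.0, 1.0)
    r[t >= event_s] = 0.0
    return r


def _rri_from_hr(rng: np.random.Generator, grid: np.ndarray, hr: np.ndarray,
                 ramp_fn, var_factor: float, sd_ms: float = 25.0,
                 artifact_rate: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Beat times by time-rescaling of the HR trend, plus HRV noise.

    The cumulative beat intensity Lambda(t) = integral HR/60 dt is
    inverted on the 2-s grid so beats fall at integer Lambda; interval
    noise is AR(1) with SD shrinking toward ``var_factor``·SD along the
    pre-event ramp.
    """
    lam = np.cumsum(hr / 60.0) * GRID_DT_S
    n_beats = int(lam[-1])
    if n_beats < 3:
        return np.array([]), np.array([])
    beats = np.interp(np.arange(1, n_beats + 1, dtype=float), lam, grid)
    rri = np.diff(beats) * 1000.0
    t_rri = beats[1:].astype(np.float32)
    scale = 1.0 - (1.0 - var_factor) * ramp_fn(t_rri)
    rri = rri + _ar1(rng, rri.size, sd_ms, phi=0.9) * scale
    rri = np.maximum(rri, 260.0)
    if artifact_rate > 0:
        bad = rng.random(rri.size) < artifact_rate
        rri[bad] = rng.uniform(2100.0, 4000.0, size=int(bad.sum()))
    return t_rri, rri.astype(np.float32)


def generate_rri_segment(duration_s: float, mean_ms: float, sd_ms: float,
                         dynamics_class: str = "regular",
                         seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stand-alone inter-beat-interval segment of a given character.

    ``regular`` is an AR(1) rhythm (organized, repeatable — low sample
    entropy); ``erratic`` draws i.i.d. intervals uniform around the mean
    (maximally irregular at matched SD — high entropy, exercising the
    AF surrogate); ``low_variability`` shrinks the SD five-fold.
    Returns (beat times s, intervals ms).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if mean_ms <= 0 or sd_ms < 0:
        raise ValueError("mean_ms must be positive and sd_ms non-negative")
    if dynamics_class not in ("regular", "erratic", "low_variability"):
        raise ValueError(f"unknown dynamics_class: {dynamics_class!r}")
    rng = np.random.default_rng(seed)
    n = max(3, int(round(duration_s / (mean_ms / 1000.0))))
    if dynamics_class == "erratic":
        half = np.sqrt(3.0) * sd_ms
        rri = rng.uniform(mean_ms - half, mean_ms + half, size=n)
    else:
        sd = sd_ms if dynamics_class == "regular" else 0.2 * sd_ms
        rri = mean_ms + _ar1(rng, n, sd, phi=0.9)
    rri = np.maximum(rri, 0.3 * mean_ms)
    times = np.cumsum(rri) / 1000.0
    return times, rri


def _simulate_admission(rng: np.random.Generator, adm_id: str, age: float,
                        ptype: str, has_event: bool, elective: bool,
                        cfg: CohortConfig):
    dur = int(rng.uniform(*cfg.duration_s)) // GRID_DT_S * GRID_DT_S
    norms = _norms(age)
    spec: ProdromeSpec = cfg.prodrome.get(ptype, ProdromeSpec())

    event_s = None
    if has_event:
        event_s = float(int(rng.uniform(PRODROME_S + 2 * 3600, dur - 2 * 3600)))
    grid = (GRID_DT_S * np.arange(dur // GRID_DT_S)).astype(float)
    ramp = _ramp(grid, event_s)

    def channel(name: str, delta: float) -> np.ndarray:
        base = norms[name] + _ar1(rng, grid.size, _MARGINAL_SD[name])
        lo, hi = _BOUNDS[name]
        return np.clip(base + delta * ramp, lo, hi).astype(np.float32)

    hr = channel("HR", spec.d_hr)
    rr = channel("RR", spec.d_rr)
    so2 = channel("SO2", spec.d_spo2)

    has_ibp = ptype == "cardiac_surgery" or rng.random() < 0.3
    ibp_sys = channel("SBP", spec.d_sbp) if has_ibp else None
    ibp_dia = channel("DBP", spec.d_sbp * 0.6) if has_ibp else None

    nibp_t = np.arange(600, dur, 1200, dtype=float)
    nibp_ramp = _ramp(nibp_t, event_s)
    nibp = pd.DataFrame({
        "time_s": nibp_t.astype(int),
        "sys": norms["SBP"] + spec.d_sbp * nibp_ramp
        + rng.normal(0, _MARGINAL_SD["SBP"], nibp_t.size),
        "dia": norms["DBP"] + 0.6 * spec.d_sbp * nibp_ramp
        + rng.normal(0, _MARGINAL_SD["DBP"], nibp_t.size),
    })

    rri_t, rri_v = _rri_from_hr(rng, grid, hr.astype(float),
                                lambda t: _ramp(t, event_s),
                                spec.rri_var_factor,
                                artifact_rate=cfg.artifact_rate)

    # --- events, ventilation, extubation, OR records -------------------
    events = []
    or_records = []
    vent_times: list[float] = []
    if elective:
        t_or = float(int(rng.uniform(3600, 2 * 3600)))
        events.append((adm_id, t_or, "intubation", True, False, "elective"))
        v_end = float(int(min(t_or + rng.uniform(*cfg.vent_duration_s),
                              dur - 3600.0)))
        vent_times.extend(np.arange(t_or, v_end, 3600.0))
        events.append((adm_id, v_end, "extubation", False, True, "none"))
        service = ("thoracic_cardiovascular" if ptype == "cardiac_surgery"
                   else "other")
        or_records.append((adm_id, t_or, service))
    elif ptype != "medical":
        # surgical patients carry an OR record even without an airway event
        service = ("thoracic_cardiovascular" if ptype == "cardiac_surgery"
                   else "other")
        or_records.append((adm_id, float(rng.uniform(0, 3600)), service))
    if has_event:
        ind = rng.choice(INDICATIONS, p=INDICATION_P)
        events.append((adm_id, event_s, "intubation", False, True, str(ind)))
        v_end = float(int(min(event_s + rng.uniform(*cfg.vent_duration_s),
                              float(dur))))
        vent_times.extend(np.arange(event_s, v_end, 3600.0))
        if v_end < dur - 1800:
            events.append((adm_id, v_end, "extubation", False, True, "none"))

    streams = AdmissionStreams(
        start_s=0, hr=hr, rr=rr, so2=so2, ibp_sys=ibp_sys, ibp_dia=ibp_dia,
        nibp=nibp, vent_rr_times=np.array(sorted(vent_times)))

    # --- flowsheet ------------------------------------------------------
    fs_t = np.arange(1800, dur, cfg.flowsheet_interval_s, dtype=float)
    idx = np.clip((fs_t / GRID_DT_S).astype(int), 0, grid.size - 1)
    fs_ramp = _ramp(fs_t, event_s)
    base_flow = (rng.uniform(0.5, 2.0)
                 if rng.random() < cfg.baseline_o2_rate else 0.0)
    flow = np.clip(base_flow + spec.d_flow * fs_ramp
                   + rng.normal(0, 0.2, fs_t.size), 0.0, None)
    flow[flow < 0.3] = 0.0
    flow = np.round(flow * 2.0) / 2.0  # charted to the half litre
    cn = cfg.charting_noise
    rows = []
    for var, vals in (
            ("HR", np.round(hr[idx] + rng.normal(0, cn, fs_t.size))),
            ("RR", np.round(rr[idx] + rng.normal(0, cn, fs_t.size))),
            ("SpO2", np.round(np.clip(
                so2[idx] + rng.normal(0, 0.01, fs_t.size), 0.5, 1.0), 2)),
            ("SBP", np.round(np.interp(fs_t, nibp_t, nibp["sys"]))),
            ("DBP", np.round(np.interp(fs_t, nibp_t, nibp["dia"]))),
            ("temperature", 37.0 + rng.normal(0, 0.4, fs_t.size)),
            ("O2_flow", flow)):
        rows.append(pd.DataFrame({"admission_id": adm_id,
                                  "time_s": fs_t.astype(int),
                                  "variable": var,
                                  "value": np.asarray(vals, dtype=float)}))
    flowsheet = pd.concat(rows, ignore_index=True)

    # --- labs -----------------------------------------------------------
    lab_rows = []
    for analyte, (mu, sd) in _LAB_NORMS.items():
        t = 1800.0 + rng.exponential(cfg.lab_interval_h * 3600.0)
        times = []
        while t < dur:
            times.append(t)
            t += rng.exponential(cfg.lab_interval_h * 3600.0)
        if not times:
            times = [float(rng.uniform(1800, dur))]
        times = np.asarray(sorted(times))
        shift = spec.lab_shifts.get(analyte, 0.0) * _ramp(times, event_s)
        vals = np.maximum(mu + rng.normal(0, sd, times.size) + shift, 0.01)
        lab_rows.append(pd.DataFrame({
            "admission_id": adm_id, "time_s": times.astype(int),
            "analyte": analyte, "value": vals}))
    labs = pd.concat(lab_rows, ignore_index=True)

    died = rng.random() < (0.185 if has_event else 0.033)
    los_days = dur / 86400.0 + (rng.exponential(20.0) if has_event
                                else rng.exponential(3.0))
    admission = {
        "admission_id": adm_id, "age_years": age, "patient_type": ptype,
        "sex": "M" if rng.random() < 0.55 else "F",
        "picu_in_s": 0, "picu_out_s": dur,
        "died": bool(died), "los_days": float(los_days),
    }
    return (admission, streams, (rri_t, rri_v), flowsheet, labs,
            events, or_records)


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Simulate a full cohort; deterministic for a given configuration.

    Every admission with an unplanned event has at least 12 h of
    monitored, at-risk time before it, and the prodrome is applied only
    in that final 12 h.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    mix = np.asarray(config.patient_type_mix, dtype=float)

    admissions, streams, rri = [], {}, {}
    fs_parts, lab_parts, ev_rows, or_rows = [], [], [], []
    for i in range(config.n_admissions):
        adm_id = f"A{i:05d}"
        ptype = str(rng.choice(PATIENT_TYPES, p=mix / mix.sum()))
        age = _sample_age(rng, ptype)
        p_event = config.event_rate
        if config.age_risk is not None and age < config.age_risk[0]:
            p_event = min(1.0, p_event * config.age_risk[1])
        has_event = rng.random() < p_event
        elective = (ptype != "medical" and not has_event
                    and rng.random() < config.elective_rate)
        (adm, st, rr_pair, fs, lb, evs, ors) = _simulate_admission(
            rng, adm_id, age, ptype, has_event, elective, config)
        admissions.append(adm)
        streams[adm_id] = st
        rri[adm_id] = rr_pair
        fs_parts.append(fs)
        lab_parts.append(lb)
        ev_rows.extend(evs)
        or_rows.extend(ors)

    events = pd.DataFrame(
        ev_rows, columns=["admission_id", "time_s", "kind", "elective",
                          "in_picu", "indication"])
    or_records = pd.DataFrame(or_rows,
                              columns=["admission_id", "time_s", "service"])
    empty_fs = pd.DataFrame(
        columns=["admission_id", "time_s", "variable", "value"])
    empty_lab = pd.DataFrame(
        columns=["admission_id", "time_s", "analyte", "value"])
    return CohortBundle(
        admissions=pd.DataFrame(admissions, columns=[
            "admission_id", "age_years", "patient_type", "sex",
            "picu_in_s", "picu_out_s", "died", "los_days"]),
        streams=streams, rri=rri,
        flowsheet=(pd.concat(fs_parts, ignore_index=True)
                   if fs_parts else empty_fs),
        labs=pd.concat(lab_parts, ignore_index=True) if lab_parts else empty_lab,
        events=events, or_records=or_records, config=config)


def emit_cohort(bundle: CohortBundle, directory) -> None:
    """Write the bundle as the package's CSV schemas (see io module)."""
    from . import io as _io
    _io.write_cohort(bundle, directory)
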