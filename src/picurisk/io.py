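"""Cohort table schemas, configuration and the metrics report.

All tables are flat UTF-8 CSV with a header row; times are integer
seconds since hospital admission; missing values are empty fields.

Schemas
-------
admissions.csv        admission_id, age_years, patient_type, sex,
                      picu_in_s, picu_out_s, died, los_days
vitals_continuous.csv admission_id, time_s, channel, value
rri.csv               admission_id, time_s, rri_ms
flowsheet.csv         admission_id, time_s, variable, value
labs.csv              admission_id, time_s, analyte, value
events.csv            admission_id, time_s, kind, elective, in_picu,
                      indication
or_records.csv        admission_id, time_s, service
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clinical import LAB_ANALYTES, FLOWSHEET_VARIABLES
from .synthetic import (AdmissionStreams, CohortBundle, PATIENT_TYPES,
                        GRID_DT_S)

__all__ = [
    "PipelineConfig",
    "SchemaError",
    "write_cohort",
    "read_cohort",
    "write_metrics",
]

CONTINUOUS_CHANNELS = ["HR", "RR", "SO2"]
ALL_CHANNELS = CONTINUOUS_CHANNELS + ["IBP_sys", "IBP_dia",
                                      "NIBP_sys", "NIBP_dia", "vent_RR"]

_SCHEMAS = {
    "admissions.csv": ["admission_id", "age_years", "patient_type", "sex",
                       "picu_in_s", "picu_out_s", "died", "los_days"],
    "vitals_continuous.csv": ["admission_id", "time_s", "channel", "value"],
    "rri.csv": ["admission_id", "time_s", "rri_ms"],
    "flowsheet.csv": ["admission_id", "time_s", "variable", "value"],
    "labs.csv": ["admission_id", "time_s", "analyte", "value"],
    "events.csv": ["admission_id", "time_s", "kind", "elective", "in_picu",
                   "indication"],
    "or_records.csv": ["admission_id", "time_s", "service"],
}


class SchemaError(ValueError):
    """A cohort file violates its declared schema."""


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration; defaults are the published
    analysis settings (800 trees, sqrt-p candidate features, 12-h case
    horizon, 24/48-h censoring, 5 folds, 200 bootstrap replicates,
    30 heatmap replicates)."""

    out_dir: str = "picurisk_out"
    cohort_dir: str | None = None  # read cohort from disk; None = simulate
    seed: int = 0
    n_admissions: int = 400
    event_rate: float = 0.033
    horizon_h: float = 12.0
    event_definition: str = "chart_review"  # or computable_phenotype
    feature_set: str = "all"  # or no_monitoring
    n_trees: int = 800
    mtry: int | None = None
    n_folds: int = 5
    vitals_censor_h: float = 24.0
    labs_censor_h: float = 48.0
    auc_bootstrap: int = 200
    heatmap_reps: int = 30
    heatmap_features: tuple = ("mean_RR",)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.event_definition not in ("chart_review",
                                         "computable_phenotype"):
            raise ValueError(
                f"event_definition: {self.event_definition!r}")
        if self.feature_set not in ("all", "no_monitoring"):
            raise ValueError(f"feature_set: {self.feature_set!r}")
        if self.horizon_h <= 0:
            raise ValueError("horizon_h must be positive")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def _require_columns(df: pd.DataFrame, name: str) -> None:
    missing = [c for c in _SCHEMAS[name] if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing columns {missing}")


def write_cohort(bundle: CohortBundle, directory) -> None:
    """Emit a bundle as the CSV schemas above (lossless round-trip)."""
    d = Path(directory)
    if not d.is_dir():
        raise FileNotFoundError(f"not a directory: {d}")
    bundle.admissions.to_csv(d / "admissions.csv", index=False)

    vit_parts = []
    for adm_id, st in bundle.streams.items():
        grid = st.grid()
        for ch, vals in (("HR", st.hr), ("RR", st.rr), ("SO2", st.so2),
                         ("IBP_sys", st.ibp_sys), ("IBP_dia", st.ibp_dia)):
            if vals is None:
                continue
            vit_parts.append(pd.DataFrame({
                "admission_id": adm_id, "time_s": grid.astype(int),
                "channel": ch, "value": np.asarray(vals, dtype=float)}))
        if len(st.nibp):
            for ch, col in (("NIBP_sys", "sys"), ("NIBP_dia", "dia")):
                vit_parts.append(pd.DataFrame({
                    "admission_id": adm_id,
                    "time_s": st.nibp["time_s"].astype(int),
                    "channel": ch,
                    "value": st.nibp[col].astype(float)}))
        if st.vent_rr_times.size:
            vit_parts.append(pd.DataFrame({
                "admission_id": adm_id,
                "time_s": st.vent_rr_times.astype(int),
                "channel": "vent_RR", "value": 20.0}))
    vitals = (pd.concat(vit_parts, ignore_index=True) if vit_parts
              else pd.DataFrame(columns=_SCHEMAS["vitals_continuous.csv"]))
    vitals.to_csv(d / "vitals_continuous.csv", index=False)

    rri_parts = [pd.DataFrame({"admission_id": adm_id,
                               "time_s": np.asarray(t, dtype=float),
                               "rri_ms": np.asarray(v, dtype=float)})
                 for adm_id, (t, v) in bundle.rri.items() if len(t)]
    rri = (pd.concat(rri_parts, ignore_index=True) if rri_parts
           else pd.DataFrame(columns=_SCHEMAS["rri.csv"]))
    rri.to_csv(d / "rri.csv", index=False)

    bundle.flowsheet.to_csv(d / "flowsheet.csv", index=False)
    bundle.labs.to_csv(d / "labs.csv", index=False)
    bundle.events.to_csv(d / "events.csv", index=False)
    bundle.or_records.to_csv(d / "or_records.csv", index=False)


def _check_sorted(df: pd.DataFrame, name: str, group: str = "admission_id",
                  extra_key: str | None = None) -> None:
    keys = [group] + ([extra_key] if extra_key else [])
    for gid, grp in df.groupby(keys[0]):
        sub = grp
        if extra_key:
            for _, sub2 in grp.groupby(extra_key):
                if np.any(np.diff(sub2["time_s"].to_numpy(float)) < 0):
                    raise SchemaError(f"{name}: unsorted times for {gid}")
            continue
        if np.any(np.diff(sub["time_s"].to_numpy(float)) < 0):
            raise SchemaError(f"{name}: unsorted times for {gid}")


def read_cohort(directory) -> CohortBundle:
    """Read the CSV schemas back into an in-memory bundle.

    Continuous channels are re-gridded onto the 2-s grid implied by
    their timestamps; schema violations raise :class:`SchemaError`
    naming the file and offending rows.
    """
    d = Path(directory)
    if not d.is_dir():
        raise FileNotFoundError(f"not a directory: {d}")
    tables = {}
    for name in _SCHEMAS:
        path = d / name
        if not path.exists():
            raise FileNotFoundError(f"missing cohort file: {path}")
        tables[name] = pd.read_csv(path, float_precision="round_trip")
        _require_columns(tables[name], name)

    adm = tables["admissions.csv"]
    bad_type = ~adm["patient_type"].isin(PATIENT_TYPES)
    if bad_type.any():
        raise SchemaError(
            f"admissions.csv: unknown patient_type at rows "
            f"{list(adm.index[bad_type])}")

    labs = tables["labs.csv"]
    if len(labs):
        bad = ~labs["analyte"].isin(LAB_ANALYTES)
        if bad.any():
            raise SchemaError(
                f"labs.csv: unknown analyte at rows {list(labs.index[bad])}: "
                f"{sorted(labs.loc[bad, 'analyte'].unique())}")
    fs = tables["flowsheet.csv"]
    if len(fs):
        bad = ~fs["variable"].isin(FLOWSHEET_VARIABLES)
        if bad.any():
            raise SchemaError(
                f"flowsheet.csv: unknown variable at rows "
                f"{list(fs.index[bad])}")
    vit = tables["vitals_continuous.csv"]
    if len(vit):
        bad = ~vit["channel"].isin(ALL_CHANNELS)
        if bad.any():
            raise SchemaError(
                f"vitals_continuous.csv: unknown channel at rows "
                f"{list(vit.index[bad])}")
        _check_sorted(vit, "vitals_continuous.csv", extra_key="channel")
    rri_t = tables["rri.csv"]
    if len(rri_t):
        _check_sorted(rri_t, "rri.csv")

    streams = {}
    rri = {}
    for adm_id in adm["admission_id"]:
        sub = vit[vit["admission_id"] == adm_id] if len(vit) else vit
        chans = {}
        for ch in ("HR", "RR", "SO2", "IBP_sys", "IBP_dia"):
            s = sub[sub["channel"] == ch] if len(sub) else sub
            if len(s) == 0:
                chans[ch] = None
                continue
            t = s["time_s"].to_numpy(dtype=int)
            n = t[-1] // GRID_DT_S + 1
            arr = np.full(n, np.nan, dtype=np.float32)
            arr[t // GRID_DT_S] = s["value"].to_numpy(dtype=float)
            chans[ch] = arr
        for ch in CONTINUOUS_CHANNELS:
            if chans[ch] is None:
                chans[ch] = np.zeros(0, dtype=np.float32)
        n_grid = max(len(chans[ch]) for ch in CONTINUOUS_CHANNELS)
        for ch in CONTINUOUS_CHANNELS:
            if len(chans[ch]) < n_grid:
                pad = np.full(n_grid - len(chans[ch]), np.nan, np.float32)
                chans[ch] = np.concatenate([chans[ch], pad])
        nibp_sys = sub[sub["channel"] == "NIBP_sys"] if len(sub) else sub
        nibp_dia = sub[sub["channel"] == "NIBP_dia"] if len(sub) else sub
        nibp = pd.DataFrame({
            "time_s": nibp_sys["time_s"].to_numpy(dtype=int)
            if len(nibp_sys) else np.zeros(0, dtype=int),
            "sys": nibp_sys["value"].to_numpy(dtype=float)
            if len(nibp_sys) else np.zeros(0),
            "dia": nibp_dia["value"].to_numpy(dtype=float)
            if len(nibp_dia) else np.zeros(0),
        })
        vent = sub[sub["channel"] == "vent_RR"] if len(sub) else sub
        streams[adm_id] = AdmissionStreams(
            start_s=0, hr=chans["HR"], rr=chans["RR"], so2=chans["SO2"],
            ibp_sys=chans["IBP_sys"], ibp_dia=chans["IBP_dia"], nibp=nibp,
            vent_rr_times=vent["time_s"].to_numpy(dtype=float)
            if len(vent) else np.zeros(0))
        s = rri_t[rri_t["admission_id"] == adm_id] if len(rri_t) else rri_t
        rri[adm_id] = (s["time_s"].to_numpy(dtype=float),
                       s["rri_ms"].to_numpy(dtype=np.float32))

    return CohortBundle(
        admissions=adm, streams=streams, rri=rri,
        flowsheet=fs, labs=labs, events=tables["events.csv"],
        or_records=tables["or_records.csv"])


def write_metrics(metrics: dict, path) -> None:
    """Write the evaluation report as flat JSON."""
    def _clean(v):
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if isinstance(v, dict):
            return {k: _clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [_clean(x) for x in v]
        return v
    Path(path).write_text(json.dumps(_clean(metrics), indent=2))
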