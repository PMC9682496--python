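"""End-to-end analysis pipeline.

Stages: simulate (or ingest) -> featurize -> label -> cross-validated
forest -> evaluation report -> predictiveness heatmaps.  Each stage is
a plain function over the in-memory cohort bundle so the command-line
subcommands and :func:`run_pipeline` compose to identical results.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical, labeling, monitoring, predictiveness
from .evaluate import (auc, auc_ci_bootstrap, cohort_table, cross_validate,
                       horizon_auc, patient_folds, time_to_event_curve)
from .io import PipelineConfig, write_metrics
from .labeling import HORIZON_4H_S, HORIZON_12H_S
from .monitoring import MONITORING_FEATURES, STRIDE_S, WINDOW_S
from .synthetic import CohortBundle, CohortConfig, generate_cohort

log = logging.getLogger("picurisk")

__all__ = [
    "FEATURE_COLUMNS_ALL",
    "FEATURE_COLUMNS_NO_MONITORING",
    "build_feature_table",
    "label_records",
    "event_times_by_admission",
    "run_pipeline",
]

FEATURE_COLUMNS_ALL = (MONITORING_FEATURES + clinical.CLINICAL_FEATURES
                       + ["age_years"])
FEATURE_COLUMNS_NO_MONITORING = clinical.CLINICAL_FEATURES + ["age_years"]


def _window_slice(arr: np.ndarray, w: monitoring.Window) -> np.ndarray:
    from .synthetic import GRID_DT_S
    return arr[w.t_start // GRID_DT_S: w.t_end // GRID_DT_S]


def build_feature_table(bundle: CohortBundle, *, only_eligible: bool = True,
                        cardiac_dynamics: bool = True) -> pd.DataFrame:
    """Per-window predictor vectors for every admission.

    One row per 30-min window (stamped by end time): the 17 monitoring
    measures, the 21 held clinical features and age.  With
    ``only_eligible`` (default) features are computed only for at-risk
    windows — windows during ventilation or outside the PICU are never
    scored, so skipping them changes nothing downstream.  Setting
    ``cardiac_dynamics=False`` leaves the six inter-beat-interval
    measures missing, which is much faster when only vitals-based
    columns are needed (e.g. a single-feature heatmap).
    """
    parts = []
    for _, adm in bundle.admissions.iterrows():
        adm_id = adm["admission_id"]
        st = bundle.streams[adm_id]
        windows = monitoring.make_windows(st.start_s, st.end_s)
        if not windows:
            continue
        ends = np.array([w.t_end for w in windows], dtype=float)
        eligible = labeling.eligibility(
            ends, [(adm["picu_in_s"], adm["picu_out_s"])],
            labeling.ventilation_episodes(st.vent_rr_times))
        use = [w for w, e in zip(windows, eligible) if e or not only_eligible]
        if not use:
            continue
        rri_t, rri_v = bundle.rri[adm_id]
        nibp = st.nibp
        rows = []
        for w in use:
            nmask = (nibp["time_s"] >= w.t_start) & (nibp["time_s"] < w.t_end) \
                if len(nibp) else np.zeros(0, dtype=bool)
            i0, i1 = np.searchsorted(rri_t, [w.t_start, w.t_end])
            feats = monitoring.compute_window_features(
                _window_slice(st.hr, w), _window_slice(st.rr, w),
                _window_slice(st.so2, w),
                nibp["sys"].to_numpy()[nmask] if len(nibp) else np.zeros(0),
                nibp["dia"].to_numpy()[nmask] if len(nibp) else np.zeros(0),
                _window_slice(st.ibp_sys, w) if st.ibp_sys is not None
                else np.zeros(0),
                _window_slice(st.ibp_dia, w) if st.ibp_dia is not None
                else np.zeros(0),
                rri_v[i0:i1], cardiac_dynamics=cardiac_dynamics)
            feats["t"] = w.t_end
            rows.append(feats)
        mon = pd.DataFrame(rows)
        fs = bundle.flowsheet[bundle.flowsheet["admission_id"] == adm_id]
        lb = bundle.labs[bundle.labs["admission_id"] == adm_id]
        clin = clinical.assemble_clinical(fs, lb, mon["t"].to_numpy(),
                                          adm["age_years"])
        merged = mon.merge(clin, on="t")
        merged.insert(0, "admission_id", adm_id)
        merged["patient_type"] = labeling.patient_type(
            bundle.or_records[bundle.or_records["admission_id"] == adm_id])
        parts.append(merged)
    if not parts:
        return pd.DataFrame(columns=["admission_id", "t"]
                            + FEATURE_COLUMNS_ALL + ["patient_type"])
    return pd.concat(parts, ignore_index=True)


def event_times_by_admission(bundle: CohortBundle, mode: str) -> dict:
    """Filtered unplanned-event times per admission under a definition."""
    out = {}
    for _, adm in bundle.admissions.iterrows():
        adm_id = adm["admission_id"]
        evs = bundle.events[bundle.events["admission_id"] == adm_id]
        selected = labeling.unplanned_events(evs, mode)
        extub = evs.loc[evs["kind"] == "extubation", "time_s"].to_numpy(float)
        kept = labeling.apply_exclusions(
            selected, [(adm["picu_in_s"], adm["picu_out_s"])], extub)
        out[adm_id] = kept["time_s"].to_numpy(dtype=float)
    return out


def label_records(features: pd.DataFrame, bundle: CohortBundle,
                  *, mode: str = "chart_review",
                  horizon_s: float = HORIZON_12H_S) -> pd.DataFrame:
    """Attach eligibility and case/control labels to the feature table."""
    ev_times = event_times_by_admission(bundle, mode)
    parts = []
    for _, adm in bundle.admissions.iterrows():
        adm_id = adm["admission_id"]
        sub = features[features["admission_id"] == adm_id]
        if len(sub) == 0:
            continue
        st = bundle.streams[adm_id]
        t = sub["t"].to_numpy(dtype=float)
        eligible = labeling.eligibility(
            t, [(adm["picu_in_s"], adm["picu_out_s"])],
            labeling.ventilation_episodes(st.vent_rr_times))
        lab = labeling.label(t, eligible, ev_times[adm_id], horizon_s)
        merged = sub.reset_index(drop=True)
        merged["eligible"] = lab["eligible"].to_numpy()
        merged["label"] = lab["label"].to_numpy()
        merged["event_id"] = lab["event_id"].to_numpy()
        parts.append(merged[merged["eligible"]])
    if not parts:
        raise ValueError("no eligible records in cohort")
    return pd.concat(parts, ignore_index=True)


def run_pipeline(config: PipelineConfig,
                 bundle: CohortBundle | None = None) -> dict:
    """Execute every stage and emit artifacts under ``config.out_dir``.

    Returns the metrics dict (also written as ``metrics.json``).
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if bundle is None:
        if config.cohort_dir is not None:
            from .io import read_cohort
            log.info("stage ingest: %s", config.cohort_dir)
            bundle = read_cohort(config.cohort_dir)
        else:
            log.info("stage simulate: n=%d", config.n_admissions)
            bundle = generate_cohort(CohortConfig(
                n_admissions=config.n_admissions,
                event_rate=config.event_rate, seed=config.seed))

    log.info("stage featurize: %d admissions", bundle.n_admissions)
    features = build_feature_table(bundle)
    log.info("featurize: %d window records", len(features))

    horizon_s = float(config.horizon_h) * 3600.0
    records = label_records(features, bundle, mode=config.event_definition,
                            horizon_s=horizon_s)
    n_cases = int((records["label"] == "case").sum())
    log.info("stage label: %d eligible records, %d cases",
             len(records), n_cases)
    if n_cases == 0:
        raise RuntimeError("stage label: no case records in cohort")

    cols = (FEATURE_COLUMNS_ALL if config.feature_set == "all"
            else FEATURE_COLUMNS_NO_MONITORING)
    folds = patient_folds(records["admission_id"], k=config.n_folds,
                          seed=config.seed)
    log.info("stage train/cv: %d folds, %d trees", config.n_folds,
             config.n_trees)
    cv = cross_validate(records, cols, folds, n_trees=config.n_trees,
                        seed=config.seed)
    cv.to_csv(out_dir / "cv_predictions.csv", index=False)

    log.info("stage evaluate")
    ev_times = event_times_by_admission(bundle, config.event_definition)
    y = (cv["label"] == "case").to_numpy()
    point_auc = auc(cv["votes"].to_numpy(), y)
    ci = auc_ci_bootstrap(cv, b=config.auc_bootstrap, seed=config.seed)
    auc4 = horizon_auc(cv, ev_times, HORIZON_4H_S)
    curve = time_to_event_curve(cv, ev_times, by_type=True)
    curve.to_csv(out_dir / "time_to_event_curve.csv", index=False)
    table = cohort_table(
        bundle.admissions,
        [a for a, t in ev_times.items() if len(np.atleast_1d(t))])
    table.to_csv(out_dir / "cohort_table.csv", index=False)

    metrics = {
        "n_admissions": int(bundle.n_admissions),
        "n_records": int(len(records)),
        "n_cases": n_cases,
        "prior_12h": float(y.mean()),
        "auc": point_auc,
        "auc_ci": list(ci),
        "auc_4h": float(auc4),
        "event_definition": config.event_definition,
        "feature_set": config.feature_set,
        "seed": config.seed,
    }

    log.info("stage heatmaps: %s", ", ".join(config.heatmap_features))
    for feat in config.heatmap_features:
        grids = predictiveness.bootstrap_heatmap(
            records, feat, ev_times, reps=config.heatmap_reps,
            seed=config.seed)
        rows = []
        for panel, g in grids.items():
            if not isinstance(g, dict):
                continue
            for i in range(10):
                for j in range(10):
                    rows.append({"panel": panel, "feature_decile": i + 1,
                                 "age_decile": j + 1,
                                 "relative_risk": g["grid"][i, j],
                                 "occupancy": g["occupancy"][i, j]})
        pd.DataFrame(rows).to_csv(out_dir / f"heatmap_{feat}.csv",
                                  index=False)
        profile = predictiveness.marginalize_grid(grids)
        metrics[f"heatmap_{feat}_profile"] = [float(v) for v in profile]

    write_metrics(metrics, out_dir / "metrics.json")
    log.info("pipeline complete: %s", out_dir / "metrics.json")
    return metrics
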