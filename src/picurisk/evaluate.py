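"""Patient-wise cross-validated evaluation of the risk model.

Folds are assigned at the admission level so no patient's records are
split between training and test — row-wise folds leak repeated measures
and inflate performance.  AUC is reported at the record level over all
case and control records where the patient is at risk, at both the
12-h and 4-h pre-event horizons, overall and per patient type, with
percentile confidence intervals from admission-resampled bootstraps.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .model import UnplannedIntubationForest

__all__ = [
    "patient_folds",
    "cross_validate",
    "auc",
    "horizon_auc",
    "model_grid",
    "auc_ci_bootstrap",
    "auc_above_chance_reduction",
    "time_to_event_curve",
    "cohort_table",
]


def patient_folds(admission_ids, k: int = 5, seed: int = 0) -> dict:
    """Random disjoint admission-level folds of near-equal size."""
    ids = list(dict.fromkeys(admission_ids))  # unique, order-preserving
    if len(ids) < k:
        raise ValueError(f"need at least {k} admissions, got {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = {}
    for pos, idx in enumerate(perm):
        folds[ids[idx]] = pos % k + 1
    return folds


def cross_validate(records: pd.DataFrame, feature_columns: list[str],
                   folds: dict, *, n_trees: int = 800, seed: int = 0,
                   prior12h: float | None = None) -> pd.DataFrame:
    """Out-of-fold votes/relative risk/probability for every record.

    Per fold, the imputer, forest and risk-scaling constants (reference
    mean votes, 12-h prior) are fitted on the training split only.
    Returns ``records`` plus votes, relative_risk and probability.
    """
    rec = records.reset_index(drop=True)
    fold_of = rec["admission_id"].map(folds)
    if fold_of.isna().any():
        raise ValueError("records contain admissions without a fold")
    out = rec.copy()
    for col in ("votes", "relative_risk", "probability"):
        out[col] = np.nan
    rng = np.random.default_rng(seed)
    for f in sorted(fold_of.unique()):
        test = fold_of == f
        train = rec[~test]
        if (train["label"] == "case").sum() == 0:
            raise ValueError(
                f"fold {f}: no case records in training data (re-seed advised)")
        model = UnplannedIntubationForest(
            train[feature_columns],
            train["label"].to_numpy() == "case",
            train["age_years"].to_numpy(),
            n_trees=n_trees, seed=int(rng.integers(0, 2**31 - 1)))
        res = model.fit(prior12h=prior12h)
        risk = res.predict_risk(rec.loc[test, feature_columns],
                                rec.loc[test, "age_years"].to_numpy())
        out.loc[test, ["votes", "relative_risk", "probability"]] = \
            risk.to_numpy()
    return out


def auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney estimator with ties = 1/2.

    The probability that a randomly drawn case score exceeds a randomly
    drawn control score (ties counted half).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both cases and controls")
    ranks = stats.rankdata(s)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def horizon_auc(cv_predictions: pd.DataFrame, event_times: dict,
                horizon_s: float, *, score_col: str = "votes",
                by_type: bool = False):
    """Record-level AUC after relabeling cases to a different horizon.

    ``event_times`` maps admission_id -> array of (filtered) event
    times.  Cases are records within ``horizon_s`` before an event;
    original controls are unchanged; records that were cases at the
    labeling horizon but fall outside the new one are dropped (they are
    neither clean cases nor clean controls).
    """
    if horizon_s <= 0:
        raise ValueError("horizon must be positive")
    rec = cv_predictions
    t = rec["t"].to_numpy(dtype=float)
    new_case = np.zeros(len(rec), dtype=bool)
    for adm, evs in event_times.items():
        mask = (rec["admission_id"] == adm).to_numpy()
        for e in np.atleast_1d(np.asarray(evs, dtype=float)):
            new_case |= mask & (t < e) & (e <= t + horizon_s)
    was_case = (rec["label"] == "case").to_numpy()
    keep = new_case | ~was_case
    sub = rec[keep]
    y = new_case[keep]
    if not by_type:
        return auc(sub[score_col].to_numpy(), y)
    out = {"all": auc(sub[score_col].to_numpy(), y)}
    for ptype, grp in sub.groupby("patient_type"):
        yy = y[sub["patient_type"].to_numpy() == ptype]
        if yy.any() and not yy.all():
            out[str(ptype)] = auc(grp[score_col].to_numpy(), yy)
    return out


def auc_above_chance_reduction(auc_ref: float, auc_alt: float) -> float:
    """Percent of above-chance discrimination lost going ref -> alt:
    100 x (auc_ref - auc_alt) / (auc_ref - 0.5)."""
    if auc_ref <= 0.5:
        raise ValueError("reference AUC must exceed 0.5")
    return 100.0 * (auc_ref - auc_alt) / (auc_ref - 0.5)


def auc_ci_bootstrap(cv_predictions: pd.DataFrame, *, b: int = 200,
                     seed: int = 0, score_col: str = "votes",
                     max_redraws: int = 1000) -> tuple[float, float]:
    """Percentile 95% CI for the record-level AUC.

    Admissions are resampled with replacement B times; a replicate whose
    resample contains a single class is redrawn.
    """
    if b < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    groups = {adm: (grp[score_col].to_numpy(),
                    (grp["label"] == "case").to_numpy())
              for adm, grp in cv_predictions.groupby("admission_id")}
    ids = list(groups)
    aucs = []
    redraws = 0
    while len(aucs) < b:
        pick = rng.choice(len(ids), size=len(ids), replace=True)
        s = np.concatenate([groups[ids[i]][0] for i in pick])
        y = np.concatenate([groups[ids[i]][1] for i in pick])
        if y.all() or not y.any():
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("bootstrap replicates keep losing a class")
            continue
        aucs.append(auc(s, y))
    return (float(np.percentile(aucs, 2.5)),
            float(np.percentile(aucs, 97.5)))


def model_grid(records_by_mode: dict, feature_sets: dict, folds: dict,
               *, n_trees: int = 800, seed: int = 0, ci_b: int = 0) -> pd.DataFrame:
    """Cross-validated AUC for every event definition x feature set.

    ``records_by_mode`` maps event-definition mode (chart_review /
    computable_phenotype) to its labeled record table;
    ``feature_sets`` maps feature-set name (all / no_monitoring) to its
    column list.  Returns one row per cell with AUC and optional
    admission-bootstrap CI (``ci_b`` replicates; 0 skips the CI).
    """
    rows = []
    for mode, records in records_by_mode.items():
        for fs_name, cols in feature_sets.items():
            cv = cross_validate(records, cols, folds,
                                n_trees=n_trees, seed=seed)
            a = auc(cv["votes"].to_numpy(),
                    (cv["label"] == "case").to_numpy())
            lo = hi = math.nan
            if ci_b:
                lo, hi = auc_ci_bootstrap(cv, b=ci_b, seed=seed)
            rows.append({"event_definition": mode, "feature_set": fs_name,
                         "auc": a, "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)


def time_to_event_curve(cv_predictions: pd.DataFrame, event_times: dict,
                        *, bin_s: int = 900, span_s: int = 24 * 3600,
                        lag_s: int = 8 * 3600, min_pairs: int = 6,
                        alpha: float = 0.05,
                        by_type: bool = False) -> pd.DataFrame:
    """Mean relative risk versus time before the event, with flags.

    For each event, the admission's cross-validated relative-risk
    predictions within ``span_s`` before the event are binned by time to
    event (15-min bins).  Per bin the mean over events is reported, and
    a one-sided paired Wilcoxon signed-rank test compares each event's
    risk in that bin with its risk ``lag_s`` (8 h) earlier; the flag is
    set when p < alpha, and withheld (NaN p) below ``min_pairs`` pairs.
    """
    per_event = []  # (event key, patient_type, {bin -> mean rr})
    for adm, evs in event_times.items():
        sub = cv_predictions[cv_predictions["admission_id"] == adm]
        if len(sub) == 0:
            continue
        t = sub["t"].to_numpy(dtype=float)
        rr = sub["relative_risk"].to_numpy(dtype=float)
        ptype = (sub["patient_type"].iloc[0]
                 if "patient_type" in sub.columns else "all")
        for e in np.atleast_1d(np.asarray(evs, dtype=float)):
            tte = e - t
            ok = (tte > 0) & (tte <= span_s) & np.isfinite(rr)
            if not ok.any():
                continue
            bins = (np.ceil(tte[ok] / bin_s) * bin_s).astype(int)
            d = pd.Series(rr[ok]).groupby(bins).mean().to_dict()
            per_event.append(((adm, float(e)), ptype, d))
    if len(per_event) < 2:
        raise ValueError("need at least 2 events with prediction data")

    groups = {"all": per_event}
    if by_type:
        for _, ptype, _d in per_event:
            groups.setdefault(ptype, [])
        for ev in per_event:
            groups[ev[1]].append(ev)

    rows = []
    bin_grid = range(bin_s, span_s + 1, bin_s)
    for gname, evts in groups.items():
        for b in bin_grid:
            now = [d.get(b, math.nan) for _, _, d in evts]
            prior = [d.get(b + lag_s, math.nan) for _, _, d in evts]
            now_a = np.asarray(now)
            mean_rr = (float(np.nanmean(now_a))
                       if np.isfinite(now_a).any() else math.nan)
            pairs = [(a, p) for a, p in zip(now, prior)
                     if math.isfinite(a) and math.isfinite(p)]
            pval = math.nan
            if len(pairs) >= min_pairs:
                diffs = np.array([a - p for a, p in pairs])
                if np.any(diffs != 0):
                    pval = float(stats.wilcoxon(
                        diffs, alternative="greater").pvalue)
                else:
                    pval = 1.0
            rows.append({"group": gname, "time_to_event_s": b,
                         "mean_relative_risk": mean_rr,
                         "n_events": int(np.isfinite(now_a).sum()),
                         "n_pairs": len(pairs), "p_value": pval,
                         "significant": bool(pval < alpha)
                         if math.isfinite(pval) else False})
    return pd.DataFrame(rows)


def cohort_table(admissions: pd.DataFrame, event_admission_ids) -> pd.DataFrame:
    """Table-1-style summary by event status.

    Numerical rows (age, length of stay): median (IQR) per group with a
    Wilcoxon rank-sum p-value.  Proportion rows (mortality, male sex,
    patient types): percentages with a two-proportion z-test p-value.
    """
    ev_ids = set(event_admission_ids)
    is_event = admissions["admission_id"].isin(ev_ids).to_numpy()
    g_no = admissions[~is_event]
    g_ev = admissions[is_event]

    def _num_row(name, col):
        a, b = g_no[col].to_numpy(float), g_ev[col].to_numpy(float)
        if len(a) and len(b):
            p = float(stats.mannwhitneyu(a, b,
                                         alternative="two-sided").pvalue)
        else:
            p = math.nan

        def fmt(x):
            if len(x) == 0:
                return "-"
            q1, q2, q3 = np.percentile(x, [25, 50, 75])
            return f"{q2:.2g} ({q1:.2g} - {q3:.2g})"
        return {"row": name, "no_event": fmt(a), "event": fmt(b),
                "p_value": p}

    def _prop_row(name, mask_col):
        x = np.array([mask_col(g_no).sum(), mask_col(g_ev).sum()])
        n = np.array([len(g_no), len(g_ev)])
        if (n > 0).all() and 0 < x.sum() < n.sum():
            _, p = proportions_ztest(x, n)
            p = float(p)
        else:
            p = math.nan
        pct = [100.0 * xi / ni if ni else math.nan for xi, ni in zip(x, n)]
        return {"row": name, "no_event": f"{pct[0]:.1f}%",
                "event": f"{pct[1]:.1f}%", "p_value": p}

    rows = [
        _num_row("Age, median (IQR), years", "age_years"),
        _num_row("Hospital LOS, median (IQR), days", "los_days"),
        _prop_row("In-hospital mortality, %",
                  lambda g: g["died"].astype(bool)),
    ]
    if "sex" in admissions.columns:
        rows.append(_prop_row("Male sex, %", lambda g: g["sex"] == "M"))
    for ptype in ("medical", "noncardiac_surgery", "cardiac_surgery"):
        rows.append(_prop_row(f"{ptype}, %",
                              lambda g, p=ptype: g["patient_type"] == p))
    out = pd.DataFrame(rows)
    out.attrs["n_no_event"] = len(g_no)
    out.attrs["n_event"] = len(g_ev)
    return out
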