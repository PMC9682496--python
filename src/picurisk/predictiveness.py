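"""Bootstrapped decile-by-decile relative-risk heatmaps.

The empirical "predictiveness" of a single measurement is displayed as
a 10 x 10 grid: deciles of the feature against deciles of age, each
tile holding the relative risk of unplanned intubation in the next 12 h
for measurements in the *surrounding quintile* — the 20-percentile-wide
band centred on the decile, truncated at the range ends — divided by
the average event rate in the sampled set.

To limit bias from repeated measures, each replicate samples eight
measurements from the 12 h before every unplanned intubation and eight
from every admission without an event (or far from its event); the
sampling and tiling are repeated (30 times by default) and the tiles
averaged.  Feature and age decile edges are recomputed per replicate
from the pooled sample and shared across patient-type panels, so the
panels are directly comparable.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .labeling import HORIZON_12H_S

__all__ = [
    "sample_measurements",
    "quintile_band",
    "tile_relative_risk",
    "relative_risk_grid",
    "bootstrap_heatmap",
    "marginalize_grid",
]

SAMPLES_PER_UNIT = 8
MIN_TILE_N = 20


def sample_measurements(records: pd.DataFrame, feature: str,
                        event_times: dict, seed: int = 0,
                        *, n_per_unit: int = SAMPLES_PER_UNIT,
                        horizon_s: float = HORIZON_12H_S) -> pd.DataFrame:
    """One replicate's sampled measurement set.

    ``records`` is the eligible window table (admission_id, t,
    patient_type, age_years, the feature column).  For each event,
    ``n_per_unit`` measurements are drawn from the eligible windows in
    the 12 h before it (case rows); for each admission, the same number
    from windows far from any event — outside every pre-event horizon —
    (control rows).  Sampling is uniform without replacement, falling
    back to with-replacement when fewer measurements are available.
    """
    if feature not in records.columns:
        raise KeyError(f"feature {feature!r} not in record table")
    rng = np.random.default_rng(seed)
    rec = records.dropna(subset=[feature])
    rows = []

    def _draw(pool: pd.DataFrame, case: bool):
        if len(pool) == 0:
            return
        replace = len(pool) < n_per_unit
        idx = rng.choice(len(pool), size=n_per_unit, replace=replace)
        for i in idx:
            r = pool.iloc[int(i)]
            rows.append({"admission_id": r["admission_id"],
                         "patient_type": r["patient_type"],
                         "age_years": float(r["age_years"]),
                         "value": float(r[feature]),
                         "case": case})

    for adm, grp in rec.groupby("admission_id"):
        t = grp["t"].to_numpy(dtype=float)
        evs = np.atleast_1d(np.asarray(event_times.get(adm, []), dtype=float))
        pre_event = np.zeros(t.shape, dtype=bool)
        for e in evs:
            pre_event |= (t < e) & (e <= t + horizon_s)
        for e in evs:
            _draw(grp[(t < e) & (e <= t + horizon_s)], case=True)
        _draw(grp[~pre_event], case=False)
    return pd.DataFrame(
        rows, columns=["admission_id", "patient_type", "age_years",
                       "value", "case"])


def quintile_band(decile: int) -> tuple[float, float]:
    """Percentile interval of the quintile surrounding decile ``decile``
    (1-based): 20 points wide, centred on the decile midpoint, truncated
    at [0, 100]."""
    if not 1 <= decile <= 10:
        raise ValueError("decile must be in 1..10")
    mid = 10.0 * decile - 5.0
    return (max(0.0, mid - 10.0), min(100.0, mid + 10.0))


def _band_mask(values: np.ndarray, edges: np.ndarray,
               decile: int) -> np.ndarray:
    lo_p, hi_p = quintile_band(decile)
    lo = np.interp(lo_p, np.linspace(0, 100, 11), edges)
    hi = np.interp(hi_p, np.linspace(0, 100, 11), edges)
    return (values >= lo) & (values <= hi)


def tile_relative_risk(samples: pd.DataFrame, feature_decile: int,
                       age_decile: int, *,
                       feature_edges: np.ndarray | None = None,
                       age_edges: np.ndarray | None = None,
                       min_n: int = MIN_TILE_N) -> float:
    """Relative risk for one (feature decile, age decile) tile.

    P(case | feature in band_i and age in band_j) / P(case overall),
    with the bands the surrounding quintiles; NaN below ``min_n``
    samples in the cell.  Decile edges default to the sample's own
    percentiles (0, 10, ..., 100).
    """
    v = samples["value"].to_numpy(dtype=float)
    a = samples["age_years"].to_numpy(dtype=float)
    y = samples["case"].to_numpy(dtype=bool)
    if feature_edges is None:
        feature_edges = np.percentile(v, np.linspace(0, 100, 11))
    if age_edges is None:
        age_edges = np.percentile(a, np.linspace(0, 100, 11))
    overall = y.mean()
    if overall == 0:
        return math.nan
    cell = _band_mask(v, feature_edges, feature_decile) & \
        _band_mask(a, age_edges, age_decile)
    if cell.sum() < min_n:
        return math.nan
    return float(y[cell].mean() / overall)


def relative_risk_grid(samples: pd.DataFrame, *,
                       feature_edges: np.ndarray | None = None,
                       age_edges: np.ndarray | None = None,
                       min_n: int = MIN_TILE_N) -> tuple[np.ndarray, np.ndarray]:
    """Full 10 x 10 tile grid plus per-tile occupancy counts.

    Rows index feature deciles 1..10, columns age deciles 1..10.
    """
    v = samples["value"].to_numpy(dtype=float)
    a = samples["age_years"].to_numpy(dtype=float)
    y = samples["case"].to_numpy(dtype=bool)
    if feature_edges is None:
        feature_edges = np.percentile(v, np.linspace(0, 100, 11))
    if age_edges is None:
        age_edges = np.percentile(a, np.linspace(0, 100, 11))
    grid = np.full((10, 10), np.nan)
    occ = np.zeros((10, 10), dtype=int)
    overall = y.mean()
    f_masks = [_band_mask(v, feature_edges, i) for i in range(1, 11)]
    a_masks = [_band_mask(a, age_edges, j) for j in range(1, 11)]
    for i in range(10):
        for j in range(10):
            cell = f_masks[i] & a_masks[j]
            occ[i, j] = int(cell.sum())
            if occ[i, j] >= min_n and overall > 0:
                grid[i, j] = y[cell].mean() / overall
    return grid, occ


def bootstrap_heatmap(records: pd.DataFrame, feature: str,
                      event_times: dict, *, reps: int = 30,
                      seed: int = 0, min_n: int = MIN_TILE_N) -> dict:
    """Averaged relative-risk grids, pooled and per patient type.

    Each replicate resamples measurements, recomputes pooled decile
    edges (shared by all panels) and tiles each panel; tiles are
    averaged across replicates ignoring missing values.  Returns a dict
    with per-panel ``grid`` (10 x 10 means), ``occupancy`` (summed) and
    ``n_reps``, plus the last replicate's edges for rendering.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    panels = ["pooled"] + sorted(records["patient_type"].dropna().unique())
    sums = {p: np.zeros((10, 10)) for p in panels}
    counts = {p: np.zeros((10, 10), dtype=int) for p in panels}
    occ_total = {p: np.zeros((10, 10), dtype=int) for p in panels}
    feature_edges = age_edges = None
    for _ in range(reps):
        samples = sample_measurements(
            records, feature, event_times,
            seed=int(rng.integers(0, 2**31 - 1)))
        if len(samples) == 0:
            continue
        feature_edges = np.percentile(samples["value"],
                                      np.linspace(0, 100, 11))
        age_edges = np.percentile(samples["age_years"],
                                  np.linspace(0, 100, 11))
        for panel in panels:
            sub = samples if panel == "pooled" else \
                samples[samples["patient_type"] == panel]
            if len(sub) == 0:
                continue
            grid, occ = relative_risk_grid(
                sub, feature_edges=feature_edges, age_edges=age_edges,
                min_n=min_n)
            ok = np.isfinite(grid)
            sums[panel][ok] += grid[ok]
            counts[panel][ok] += 1
            occ_total[panel] += occ
    out = {}
    for panel in panels:
        with np.errstate(invalid="ignore"):
            mean = np.where(counts[panel] > 0,
                            sums[panel] / np.maximum(counts[panel], 1),
                            np.nan)
        out[panel] = {"grid": mean, "occupancy": occ_total[panel],
                      "n_reps": reps}
    out["feature_edges"] = feature_edges
    out["age_edges"] = age_edges
    out["feature"] = feature
    return out


def marginalize_grid(grids: dict) -> np.ndarray:
    """Occupancy-weighted average over age deciles and panels.

    Collapses the per-type 10 x 10 grids to the 10-value age- and
    patient-type-marginalised risk profile of the feature.
    """
    panels = [k for k in grids
              if isinstance(grids[k], dict) and k != "pooled"]
    if not panels:
        panels = ["pooled"]
    num = np.zeros(10)
    den = np.zeros(10)
    for p in panels:
        g = grids[p]["grid"]
        w = grids[p]["occupancy"].astype(float)
        ok = np.isfinite(g)
        num += np.where(ok, g * w, 0.0).sum(axis=1)
        den += np.where(ok, w, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)
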