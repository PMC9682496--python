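"""Decile-by-decile relative-risk heatmaps."""

import numpy as np
import pandas as pd
import pytest

from picurisk import predictiveness as pv


def _null_samples(n=5000, p_case=0.5, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "admission_id": [f"A{i % 500}" for i in range(n)],
        "patient_type": "medical",
        "age_years": rng.uniform(0, 18, n),
        "value": rng.normal(25, 6, n),
        "case": rng.random(n) < p_case,
    })


def _records_for_sampling(seed=0):
    """Window table with one event admission and several controls."""
    rng = np.random.default_rng(seed)
    rows = []
    e = 20 * 3600.0
    for adm, n_windows, has_event in (
            ("E0", 100, True), ("C0", 100, False), ("C1", 5, False)):
        for k in range(n_windows):
            t = 1800.0 + 900.0 * k
            rows.append({"admission_id": adm, "t": t,
                         "patient_type": "medical",
                         "age_years": 2.0 if has_event else 8.0,
                         "mean_RR": rng.normal(25, 4)})
    return pd.DataFrame(rows), {"E0": [e]}


class TestQuintileBand:
    def test_center_and_truncation(self):
        assert pv.quintile_band(5) == (35.0, 55.0)
        assert pv.quintile_band(1) == (0.0, 15.0)
        assert pv.quintile_band(10) == (85.0, 100.0)

    def test_invalid(self):
        with pytest.raises(ValueError):
            pv.quintile_band(0)


class TestSampleMeasurements:
    def test_eight_per_control_admission(self):
        rec, et = _records_for_sampling()
        s = pv.sample_measurements(rec, "mean_RR", et, seed=1)
        counts = s.groupby("admission_id").size()
        assert counts["C0"] == 8
        assert counts["C1"] == 8  # fewer than 8 windows -> with replacement

    def test_case_samples_within_12h_pre_event(self):
        rec, et = _records_for_sampling()
        s = pv.sample_measurements(rec, "mean_RR", et, seed=1)
        cases = s[s["case"]]
        assert len(cases) == 8
        assert (cases["admission_id"] == "E0").all()

    def test_control_rows_far_from_event(self):
        rec, et = _records_for_sampling()
        s = pv.sample_measurements(rec, "mean_RR", et, seed=2)
        ctrl_e0 = s[(s["admission_id"] == "E0") & (~s["case"])]
        assert len(ctrl_e0) == 8  # far-from-event windows exist

    def test_seeded(self):
        rec, et = _records_for_sampling()
        s1 = pv.sample_measurements(rec, "mean_RR", et, seed=9)
        s2 = pv.sample_measurements(rec, "mean_RR", et, seed=9)
        pd.testing.assert_frame_equal(s1, s2)

    def test_unknown_feature(self):
        rec, et = _records_for_sampling()
        with pytest.raises(KeyError):
            pv.sample_measurements(rec, "nope", et)


class TestTileRelativeRisk:
    def test_null_tiles_near_one(self):
        s = _null_samples()
        grid, occ = pv.relative_risk_grid(s)
        filled = grid[np.isfinite(grid)]
        assert filled.size > 50
        assert np.all(np.abs(filled - 1.0) < 0.35)
        # central tiles, well occupied, are tighter
        assert abs(grid[4, 4] - 1.0) < 0.2

    def test_enriched_corner(self):
        s = _null_samples(n=4000, p_case=0.1, seed=3)
        v = s["value"].to_numpy()
        a = s["age_years"].to_numpy()
        corner = (v <= np.percentile(v, 15)) & (a <= np.percentile(a, 15))
        case = s["case"].to_numpy()
        case[corner] = np.arange(corner.sum()) % 10 < 3  # exactly 30% cases
        s["case"] = case
        tile = pv.tile_relative_risk(s, 1, 1)
        assert tile == pytest.approx(0.3 / s["case"].mean(), rel=0.25)

    def test_forty_row_toy_matches_hand_count(self):
        rng = np.random.default_rng(5)
        s = pd.DataFrame({
            "admission_id": "A", "patient_type": "medical",
            "age_years": rng.uniform(0, 10, 40),
            "value": rng.uniform(0, 100, 40),
            "case": rng.random(40) < 0.5,
        })
        f_edges = np.percentile(s["value"], np.linspace(0, 100, 11))
        a_edges = np.percentile(s["age_years"], np.linspace(0, 100, 11))
        lo = np.interp(0.0, np.linspace(0, 100, 11), f_edges)
        hi = np.interp(15.0, np.linspace(0, 100, 11), f_edges)
        alo = np.interp(0.0, np.linspace(0, 100, 11), a_edges)
        ahi = np.interp(15.0, np.linspace(0, 100, 11), a_edges)
        cell = s[(s["value"] >= lo) & (s["value"] <= hi)
                 & (s["age_years"] >= alo) & (s["age_years"] <= ahi)]
        expected = (cell["case"].mean() / s["case"].mean()
                    if len(cell) >= 3 else np.nan)
        got = pv.tile_relative_risk(s, 1, 1, min_n=3)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected)

    def test_sparse_cell_missing(self):
        s = _null_samples(n=50)
        assert np.isnan(pv.tile_relative_risk(s, 1, 1, min_n=20))


class TestBootstrapHeatmap:
    def test_single_rep_equals_single_pass(self):
        rec, et = _records_for_sampling()
        rng = np.random.default_rng(11)
        out = pv.bootstrap_heatmap(rec, "mean_RR", et, reps=1, seed=11,
                                   min_n=1)
        samples = pv.sample_measurements(rec, "mean_RR", et,
                                         seed=int(rng.integers(0, 2**31 - 1)))
        grid, _ = pv.relative_risk_grid(samples, min_n=1)
        np.testing.assert_allclose(out["pooled"]["grid"], grid)

    def test_variance_shrinks_with_reps(self, prodrome_records,
                                        prodrome_event_times):
        rec = prodrome_records
        single = pv.bootstrap_heatmap(rec, "mean_RR", prodrome_event_times,
                                      reps=1, seed=0)
        many = pv.bootstrap_heatmap(rec, "mean_RR", prodrome_event_times,
                                    reps=10, seed=0)
        # replicate-averaged grids vary less across seeds than single grids
        single2 = pv.bootstrap_heatmap(rec, "mean_RR", prodrome_event_times,
                                       reps=1, seed=1)
        many2 = pv.bootstrap_heatmap(rec, "mean_RR", prodrome_event_times,
                                     reps=10, seed=1)
        d1 = np.nanmean(np.abs(single["pooled"]["grid"]
                               - single2["pooled"]["grid"]))
        d10 = np.nanmean(np.abs(many["pooled"]["grid"]
                                - many2["pooled"]["grid"]))
        assert d10 < d1

    def test_seeded_determinism(self):
        rec, et = _records_for_sampling()
        a = pv.bootstrap_heatmap(rec, "mean_RR", et, reps=3, seed=2, min_n=1)
        b = pv.bootstrap_heatmap(rec, "mean_RR", et, reps=3, seed=2, min_n=1)
        np.testing.assert_array_equal(a["pooled"]["grid"],
                                      b["pooled"]["grid"])

    def test_bad_reps(self):
        rec, et = _records_for_sampling()
        with pytest.raises(ValueError):
            pv.bootstrap_heatmap(rec, "mean_RR", et, reps=0)


class TestMarginalize:
    def test_uniform_grids_flat(self):
        grids = {"medical": {"grid": np.ones((10, 10)),
                             "occupancy": np.full((10, 10), 5)},
                 "pooled": {"grid": np.ones((10, 10)),
                            "occupancy": np.full((10, 10), 5)}}
        np.testing.assert_allclose(pv.marginalize_grid(grids), 1.0)

    def test_single_panel_column_means(self):
        g = np.arange(100, dtype=float).reshape(10, 10)
        grids = {"pooled": {"grid": g, "occupancy": np.ones((10, 10))}}
        np.testing.assert_allclose(pv.marginalize_grid(grids), g.mean(axis=1))

    def test_weighted_average_hand_computed(self):
        g1 = np.full((10, 10), 2.0)
        g2 = np.full((10, 10), 4.0)
        grids = {"a": {"grid": g1, "occupancy": np.full((10, 10), 1)},
                 "b": {"grid": g2, "occupancy": np.full((10, 10), 3)}}
        np.testing.assert_allclose(pv.marginalize_grid(grids), 3.5)
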