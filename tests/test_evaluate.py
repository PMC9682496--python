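"""Patient-wise CV, AUC, bootstrap CIs, curves and cohort summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from picurisk import evaluate as ev
from oracles import (brute_auc, brute_rank_sum_p, brute_signed_rank_stat)


class TestPatientFolds:
    def test_balanced_folds(self):
        folds = ev.patient_folds([f"A{i}" for i in range(10)], k=5, seed=0)
        sizes = pd.Series(folds).value_counts()
        assert sorted(sizes) == [2, 2, 2, 2, 2]

    def test_no_admission_in_two_folds(self):
        ids = [f"A{i}" for i in range(23)]
        folds = ev.patient_folds(ids, k=5, seed=1)
        assert set(folds) == set(ids)
        sizes = pd.Series(folds).value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_seeded(self):
        ids = [f"A{i}" for i in range(12)]
        assert ev.patient_folds(ids, seed=3) == ev.patient_folds(ids, seed=3)

    def test_too_few(self):
        with pytest.raises(ValueError):
            ev.patient_folds(["A", "B"], k=5)


class TestAUC:
    def test_perfect_separation(self):
        assert ev.auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=4000)
        y = rng.random(4000) < 0.5
        assert ev.auc(s, y) == pytest.approx(0.5, abs=0.05)

    def test_six_record_toy(self):
        s = [0.1, 0.4, 0.35, 0.8, 0.35, 0.9]
        y = [0, 0, 1, 1, 0, 1]
        assert ev.auc(s, y) == pytest.approx(brute_auc(s, y))

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.tuples(st.integers(-5, 5), st.booleans()),
                    min_size=2, max_size=50))
    def test_matches_pair_counting_oracle(self, rows):
        s = [r[0] for r in rows]
        y = [r[1] for r in rows]
        if all(y) or not any(y):
            with pytest.raises(ValueError):
                ev.auc(s, y)
        else:
            assert ev.auc(s, y) == pytest.approx(brute_auc(s, y))


class TestAboveChanceReduction:
    def test_reduction_arithmetic(self):
        assert ev.auc_above_chance_reduction(0.696, 0.638) == pytest.approx(
            29.59, abs=0.01)

    def test_zero_and_full(self):
        assert ev.auc_above_chance_reduction(0.696, 0.696) == 0.0
        assert ev.auc_above_chance_reduction(0.696, 0.5) == 100.0

    def test_reference_at_chance_error(self):
        with pytest.raises(ValueError):
            ev.auc_above_chance_reduction(0.5, 0.4)


def _toy_predictions(seed=0, n_adm=12, sep=2.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_adm):
        case_adm = i < n_adm // 2
        for t in range(6):
            is_case = case_adm and t >= 3
            rows.append({
                "admission_id": f"A{i}", "t": 900 * (t + 2),
                "label": "case" if is_case else "control",
                "votes": rng.normal(sep if is_case else 0.0, 1.0),
                "patient_type": "medical",
            })
    df = pd.DataFrame(rows)
    df["relative_risk"] = df["votes"] - df["votes"].min() + 0.1
    return df


class TestBootstrapCI:
    def test_seeded_determinism(self):
        cv = _toy_predictions()
        assert ev.auc_ci_bootstrap(cv, b=50, seed=4) == \
            ev.auc_ci_bootstrap(cv, b=50, seed=4)

    def test_degenerate_perfect_separation(self):
        cv = _toy_predictions(sep=100.0)
        lo, hi = ev.auc_ci_bootstrap(cv, b=30, seed=0)
        assert lo == 1.0 and hi == 1.0

    def test_ci_contains_point_estimate(self):
        cv = _toy_predictions(seed=5)
        a = ev.auc(cv["votes"], cv["label"] == "case")
        lo, hi = ev.auc_ci_bootstrap(cv, b=200, seed=1)
        assert lo <= a <= hi

    def test_b_too_small(self):
        with pytest.raises(ValueError):
            ev.auc_ci_bootstrap(_toy_predictions(), b=1)


class TestTimeToEventCurve:
    def _rising_predictions(self, n_events=8, const=False):
        rows = []
        event_times = {}
        for i in range(n_events):
            adm = f"E{i}"
            e = 30 * 3600.0
            event_times[adm] = [e]
            for k in range(1, 97):  # every 15 min over 24 h pre-event
                t = e - 900.0 * k
                rr = 1.0 if const else 5.0 - 0.04 * k + 0.01 * (i % 3)
                rows.append({"admission_id": adm, "t": t, "label": "case",
                             "relative_risk": rr,
                             "patient_type": "medical"})
        return pd.DataFrame(rows), event_times

    def test_rising_risk_flags_late_bins(self):
        cv, et = self._rising_predictions()
        curve = ev.time_to_event_curve(cv, et)
        sub = curve[(curve["group"] == "all")
                    & (curve["time_to_event_s"] <= 4 * 3600)]
        assert sub["significant"].all()

    def test_constant_risk_no_flags(self):
        cv, et = self._rising_predictions(const=True)
        curve = ev.time_to_event_curve(cv, et)
        assert not curve["significant"].any()

    def test_statistic_matches_signed_rank_enumeration(self):
        diffs = [0.5, 1.2, -0.3, 0.8, 2.0, -0.1, 0.9, 1.1]
        w = brute_signed_rank_stat(diffs)
        res = stats.wilcoxon(diffs, alternative="greater", method="exact")
        assert res.statistic == pytest.approx(w)

    def test_underpowered_flag_withheld(self):
        cv, et = self._rising_predictions(n_events=3)
        curve = ev.time_to_event_curve(cv, et, min_pairs=6)
        assert not curve["significant"].any()
        assert curve["mean_relative_risk"].notna().any()

    def test_too_few_events(self):
        cv, et = self._rising_predictions(n_events=1)
        with pytest.raises(ValueError):
            ev.time_to_event_curve(cv, et)


@pytest.fixture(scope="module")
def grid(tiny_bundle):
    from picurisk import build_feature_table, label_records
    from picurisk.pipeline import (FEATURE_COLUMNS_ALL,
                                   FEATURE_COLUMNS_NO_MONITORING)
    features = build_feature_table(tiny_bundle)
    records = {
        mode: label_records(features, tiny_bundle, mode=mode)
        for mode in ("chart_review", "computable_phenotype")}
    folds = ev.patient_folds(
        records["chart_review"]["admission_id"], k=3, seed=0)
    return ev.model_grid(
        records,
        {"all": FEATURE_COLUMNS_ALL,
         "no_monitoring": FEATURE_COLUMNS_NO_MONITORING},
        folds, n_trees=40, seed=0)


class TestModelGrid:
    def test_four_cells(self, grid):
        assert len(grid) == 4
        assert set(grid["event_definition"]) == {"chart_review",
                                                 "computable_phenotype"}
        assert set(grid["feature_set"]) == {"all", "no_monitoring"}

    def test_aucs_valid(self, grid):
        assert grid["auc"].between(0, 1).all()

    def test_phenotype_strictly_contains_chart_review(self, tiny_bundle):
        from picurisk.pipeline import event_times_by_admission
        chart = event_times_by_admission(tiny_bundle, "chart_review")
        pheno = event_times_by_admission(tiny_bundle,
                                         "computable_phenotype")
        n_chart = sum(len(v) for v in chart.values())
        n_pheno = sum(len(v) for v in pheno.values())
        assert n_pheno > n_chart


class TestCohortTable:
    def _admissions(self, shift=0.0):
        rng = np.random.default_rng(0)
        n = 40
        return pd.DataFrame({
            "admission_id": [f"A{i}" for i in range(n)],
            "age_years": np.r_[rng.uniform(0, 10, 20),
                               rng.uniform(0, 10, 20) + shift],
            "los_days": rng.uniform(1, 30, n),
            "died": rng.random(n) < 0.1,
            "sex": np.where(rng.random(n) < 0.5, "M", "F"),
            "patient_type": rng.choice(
                ["medical", "cardiac_surgery", "noncardiac_surgery"], n),
        })

    def test_identical_groups_high_p(self):
        adm = self._admissions()
        # event group = a random half with the same distribution
        table = ev.cohort_table(adm, adm["admission_id"][20:])
        age_row = table[table["row"].str.startswith("Age")].iloc[0]
        assert age_row["p_value"] > 0.01

    def test_rank_sum_matches_enumeration(self):
        a = [1.0, 3.0, 5.0, 7.0]
        b = [2.0, 4.0, 20.0, 30.0]
        p = stats.mannwhitneyu(a, b, alternative="two-sided",
                               method="exact").pvalue
        assert p == pytest.approx(brute_rank_sum_p(a, b), abs=1e-12)

    def test_two_proportion_z(self):
        from statsmodels.stats.proportion import proportions_ztest
        # hand computation for x=(30,10), n=(100,20)
        p_pool = 40 / 120
        se = math.sqrt(p_pool * (1 - p_pool) * (1 / 100 + 1 / 20))
        z_hand = (0.30 - 0.50) / se
        z, _ = proportions_ztest([30, 10], [100, 20])
        assert z == pytest.approx(z_hand)

    def test_table_structure(self):
        adm = self._admissions(shift=5.0)
        table = ev.cohort_table(adm, adm["admission_id"][20:])
        assert {"row", "no_event", "event", "p_value"} <= set(table.columns)
        assert len(table) == 7
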