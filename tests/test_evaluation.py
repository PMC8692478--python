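"""Metrics, category rates, error grids and model comparison."""

import numpy as np
import pandas as pd
import pytest
from matplotlib.path import Path as MplPath

from bgpredict.evaluation import (category_rates, compare_models,
                                  compute_metrics, evaluation_report,
                                  forecasts_to_frame, report_to_json)
from bgpredict.grids import (PARKES_DOMAIN, PARKES_T1_BOUNDARIES,
                             clarke_zone, clarke_zones, parkes_grid,
                             parkes_zone_type1, parkes_zones_type1)
from bgpredict.model import ForecastBatch


class TestComputeMetrics:
    def test_perfect_forecast_all_zero(self):
        r = compute_metrics([100.0, 200.0], [100.0, 200.0])
        assert (r.rmse, r.mae, r.mape) == (0.0, 0.0, 0.0)
        assert r.nrmse == 0.0

    def test_hand_evaluated_example(self):
        r = compute_metrics([100.0, 200.0], [110.0, 190.0])
        assert r.mae == pytest.approx(10.0)
        assert r.rmse == pytest.approx(10.0)
        assert r.mape == pytest.approx(7.5)       # (10/100 + 10/200)/2 * 100
        assert r.nrmse == pytest.approx(0.1)      # 10 / (200 - 100)

    def test_category_partition(self):
        r = compute_metrics([60.0, 100.0, 200.0], [61.0, 99.0, 199.0])
        assert r.per_category["hypo"].n == 1
        assert r.per_category["normo"].n == 1
        assert r.per_category["hyper"].n == 1

    def test_empty_category_reported_missing(self):
        r = compute_metrics([100.0, 120.0], [101.0, 119.0])
        assert r.per_category["hypo"] is None
        assert r.per_category["hyper"] is None

    def test_rmse_at_least_mae_randomized(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            y = rng.uniform(25, 400, 30)
            p = y + rng.normal(0, 20, 30)
            r = compute_metrics(y, np.maximum(p, 21), per_category=False)
            assert r.rmse >= r.mae >= 0

    def test_matches_brute_force_formulas(self):
        """Oracle: independent elementwise evaluation of all four formulas."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(2, 40))
            y = rng.uniform(21, 400, n)
            p = rng.uniform(21, 400, n)
            r = compute_metrics(y, p, per_category=False)
            rmse = np.sqrt(sum((pi - yi) ** 2 for pi, yi in zip(p, y)) / n)
            mae = sum(abs(pi - yi) for pi, yi in zip(p, y)) / n
            mape = sum(abs(pi - yi) / yi for pi, yi in zip(p, y)) / n * 100
            assert r.rmse == pytest.approx(rmse, rel=1e-9)
            assert r.mae == pytest.approx(mae, rel=1e-9)
            assert r.mape == pytest.approx(mape, rel=1e-9)
            assert r.nrmse == pytest.approx(rmse / (y.max() - y.min()),
                                            rel=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            compute_metrics([], [])
        r = compute_metrics([120.0, 120.0], [121.0, 119.0])
        assert r.nrmse is None  # y_max == y_min


class TestCategoryRates:
    def test_hypo_enumeration(self):
        y = [60.0, 65.0, 100.0, 200.0]
        p = [65.0, 80.0, 90.0, 210.0]
        cm = category_rates(y, p, "hypo")
        assert (cm.p, cm.tp, cm.fp, cm.n) == (2, 1, 0, 2)
        assert cm.tpr == 0.5
        assert cm.fpr == 0.0

    def test_hyper_enumeration(self):
        y = [60.0, 65.0, 100.0, 200.0]
        p = [65.0, 80.0, 90.0, 210.0]
        cm = category_rates(y, p, "hyper")
        assert (cm.p, cm.tp, cm.fp) == (1, 1, 0)
        assert cm.tpr == 1.0

    def test_perfect_forecast_rates(self):
        y = np.array([50.0, 120.0, 250.0, 65.0, 90.0])
        for cat in ("hypo", "normo", "hyper"):
            cm = category_rates(y, y, cat)
            assert cm.tpr == 1.0
            assert cm.fpr == 0.0

    def test_conservation_properties_randomized(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            y = rng.uniform(25, 350, 50)
            p = rng.uniform(25, 350, 50)
            for cat in ("hypo", "normo", "hyper"):
                cm = category_rates(y, p, cat)
                assert cm.tp <= cm.p
                assert cm.fp <= cm.n
                assert cm.p + cm.n == 50

    def test_empty_denominator_missing(self):
        cm = category_rates([120.0], [60.0], "hypo")
        assert cm.tpr is None  # no true hypo samples
        assert cm.fpr == 1.0


class TestClarkeGrid:
    @pytest.mark.parametrize("ref,pred,zone", [
        (100, 100, "A"), (100, 118, "A"), (60, 65, "A"),
        (200, 150, "B"),
        (60, 200, "E"), (200, 60, "E"),
        (100, 215, "C"), (160, 38, "C"),
        (250, 120, "D"), (50, 120, "D"),
    ])
    def test_canonical_points(self, ref, pred, zone):
        assert clarke_zone(ref, pred) == zone

    def test_within_twenty_percent_is_a(self):
        rng = np.random.default_rng(3)
        ref = rng.uniform(75, 400, 500)
        pred = ref * rng.uniform(0.81, 1.19, 500)
        assert (clarke_zones(ref, pred) == 0).all()

    def test_partition_no_gaps(self):
        rng = np.random.default_rng(4)
        ref = rng.uniform(0, 550, 100_000)
        pred = rng.uniform(0, 550, 100_000)
        z = clarke_zones(ref, pred)
        assert z.min() >= 0 and z.max() <= 4

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            clarke_zone(-1.0, 100.0)


def parkes_oracle(ref, pred):
    """Independent point-in-polygon classifier built from the same published
    vertex table: each region between consecutive boundaries becomes a
    closed polygon classified with matplotlib's path logic."""
    lo, hi = PARKES_DOMAIN

    def extended(name):
        pts = np.asarray(PARKES_T1_BOUNDARIES[name], float)
        if pts[-1, 0] < hi:
            slope = (pts[-1, 1] - pts[-2, 1]) / (pts[-1, 0] - pts[-2, 0])
            y_end = pts[-1, 1] + slope * (hi - pts[-1, 0])
            if y_end > hi:
                x_top = pts[-1, 0] + (hi - pts[-1, 1]) / slope
                pts = np.vstack([pts, [x_top, hi]])
            else:
                pts = np.vstack([pts, [hi, y_end]])
        return pts

    def region_above(name):  # polygon above an upper boundary polyline
        pts = extended(name)
        return MplPath(np.vstack([pts, [lo, hi] if pts[-1, 1] >= hi
                                  else [[hi, hi], [lo, hi]], ]))

    def region_below(name):  # polygon below a lower boundary polyline
        pts = extended(name)
        return MplPath(np.vstack([pts, [[hi, lo]]]))

    points = np.column_stack([np.asarray(ref, float).ravel(),
                              np.asarray(pred, float).ravel()])
    zones = np.zeros(len(points), int)
    for name, idx in (("B_upper", 1), ("C_upper", 2), ("D_upper", 3),
                      ("E_upper", 4)):
        inside = region_above(name).contains_points(points)
        upper = points[:, 1] >= points[:, 0]
        zones[inside & upper] = np.maximum(zones[inside & upper], idx)
    for name, idx in (("B_lower", 1), ("C_lower", 2), ("D_lower", 3)):
        inside = region_below(name).contains_points(points)
        lower = points[:, 1] < points[:, 0]
        zones[inside & lower] = np.maximum(zones[inside & lower], idx)
    return zones


class TestParkesGrid:
    @pytest.mark.parametrize("ref,pred", [(100, 100), (550, 550), (20, 20)])
    def test_identity_line_is_zone_a(self, ref, pred):
        assert parkes_zone_type1(ref, pred) == "A"

    @pytest.mark.parametrize("ref,pred,zone", [
        (100, 170, "B"), (100, 250, "C"), (30, 130, "D"), (20, 300, "E"),
        (300, 150, "B"), (300, 100, "C"), (300, 30, "D"),
    ])
    def test_representative_points(self, ref, pred, zone):
        assert parkes_zone_type1(ref, pred) == zone

    def test_matches_point_in_polygon_oracle(self):
        rng = np.random.default_rng(5)
        ref = rng.uniform(0, 550, 10_000)
        pred = rng.uniform(0, 550, 10_000)
        mine = parkes_zones_type1(ref, pred)
        oracle = parkes_oracle(ref, pred)
        agree = mine == oracle
        assert agree.mean() == 1.0

    def test_out_of_domain_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            z = parkes_zones_type1([600.0], [600.0])
        assert z[0] == 0  # clamps to (550, 550), identity -> A

    def test_grid_percentages_sum_to_100(self):
        rng = np.random.default_rng(6)
        res = parkes_grid(rng.uniform(0, 550, 1000), rng.uniform(0, 550, 1000))
        assert sum(res.zone_percent.values()) == pytest.approx(100.0,
                                                               abs=1e-9)
        assert sum(res.zone_counts.values()) == 1000


class TestCompareModels:
    def test_identical_groups_p_one(self):
        t, p = compare_models([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.0, 1e-3, 6)
        b = 1.0 + rng.normal(0.0, 1e-3, 6)
        _, p = compare_models(a, b)
        assert p < 0.001

    def test_antisymmetric_statistic(self):
        a = [1.0, 2.0, 4.0]
        b = [2.0, 3.0, 5.0]
        t_ab, _ = compare_models(a, b)
        t_ba, _ = compare_models(b, a)
        assert t_ab == pytest.approx(-t_ba)

    def test_matches_welch_formula_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            a = rng.normal(0, 1, int(rng.integers(3, 20)))
            b = rng.normal(0.3, 1.5, int(rng.integers(3, 20)))
            t, p = compare_models(a, b)
            va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
            t_ref = (a.mean() - b.mean()) / np.sqrt(va + vb)
            df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1)
                                   + vb ** 2 / (len(b) - 1))
            from scipy import stats
            p_ref = 2 * stats.t.sf(abs(t_ref), df)
            assert t == pytest.approx(t_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            compare_models([1.0], [1.0, 2.0])


class TestEvaluationReport:
    def make_forecasts(self, pid, y_true, y_pred, f=6):
        batch = ForecastBatch(anchors=np.arange(len(y_true)),
                              y_true=np.tile(np.asarray(y_true)[:, None], f),
                              y_pred=np.tile(np.asarray(y_pred)[:, None], f))
        return forecasts_to_frame(pid, batch)

    def test_perfect_single_patient(self, tmp_path):
        y = np.linspace(80, 220, 40)
        df = self.make_forecasts("p1", y, y)
        rep = evaluation_report(df, horizon_step=6, plot_dir=tmp_path)
        r = rep["per_patient"]["p1"]
        assert r["metrics"].rmse == 0.0
        assert r["clarke"].zone_percent["A"] == 100.0
        assert r["parkes"].zone_percent["A"] == 100.0
        assert (tmp_path / "p1_clarke.png").exists()
        assert (tmp_path / "p1_parkes.png").exists()

    def test_cohort_mean_and_sample_sd(self):
        y = np.full(30, 150.0) + np.arange(30)  # nondegenerate range
        dfs = []
        for pid, err in (("a", 10.0), ("b", 20.0)):
            dfs.append(self.make_forecasts(pid, y, y + err))
        rep = evaluation_report(pd.concat(dfs, ignore_index=True),
                                horizon_step=6)
        assert rep["cohort"]["rmse"]["mean"] == pytest.approx(15.0)
        assert rep["cohort"]["rmse"]["sd"] == pytest.approx(7.0710678, rel=1e-6)

    def test_no_hypo_samples_marked(self):
        y = np.linspace(100, 170, 20)
        df = self.make_forecasts("p1", y, y + 5)
        rep = report_to_json(evaluation_report(df, horizon_step=6))
        assert rep["per_patient"]["p1"]["category_rates"]["hypo"] == \
            "No test samples"

    def test_missing_horizon_step_rejected(self):
        df = self.make_forecasts("p1", np.linspace(80, 200, 10),
                                 np.linspace(80, 200, 10), f=3)
        with pytest.raises(ValueError):
            evaluation_report(df, horizon_step=6)
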