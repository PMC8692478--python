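"""Quantitative and clinical evaluation of glucose forecasts.

Implements the standard point-accuracy metrics

    RMSE  = sqrt(mean (y_hat - y)^2)            mg/dL
    MAE   = mean |y_hat - y|                    mg/dL
    MAPE  = mean |y_hat - y| / y * 100          percent
    NRMSE = RMSE / (y_max - y_min)              dimensionless

(y_max/y_min over the evaluated true values), the per-category breakdown for
hypo- (< 70 mg/dL), normo- ([70, 180)) and hyperglycemia (>= 180 mg/dL),
event detection rates (TPR = TP/P, FPR = FP/N with category membership
evaluated on predicted vs true values), Clarke/Parkes error-grid summaries,
Welch's unequal-variance t-test for model comparison, and per-patient /
cohort report assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .grids import clarke_grid, parkes_grid
from .preprocess import HYPER_THRESHOLD, HYPO_THRESHOLD

CATEGORY_BOUNDS = {
    "hypo": lambda y: y < HYPO_THRESHOLD,
    "normo": lambda y: (y >= HYPO_THRESHOLD) & (y < HYPER_THRESHOLD),
    "hyper": lambda y: y >= HYPER_THRESHOLD,
}


@dataclass
class MetricsReport:
    rmse: float
    mae: float
    mape: float
    nrmse: float | None
    n: int
    per_category: dict = field(default_factory=dict)  # name -> MetricsReport | None

    def to_dict(self) -> dict:
        d = {"rmse": self.rmse, "mae": self.mae, "mape": self.mape,
             "nrmse": self.nrmse, "n": self.n}
        for name, sub in self.per_category.items():
            d[name] = None if sub is None else sub.to_dict()
        return d


@dataclass
class CategoryMetrics:
    category: str
    tp: int
    p: int
    fp: int
    n: int
    tpr: float | None  # None when P == 0 ("No test samples")
    fpr: float | None


def _basic_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> "MetricsReport":
    err = y_pred - y_true
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mae = float(np.mean(np.abs(err)))
    mape = float(np.mean(np.abs(err) / y_true) * 100.0)
    y_range = float(np.max(y_true) - np.min(y_true))
    nrmse = rmse / y_range if y_range > 0 else None
    return MetricsReport(rmse=rmse, mae=mae, mape=mape, nrmse=nrmse,
                         n=len(y_true))


def compute_metrics(y_true, y_pred, per_category: bool = True) -> MetricsReport:
    """Overall metrics plus per-category sub-reports.

    Category membership is decided by the TRUE value; a category with no
    test samples gets a ``None`` sub-report (the "No test samples" case).
    MAPE relies on strictly positive true values (guaranteed in practice by
    the 20 mg/dL sensor floor).  NRMSE is ``None`` when all true values are
    equal.
    """
    y_true = np.asarray(y_true, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    if len(y_true) == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    report = _basic_metrics(y_true, y_pred)
    if per_category:
        for name, pred_fn in CATEGORY_BOUNDS.items():
            m = pred_fn(y_true)
            report.per_category[name] = (_basic_metrics(y_true[m], y_pred[m])
                                         if m.any() else None)
    return report


def category_rates(y_true, y_pred, category: str) -> CategoryMetrics:
    """Event detection rates for one glycemic category.

    TP counts samples where predicted and true values are both in the
    category; P counts true values in the category; FP counts predictions in
    the category whose true value is not; N counts true values outside it.
    TPR/FPR are ``None`` when their denominator is zero.
    """
    in_cat = CATEGORY_BOUNDS[category]
    y_true = np.asarray(y_true, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    true_in = in_cat(y_true)
    pred_in = in_cat(y_pred)
    tp = int(np.sum(true_in & pred_in))
    p = int(np.sum(true_in))
    fp = int(np.sum(pred_in & ~true_in))
    n = int(np.sum(~true_in))
    return CategoryMetrics(category=category, tp=tp, p=p, fp=fp, n=n,
                           tpr=tp / p if p else None,
                           fpr=fp / n if n else None)


def compare_models(errors_a, errors_b):
    """Welch's two-sample t-test (unequal variances), two-sided.

    Returns ``(t_statistic, p_value)`` comparing per-patient metric values
    of two models.
    """
    a = np.asarray(errors_a, float)
    b = np.asarray(errors_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# report assembly

FORECAST_COLUMNS = ["patient_id", "anchor_time", "step",
                    "y_true_mg_dl", "y_pred_mg_dl"]


def forecasts_to_frame(patient_id: str, batch, anchor_times=None) -> pd.DataFrame:
    """Long-format forecasts table (one row per anchor and horizon step)."""
    n, f = batch.y_true.shape
    anchors = (np.repeat(batch.anchors, f) if anchor_times is None
               else np.repeat(np.asarray(anchor_times), f))
    return pd.DataFrame({
        "patient_id": patient_id,
        "anchor_time": anchors,
        "step": np.tile(np.arange(1, f + 1), n),
        "y_true_mg_dl": batch.y_true.ravel(),
        "y_pred_mg_dl": batch.y_pred.ravel(),
    })


def evaluation_report(forecasts: pd.DataFrame, horizon_step: int,
                      plot_dir: str | Path | None = None) -> dict:
    """Per-patient metrics, category rates and error grids at one horizon step.

    ``forecasts`` follows the long CSV schema (patient_id, anchor_time,
    step, y_true_mg_dl, y_pred_mg_dl).  Returns per-patient reports plus a
    cohort aggregate (mean and sample standard deviation of each metric over
    patients).  With ``plot_dir`` set, writes one Clarke and one Parkes
    scatter per patient.
    """
    sel = forecasts[forecasts["step"] == horizon_step]
    if len(sel) == 0:
        raise ValueError(f"no forecasts at horizon step {horizon_step}")
    per_patient = {}
    for pid, grp in sel.groupby("patient_id", sort=True):
        y_true = grp["y_true_mg_dl"].to_numpy()
        y_pred = grp["y_pred_mg_dl"].to_numpy()
        metrics = compute_metrics(y_true, y_pred)
        rates = {c: category_rates(y_true, y_pred, c) for c in CATEGORY_BOUNDS}
        clarke = clarke_grid(y_true, np.maximum(y_pred, 0.0))
        parkes = parkes_grid(np.clip(y_true, 0, 550), np.clip(y_pred, 0, 550))
        per_patient[pid] = {"metrics": metrics, "category_rates": rates,
                            "clarke": clarke, "parkes": parkes}
        if plot_dir is not None:
            plot_error_grids(y_true, y_pred, pid, plot_dir)

    agg = {}
    for key in ("rmse", "mae", "mape", "nrmse"):
        vals = [getattr(r["metrics"], key) for r in per_patient.values()
                if getattr(r["metrics"], key) is not None]
        agg[key] = {"mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0}
    for grid in ("clarke", "parkes"):
        vals = [r[grid].zone_percent["A"] for r in per_patient.values()]
        agg[f"{grid}_zone_a_percent"] = {
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0}
    return {"per_patient": per_patient, "cohort": agg,
            "horizon_step": horizon_step}


def report_to_json(report: dict) -> dict:
    """JSON-serializable view of an evaluation report."""
    out = {"horizon_step": report["horizon_step"], "per_patient": {},
           "cohort": report["cohort"]}
    for pid, r in report["per_patient"].items():
        rates = {}
        for c, cm in r["category_rates"].items():
            if cm.p == 0:
                rates[c] = "No test samples"
            else:
                rates[c] = {"tp": cm.tp, "p": cm.p, "fp": cm.fp, "n": cm.n,
                            "tpr": cm.tpr, "fpr": cm.fpr}
        out["per_patient"][pid] = {
            "metrics": r["metrics"].to_dict(),
            "category_rates": rates,
            "clarke_zone_percent": r["clarke"].zone_percent,
            "parkes_zone_percent": r["parkes"].zone_percent,
        }
    return out


# ---------------------------------------------------------------------------
# plotting

def plot_error_grids(y_true, y_pred, patient_id: str,
                     out_dir: str | Path) -> list:
    """Clarke and Parkes scatter plots with zone boundaries, saved as PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .grids import PARKES_T1_BOUNDARIES, _boundary_y

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(y_true, y_pred, s=4, alpha=0.4, color="tab:blue")
    xs = np.linspace(0, 400, 200)
    ax.plot(xs, xs, "k:", lw=0.8)
    ax.plot(xs, 1.2 * xs, "k-", lw=0.6)
    ax.plot(xs, 0.8 * xs, "k-", lw=0.6)
    for x in (70, 180):
        ax.axvline(x, color="grey", lw=0.5)
        ax.axhline(x, color="grey", lw=0.5)
    ax.set(xlim=(0, 400), ylim=(0, 400), xlabel="reference BG (mg/dL)",
           ylabel="predicted BG (mg/dL)", title=f"Clarke grid — {patient_id}")
    p = out_dir / f"{patient_id}_clarke.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(y_true, y_pred, s=4, alpha=0.4, color="tab:green")
    xs = np.linspace(0, 550, 300)
    ax.plot(xs, xs, "k:", lw=0.8)
    for name in PARKES_T1_BOUNDARIES:
        ax.plot(xs, _boundary_y(name, xs), lw=0.6, color="k")
    ax.set(xlim=(0, 550), ylim=(0, 550), xlabel="reference BG (mg/dL)",
           ylabel="predicted BG (mg/dL)", title=f"Parkes grid — {patient_id}")
    p = out_dir / f"{patient_id}_parkes.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(p)
    return paths
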