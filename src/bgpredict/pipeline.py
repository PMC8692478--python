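"""End-to-end orchestration: simulate -> preprocess -> train -> evaluate.

One :class:`RunConfig` is the unit of reproducibility: it fixes the cohort,
the preprocessing thresholds, the model configuration, the baselines and
the global seed.  Re-running the same config reproduces every report.
Per-patient records are split chronologically (the final ``test_fraction``
of samples is the unseen test period), models are trained per patient, and
metrics are aggregated over the cohort as mean +/- sample sd.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import baselines as bl
from .evaluation import evaluation_report, forecasts_to_frame, report_to_json
from .model import ModelConfig, build_model
from .preprocess import (ContiguousSegment, QCThresholds, Scaler,
                         WindowSet, apply_qc, fill_short_gaps, read_patient,
                         split_and_reject, windows_from_segments)
from .simulate import (PatientTimeSeries, inject_artifacts, sample_cohort,
                       simulate_patient, write_patient)

log = logging.getLogger("bgpredict")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one experiment."""

    out_dir: str = "bgpredict_run"
    data_dir: str | None = None      # read existing CSVs; None -> simulate
    n_patients: int = 2
    n_days: int = 14
    seed: int = 0
    horizons: tuple = (6,)           # prediction horizons in 5-min steps
    test_fraction: float = 0.20
    model: ModelConfig = field(default_factory=ModelConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    enforce_qc: bool = False         # drop patients failing eligibility
    baselines: tuple = ("naive",)    # of: naive, krr-linear, krr-rbf, gp, arx
    n_gaps: int = 4                  # simulated sensor dropouts per patient
    n_calibrations: int = 3          # simulated fingerstick checks per patient
    make_plots: bool = True

    def __post_init__(self):
        if any(h < 1 for h in self.horizons):
            raise ValueError("horizons must be positive step counts")
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie in (0, 1)")

    def config_hash(self) -> str:
        blob = json.dumps(_config_dict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def _split_segments(segments: list[ContiguousSegment], series_len: int,
                    test_fraction: float):
    """Chronological split: segments are cut at the train/test boundary."""
    boundary = int(round(series_len * (1.0 - test_fraction)))
    train, test = [], []
    for seg in segments:
        start, stop = seg.start_index, seg.start_index + len(seg)
        if stop <= boundary:
            train.append(seg)
        elif start >= boundary:
            test.append(seg)
        else:
            cut = boundary - start
            train.append(ContiguousSegment(seg.parent_id, start,
                                           seg.cgm[:cut].copy(),
                                           seg.basal[:cut].copy(),
                                           seg.bolus[:cut].copy(),
                                           seg.carbs[:cut].copy()))
            test.append(ContiguousSegment(seg.parent_id, boundary,
                                          seg.cgm[cut:].copy(),
                                          seg.basal[cut:].copy(),
                                          seg.bolus[cut:].copy(),
                                          seg.carbs[cut:].copy()))
    return train, test


def preprocess_patient(series: PatientTimeSeries, cfg: RunConfig,
                       report: dict | None = None):
    """Clean one record and return (train_segments, test_segments, scaler)."""
    filled = fill_short_gaps(series)
    seg_report: dict = {}
    segments = split_and_reject(filled, report=seg_report)
    train_segs, test_segs = _split_segments(segments, len(series),
                                            cfg.test_fraction)
    scaler = Scaler.fit(train_segs)
    if report is not None:
        report.update(seg_report)
        report["n_train_segments"] = len(train_segs)
        report["n_test_segments"] = len(test_segs)
    return train_segs, test_segs, scaler


def _patient_windows(train_segs, test_segs, scaler, model_cfg: ModelConfig):
    kw = dict(p1=model_cfg.p1, p2=model_cfg.p2, p3=model_cfg.p3,
              p4=model_cfg.p4, f=model_cfg.f)
    train = windows_from_segments(train_segs, scaler=scaler,
                                  stride=model_cfg.train_stride, **kw)
    test = windows_from_segments(test_segs, scaler=scaler, stride=1, **kw)
    return train, test


def _run_baseline(name: str, train_w: WindowSet, test_w: WindowSet,
                  test_segs, scaler, f: int) -> "bl.ForecastBatch":
    if name == "naive":
        return bl.naive_forecast(test_w)
    if name == "krr-linear":
        return bl.krr_fit_predict(train_w, test_w, scaler, kernel="linear",
                                  spec=bl.BaselineFeatureSpec(target_step=f))
    if name == "krr-rbf":
        return bl.krr_fit_predict(train_w, test_w, scaler, kernel="rbf",
                                  spec=bl.BaselineFeatureSpec(target_step=f))
    if name == "gp":
        return bl.gp_fit_predict(train_w, test_w, scaler,
                                 spec=bl.BaselineFeatureSpec(target_step=f))
    if name == "arx":
        raise ValueError("arx is handled per segment, not via _run_baseline")
    raise ValueError(f"unknown baseline '{name}'")


def _baseline_frames(name: str, pid: str, train_w, test_w, train_segs,
                     test_segs, scaler, model_cfg) -> pd.DataFrame:
    if name == "arx":
        model = bl.arx_fit(train_segs)
        frames = []
        for seg in test_segs:
            ws = windows_from_segments([seg], scaler=scaler, p1=model_cfg.p1,
                                       p2=model_cfg.p2, p3=model_cfg.p3,
                                       p4=model_cfg.p4, f=model_cfg.f)
            batch = bl.arx_forecast(model, seg, ws.anchors, model_cfg.f)
            frames.append(forecasts_to_frame(pid, batch))
        return pd.concat(frames, ignore_index=True)
    batch = _run_baseline(name, train_w, test_w, test_segs, scaler,
                          model_cfg.f)
    frame = forecasts_to_frame(pid, batch)
    if name.startswith(("krr", "gp")):
        # single-target baselines report the horizon-end step only
        frame["step"] = model_cfg.f
    return frame


def simulate_cohort(cfg: RunConfig, out_dir: Path) -> list[Path]:
    """Simulate the cohort and write per-patient CSVs; returns the paths."""
    params = sample_cohort(cfg.n_patients, cfg.seed)
    paths = []
    for i, p in enumerate(params):
        series = simulate_patient(p, cfg.n_days)
        series = inject_artifacts(series, cfg.n_gaps, cfg.n_calibrations,
                                  seed=p.seed + 1)
        paths.append(write_patient(series, out_dir))
        log.info("simulated %s: %d days", series.patient_id, cfg.n_days)
    return paths


def run_experiment(cfg: RunConfig) -> Path:
    """Execute the full pipeline and return the experiment directory."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(
        json.dumps({**_config_dict(cfg), "config_hash": cfg.config_hash()},
                   indent=2, default=str))

    if cfg.data_dir is None:
        data_dir = out / "data"
        patient_paths = simulate_cohort(cfg, data_dir)
    else:
        patient_paths = sorted(Path(cfg.data_dir).glob("*.csv"))
        patient_paths = [p for p in patient_paths
                         if not p.stem.endswith("_truth")]
    if not patient_paths:
        raise FileNotFoundError("no patient CSV files found")

    all_reports = {}
    for path in patient_paths:
        series = read_patient(path)
        pid = series.patient_id
        stage = "qc"
        try:
            qc = apply_qc(series, cfg.qc) if series.metadata else None
            if cfg.enforce_qc and qc is not None and not qc["eligible"]:
                log.info("patient %s excluded by eligibility criteria", pid)
                continue
            stage = "preprocess"
            prep_report: dict = {}
            train_segs, test_segs, scaler = preprocess_patient(
                series, cfg, prep_report)
            patient_out = out / pid
            patient_out.mkdir(exist_ok=True)
            (patient_out / "preprocess_report.json").write_text(json.dumps({
                "patient_id": pid, "qc": qc, **prep_report,
                "config_hash": cfg.config_hash(), "seed": cfg.seed,
            }, indent=2))

            for f in cfg.horizons:
                stage = f"train(f={f})"
                model_cfg = replace(cfg.model, f=int(f),
                                    seed=cfg.seed + int(f))
                train_w, test_w = _patient_windows(train_segs, test_segs,
                                                   scaler, model_cfg)
                model = build_model(model_cfg, scaler=scaler)
                model.train(train_w)
                ckpt = patient_out / f"model_f{f}.npz"
                model.save(ckpt)
                stage = f"predict(f={f})"
                batch = model.predict(test_w)
                frame = forecasts_to_frame(pid, batch)
                frame.to_csv(patient_out / f"forecasts_f{f}.csv", index=False)
                frames = {"bgpredict": frame}
                for name in cfg.baselines:
                    stage = f"baseline {name}(f={f})"
                    bframe = _baseline_frames(name, pid, train_w, test_w,
                                              train_segs, test_segs, scaler,
                                              model_cfg)
                    bframe.to_csv(patient_out / f"forecasts_{name}_f{f}.csv",
                                  index=False)
                    frames[name] = bframe
                all_reports.setdefault(f, {}).setdefault(pid, frames)
                fusion = model.report_fusion_contributions()
                (patient_out / f"fusion_f{f}.json").write_text(json.dumps({
                    "mean_abs": fusion["mean_abs"].tolist(),
                    "weights": fusion["weights"].tolist()}, indent=2))
        except Exception as err:
            raise RuntimeError(
                f"stage '{stage}' failed for patient {pid}: {err}") from err
        log.info("patient %s done (%.1fs elapsed)", pid, time.time() - t0)

    # cohort evaluation per horizon and method
    summary = {}
    for f, per_patient in all_reports.items():
        methods = sorted({m for frames in per_patient.values() for m in frames})
        summary[str(f)] = {}
        for method in methods:
            frames = [per_patient[pid][method] for pid in per_patient
                      if method in per_patient[pid]]
            forecasts = pd.concat(frames, ignore_index=True)
            plot_dir = (out / "plots" / f"f{f}_{method}"
                        if cfg.make_plots and method == "bgpredict" else None)
            report = evaluation_report(forecasts, horizon_step=f,
                                       plot_dir=plot_dir)
            summary[str(f)][method] = report_to_json(report)
    (out / "metrics.json").write_text(json.dumps({
        "config_hash": cfg.config_hash(), "seed": cfg.seed,
        "results": summary}, indent=2))
    log.info("experiment finished in %.1fs", time.time() - t0)
    return out


def ablation_run(cfg: RunConfig, masks: list, histories: list | None = None) -> pd.DataFrame:
    """Train one model per component mask (and optional history override).

    All variants share the same data, scaler and seeds; the returned table
    lists the horizon-end test RMSE per variant.
    """
    if not masks:
        raise ValueError("empty mask list")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data_dir = out / "data"
    if not list(data_dir.glob("*.csv")):
        simulate_cohort(cfg, data_dir)
    path = sorted(p for p in data_dir.glob("*.csv")
                  if not p.stem.endswith("_truth"))[0]
    series = read_patient(path)
    train_segs, test_segs, scaler = preprocess_patient(series, cfg)

    rows = []
    variants = [(m, None) for m in masks]
    if histories:
        variants += [(None, h) for h in histories]
    from .evaluation import compute_metrics
    for mask, hist in variants:
        model_cfg = cfg.model
        if mask is not None:
            model_cfg = replace(model_cfg, component_mask=tuple(mask))
        if hist is not None:
            model_cfg = replace(model_cfg, **hist)
        model_cfg = replace(model_cfg, seed=cfg.seed)
        train_w, test_w = _patient_windows(train_segs, test_segs, scaler,
                                           model_cfg)
        model = build_model(model_cfg, scaler=scaler)
        model.train(train_w)
        batch = model.predict(test_w)
        rmse = compute_metrics(batch.y_true[:, -1], batch.y_pred[:, -1],
                               per_category=False).rmse
        rows.append({"mask": tuple(model_cfg.component_mask),
                     "histories": model_cfg.histories, "rmse": rmse})
    table = pd.DataFrame(rows)
    table.to_csv(out / "ablation.csv", index=False)
    return table
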