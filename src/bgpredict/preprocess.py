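"""Reading, cleaning and windowing of per-patient CGM records.

The cleaning pipeline mirrors common CGM practice: short sensor dropouts
(up to 30 min, i.e. six 5-min samples) are filled by shape-preserving
piecewise-cubic interpolation; longer gaps split the record into contiguous
segments; any segment containing a fingerstick calibration that disagrees
with the simultaneous CGM reading by more than 50 mg/dL is dismissed, since
such calibrations produce step discontinuities that do not reflect true
glucose.  Surviving segments are min-max scaled (fit on training data only)
and cut into multi-view windows: four input histories ending at a shared
anchor t plus the f-step future glucose target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .simulate import (CSV_COLUMNS, MINUTES_PER_STEP, SENSOR_MAX, SENSOR_MIN,
                       PatientTimeSeries)

HYPO_THRESHOLD = 70.0    # mg/dL, hypoglycemia below this
HYPER_THRESHOLD = 180.0  # mg/dL, hyperglycemia at or above this

DEFAULT_MAX_GAP_STEPS = 6       # "up to 30 mins" at 5-min sampling
DEFAULT_CALIB_DISCREPANCY = 50  # mg/dL


class SchemaError(ValueError):
    """Raised when a patient file violates the CSV schema."""


class QCError(ValueError):
    """Raised when metadata needed for quality control is missing."""


# ---------------------------------------------------------------------------
# reading

def read_patient(path: str | Path) -> PatientTimeSeries:
    """Read and validate a patient CSV written by :mod:`bgpredict.simulate`.

    A companion ``<stem>.json`` metadata file and ``<stem>_truth.csv`` trace
    are picked up when present.  Violations of the schema (non-monotone or
    off-grid timestamps, negative doses, out-of-range CGM) raise
    :class:`SchemaError` naming the offending row (1-based data row).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = set(CSV_COLUMNS) - set(df.columns)
    if missing_cols:
        raise SchemaError(f"{path.name}: missing columns {sorted(missing_cols)}")
    ts = pd.to_datetime(df["timestamp_iso8601"], errors="coerce")
    if ts.isna().any():
        row = int(ts.isna().idxmax()) + 1
        raise SchemaError(f"{path.name}: unparseable timestamp at row {row}")
    deltas = ts.diff().dropna().dt.total_seconds()
    bad = deltas[deltas != MINUTES_PER_STEP * 60]
    if len(bad):
        row = int(bad.index[0]) + 1
        raise SchemaError(
            f"{path.name}: non-monotone or off-grid timestamp at row {row} "
            f"(delta {bad.iloc[0]:.0f} s, expected {MINUTES_PER_STEP * 60} s)")
    for col in ("basal_u_per_hr", "bolus_u", "carbs_g"):
        vals = df[col].to_numpy(float)
        if np.isnan(vals).any():
            row = int(np.argmax(np.isnan(vals))) + 1
            raise SchemaError(f"{path.name}: missing {col} at row {row}")
        if (vals < 0).any():
            row = int(np.argmax(vals < 0)) + 1
            raise SchemaError(f"{path.name}: negative {col} at row {row}")
    cgm = df["cgm_mg_dl"].to_numpy(float)
    observed = ~np.isnan(cgm)
    out_of_range = observed & ((cgm < SENSOR_MIN) | (cgm > SENSOR_MAX))
    if out_of_range.any():
        row = int(np.argmax(out_of_range)) + 1
        raise SchemaError(f"{path.name}: cgm_mg_dl outside sensor range at row {row}")

    calib_col = df["calibration_mg_dl"].to_numpy(float)
    calibrations = [(int(i), float(v)) for i, v in enumerate(calib_col)
                    if not np.isnan(v)]
    meta_path = path.with_suffix(".json")
    metadata = {}
    if meta_path.exists():
        import json
        metadata = json.loads(meta_path.read_text())
    truth = None
    truth_path = path.with_name(path.stem + "_truth.csv")
    if truth_path.exists():
        truth = pd.read_csv(truth_path, float_precision="round_trip")[
            "bg_true_mg_dl"].to_numpy(float)

    return PatientTimeSeries(
        patient_id=metadata.get("patient_id", path.stem),
        start_time=ts.iloc[0],
        cgm=cgm,
        basal=df["basal_u_per_hr"].to_numpy(float),
        bolus=df["bolus_u"].to_numpy(float),
        carbs=df["carbs_g"].to_numpy(float),
        calibrations=calibrations,
        metadata=metadata,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# gap filling and segmentation

def _missing_runs(cgm: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of each maximal run of NaNs."""
    isnan = np.isnan(cgm)
    runs = []
    i = 0
    n = len(cgm)
    while i < n:
        if isnan[i]:
            j = i
            while j < n and isnan[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def fill_short_gaps(series: PatientTimeSeries,
                    max_gap_steps: int = DEFAULT_MAX_GAP_STEPS) -> PatientTimeSeries:
    """Fill CGM gaps of up to ``max_gap_steps`` samples by PCHIP interpolation.

    Interpolation is shape-preserving (monotone piecewise cubic Hermite)
    through the surrounding non-missing readings, which cannot overshoot
    into spurious hypo/hyper excursions the way an unconstrained cubic
    spline can.  Longer runs, and runs touching either series boundary, are
    left untouched.  Non-CGM channels and already-observed CGM values are
    never altered.
    """
    out = series.copy()
    cgm = out.cgm
    observed = ~np.isnan(cgm)
    if observed.sum() < 2:
        return out
    idx = np.nonzero(observed)[0]
    interp = PchipInterpolator(idx, cgm[idx], extrapolate=False)
    for start, length in _missing_runs(cgm):
        if length > max_gap_steps:
            continue
        if start == 0 or start + length == len(cgm):
            continue  # boundary gap: no neighbor on one side
        fill = interp(np.arange(start, start + length))
        cgm[start:start + length] = np.clip(fill, SENSOR_MIN, SENSOR_MAX)
    return out


@dataclass
class ContiguousSegment:
    """A gap-free stretch of a patient record."""

    parent_id: str
    start_index: int
    cgm: np.ndarray
    basal: np.ndarray
    bolus: np.ndarray
    carbs: np.ndarray
    calibrations: list = field(default_factory=list)  # indices local to segment

    def __len__(self) -> int:
        return len(self.cgm)


def split_and_reject(series: PatientTimeSeries,
                     calib_discrepancy: float = DEFAULT_CALIB_DISCREPANCY,
                     report: dict | None = None) -> list[ContiguousSegment]:
    """Split at remaining CGM gaps and dismiss calibration-discordant segments.

    Every maximal gap-free run becomes a :class:`ContiguousSegment`.  A
    segment is dismissed when it contains a calibration reading whose
    absolute difference from the simultaneous CGM value exceeds
    ``calib_discrepancy`` (strictly greater; a discrepancy exactly at the
    threshold is retained).  ``report``, when given, collects counts.
    """
    cgm = series.cgm
    n = len(cgm)
    calib_by_index = {}
    for idx, value in series.calibrations:
        calib_by_index.setdefault(idx, []).append(value)

    segments: list[ContiguousSegment] = []
    dismissed = 0
    bounds = []
    i = 0
    while i < n:
        if np.isnan(cgm[i]):
            i += 1
            continue
        j = i
        while j < n and not np.isnan(cgm[j]):
            j += 1
        bounds.append((i, j))
        i = j
    for start, stop in bounds:
        local_calibs = [(idx - start, v) for idx, vs in calib_by_index.items()
                        if start <= idx < stop for v in vs]
        discordant = any(abs(v - cgm[start + li]) > calib_discrepancy
                         for li, v in local_calibs)
        if discordant:
            dismissed += 1
            continue
        segments.append(ContiguousSegment(
            parent_id=series.patient_id,
            start_index=start,
            cgm=cgm[start:stop].copy(),
            basal=series.basal[start:stop].copy(),
            bolus=series.bolus[start:stop].copy(),
            carbs=series.carbs[start:stop].copy(),
            calibrations=local_calibs,
        ))
    if report is not None:
        report.update(n_runs=len(bounds), n_segments=len(segments),
                      n_dismissed=dismissed)
    return segments


# ---------------------------------------------------------------------------
# quality control

@dataclass(frozen=True)
class QCThresholds:
    """Eligibility and data-quality thresholds.

    Eligibility: confirmed type-1 diabetes, age over 18 years and more than
    2 years since diagnosis.  The optional quality trio keeps records with
    time in range (70-180 mg/dL) above 70%, more than 3.5 reported meals per
    day and under 2% of time in hypoglycemia.
    """

    min_age: float = 18.0
    min_years_diagnosed: float = 2.0
    min_time_in_range_frac: float = 0.70
    min_meals_per_day: float = 3.5
    max_time_hypo_frac: float = 0.02


def apply_qc(series: PatientTimeSeries,
             thresholds: QCThresholds = QCThresholds(),
             include_quality: bool = True) -> dict:
    """Evaluate eligibility (EC1-EC3) and quality criteria for one patient.

    Returns a dict with per-criterion pass/fail plus the computed statistics
    (time-in-range fraction, meals/day, time-in-hypo fraction) and an overall
    ``eligible`` / ``quality_ok`` verdict.  Fractions are computed over
    non-missing CGM samples.
    """
    meta = series.metadata
    for key in ("diabetes_type", "age", "years_since_diagnosis"):
        if key not in meta:
            raise QCError(f"missing metadata field '{key}'")
    cgm = series.cgm[~np.isnan(series.cgm)]
    if len(cgm) == 0:
        raise QCError("no CGM samples to evaluate")
    tir = float(np.mean((cgm >= HYPO_THRESHOLD) & (cgm < HYPER_THRESHOLD)))
    time_hypo = float(np.mean(cgm < HYPO_THRESHOLD))
    n_days = len(series) * MINUTES_PER_STEP / (24 * 60)
    meals_per_day = float(np.count_nonzero(series.carbs) / n_days)

    report = {
        "ec1_type1": meta["diabetes_type"] == "type1",
        "ec2_age": meta["age"] > thresholds.min_age,
        "ec3_years_diagnosed": meta["years_since_diagnosis"] > thresholds.min_years_diagnosed,
        "time_in_range_frac": tir,
        "time_hypo_frac": time_hypo,
        "meals_per_day": meals_per_day,
    }
    report["eligible"] = (report["ec1_type1"] and report["ec2_age"]
                          and report["ec3_years_diagnosed"])
    if include_quality:
        report["q_time_in_range"] = tir > thresholds.min_time_in_range_frac
        report["q_meals_per_day"] = meals_per_day > thresholds.min_meals_per_day
        report["q_time_hypo"] = time_hypo < thresholds.max_time_hypo_frac
        report["quality_ok"] = (report["q_time_in_range"]
                                and report["q_meals_per_day"]
                                and report["q_time_hypo"])
    return report


# ---------------------------------------------------------------------------
# scaling

SCALED_VARIABLES = ("cgm", "basal", "bolus", "carbs")


class Scaler:
    """Per-variable min-max scaler fitted on training segments only.

    ``scale`` maps the training minimum to 0 and maximum to 1; ``unscale``
    is the exact inverse.  Values outside the training range map outside
    [0, 1] — no clipping, so test-time extremes stay distinguishable.
    """

    def __init__(self, ranges: dict[str, tuple[float, float]]):
        for var, (lo, hi) in ranges.items():
            if not hi > lo:
                raise ValueError(f"constant variable '{var}': max == min")
        self.ranges = dict(ranges)

    @classmethod
    def fit(cls, train_segments: list[ContiguousSegment]) -> "Scaler":
        if not train_segments:
            raise ValueError("no training segments to fit on")
        ranges = {}
        for var in SCALED_VARIABLES:
            vals = np.concatenate([getattr(s, var) for s in train_segments])
            ranges[var] = (float(np.min(vals)), float(np.max(vals)))
        return cls(ranges)

    def scale(self, values: np.ndarray, variable: str) -> np.ndarray:
        lo, hi = self.ranges[variable]
        return (np.asarray(values, float) - lo) / (hi - lo)

    def unscale(self, values: np.ndarray, variable: str) -> np.ndarray:
        lo, hi = self.ranges[variable]
        return np.asarray(values, float) * (hi - lo) + lo

    def to_dict(self) -> dict:
        return {k: list(v) for k, v in self.ranges.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "Scaler":
        return cls({k: (float(v[0]), float(v[1])) for k, v in d.items()})


# ---------------------------------------------------------------------------
# windowing

@dataclass(frozen=True)
class SampleWindow:
    """One multi-view example: four input histories plus the future target."""

    x1: np.ndarray  # (p1, 2): glucose, carbs
    x2: np.ndarray  # (p2, 1): glucose
    x3: np.ndarray  # (p3, 2): glucose, basal
    x4: np.ndarray  # (p4, 2): glucose, bolus
    y: np.ndarray   # (f,): future glucose, same units as inputs
    anchor_index: int


class WindowSet:
    """Stacked multi-view windows of one segment (array-of-windows layout).

    ``x1``..``x4`` and ``y`` hold the (scaled, when a scaler was supplied)
    model inputs; ``y_mgdl`` and ``anchor_bg_mgdl`` keep the raw glucose for
    event weighting and persistence baselines.
    """

    def __init__(self, x1, x2, x3, x4, y, y_mgdl, anchor_bg_mgdl, anchors,
                 segment_id: str = ""):
        self.x1, self.x2, self.x3, self.x4 = x1, x2, x3, x4
        self.y = y
        self.y_mgdl = y_mgdl
        self.anchor_bg_mgdl = anchor_bg_mgdl
        self.anchors = anchors
        self.segment_id = segment_id

    def __len__(self) -> int:
        return len(self.anchors)

    def __getitem__(self, i: int) -> SampleWindow:
        return SampleWindow(self.x1[i], self.x2[i], self.x3[i], self.x4[i],
                            self.y[i], int(self.anchors[i]))

    def subset(self, idx) -> "WindowSet":
        return WindowSet(self.x1[idx], self.x2[idx], self.x3[idx],
                         self.x4[idx], self.y[idx], self.y_mgdl[idx],
                         self.anchor_bg_mgdl[idx], self.anchors[idx],
                         self.segment_id)

    @staticmethod
    def concatenate(sets: list["WindowSet"]) -> "WindowSet":
        if not sets:
            raise ValueError("no window sets to concatenate")
        cat = lambda attr: np.concatenate([getattr(s, attr) for s in sets])
        return WindowSet(cat("x1"), cat("x2"), cat("x3"), cat("x4"),
                         cat("y"), cat("y_mgdl"), cat("anchor_bg_mgdl"),
                         cat("anchors"), sets[0].segment_id)


def _sliding(arr: np.ndarray, anchors: np.ndarray, p: int) -> np.ndarray:
    """(n, p) history windows ending at (and including) each anchor."""
    win = np.lib.stride_tricks.sliding_window_view(arr, p)
    return win[anchors - p + 1]


def make_windows(segment: ContiguousSegment,
                 p1: int = 36, p2: int = 6, p3: int = 36, p4: int = 36,
                 f: int = 6, stride: int = 1,
                 scaler: Scaler | None = None) -> WindowSet | None:
    """Cut multi-view windows from a gap-free segment.

    A history of length p means exactly p samples ending at and including
    the anchor t; the target covers t+1 ... t+f.  Anchors run from
    ``p_max - 1`` to ``L - f - 1`` in steps of ``stride``, giving
    ``L - p_max - f + 1`` windows at stride 1.  Segments shorter than
    ``p_max + f`` yield an empty window set.
    """
    if min(p1, p2, p3, p4, f, stride) < 1:
        raise ValueError("history lengths, horizon and stride must be >= 1")
    L = len(segment)
    p_max = max(p1, p2, p3, p4)
    anchors = np.arange(p_max - 1, L - f, stride)

    if scaler is not None:
        cgm = scaler.scale(segment.cgm, "cgm")
        basal = scaler.scale(segment.basal, "basal")
        bolus = scaler.scale(segment.bolus, "bolus")
        carbs = scaler.scale(segment.carbs, "carbs")
    else:
        cgm, basal = segment.cgm, segment.basal
        bolus, carbs = segment.bolus, segment.carbs

    if len(anchors) == 0:
        empty2 = lambda p, c: np.empty((0, p, c))
        return WindowSet(empty2(p1, 2), np.empty((0, p2, 1)), empty2(p3, 2),
                         empty2(p4, 2), np.empty((0, f)), np.empty((0, f)),
                         np.empty((0,)), anchors, segment.parent_id)

    x1 = np.stack([_sliding(cgm, anchors, p1), _sliding(carbs, anchors, p1)], axis=2)
    x2 = _sliding(cgm, anchors, p2)[:, :, None]
    x3 = np.stack([_sliding(cgm, anchors, p3), _sliding(basal, anchors, p3)], axis=2)
    x4 = np.stack([_sliding(cgm, anchors, p4), _sliding(bolus, anchors, p4)], axis=2)
    fut = np.lib.stride_tricks.sliding_window_view(segment.cgm, f)[anchors + 1]
    y = scaler.scale(fut, "cgm") if scaler is not None else fut.copy()
    return WindowSet(x1, x2, x3, x4, y, fut.copy(),
                     segment.cgm[anchors].copy(), anchors, segment.parent_id)


def windows_from_segments(segments: list[ContiguousSegment], scaler=None,
                          **kwargs) -> WindowSet:
    """Pool windows from all of a patient's segments (never across gaps)."""
    sets = [make_windows(s, scaler=scaler, **kwargs) for s in segments]
    sets = [s for s in sets if s is not None and len(s) > 0]
    if not sets:
        raise ValueError("no segment long enough to yield windows")
    return WindowSet.concatenate(sets)
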