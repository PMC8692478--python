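"""Virtual type-1-diabetes patient simulator.

Generates seedable per-patient datasets on a 5-minute grid with the signal
structure a CGM-based forecaster consumes: glucose (CGM with sensor noise),
basal insulin rate, meal carbohydrates, meal/correction boluses, plus the
defects real exports contain (missing CGM stretches, discordant calibration
readings).

The physiology is a Bergman-style minimal model with a two-compartment gut:

    dG/dt  = -SG (G - Gb) - X G + Ra(t)        plasma glucose, mg/dL
    dX/dt  = p2 (SI (I - Ib) - X)              remote insulin action, 1/min
    dI/dt  = -ke I + u(t) / Vi                 plasma insulin, U/L
    dQ1/dt = -ka Q1  (+ carb impulses)         gut compartment 1, g
    dQ2/dt =  ka (Q1 - Q2)                     gut compartment 2, g
    Ra     = 1000 f_bio ka Q2 / Vg             glucose appearance, mg/dL/min

where u(t) is insulin delivery (basal + boluses, U/min), Vi = 0.12 L/kg x BW
and Vg = 1.8 dL/kg x BW are insulin/glucose distribution volumes, and Ib is
the steady-state plasma insulin produced by the mean programmed basal rate.
At that operating point (no meals, flat basal) glucose rests at Gb.

Integration is fixed-step RK4 at 1-minute resolution, resampled to the 5-min
sensor grid; CGM = true glucose + AR(1) sensor noise, clamped to the sensor
range [20, 600] mg/dL.  Everything is driven by explicit seeds so identical
inputs give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

MINUTES_PER_STEP = 5
SENSOR_MIN, SENSOR_MAX = 20.0, 600.0

#: Insulin distribution volume, L per kg body weight.
INSULIN_VOLUME_L_PER_KG = 0.12
#: Glucose distribution volume, dL per kg body weight.
GLUCOSE_VOLUME_DL_PER_KG = 1.8


class SimulationError(RuntimeError):
    """Raised when the ODE state becomes non-finite."""


@dataclass(frozen=True)
class VirtualPatientParams:
    """Parameters of one virtual patient.

    Units follow the minimal-model convention: rate constants in 1/min,
    glucose in mg/dL, insulin amounts in U.
    """

    basal_glucose: float            # Gb, mg/dL
    insulin_sensitivity: float      # SI, 1/(U/L . min)
    glucose_effectiveness: float    # SG, 1/min
    insulin_action_rate: float      # p2, 1/min
    insulin_clearance: float        # ke, 1/min
    carb_bioavailability: float     # f_bio, dimensionless in (0, 1]
    gut_absorption_rate: float      # ka, 1/min
    body_weight: float              # kg
    carb_ratio: float               # g of carbs covered per U of bolus
    correction_factor: float        # mg/dL drop per U
    basal_rate_profile: tuple       # 24 hourly rates, U/h
    sensor_noise_sd: float          # innovation sd of CGM noise, mg/dL
    sensor_ar_coeff: float          # AR(1) coefficient in [0, 1)
    seed: int
    age: float = 35.0
    diabetes_type: str = "type1"
    years_since_diagnosis: float = 10.0

    def __post_init__(self):
        for name in ("insulin_sensitivity", "glucose_effectiveness",
                     "insulin_action_rate", "insulin_clearance",
                     "gut_absorption_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 <= self.sensor_ar_coeff < 1):
            raise ValueError("sensor_ar_coeff must lie in [0, 1)")
        if not (80.0 <= self.basal_glucose <= 160.0):
            raise ValueError("basal_glucose must lie in [80, 160] mg/dL")
        if len(self.basal_rate_profile) != 24:
            raise ValueError("basal_rate_profile needs 24 hourly entries")

    @property
    def insulin_volume(self) -> float:
        """Plasma insulin distribution volume Vi, L."""
        return INSULIN_VOLUME_L_PER_KG * self.body_weight

    @property
    def glucose_volume(self) -> float:
        """Glucose distribution volume Vg, dL."""
        return GLUCOSE_VOLUME_DL_PER_KG * self.body_weight

    @property
    def basal_insulin(self) -> float:
        """Steady-state plasma insulin Ib (U/L) under the mean basal rate."""
        mean_rate = float(np.mean(self.basal_rate_profile))  # U/h
        return (mean_rate / 60.0) / (self.insulin_clearance * self.insulin_volume)

    def equilibrium_basal_rate(self) -> float:
        """Flat basal rate (U/h) that holds glucose at basal_glucose."""
        return float(np.mean(self.basal_rate_profile))


@dataclass(frozen=True)
class SimulatedDay:
    """Meal/bolus schedule for one simulated day.

    ``boluses`` aligns with ``meal_times``; correction boluses the dosing
    policy adds on top are computed during simulation.
    """

    meal_times: tuple   # minutes of day
    meal_carbs: tuple   # g
    boluses: tuple      # U, same length as meal_times

    def __post_init__(self):
        if not (len(self.meal_times) == len(self.meal_carbs) == len(self.boluses)):
            raise ValueError("meal_times, meal_carbs, boluses must align")
        if any(c <= 0 for c in self.meal_carbs):
            raise ValueError("meal carbs must be > 0")
        if any(b < 0 for b in self.boluses):
            raise ValueError("boluses must be >= 0")


@dataclass
class PatientTimeSeries:
    """Raw per-patient record on a strict 5-minute grid.

    ``cgm`` uses NaN as the missing marker; ``truth`` is the noise-free
    glucose trace (available for simulated patients only).
    """

    patient_id: str
    start_time: pd.Timestamp
    cgm: np.ndarray            # mg/dL, NaN = missing
    basal: np.ndarray          # U/h, forward-held
    bolus: np.ndarray          # U impulses, 0 elsewhere
    carbs: np.ndarray          # g impulses, 0 elsewhere
    calibrations: list         # [(index, mg/dL), ...]
    metadata: dict
    truth: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.cgm)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=len(self.cgm),
                             freq=f"{MINUTES_PER_STEP}min")

    def copy(self) -> "PatientTimeSeries":
        return PatientTimeSeries(
            patient_id=self.patient_id,
            start_time=self.start_time,
            cgm=self.cgm.copy(),
            basal=self.basal.copy(),
            bolus=self.bolus.copy(),
            carbs=self.carbs.copy(),
            calibrations=list(self.calibrations),
            metadata=dict(self.metadata),
            truth=None if self.truth is None else self.truth.copy(),
        )


# ---------------------------------------------------------------------------
# cohort sampling

#: Documented sampling ranges for cohort generation (uniform unless noted).
#: Insulin sensitivity and carb ratio are not drawn independently: pump
#: settings are tuned to the patient, so SI is derived from the correction
#: factor (1 U must actually drop glucose by about correction_factor) and the
#: carb ratio from the model's own carb impact (CF/CR is the glucose rise per
#: gram), each with a multiplicative mismatch factor that leaves some
#: patients running high and others low.
COHORT_RANGES = {
    "basal_glucose": (100.0, 140.0),
    "glucose_effectiveness": (0.004, 0.009),
    "insulin_action_rate": (0.009, 0.018),
    "insulin_clearance": (0.025, 0.050),
    "carb_bioavailability": (0.70, 0.95),
    "gut_absorption_rate": (0.020, 0.040),
    "body_weight": (50.0, 95.0),
    "correction_factor": (30.0, 60.0),
    "si_mismatch": (0.70, 1.25),
    "cr_mismatch": (0.85, 1.20),
    "basal_rate_base": (0.7, 1.3),     # U/h before circadian modulation
    "sensor_noise_sd": (3.0, 5.0),
    "sensor_ar_coeff": (0.50, 0.80),
    "age": (19.0, 65.0),
    "years_since_diagnosis": (3.0, 30.0),
}

#: reference glucose used when converting the correction factor into SI
_SI_REFERENCE_BG = 140.0


def sample_cohort(n_patients: int, seed: int) -> list[VirtualPatientParams]:
    """Draw ``n_patients`` virtual patients from the documented ranges.

    Deterministic given ``seed``; each patient receives a child seed so
    per-patient simulation is reproducible independently of cohort size.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    child_seeds = ss.spawn(n_patients)
    patients = []
    for i in range(n_patients):
        u = {k: rng.uniform(*v) for k, v in COHORT_RANGES.items()}
        base = u.pop("basal_rate_base")
        hours = np.arange(24)
        # mild circadian modulation: more basal need in the early morning
        profile = base * (1.0 + 0.15 * np.cos((hours - 4) / 24 * 2 * np.pi))
        # self-consistent pump settings: 1 U drops ~CF mg/dL; CF/CR mg/dL per g
        vi = INSULIN_VOLUME_L_PER_KG * u["body_weight"]
        vg = GLUCOSE_VOLUME_DL_PER_KG * u["body_weight"]
        si = (u["correction_factor"] * u["insulin_clearance"] * vi
              / _SI_REFERENCE_BG) * u["si_mismatch"]
        rise_per_g = 1000.0 * u["carb_bioavailability"] / vg
        carb_ratio = (u["correction_factor"] / rise_per_g) * u["cr_mismatch"]
        patients.append(VirtualPatientParams(
            basal_glucose=u["basal_glucose"],
            insulin_sensitivity=si,
            glucose_effectiveness=u["glucose_effectiveness"],
            insulin_action_rate=u["insulin_action_rate"],
            insulin_clearance=u["insulin_clearance"],
            carb_bioavailability=u["carb_bioavailability"],
            gut_absorption_rate=u["gut_absorption_rate"],
            body_weight=u["body_weight"],
            carb_ratio=carb_ratio,
            correction_factor=u["correction_factor"],
            basal_rate_profile=tuple(np.round(profile, 4)),
            sensor_noise_sd=u["sensor_noise_sd"],
            sensor_ar_coeff=u["sensor_ar_coeff"],
            seed=int(child_seeds[i].generate_state(1)[0] % (2**31)),
            age=round(u["age"], 1),
            years_since_diagnosis=round(u["years_since_diagnosis"], 1),
        ))
    return patients


# ---------------------------------------------------------------------------
# meal scheduling and dosing policy

MEAL_SLOTS = (7.5 * 60, 12.5 * 60, 18.5 * 60)   # breakfast / lunch / dinner
SNACK_SLOTS = (10.0 * 60, 21.5 * 60)
MEAL_CARB_MEAN, MEAL_CARB_SD = 65.0, 22.0
SNACK_CARB_MEAN, SNACK_CARB_SD = 25.0, 8.0
#: sd of multiplicative carb-counting error in the meal bolus; this mis-dosing
#: is what produces realistic post-meal hyper- and late hypoglycemia.
BOLUS_DOSE_ERROR_SD = 0.40


def _sample_day(params: VirtualPatientParams, rng: np.random.Generator) -> SimulatedDay:
    """Draw 3-5 meals for one day with jittered times and dosing error."""
    times, carbs = [], []
    for slot in MEAL_SLOTS:
        times.append(slot + rng.normal(0, 25))
        carbs.append(float(np.clip(rng.normal(MEAL_CARB_MEAN, MEAL_CARB_SD), 15, 130)))
    n_snacks = int(rng.integers(0, 3))  # 0, 1 or 2 snacks -> 3-5 meals/day
    for slot in rng.permutation(SNACK_SLOTS)[:n_snacks]:
        times.append(slot + rng.normal(0, 30))
        carbs.append(float(np.clip(rng.normal(SNACK_CARB_MEAN, SNACK_CARB_SD), 10, 60)))
    boluses = []
    for c in carbs:
        dose = (c / params.carb_ratio) * rng.lognormal(0.0, BOLUS_DOSE_ERROR_SD)
        boluses.append(max(0.0, float(np.round(dose, 2))))
    order = np.argsort(times)
    times = tuple(float(np.clip(times[i], 0, 24 * 60 - 1)) for i in order)
    return SimulatedDay(times, tuple(carbs[i] for i in order),
                        tuple(boluses[i] for i in order))


def generate_meal_plan(params: VirtualPatientParams, n_days: int) -> list[SimulatedDay]:
    """Deterministic (seeded from params) meal/bolus plan for ``n_days``."""
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 101)))
    return [_sample_day(params, rng) for _ in range(n_days)]


# ---------------------------------------------------------------------------
# ODE integration

#: BG above which the dosing policy adds a correction bolus at meal time.
CORRECTION_THRESHOLD = 180.0
CORRECTION_TARGET = 120.0


def _derivs(G, X, I, Q1, Q2, p, Ib, u_insulin):
    # scalar maths on purpose: the 1-min RK4 loop is the hot path
    Ra = 1000.0 * p.carb_bioavailability * p.gut_absorption_rate * Q2 / p.glucose_volume
    dG = -p.glucose_effectiveness * (G - p.basal_glucose) - X * G + Ra
    dX = p.insulin_action_rate * (p.insulin_sensitivity * (I - Ib) - X)
    dI = -p.insulin_clearance * I + u_insulin / p.insulin_volume
    dQ1 = -p.gut_absorption_rate * Q1
    dQ2 = p.gut_absorption_rate * (Q1 - Q2)
    return dG, dX, dI, dQ1, dQ2


def simulate_patient(params: VirtualPatientParams, n_days: int,
                     meal_plan: list[SimulatedDay] | None = None,
                     basal_rate: float | None = None,
                     start_time: str = "2024-01-01 00:00:00",
                     correction_boluses: bool = True) -> PatientTimeSeries:
    """Simulate ``n_days`` of a virtual patient on the 5-min sensor grid.

    Parameters
    ----------
    meal_plan
        One :class:`SimulatedDay` per day.  ``None`` draws a plan seeded from
        ``params.seed`` (3-5 meals/day).  Pass explicit empty days for a
        fasting experiment.
    basal_rate
        Flat basal override in U/h; ``None`` uses the 24-h profile.
    correction_boluses
        When True (default) a correction dose (BG - 120)/correction_factor is
        added to the meal bolus whenever simulated BG exceeds 180 mg/dL.

    Returns the series with both the noisy CGM channel and the noise-free
    ``truth`` trace (sensor-range-clamped) for oracle use.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if meal_plan is None:
        meal_plan = generate_meal_plan(params, n_days)
    if len(meal_plan) != n_days:
        raise ValueError("meal_plan length must equal n_days")

    total_min = n_days * 24 * 60
    # per-minute exogenous inputs
    basal_per_min = np.empty(total_min)
    if basal_rate is not None:
        basal_per_min[:] = basal_rate
    else:
        hours = (np.arange(total_min) // 60) % 24
        basal_per_min[:] = np.asarray(params.basal_rate_profile)[hours]
    carb_impulse = np.zeros(total_min)   # g delivered at that minute
    bolus_impulse = np.zeros(total_min)  # U delivered at that minute
    for day, plan in enumerate(meal_plan):
        for t_min, carbs, bolus in zip(plan.meal_times, plan.meal_carbs, plan.boluses):
            idx = day * 24 * 60 + int(round(t_min))
            # snap to the 5-min grid so meals/boluses land on sample points
            idx = min(total_min - 1, int(round(idx / MINUTES_PER_STEP)) * MINUTES_PER_STEP)
            carb_impulse[idx] += carbs
            bolus_impulse[idx] += bolus

    G, X, I, Q1, Q2 = params.basal_glucose, 0.0, params.basal_insulin, 0.0, 0.0
    Ib = params.basal_insulin
    n_samples = total_min // MINUTES_PER_STEP
    truth = np.empty(n_samples)
    truth[0] = G
    p = params
    isfinite = np.isfinite
    for t in range(total_min - 1):
        if carb_impulse[t]:
            Q1 += carb_impulse[t]
        if bolus_impulse[t]:
            if correction_boluses and G > CORRECTION_THRESHOLD:
                extra = round((G - CORRECTION_TARGET) / p.correction_factor, 2)
                bolus_impulse[t] += extra
            I += bolus_impulse[t] / p.insulin_volume
        u = basal_per_min[t] / 60.0  # U/h -> U/min
        k1 = _derivs(G, X, I, Q1, Q2, p, Ib, u)
        k2 = _derivs(G + 0.5 * k1[0], X + 0.5 * k1[1], I + 0.5 * k1[2],
                     Q1 + 0.5 * k1[3], Q2 + 0.5 * k1[4], p, Ib, u)
        k3 = _derivs(G + 0.5 * k2[0], X + 0.5 * k2[1], I + 0.5 * k2[2],
                     Q1 + 0.5 * k2[3], Q2 + 0.5 * k2[4], p, Ib, u)
        k4 = _derivs(G + k3[0], X + k3[1], I + k3[2], Q1 + k3[3], Q2 + k3[4],
                     p, Ib, u)
        G += (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]) / 6.0
        X += (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]) / 6.0
        I += (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]) / 6.0
        Q1 += (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3]) / 6.0
        Q2 += (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4]) / 6.0
        G = min(max(G, SENSOR_MIN), SENSOR_MAX)
        X = max(X, 0.0)
        if not (isfinite(G) and isfinite(X) and isfinite(I)
                and isfinite(Q1) and isfinite(Q2)):
            raise SimulationError(f"non-finite ODE state at t={t + 1} min")
        if (t + 1) % MINUTES_PER_STEP == 0 and (t + 1) // MINUTES_PER_STEP < n_samples:
            truth[(t + 1) // MINUTES_PER_STEP] = G

    # sensor noise: AR(1) with white innovations
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 202)))
    innov = rng.normal(0.0, params.sensor_noise_sd, n_samples)
    noise = lfilter([1.0], [1.0, -params.sensor_ar_coeff], innov)
    cgm = np.clip(truth + noise, SENSOR_MIN, SENSOR_MAX)

    basal_5min = basal_per_min[::MINUTES_PER_STEP].copy()
    carbs_5min = np.add.reduceat(carb_impulse, np.arange(0, total_min, MINUTES_PER_STEP))
    bolus_5min = np.add.reduceat(bolus_impulse, np.arange(0, total_min, MINUTES_PER_STEP))

    metadata = {
        "patient_id": f"vp{params.seed:010d}",
        "age": params.age,
        "diabetes_type": params.diabetes_type,
        "years_since_diagnosis": params.years_since_diagnosis,
        "seed": params.seed,
    }
    return PatientTimeSeries(
        patient_id=metadata["patient_id"],
        start_time=pd.Timestamp(start_time),
        cgm=cgm, basal=basal_5min, bolus=bolus_5min, carbs=carbs_5min,
        calibrations=[], metadata=metadata, truth=truth,
    )


# ---------------------------------------------------------------------------
# artifact injection

def inject_artifacts(series: PatientTimeSeries,
                     gap_spec: list | None = None,
                     calibration_spec: list | None = None,
                     seed: int = 0) -> PatientTimeSeries:
    """Return a copy of ``series`` with CGM gaps and calibration records.

    ``gap_spec`` is a list of ``(start_index, length)`` pairs; each run of
    CGM values is set to missing.  ``calibration_spec`` is a list of
    ``(index, offset_mg_dl)`` pairs; each adds a fingerstick record equal to
    the simultaneous CGM reading plus the offset.  Alternatively either spec
    may be an integer count, in which case that many artifacts are placed at
    random positions drawn from ``seed``.  The input series is unmodified.
    """
    gap_spec = [] if gap_spec is None else gap_spec
    calibration_spec = [] if calibration_spec is None else calibration_spec
    rng = np.random.default_rng(seed)
    n = len(series)
    if isinstance(gap_spec, int):
        gap_spec = [(int(rng.integers(12, n - 12)), int(rng.integers(2, 10)))
                    for _ in range(gap_spec)]
    if isinstance(calibration_spec, int):
        # fingersticks mostly agree with the sensor; the Gaussian tail still
        # produces the occasional discordant (> 50 mg/dL) calibration
        calibration_spec = [(int(rng.integers(0, n)),
                             float(rng.normal(0.0, 18.0)))
                            for _ in range(calibration_spec)]

    gap_indices = set()
    for start, length in gap_spec:
        if length < 1 or start < 0 or start + length > n:
            raise ValueError(f"gap ({start}, {length}) outside series of length {n}")
        gap_indices.update(range(start, start + length))
    out = series.copy()
    for idx, offset in calibration_spec:
        if not (0 <= idx < n):
            raise ValueError(f"calibration index {idx} outside series")
        if idx in gap_indices:
            raise ValueError(f"calibration at index {idx} overlaps an injected gap")
        out.calibrations.append((int(idx), float(series.cgm[idx] + offset)))
    for start, length in gap_spec:
        out.cgm[start:start + length] = np.nan
    return out


# ---------------------------------------------------------------------------
# CSV/JSON writers (schema shared with bgpredict.preprocess.read_patient)

CSV_COLUMNS = ["timestamp_iso8601", "cgm_mg_dl", "basal_u_per_hr",
               "bolus_u", "carbs_g", "calibration_mg_dl"]


def write_patient(series: PatientTimeSeries, out_dir: str | Path) -> Path:
    """Write ``<id>.csv`` + ``<id>.json`` metadata (+ ``<id>_truth.csv``)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    calib = np.full(len(series), np.nan)
    for idx, value in series.calibrations:
        calib[idx] = value
    df = pd.DataFrame({
        "timestamp_iso8601": series.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
        "cgm_mg_dl": series.cgm,
        "basal_u_per_hr": series.basal,
        "bolus_u": series.bolus,
        "carbs_g": series.carbs,
        "calibration_mg_dl": calib,
    })
    path = out_dir / f"{series.patient_id}.csv"
    df.to_csv(path, index=False, float_format="%.17g")
    (out_dir / f"{series.patient_id}.json").write_text(
        json.dumps(series.metadata, indent=2))
    if series.truth is not None:
        pd.DataFrame({
            "timestamp_iso8601": df["timestamp_iso8601"],
            "bg_true_mg_dl": series.truth,
        }).to_csv(out_dir / f"{series.patient_id}_truth.csv",
                  index=False, float_format="%.17g")
    return path
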