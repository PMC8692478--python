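# Methods

This note documents the models, algorithms and numerical choices behind
`bgpredict`, in the order data flows through the package.

## Problem setting

Given per-patient records on a 5-minute grid — CGM glucose (mg/dL), basal
insulin rate (U/h), bolus insulin (U) and carbohydrate intake (g) — the
forecaster predicts the glucose sequence BG_{t+1} … BG_{t+f} from histories
ending at anchor t. The default prediction horizon is f = 6 steps (30 min);
f = 12 (60 min) is supported throughout. Models are trained per patient
("individual-specific"): glucose dynamics, pump settings and meal habits
differ enough between people that a personal model is the natural unit.

## Virtual patient simulator

Because real CGM/pump exports are proprietary, the package ships a
first-class simulator with the statistical structure the pipeline assumes.
The physiology is a Bergman-style minimal model plus a two-compartment gut:

    dG/dt  = -SG (G - Gb) - X G + Ra(t)        plasma glucose, mg/dL
    dX/dt  = p2 (SI (I - Ib) - X)              remote insulin action, 1/min
    dI/dt  = -ke I + u(t)/Vi                   plasma insulin, U/L
    dQ1/dt = -ka Q1 + carb impulses            gut compartment 1, g
    dQ2/dt =  ka (Q1 - Q2)                     gut compartment 2, g
    Ra     = 1000 f_bio ka Q2 / Vg             appearance, mg/dL/min

with Vi = 0.12 L/kg and Vg = 1.8 dL/kg body weight. Ib is the steady-state
insulin from the mean programmed basal rate, so with a flat basal profile
and no meals the system rests exactly at the basal glucose Gb — a useful
oracle for tests. Integration is fixed-step RK4 at 1-minute resolution
(deterministic across platforms), resampled to the 5-min sensor grid.
CGM = true glucose + AR(1) noise (default innovation sd 4 mg/dL,
coefficient 0.5–0.8), clamped to the sensor range [20, 600] mg/dL.

Cohort sampling deliberately couples the dosing parameters to the
physiology: pump settings of a treated patient are roughly correct, so the
insulin sensitivity SI is derived from the correction factor (one unit must
actually drop glucose by about CF mg/dL at a reference glucose of
140 mg/dL), and the carb ratio from the model's own carb impact
(CF/CR equals the glucose rise per gram). Each patient gets multiplicative
mismatch factors (0.70–1.25 on SI, 0.85–1.20 on CR) so some run high and
some low. Meals (3–5/day: three jittered main meals of 65 ± 22 g plus up to
two snacks) are dosed as carbs/CR with a lognormal carb-counting error
(sd 0.40) plus a correction dose (BG − 120)/CF whenever simulated glucose
exceeds 180 mg/dL at bolus time. Insulin action (p2 ∈ [0.009, 0.018]/min)
is slower than gut absorption (ka ∈ [0.020, 0.040]/min), which is what
produces realistic post-meal spikes and occasional late hypoglycemia.
Under these defaults a 14-day record typically shows ~75–95% time in range,
~1–3% hypoglycemia and ~5–20% hyperglycemia, and at least 8 of 10 patients
visit all three glycemic categories — numbers chosen to resemble a
reasonably controlled adult type-1 cohort. What the simulator does **not**
model: exercise, stress, circadian insulin-sensitivity swings, sensor
dropout correlated with compression lows, or meal-absorption variability
beyond first-order kinetics. Passing tests on synthetic data therefore
demonstrate that the pipeline learns the meal/insulin/glucose signal
structure, not that it reaches any particular accuracy on real patients.

Artifact injection adds the defects real exports contain: missing CGM runs
(explicit or random) and fingerstick calibrations equal to the simultaneous
CGM plus an offset (random offsets are N(0, 18 mg/dL), so most agree with
the sensor while the tail produces the occasional > 50 mg/dL discordance).

## Preprocessing

* **Gap filling.** Runs of up to 6 missing samples (30 min) are filled with
  shape-preserving piecewise-cubic Hermite interpolation (PCHIP) through
  the surrounding readings. PCHIP cannot overshoot, so a filled gap never
  invents a false hypo/hyper excursion; an unconstrained cubic spline can.
  The 30-min bound is inclusive; boundary gaps (no neighbor on one side)
  stay unfilled. Observed values are never altered.
* **Segmentation.** Longer gaps split the record into contiguous segments.
  A segment containing a calibration that differs from the simultaneous CGM
  reading by strictly more than 50 mg/dL is dismissed entirely — such
  calibrations cause step discontinuities that do not reflect glucose.
* **Quality control.** Eligibility requires confirmed type-1 diabetes,
  age > 18 and > 2 years since diagnosis; the optional quality trio keeps
  records with time in range > 70%, > 3.5 reported meals/day and < 2% time
  in hypoglycemia.
* **Scaling.** Min-max to [0, 1] per variable, fitted on training segments
  only; the inverse transform is exact and test values may leave [0, 1].
* **Windowing.** A history of length p means exactly p samples ending at
  and including the anchor (p1 = 36 equals 180 min at 5-min sampling).
  Windows never span segment boundaries; a segment of length L yields
  L − p_max − f + 1 windows at stride 1. Meal and bolus channels are
  impulses on their grid slot; basal is a forward-held rate.

## Forecaster

Four independent TCN encoder–decoder components consume different views:
(BG, meal) over p1 = 36 steps, BG over p2 = 6, (BG, basal) over p3 = 36,
(BG, bolus) over p4 = 36. Each TCN stack uses kernel size 2, 64 filters,
dilations (1, 2, 4), two causal convolutions per residual block (ReLU and
1-D spatial dropout 0.2 after each; normalization layers available but off
by default), and a 1×1 convolution on the skip path where channel counts
differ. The encoder's latent state is the final-time-step feature vector;
the decoder repeats it f times and maps it through its own stack
(non-autoregressive realization — the standard TCN sequence-to-sequence
pattern; autoregressive decoding is a possible alternative we did not
implement). A time-distributed dense head (one linear unit, no activation —
scaled glucose is unbounded above 1 on test data) yields one scalar per
horizon step, and the fusion layer combines components elementwise over the
horizon, Ŷ = Σ_c W_c ⊙ Ŷ_c, with length-f weight vectors initialized to
0.25 and left unconstrained.

One stack with dilations (1, 2, 4) and kernel 2 has a receptive field of
1 + 2·(1+2+4) = 15 samples — smaller than the 36-sample inputs of
components 1/3/4. We keep the stated configuration (the extra history is
simply ignored by the network) and expose `n_stacks`/`dilations` for
deeper variants. Because the latent is one causal output, the encoder
computes only the suffix each layer still needs (15 → 13 → 9 → 1 positions
instead of 36 at every layer); this is an exact reformulation that roughly
halves training cost, verified by the causality tests.

**Loss.** Training minimizes the event-weighted Huber loss. The Huber
threshold δ = 0.5 applies to normalized glucose (training operates on
[0, 1]-scaled data); the event category is decided on the *true* glucose in
mg/dL: weight 100 below 70 mg/dL, 10 at or above 180 mg/dL, 1 otherwise.
With all weights at 1 the loss reduces exactly to plain Huber. The
asymmetric weighting buys hypo/hyper sensitivity at the price of a downward
prediction pull wherever the model cannot yet rule out a low excursion;
this pull shrinks as training sharpens the conditional estimate, which is
why adequate optimization (see below) matters for overall RMSE.

**Optimization.** Adam with learning rate 1e-4, batch size 32, shuffled
epochs, default cap 200 epochs with early stopping (patience 20) on a
chronological 10% validation tail; best-validation weights are restored.
At the start of the first fit every head bias is set to the marginal mean
of the scaled training target so the fused output (fusion weights sum to 1)
opens unbiased instead of climbing out of a zero-output transient. The
whole network is plain numpy (float32) with hand-written backward passes —
gradients are verified against central finite differences in float64 — and
a single flat parameter buffer for the optimizer. All randomness (init,
shuffling, dropout) derives from the config seed; runs are bit-reproducible
at a fixed thread count.

**Evaluation anchor.** Quantitative metrics use the final predicted step
(the prediction horizon); per-step values are available from the forecasts
table. Each patient's record is split chronologically, last 20% as test.

## Baselines

* **Naive persistence** copies the anchor glucose to every horizon step.
* **Kernel ridge regression** (linear and RBF, α = 1.0, γ = 0.1) on
  flattened scaled histories — 30 min of glucose plus 3 h each of basal,
  bolus and carbs — predicting the single horizon-end value.
* **Gaussian process** with an ARD RBF kernel (length scales and signal
  variance initialized to 1.0), posterior-mean prediction, training set
  subsampled to at most 2000 windows (exact GP is cubic in n).
* **ARX(na=6, nb=[36,36,36], nk=[0,0,0])** fitted by least squares on the
  one-step regression (ridge fallback with a tiny penalty if the design is
  rank-deficient), iterated over the horizon feeding predictions back while
  exogenous inputs keep their recorded values — pump and meal records are
  known 30 min ahead. ARMAX (a moving-average noise polynomial estimated by
  nonlinear least squares) is deliberately out of scope.

All baselines consume the same windows as the forecaster, so comparisons
differ only in the model.

## Evaluation suite

RMSE, MAE, MAPE (true value in the denominator, exactly as the printed
formula) and NRMSE = RMSE/(y_max − y_min) over the evaluated true values;
per-category sub-reports (membership decided by the true value; an empty
category reports "No test samples" rather than zeros). Event rates follow
the verbatim definitions: TP counts samples with both predicted and true
values in the category, P all true members, FP predictions in the category
whose truth is not, N all true non-members; TPR/FPR with an empty
denominator are reported missing. Cohort aggregation is mean ± sample
(n−1) standard deviation over patients. Welch's unequal-variance t-test
(two-sided) compares per-patient metric values between models.

Clinical accuracy uses both error grids. Clarke zones are the published
1987 inequality rules (including the low-glucose branch of Zone A that the
±20% summary omits); Parkes type-1 zones are classified against the
published consensus boundary-vertex table, with boundary polylines extended
beyond their last vertex at the final segment's slope and inputs clamped to
[0, 550] mg/dL with a warning. Points exactly on a boundary are assigned to
the lower-risk zone in both grids (ties are not specified by the sources).
The test suite cross-checks the Parkes classifier against an independent
point-in-polygon oracle built from the same vertex table.

## Problem sizes used in the automated checks

The acceptance tests train per-patient models on a 3-patient × 21-day
synthetic cohort with the default configuration capped at 60 epochs (about
10,000 Adam steps per model at stride 1), comparing the 30-min forecaster
against persistence and the 60-min against the 30-min horizon. The
`scripts/acceptance.py` pipeline run uses 2 patients × 14 days at the same
60-epoch cap. These sizes are the package's chosen desk-scale defaults;
larger cohorts only tighten the comparisons.

## Known limitations

* The hand-written numpy network is CPU-only and single-threaded by
  design; training one patient-month takes a few minutes, which is fine
  for the per-patient setting but not for population-scale pretraining.
* The event-weighted loss biases undertrained models downward (toward the
  heavily weighted hypoglycemic range); with the default 200-epoch cap and
  early stopping this mostly resolves, but severely truncated training
  shows it. On very stable traces that still visit hypoglycemia the effect
  is structural rather than transient: persistence at 30 min sits near the
  sensor-noise floor there, while the hypo-weighted objective deliberately
  hedges low, so such patients can retain a higher overall RMSE than the
  naive baseline even as their event sensitivity improves. The end-to-end
  test suite exhibits exactly this on one of its three virtual patients.
* KRR/GP baselines predict only the horizon-end step, not the sequence.
* The simulator's realism limits (above) bound what synthetic results say
  about real cohorts; no printed clinical figure should be read off it.
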