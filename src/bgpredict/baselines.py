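"""Reference predictors for the 30-minute forecasting comparison.

* naive persistence — the last observed glucose value is copied forward;
* kernel ridge regression (linear and RBF kernels) on flattened scaled
  histories (30 min of glucose, 3 h each of basal, bolus and carbs);
* Gaussian-process regression with an ARD RBF kernel (optional, subsampled
  for tractability);
* ARX — a one-step autoregressive model with exogenous inputs fitted by
  least squares and iterated for multi-step forecasts, feeding predictions
  back while exogenous inputs stay at their recorded values (pump and meal
  records are known over a 30-min horizon).

KRR and GP predict the single horizon-end step; naive and ARX produce the
whole f-step sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel
from sklearn.kernel_ridge import KernelRidge

from .model import ForecastBatch
from .preprocess import ContiguousSegment, Scaler, WindowSet


@dataclass(frozen=True)
class BaselineFeatureSpec:
    """Feature layout for the KRR/GP baselines."""

    bg_history_steps: int = 6
    basal_history_steps: int = 36
    bolus_history_steps: int = 36
    meal_history_steps: int = 36
    target_step: int = 6  # horizon end: 30 min at 5-min sampling

    def __post_init__(self):
        if min(self.bg_history_steps, self.basal_history_steps,
               self.bolus_history_steps, self.meal_history_steps,
               self.target_step) < 1:
            raise ValueError("all feature counts must be positive")


def naive_forecast(windows: WindowSet) -> ForecastBatch:
    """Persistence: every horizon step predicts the anchor glucose value."""
    f = windows.y_mgdl.shape[1]
    y_pred = np.repeat(windows.anchor_bg_mgdl[:, None], f, axis=1)
    return ForecastBatch(anchors=windows.anchors.copy(),
                         y_true=windows.y_mgdl.copy(), y_pred=y_pred)


def _features(windows: WindowSet, spec: BaselineFeatureSpec) -> np.ndarray:
    """Flatten the scaled multi-view histories into one design matrix."""
    bg = windows.x2[:, -spec.bg_history_steps:, 0]
    basal = windows.x3[:, -spec.basal_history_steps:, 1]
    bolus = windows.x4[:, -spec.bolus_history_steps:, 1]
    meal = windows.x1[:, -spec.meal_history_steps:, 1]
    X = np.concatenate([bg, basal, bolus, meal], axis=1)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    return X


def krr_fit_predict(train_windows: WindowSet, test_windows: WindowSet,
                    scaler: Scaler, kernel: str = "rbf", alpha: float = 1.0,
                    gamma: float = 0.1,
                    spec: BaselineFeatureSpec = BaselineFeatureSpec()) -> ForecastBatch:
    """Kernel ridge regression of the horizon-end glucose on scaled histories."""
    if kernel not in ("linear", "rbf"):
        raise ValueError("kernel must be 'linear' or 'rbf'")
    Xtr = _features(train_windows, spec)
    Xte = _features(test_windows, spec)
    ytr = train_windows.y[:, spec.target_step - 1]
    model = KernelRidge(kernel=kernel, alpha=alpha,
                        gamma=gamma if kernel == "rbf" else None)
    model.fit(Xtr, ytr)
    pred_norm = model.predict(Xte)
    y_pred = scaler.unscale(pred_norm, "cgm")[:, None]
    y_true = test_windows.y_mgdl[:, spec.target_step - 1][:, None]
    return ForecastBatch(anchors=test_windows.anchors.copy(),
                         y_true=y_true, y_pred=y_pred)


def gp_fit_predict(train_windows: WindowSet, test_windows: WindowSet,
                   scaler: Scaler,
                   spec: BaselineFeatureSpec = BaselineFeatureSpec(),
                   max_train: int = 2000, noise: float = 1e-2,
                   optimize: bool = True, seed: int = 0) -> ForecastBatch:
    """GP posterior-mean forecast with an ARD RBF kernel (unit init scales).

    Exact GP regression is cubic in the training size, so at most
    ``max_train`` training windows are used (random subsample, seeded).
    """
    Xtr = _features(train_windows, spec)
    ytr = train_windows.y[:, spec.target_step - 1]
    if len(Xtr) > max_train:
        idx = np.random.default_rng(seed).choice(len(Xtr), max_train,
                                                 replace=False)
        Xtr, ytr = Xtr[idx], ytr[idx]
    Xte = _features(test_windows, spec)
    kernel = ConstantKernel(1.0) * RBF(length_scale=np.ones(Xtr.shape[1]))
    gp = GaussianProcessRegressor(kernel=kernel, alpha=noise,
                                  optimizer="fmin_l_bfgs_b" if optimize else None,
                                  normalize_y=True, random_state=seed)
    gp.fit(Xtr, ytr)
    pred_norm = gp.predict(Xte)
    y_pred = scaler.unscale(pred_norm, "cgm")[:, None]
    y_true = test_windows.y_mgdl[:, spec.target_step - 1][:, None]
    return ForecastBatch(anchors=test_windows.anchors.copy(),
                         y_true=y_true, y_pred=y_pred)


# ---------------------------------------------------------------------------
# ARX

@dataclass(frozen=True)
class ARXConfig:
    """Orders of the ARX(na; nb; nk) model: glucose lags, exogenous lags, delays."""

    na: int = 6
    nb: tuple = (36, 36, 36)
    nk: tuple = (0, 0, 0)

    def __post_init__(self):
        if self.na < 1 or any(b < 1 for b in self.nb) or any(k < 0 for k in self.nk):
            raise ValueError("need na >= 1, nb entries >= 1, nk entries >= 0")


@dataclass
class ARXModel:
    config: ARXConfig
    a: np.ndarray        # (na,) autoregressive coefficients
    b: list              # per-channel (nb_i,) exogenous coefficients
    intercept: float

    @property
    def min_history(self) -> int:
        return max(self.config.na,
                   max(k + b for b, k in zip(self.config.nb, self.config.nk)))


def _arx_design(y: np.ndarray, exo: list, config: ARXConfig):
    """Rows: [y_{t-1}..y_{t-na}, u_{t-nk}..u_{t-nk-nb+1} per channel, 1]."""
    na, nb, nk = config.na, config.nb, config.nk
    start = max(na, max(k + b for b, k in zip(nb, nk)))
    t = np.arange(start, len(y))
    cols = [y[t - i] for i in range(1, na + 1)]
    for u, b, k in zip(exo, nb, nk):
        cols += [u[t - k - j] for j in range(b)]
    cols.append(np.ones(len(t)))
    return np.column_stack(cols), y[t]


def arx_fit(segments: list, config: ARXConfig = ARXConfig(),
            ridge: float = 0.0) -> ARXModel:
    """Least-squares fit of the one-step ARX regression over all segments.

    The glucose at t is regressed on its ``na`` previous values and on
    ``nb[i]`` past values of each exogenous channel (basal, bolus, carbs)
    delayed by ``nk[i]``.  A rank-deficient design falls back to a tiny
    ridge penalty with a warning.
    """
    rows, targets = [], []
    for seg in segments:
        exo = [seg.basal, seg.bolus, seg.carbs]
        if len(seg) <= max(config.na,
                           max(k + b for b, k in zip(config.nb, config.nk))):
            continue
        X, y = _arx_design(seg.cgm, exo, config)
        rows.append(X)
        targets.append(y)
    if not rows:
        raise ValueError("no segment long enough for the ARX orders")
    X = np.vstack(rows)
    y = np.concatenate(targets)
    if ridge > 0:
        coef = np.linalg.solve(X.T @ X + ridge * np.eye(X.shape[1]), X.T @ y)
    else:
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            import warnings
            warnings.warn("rank-deficient ARX design; refitting with tiny ridge")
            coef = np.linalg.solve(X.T @ X + 1e-8 * np.eye(X.shape[1]), X.T @ y)
    if not np.all(np.isfinite(coef)):
        raise ValueError("non-finite ARX coefficients")
    a = coef[:config.na]
    b = []
    ofs = config.na
    for nb_i in config.nb:
        b.append(coef[ofs:ofs + nb_i])
        ofs += nb_i
    return ARXModel(config=config, a=a, b=b, intercept=float(coef[-1]))


def arx_forecast(model: ARXModel, segment: ContiguousSegment,
                 anchors: np.ndarray, f: int) -> ForecastBatch:
    """Iterated multi-step ARX forecast from each anchor.

    One-step predictions are fed back for the glucose lags; exogenous
    channels use their recorded values over the horizon.
    """
    cfg = model.config
    y = segment.cgm
    exo = [segment.basal, segment.bolus, segment.carbs]
    anchors = np.asarray(anchors, int)
    if anchors.min() + 1 < model.min_history or anchors.max() + f >= len(y):
        raise ValueError("anchor without enough history or future in segment")
    preds = np.empty((len(anchors), f))
    for i, t in enumerate(anchors):
        hist = list(y[t - cfg.na + 1: t + 1])  # last na true values
        for j in range(1, f + 1):
            s = t + j
            val = model.intercept + sum(model.a[q - 1] * hist[-q]
                                        for q in range(1, cfg.na + 1))
            for u, bcoef, k in zip(exo, model.b, cfg.nk):
                for q in range(len(bcoef)):
                    val += bcoef[q] * u[s - k - q]
            hist.append(val)
            preds[i, j - 1] = val
    y_true = np.stack([y[t + 1: t + f + 1] for t in anchors])
    return ForecastBatch(anchors=anchors.copy(), y_true=y_true, y_pred=preds)
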