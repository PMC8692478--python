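"""The four-component multi-view glucose forecaster.

Four independent TCN encoder-decoder components consume different views of
the recent past — (glucose, carbs) over p1 steps, glucose alone over p2
steps, (glucose, basal) over p3, (glucose, bolus) over p4 — each ending at
the same anchor.  A time-distributed dense head maps every component's
decoder output to one scalar per horizon step, and a learnable parametric
fusion layer combines the component forecasts elementwise over the horizon:

    Y_hat = W1 . Y1 + W2 . Y2 + W3 . Y3 + W4 . Y4

with per-horizon-step weight vectors W_c initialized to 0.25.  Training
minimizes an event-weighted Huber loss: the pointwise Huber value (threshold
delta on normalized glucose) is multiplied by lambda_hypo, lambda_hyper or
lambda_normo according to the glycemic category of the *true* glucose in
mg/dL, which concentrates learning on the clinically critical rare events.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .preprocess import HYPER_THRESHOLD, HYPO_THRESHOLD, Scaler, WindowSet
from .tcn import (DTYPE, Adam, Param, TCNConfig, TCNDecoder, TCNEncoder,
                  TimeDistributedDense)

#: channel counts of the four component views
COMPONENT_CHANNELS = (2, 1, 2, 2)


@dataclass(frozen=True)
class ModelConfig:
    """Everything needed to build and train one per-patient model."""

    p1: int = 36
    p2: int = 6
    p3: int = 36
    p4: int = 36
    f: int = 6
    tcn: TCNConfig = field(default_factory=TCNConfig)
    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 200
    early_stop_patience: int = 20
    val_fraction: float = 0.10
    delta: float = 0.5               # Huber threshold, normalized-BG units
    lambda_hypo: float = 100.0
    lambda_hyper: float = 10.0
    lambda_normo: float = 1.0
    component_mask: tuple = (1, 1, 1, 1)
    train_stride: int = 1            # training windows at every anchor
    seed: int = 0

    def __post_init__(self):
        if min(self.p1, self.p2, self.p3, self.p4, self.f) < 1:
            raise ValueError("history lengths and horizon must be >= 1")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if min(self.lambda_hypo, self.lambda_hyper, self.lambda_normo) <= 0:
            raise ValueError("event weights must be > 0")
        if len(self.component_mask) != 4 or not any(self.component_mask):
            raise ValueError("component_mask needs 4 flags with >= 1 enabled")

    @property
    def histories(self) -> tuple:
        return (self.p1, self.p2, self.p3, self.p4)


@dataclass
class ForecastBatch:
    """Paired true/predicted multi-step forecasts in mg/dL."""

    anchors: np.ndarray
    y_true: np.ndarray  # (n, f)
    y_pred: np.ndarray  # (n, f)

    def __post_init__(self):
        if self.y_true.shape != self.y_pred.shape:
            raise ValueError("y_true and y_pred shapes differ")
        if not np.all(np.isfinite(self.y_pred)):
            raise ValueError("non-finite predictions")


# ---------------------------------------------------------------------------
# losses

def huber_loss(y, y_hat, delta: float):
    """Mean elementwise Huber value; quadratic within |e| <= delta, linear beyond."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have the same shape")
    if delta <= 0:
        raise ValueError("delta must be > 0")
    e = np.abs(y - y_hat)
    val = np.where(e <= delta, 0.5 * e * e, delta * (e - 0.5 * delta))
    return float(val.mean())


def _huber_elementwise(e: np.ndarray, delta: float) -> np.ndarray:
    ae = np.abs(e)
    return np.where(ae <= delta, 0.5 * e * e, delta * (ae - 0.5 * delta))


def _huber_grad(e: np.ndarray, delta: float) -> np.ndarray:
    """d huber / d e (once-differentiable at |e| = delta)."""
    return np.clip(e, -delta, delta)


def event_weights(y_true_mg_dl, lambda_hypo: float = 100.0,
                  lambda_hyper: float = 10.0, lambda_normo: float = 1.0):
    """Per-element loss weight from the glycemic category of the true value."""
    y = np.asarray(y_true_mg_dl, float)
    w = np.full(y.shape, lambda_normo, float)
    w[y < HYPO_THRESHOLD] = lambda_hypo
    w[y >= HYPER_THRESHOLD] = lambda_hyper
    return w


def weighted_sequence_loss(y_norm, y_hat_norm, y_true_mg_dl,
                           config: ModelConfig):
    """Mean of event-weighted Huber values; plain Huber when all lambdas are 1."""
    w = event_weights(np.asarray(y_true_mg_dl, float), config.lambda_hypo,
                      config.lambda_hyper, config.lambda_normo)
    e = np.asarray(y_norm, float) - np.asarray(y_hat_norm, float)
    return float((w * _huber_elementwise(e, config.delta)).mean())


def fuse(y_components, W: np.ndarray, mask=(1, 1, 1, 1)):
    """Parametric fusion: Y = sum_c mask_c (W_c . Y_c), elementwise over horizon.

    ``y_components`` is a sequence of four (n, f) arrays; ``W`` is (4, f).
    """
    if not any(mask):
        raise RuntimeError("all components masked: nothing to fuse")
    out = None
    for c, (yc, m) in enumerate(zip(y_components, mask)):
        if not m:
            continue
        term = np.asarray(yc, float) * np.asarray(W[c], float)
        out = term if out is None else out + term
    return out


# ---------------------------------------------------------------------------
# model

class _Component:
    """One encoder-decoder-head branch of the forecaster."""

    def __init__(self, in_ch: int, config: ModelConfig,
                 rng: np.random.Generator, name: str):
        self.encoder = TCNEncoder(in_ch, config.tcn, rng, f"{name}.enc")
        self.decoder = TCNDecoder(config.tcn, rng, f"{name}.dec")
        self.head = TimeDistributedDense(config.tcn.n_filters, rng, f"{name}.head")
        self.f = config.f

    def params(self):
        return self.encoder.params() + self.decoder.params() + self.head.params()

    def forward(self, x, training: bool = False):
        latent = self.encoder.forward(x, training)
        feats = self.decoder.forward(latent, self.f, training)
        return self.head.forward(feats, training)  # (B, f)

    def backward(self, gy):
        gfeats = self.head.backward(gy)
        glatent = self.decoder.backward(gfeats)
        return self.encoder.backward(glatent)


class TrainingFailure(RuntimeError):
    pass


class BGPredictModel:
    """Four TCN encoder-decoder components with a parametric fusion layer."""

    def __init__(self, config: ModelConfig, seed: int | None = None,
                 scaler: Scaler | None = None):
        self.config = config
        seed = config.seed if seed is None else seed
        ss = np.random.SeedSequence((seed, 7))
        rngs = [np.random.default_rng(s) for s in ss.spawn(5)]
        self.components = [
            _Component(COMPONENT_CHANNELS[c], config, rngs[c], f"c{c + 1}")
            for c in range(4)
        ]
        self.fusion = Param(np.full((4, config.f), 0.25), "fusion.W")
        self.scaler = scaler
        self.history: dict = {"train_loss": [], "val_loss": []}
        self._shuffle_rng = np.random.default_rng(rngs[4].integers(2**31))

    # -- parameters --------------------------------------------------------
    def params(self, trainable_only: bool = False):
        ps = []
        for c, comp in enumerate(self.components):
            if trainable_only and not self.config.component_mask[c]:
                continue
            ps += comp.params()
        ps.append(self.fusion)
        return ps

    # -- forward/backward --------------------------------------------------
    def forward(self, windows: WindowSet, training: bool = False):
        """Fused normalized forecast (n, f) plus per-component outputs."""
        xs = (windows.x1, windows.x2, windows.x3, windows.x4)
        mask = self.config.component_mask
        ycs = []
        for c, comp in enumerate(self.components):
            if mask[c]:
                ycs.append(comp.forward(xs[c].astype(DTYPE), training))
            else:
                ycs.append(np.zeros((len(windows), self.config.f), dtype=DTYPE))
        fused = np.zeros((len(windows), self.config.f), dtype=DTYPE)
        for c in range(4):
            if mask[c]:
                fused += self.fusion.value[c] * ycs[c]
        return fused, ycs

    def _backward(self, gy, ycs):
        mask = self.config.component_mask
        g = gy.astype(DTYPE)
        for c, comp in enumerate(self.components):
            if not mask[c]:
                continue
            self.fusion.grad[c] += (g * ycs[c]).sum(axis=0)
            comp.backward(g * self.fusion.value[c])

    # -- training ----------------------------------------------------------
    def train(self, train_windows: WindowSet,
              val_windows: WindowSet | None = None,
              max_epochs: int | None = None,
              verbose: bool = False) -> "BGPredictModel":
        """Fit with Adam on the event-weighted Huber loss.

        When no validation set is given, the chronological tail
        (``val_fraction`` of the training windows) is held out; early
        stopping monitors its loss with the configured patience and the best
        weights are restored.  Deterministic for a fixed config seed.
        """
        cfg = self.config
        if len(train_windows) == 0:
            raise ValueError("empty training set")
        if val_windows is None and cfg.val_fraction > 0:
            n_val = max(1, int(len(train_windows) * cfg.val_fraction))
            if n_val < len(train_windows):
                val_windows = train_windows.subset(slice(len(train_windows) - n_val, None))
                train_windows = train_windows.subset(slice(0, len(train_windows) - n_val))
        max_epochs = cfg.max_epochs if max_epochs is None else max_epochs

        if not self.history["train_loss"]:
            # first fit: start every head at the marginal target mean so the
            # fused output (fusion weights sum to 1) opens unbiased instead of
            # spending early epochs climbing out of a zero-output transient
            ybar = float(np.mean(train_windows.y))
            for c, comp in enumerate(self.components):
                if cfg.component_mask[c]:
                    comp.head.b.value[...] = ybar

        opt = Adam(self.params(trainable_only=True), lr=cfg.learning_rate)
        n = len(train_windows)
        best_val = np.inf
        best_state = None
        bad_epochs = 0
        for epoch in range(max_epochs):
            order = self._shuffle_rng.permutation(n)
            epoch_loss = 0.0
            n_elems = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                batch = train_windows.subset(idx)
                opt.zero_grad()
                fused, ycs = self.forward(batch, training=True)
                w = event_weights(batch.y_mgdl, cfg.lambda_hypo,
                                  cfg.lambda_hyper, cfg.lambda_normo)
                e = fused - batch.y  # prediction minus target, normalized
                loss_elems = w * _huber_elementwise(e, cfg.delta)
                loss = loss_elems.mean()
                if not np.isfinite(loss):
                    raise TrainingFailure(f"non-finite loss at epoch {epoch + 1}")
                gy = (w * _huber_grad(e, cfg.delta) / e.size).astype(DTYPE)
                self._backward(gy, ycs)
                opt.step()
                epoch_loss += float(loss_elems.sum())
                n_elems += e.size
            train_loss = epoch_loss / n_elems
            self.history["train_loss"].append(train_loss)

            if val_windows is not None and len(val_windows) > 0:
                val_loss = self.evaluate_loss(val_windows)
            else:
                val_loss = train_loss
            self.history["val_loss"].append(val_loss)
            if verbose:
                print(f"epoch {epoch + 1:3d}  train {train_loss:.5f}  val {val_loss:.5f}")

            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_state = [p.value.copy() for p in self.params()]
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs > cfg.early_stop_patience:
                    break
        if best_state is not None:
            for p, v in zip(self.params(), best_state):
                p.value[...] = v
        return self

    def _forward_inference(self, windows: WindowSet,
                           chunk: int = 256) -> np.ndarray:
        """Chunked forward pass (keeps the working set cache-sized)."""
        if len(windows) <= chunk:
            return self.forward(windows, training=False)[0]
        parts = [self.forward(windows.subset(slice(s, s + chunk)),
                              training=False)[0]
                 for s in range(0, len(windows), chunk)]
        return np.concatenate(parts, axis=0)

    def evaluate_loss(self, windows: WindowSet) -> float:
        fused = self._forward_inference(windows)
        return weighted_sequence_loss(windows.y, fused, windows.y_mgdl,
                                      self.config)

    # -- inference ---------------------------------------------------------
    def predict(self, windows: WindowSet,
                component_mask: tuple | None = None) -> ForecastBatch:
        """De-scaled f-step forecasts in mg/dL (dropout off, deterministic)."""
        if self.scaler is None:
            raise RuntimeError("model has no fitted scaler; cannot de-scale")
        saved = self.config
        if component_mask is not None:
            self.config = replace(saved, component_mask=tuple(component_mask))
        try:
            fused = self._forward_inference(windows)
        finally:
            self.config = saved
        y_pred = self.scaler.unscale(fused.astype(float), "cgm")
        return ForecastBatch(anchors=windows.anchors.copy(),
                             y_true=windows.y_mgdl.copy(), y_pred=y_pred)

    def report_fusion_contributions(self) -> dict:
        """Fusion weight vectors and their magnitudes, per component."""
        W = self.fusion.value.astype(float)
        return {
            "weights": W.copy(),                      # (4, f)
            "mean_abs": np.abs(W).mean(axis=1),       # (4,)
            "per_step_abs": np.abs(W).copy(),
        }

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        """Self-describing .npz checkpoint: config, scaler, all weights."""
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        cfg = asdict(self.config)
        cfg["tcn"] = asdict(self.config.tcn)
        meta = {"config": cfg,
                "scaler": None if self.scaler is None else self.scaler.to_dict(),
                "history": self.history}
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "BGPredictModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta_json"].tobytes()).decode())
            cfg_d = meta["config"]
            cfg_d["tcn"] = TCNConfig(**{**cfg_d["tcn"],
                                        "dilations": tuple(cfg_d["tcn"]["dilations"])})
            cfg_d["component_mask"] = tuple(cfg_d["component_mask"])
            config = ModelConfig(**cfg_d)
            scaler = (None if meta["scaler"] is None
                      else Scaler.from_dict(meta["scaler"]))
            model = cls(config, scaler=scaler)
            model.history = meta["history"]
            for i, p in enumerate(model.params()):
                p.value[...] = data[f"param_{i}"]
        return model


def build_model(config: ModelConfig, seed: int | None = None,
                scaler: Scaler | None = None) -> BGPredictModel:
    """Construct an untrained model; identical seeds give identical weights."""
    return BGPredictModel(config, seed=seed, scaler=scaler)
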