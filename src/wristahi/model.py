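"""Whole-night sequence classifier for respiratory-event epochs.

The classifier maps the per-epoch feature sequence of an entire night
(n_epochs x input_dim, zero-padded to a fixed maximum length with an explicit
mask) to a per-epoch probability of being a respiratory-event epoch.  The
architecture follows the temporal-convolution pattern: Gaussian input noise
(training only), a stack of dilated 1-D convolutions whose receptive field
spans several epochs, and a per-epoch dense head with a sigmoid output.  All
hidden activations are multiplied by the real-epoch mask after every layer,
which makes the probabilities of real epochs exactly independent of the
padding length.

It is implemented directly in NumPy (forward, backprop, Adam); the scale of
the problem -- tens of recordings, hundreds of epochs, tens of features --
does not need GPU machinery, and the explicit implementation keeps the
masking semantics fully under test.

Training minimises per-epoch weighted binary cross-entropy; epochs with more
than 80% undefined features and padded epochs have weight zero and contribute
nothing to the loss.  The probability threshold that turns probabilities into
positive epochs is selected on training recordings by grid search, either
maximising the linearly weighted kappa of the derived OSA severity (default)
or the mean per-recording F1 of epoch detection.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import cohen_kappa_score, f1_score

logger = logging.getLogger("wristahi")

SEVERITY_EDGES = (5.0, 15.0, 30.0)  # canonical AHI class boundaries
DEFAULT_THRESHOLD = 0.5
THRESHOLD_GRID = np.round(np.arange(0.01, 1.0, 0.01), 2)


@dataclass
class ModelConfig:
    input_dim: int
    max_epochs: int = 1150
    noise_std: float = 0.05
    conv_filters: int = 16
    kernel: int = 5
    dilated_kernel: int = 5
    dilation: int = 2
    n_stacks: int = 2
    dropout: float = 0.1
    dense_units: int = 16
    seed: int = 0
    learning_rate: float = 0.01
    max_iter: int = 150
    patience: int = 15

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.input_dim < 1 or self.max_epochs < 1:
            raise ValueError("inconsistent model dimensions")


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, dilation: int) -> np.ndarray:
    """'same' 1-D convolution over the time axis.  x: (B,T,I), w: (K,I,O)."""
    k = w.shape[0]
    c = k // 2
    pad = c * dilation
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    t = x.shape[1]
    y = np.zeros((x.shape[0], t, w.shape[2]))
    for i in range(k):
        y += xp[:, i * dilation : i * dilation + t, :] @ w[i]
    return y + b


def _conv_backward(
    x: np.ndarray, w: np.ndarray, dilation: int, dy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    k = w.shape[0]
    c = k // 2
    pad = c * dilation
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    t = x.shape[1]
    dw = np.zeros_like(w)
    dxp = np.zeros_like(xp)
    for i in range(k):
        xs = xp[:, i * dilation : i * dilation + t, :]
        dw[i] = np.einsum("bti,bto->io", xs, dy)
        dxp[:, i * dilation : i * dilation + t, :] += dy @ w[i].T
    db = dy.sum(axis=(0, 1))
    return dxp[:, pad : pad + t, :], dw, db


class _Params(dict):
    """Named parameter arrays with elementwise helpers for Adam."""


def _init_params(cfg: ModelConfig, rng: np.random.Generator) -> _Params:
    def glorot(*shape):
        fan = shape[-2] * (shape[0] if len(shape) == 3 else 1) + shape[-1]
        return rng.normal(0.0, np.sqrt(2.0 / fan), size=shape)

    p = _Params()
    p["w_in"] = glorot(cfg.kernel, cfg.input_dim, cfg.conv_filters)
    p["b_in"] = np.zeros(cfg.conv_filters)
    for s in range(cfg.n_stacks):
        p[f"w_c{s}"] = glorot(cfg.dilated_kernel, cfg.conv_filters, cfg.conv_filters)
        p[f"b_c{s}"] = np.zeros(cfg.conv_filters)
    p["w_d1"] = glorot(cfg.conv_filters, cfg.dense_units)
    p["b_d1"] = np.zeros(cfg.dense_units)
    p["w_d2"] = glorot(cfg.dense_units, 1)
    p["b_d2"] = np.zeros(1)
    return p


def _forward(
    params: _Params,
    cfg: ModelConfig,
    x: np.ndarray,
    mask: np.ndarray,
    training: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, dict]:
    m = mask[:, :, None]
    h = x * m
    if training and cfg.noise_std > 0:
        h = (h + rng.normal(0.0, cfg.noise_std, size=h.shape)) * m
    cache: dict = {"x0": h}
    z = _conv_forward(h, params["w_in"], params["b_in"], 1)
    a = np.maximum(z, 0.0) * m
    cache["z_in"], cache["a_in"] = z, a
    for s in range(cfg.n_stacks):
        z = _conv_forward(a, params[f"w_c{s}"], params[f"b_c{s}"], cfg.dilation)
        a_new = np.maximum(z, 0.0) * m
        if training and cfg.dropout > 0:
            keep = rng.random(a_new.shape) >= cfg.dropout
            a_new = a_new * keep / (1.0 - cfg.dropout)
            cache[f"drop{s}"] = keep
        cache[f"z_c{s}"], cache[f"in_c{s}"], cache[f"a_c{s}"] = z, a, a_new
        a = a_new
    z1 = a @ params["w_d1"] + params["b_d1"]
    a1 = np.maximum(z1, 0.0)
    logits = (a1 @ params["w_d2"] + params["b_d2"])[..., 0]
    probs = 1.0 / (1.0 + np.exp(-np.clip(logits, -50, 50)))
    cache.update(a_last=a, z1=z1, a1=a1, mask=m)
    return probs, cache


def _backward(
    params: _Params,
    cfg: ModelConfig,
    cache: dict,
    probs: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray,
) -> _Params:
    wsum = weights.sum()
    dlogit = (probs - labels) * weights / wsum  # (B,T)
    grads = _Params()
    m = cache["mask"]
    dl = dlogit[:, :, None]
    grads["w_d2"] = np.einsum("btu,bto->uo", cache["a1"], dl)
    grads["b_d2"] = dl.sum(axis=(0, 1))
    da1 = dl @ params["w_d2"].T
    dz1 = da1 * (cache["z1"] > 0)
    grads["w_d1"] = np.einsum("btf,btu->fu", cache["a_last"], dz1)
    grads["b_d1"] = dz1.sum(axis=(0, 1))
    da = dz1 @ params["w_d1"].T
    for s in reversed(range(cfg.n_stacks)):
        if f"drop{s}" in cache:
            da = da * cache[f"drop{s}"] / (1.0 - cfg.dropout)
        dz = da * (cache[f"z_c{s}"] > 0) * m
        dx, dw, db = _conv_backward(cache[f"in_c{s}"], params[f"w_c{s}"], cfg.dilation, dz)
        grads[f"w_c{s}"], grads[f"b_c{s}"] = dw, db
        da = dx
    dz = da * (cache["z_in"] > 0) * m
    _, dw, db = _conv_backward(cache["x0"], params["w_in"], 1, dz)
    grads["w_in"], grads["b_in"] = dw, db
    return grads


def masked_bce(probs: np.ndarray, labels: np.ndarray, weights: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(probs, eps, 1.0 - eps)
    ll = -(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p))
    return float(np.sum(ll * weights) / np.sum(weights))


def pad_batch(
    features: Sequence[np.ndarray],
    labels: Optional[Sequence[np.ndarray]] = None,
    weights: Optional[Sequence[np.ndarray]] = None,
    pad_to: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Zero-pad per-recording sequences to a common length.

    Returns (x, mask, y, w); the mask marks real epochs, and padded positions
    always carry weight 0.
    """
    lengths = [f.shape[0] for f in features]
    t = pad_to if pad_to is not None else max(lengths)
    if max(lengths) > t:
        raise ValueError("a recording exceeds the padded length")
    b = len(features)
    dim = features[0].shape[1]
    x = np.zeros((b, t, dim))
    mask = np.zeros((b, t))
    y = np.zeros((b, t))
    w = np.zeros((b, t))
    for i, f in enumerate(features):
        n = f.shape[0]
        x[i, :n] = f
        mask[i, :n] = 1.0
        if labels is not None:
            y[i, :n] = labels[i]
        if weights is not None:
            w[i, :n] = weights[i]
    return x, mask, y, w


@dataclass
class TrainedModel:
    params: _Params
    config: ModelConfig
    history: list = field(default_factory=list)
    threshold: float = DEFAULT_THRESHOLD


def build_model(config: ModelConfig) -> TrainedModel:
    """An untrained model with freshly initialised parameters."""
    rng = np.random.default_rng(config.seed)
    return TrainedModel(params=_init_params(config, rng), config=config)


def train(
    model: TrainedModel,
    features: Sequence[np.ndarray],
    labels: Sequence[np.ndarray],
    weights: Sequence[np.ndarray],
    val_features: Optional[Sequence[np.ndarray]] = None,
    val_labels: Optional[Sequence[np.ndarray]] = None,
    val_weights: Optional[Sequence[np.ndarray]] = None,
) -> TrainedModel:
    """Fit with Adam on the masked weighted binary cross-entropy.

    Early stopping monitors the validation loss (when a validation split is
    given) with the configured patience; the best-scoring parameters are
    restored.  All randomness (noise, dropout) derives from the config seed,
    so two runs with the same seed give identical loss trajectories.
    """
    cfg = model.config
    x, mask, y, w = pad_batch(features, labels, weights)
    if w.sum() == 0:
        raise ValueError("no supervised epochs: all loss weights are zero")
    if not np.any((y > 0) & (w > 0)):
        raise ValueError("no positive epochs in the training set")
    has_val = val_features is not None
    if has_val:
        xv, maskv, yv, wv = pad_batch(val_features, val_labels, val_weights)

    rng = np.random.default_rng(cfg.seed)
    params = _Params({k: v.copy() for k, v in model.params.items()})
    mom = {k: np.zeros_like(v) for k, v in params.items()}
    vel = {k: np.zeros_like(v) for k, v in params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    best_loss, best_params, since_best = np.inf, None, 0
    history = []
    for it in range(1, cfg.max_iter + 1):
        probs, cache = _forward(params, cfg, x, mask, training=True, rng=rng)
        loss = masked_bce(probs, y, w)
        grads = _backward(params, cfg, cache, probs, y, w)
        for k in params:
            mom[k] = b1 * mom[k] + (1 - b1) * grads[k]
            vel[k] = b2 * vel[k] + (1 - b2) * grads[k] ** 2
            mhat = mom[k] / (1 - b1**it)
            vhat = vel[k] / (1 - b2**it)
            params[k] = params[k] - cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        rec = {"iteration": it, "train_loss": loss}
        if has_val:
            pv, _ = _forward(params, cfg, xv, maskv, training=False)
            vloss = masked_bce(pv, yv, wv) if wv.sum() > 0 else np.nan
            rec["val_loss"] = vloss
            monitor = vloss
        else:
            monitor = loss
        history.append(rec)
        if monitor < best_loss - 1e-6:
            best_loss = monitor
            best_params = _Params({k: v.copy() for k, v in params.items()})
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    final = best_params if best_params is not None else params
    return TrainedModel(params=final, config=cfg, history=history, threshold=model.threshold)


def predict_probabilities(
    model: TrainedModel,
    features: Sequence[np.ndarray],
    pad_to: Optional[int] = None,
) -> list[np.ndarray]:
    """Per-epoch probabilities for each recording, aligned with its epoch grid.

    Zero-weight epochs still receive a probability (their exclusion happens in
    the AHI stage, not here).
    """
    for f in features:
        if f.shape[1] != model.config.input_dim:
            raise ValueError(
                f"feature dimension {f.shape[1]} != model input_dim {model.config.input_dim}"
            )
    x, mask, _, _ = pad_batch(features, pad_to=pad_to)
    probs, _ = _forward(model.params, model.config, x, mask, training=False)
    return [probs[i, : f.shape[0]] for i, f in enumerate(features)]


def _severity_class(ahi: np.ndarray) -> np.ndarray:
    return np.digitize(ahi, SEVERITY_EDGES)


def select_threshold(
    probabilities: Sequence[np.ndarray],
    reference_ahis: Sequence[float],
    sleep_masks: Sequence[np.ndarray],
    weights: Sequence[np.ndarray],
    tst_minutes: Sequence[float],
    coefficient: float = 1.0,
    mode: str = "severity_kappa",
    labels: Optional[Sequence[np.ndarray]] = None,
) -> float:
    """Probability threshold from a 0.01-step grid search on training nights.

    ``severity_kappa`` (default) maximises the linearly weighted kappa between
    reference and estimated OSA severity; ``f1`` maximises the mean
    per-recording F1 of epoch detection (requires ``labels``).  Ties go to
    the lowest threshold; a degenerate sweep returns 0.5 with a warning.
    """
    if mode not in ("severity_kappa", "f1"):
        raise ValueError("mode must be 'severity_kappa' or 'f1'")
    if mode == "f1" and labels is None:
        raise ValueError("f1 mode requires per-epoch labels")
    if len(probabilities) == 1:
        warnings.warn("threshold selected from a single recording", stacklevel=2)
    ref = np.asarray(reference_ahis, dtype=float)
    ref_sev = _severity_class(ref)
    best_thr, best_score = DEFAULT_THRESHOLD, -np.inf
    degenerate = all(np.ptp(p) < 1e-12 for p in probabilities)
    if degenerate:
        warnings.warn("probabilities are constant; returning default threshold", stacklevel=2)
        return DEFAULT_THRESHOLD
    for thr in THRESHOLD_GRID:
        if mode == "severity_kappa":
            est = []
            for p, sm, w, tst in zip(probabilities, sleep_masks, weights, tst_minutes):
                pos = int(np.sum((p >= thr) & (sm > 0) & (w > 0)))
                est.append(coefficient * pos / (tst / 60.0))
            est_sev = _severity_class(np.asarray(est))
            if np.ptp(est_sev) == 0 and np.ptp(ref_sev) == 0:
                score = 1.0 if est_sev[0] == ref_sev[0] else 0.0
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    score = cohen_kappa_score(
                        ref_sev, est_sev, weights="linear", labels=[0, 1, 2, 3]
                    )
                if np.isnan(score):
                    score = 0.0
        else:
            scores = []
            for p, y, sm, w in zip(probabilities, labels, sleep_masks, weights):
                sel = (sm > 0) & (w > 0)
                if not np.any(sel):
                    continue
                yy = y[sel].astype(int)
                pp = (p[sel] >= thr).astype(int)
                scores.append(f1_score(yy, pp, zero_division=0))
            score = float(np.mean(scores)) if scores else 0.0
        if score > best_score + 1e-12:
            best_score = score
            best_thr = float(thr)
    return best_thr


def save_checkpoint(path: str, model: TrainedModel) -> None:
    """Save parameters + config (embedded as JSON) to a .npz checkpoint."""
    meta = json.dumps({"config": asdict(model.config), "threshold": model.threshold,
                       "history": model.history})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.params)


def load_checkpoint(path: str) -> TrainedModel:
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    params = _Params({k: data[k] for k in data.files if k != "__meta__"})
    return TrainedModel(
        params=params,
        config=ModelConfig(**meta["config"]),
        history=meta["history"],
        threshold=meta["threshold"],
    )
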