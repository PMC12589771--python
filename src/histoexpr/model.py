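"""The dual-loss weighted regressor mapping the fused histology feature
z to nucleus-level expression over the gene panel.

Sparse nuclear counts are dominated by zeros, so a plain squared-error
regressor cannot separate "lowly expressed" from "silent". The model
therefore optimizes two objectives through one shared d-gene linear output:
the raw output is the regression prediction of log-normalized expression,
and the same output passed through a sigmoid is the probability that the
gene is expressed at all. Per-gene class weights up-weight the rare
expressed entries:

    w_i = w_pos if y_i > 0 else w_neg          (w_pos > w_neg)
    L_reg = mean_batch sum_i w_i (yhat_i - y_i)^2
    L_bin = mean_batch mean_i w_i BCE(sigmoid(out_i), [y_i > 0])
    Loss  = lambda_reg * L_reg + lambda_bin * L_bin

Defaults: w_neg=1, w_pos=5, lambda_reg=1, lambda_bin=20; four hidden layers
of 512/512/1024/1024 units, each linear -> leaky-ReLU -> batch-norm ->
dropout(0.1); AdamW (lr 0.01, weight decay 0.05), batch size 256, up to 100
epochs with early stopping after 10 non-improving validation epochs.

The network, its backward pass and AdamW are implemented directly on numpy
arrays; the model is small (~4M parameters at the reference shape) and
trains comfortably on a single CPU core.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from .expression import ExpressionPanel

_BN_EPS = 1e-5
_ADAM_B1, _ADAM_B2, _ADAM_EPS = 0.9, 0.999, 1e-8


@dataclass
class ModelConfig:
    hidden_sizes: tuple[int, ...] = (512, 512, 1024, 1024)
    dropout: float = 0.1
    leaky_slope: float = 0.01
    batch_norm: bool = True
    w_pos: float = 5.0
    w_neg: float = 1.0
    lambda_reg: float = 1.0
    lambda_bin: float = 20.0
    lr: float = 0.01
    weight_decay: float = 0.05
    batch_size: int = 256
    max_epochs: int = 100
    early_stop_patience: int = 10
    val_fraction: float = 0.1
    two_head: bool = False  # separate classification head (variant; default shared)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.w_pos > self.w_neg > 0):
            raise ValueError("need w_pos > w_neg > 0")
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must be in (0, 1)")
        if min(self.lr, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("rates and sizes must be positive")


class DualLossMLP:
    """Feed-forward network with hand-written forward/backward passes.

    Parameters live in ``self.params`` (dict name -> array); batch-norm
    running statistics in ``self.state``. Hidden block k owns ``Wk``/``bk``
    (linear), ``gk``/``betak`` (batch-norm scale/shift); the output layer is
    ``Wout``/``bout`` (plus ``Wbin``/``bbin`` when a separate classification
    head is configured).
    """

    def __init__(self, cfg: ModelConfig, input_dim: int, d_genes: int):
        if input_dim < 1 or d_genes < 1:
            raise ValueError("input_dim and d_genes must be >= 1")
        self.cfg = cfg
        self.input_dim = input_dim
        self.d_genes = d_genes
        rng = np.random.default_rng(cfg.seed)
        self.params: dict[str, np.ndarray] = {}
        self.state: dict[str, np.ndarray] = {}
        fan_in = input_dim
        for k, width in enumerate(cfg.hidden_sizes):
            bound = 1.0 / np.sqrt(fan_in)
            self.params[f"W{k}"] = rng.uniform(-bound, bound, (fan_in, width))
            self.params[f"b{k}"] = rng.uniform(-bound, bound, width)
            if cfg.batch_norm:
                self.params[f"g{k}"] = np.ones(width)
                self.params[f"beta{k}"] = np.zeros(width)
                self.state[f"rm{k}"] = np.zeros(width)
                self.state[f"rv{k}"] = np.ones(width)
                self.state[f"nt{k}"] = np.zeros(1)  # batches tracked
            fan_in = width
        bound = 1.0 / np.sqrt(fan_in)
        self.params["Wout"] = rng.uniform(-bound, bound, (fan_in, d_genes))
        self.params["bout"] = rng.uniform(-bound, bound, d_genes)
        if cfg.two_head:
            self.params["Wbin"] = rng.uniform(-bound, bound, (fan_in, d_genes))
            self.params["bbin"] = rng.uniform(-bound, bound, d_genes)

    # ---- forward / backward -------------------------------------------------

    def forward(self, X: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None):
        """Returns ``(out, logits, cache)``; ``out`` is the regression output,
        ``logits`` the classification pre-sigmoid (identical to ``out`` for
        the shared head)."""
        cfg = self.cfg
        cache = {"X": X, "layers": []}
        h = X
        for k in range(len(cfg.hidden_sizes)):
            lc: dict = {}
            lc["x_in"] = h
            pre = h @ self.params[f"W{k}"] + self.params[f"b{k}"]
            lc["pre"] = pre
            act = np.where(pre > 0, pre, cfg.leaky_slope * pre)
            if cfg.batch_norm:
                if training:
                    mu = act.mean(axis=0)
                    var = act.var(axis=0)
                    # cumulative moving average over batches: stable running
                    # statistics even when an epoch holds only a few batches
                    self.state[f"nt{k}"] += 1
                    m = 1.0 / float(self.state[f"nt{k}"][0])
                    n = max(act.shape[0], 2)
                    self.state[f"rm{k}"] = (1 - m) * self.state[f"rm{k}"] + m * mu
                    self.state[f"rv{k}"] = ((1 - m) * self.state[f"rv{k}"]
                                            + m * var * n / (n - 1))
                else:
                    mu = self.state[f"rm{k}"]
                    var = self.state[f"rv{k}"]
                inv = 1.0 / np.sqrt(var + _BN_EPS)
                xhat = (act - mu) * inv
                lc["xhat"], lc["inv"] = xhat, inv
                h = self.params[f"g{k}"] * xhat + self.params[f"beta{k}"]
            else:
                h = act
            if training and cfg.dropout > 0:
                mask = (rng.random(h.shape) >= cfg.dropout) / (1 - cfg.dropout)
                lc["drop"] = mask
                h = h * mask
            cache["layers"].append(lc)
        cache["h_last"] = h
        out = h @ self.params["Wout"] + self.params["bout"]
        if cfg.two_head:
            logits = h @ self.params["Wbin"] + self.params["bbin"]
        else:
            logits = out
        return out, logits, cache

    def backward(self, cache, g_out: np.ndarray,
                 g_logits: np.ndarray | None) -> dict[str, np.ndarray]:
        """Gradients of the scalar loss w.r.t. every parameter, given
        d(loss)/d(out) and, for a two-head model, d(loss)/d(logits)."""
        cfg = self.cfg
        grads: dict[str, np.ndarray] = {}
        h = cache["h_last"]
        if cfg.two_head:
            grads["Wout"] = h.T @ g_out
            grads["bout"] = g_out.sum(axis=0)
            grads["Wbin"] = h.T @ g_logits
            grads["bbin"] = g_logits.sum(axis=0)
            g = g_out @ self.params["Wout"].T + g_logits @ self.params["Wbin"].T
        else:
            g_head = g_out if g_logits is None else g_out + g_logits
            grads["Wout"] = h.T @ g_head
            grads["bout"] = g_head.sum(axis=0)
            g = g_head @ self.params["Wout"].T
        for k in reversed(range(len(cfg.hidden_sizes))):
            lc = cache["layers"][k]
            if "drop" in lc:
                g = g * lc["drop"]
            if cfg.batch_norm:
                xhat, inv = lc["xhat"], lc["inv"]
                grads[f"g{k}"] = (g * xhat).sum(axis=0)
                grads[f"beta{k}"] = g.sum(axis=0)
                B = g.shape[0]
                gx = self.params[f"g{k}"] * inv * (
                    g - g.mean(axis=0) - xhat * (g * xhat).mean(axis=0)) \
                    if B > 1 else self.params[f"g{k}"] * inv * g
                g = gx
            g = g * np.where(lc["pre"] > 0, 1.0, cfg.leaky_slope)
            grads[f"W{k}"] = lc["x_in"].T @ g
            grads[f"b{k}"] = g.sum(axis=0)
            g = g @ self.params[f"W{k}"].T
        return grads

    def snapshot(self):
        return ({k: v.copy() for k, v in self.params.items()},
                {k: v.copy() for k, v in self.state.items()})

    def restore(self, snap) -> None:
        params, state = snap
        self.params = {k: v.copy() for k, v in params.items()}
        self.state = {k: v.copy() for k, v in state.items()}


def build_network(cfg: ModelConfig, input_dim: int, d_genes: int) -> DualLossMLP:
    """Construct the network with seeded uniform fan-in initialization."""
    return DualLossMLP(cfg, input_dim, d_genes)


def parameter_count(model) -> int:
    """Total trainable parameters: linear weights and biases plus batch-norm
    scale/shift (running statistics are buffers, not parameters)."""
    net = model.network if isinstance(model, TrainedModel) else model
    return int(sum(v.size for v in net.params.values()))


# ---- losses -----------------------------------------------------------------

def regression_weights(y: np.ndarray, w_pos: float = 5.0,
                       w_neg: float = 1.0) -> np.ndarray:
    """Per-entry class weight: ``w_pos`` where the gene is expressed
    (y > 0), ``w_neg`` where silent."""
    y = np.asarray(y)
    if y.size and y.min() < 0:
        raise ValueError("expression labels must be non-negative")
    return np.where(y > 0, float(w_pos), float(w_neg))


def loss_regression(y_hat: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted squared error summed over genes, averaged over the batch."""
    y_hat, y, w = np.atleast_2d(y_hat), np.atleast_2d(y), np.atleast_2d(w)
    if y_hat.shape != y.shape or y.shape != w.shape:
        raise ValueError("y_hat, y and w must have matching shapes")
    return float((w * (y_hat - y) ** 2).sum(axis=1).mean())


def loss_binary(logits: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    """Weighted binary cross-entropy on the expressed/silent labels, mean
    over genes then over the batch; numerically stable in the logits."""
    logits, w = np.atleast_2d(logits), np.atleast_2d(w)
    b = np.atleast_2d(b).astype(float)
    bce = np.maximum(logits, 0) - logits * b + np.log1p(np.exp(-np.abs(logits)))
    return float((w * bce).mean(axis=1).mean())


def loss_total(y_hat: np.ndarray, y: np.ndarray, b: np.ndarray,
               cfg: ModelConfig, logits: np.ndarray | None = None) -> float:
    """lambda_reg * L_reg + lambda_bin * L_bin (shared-head logits default
    to the regression output)."""
    w = regression_weights(y, cfg.w_pos, cfg.w_neg)
    if logits is None:
        logits = y_hat
    return (cfg.lambda_reg * loss_regression(y_hat, y, w)
            + cfg.lambda_bin * loss_binary(logits, b, w))


def _loss_and_grads(out, logits, y, b, w, cfg):
    B, d = y.shape
    l_reg = float((w * (out - y) ** 2).sum(axis=1).mean())
    bce = np.maximum(logits, 0) - logits * b + np.log1p(np.exp(-np.abs(logits)))
    l_bin = float((w * bce).mean(axis=1).mean())
    g_out = cfg.lambda_reg * (2.0 / B) * w * (out - y)
    sig = 1.0 / (1.0 + np.exp(-logits))
    g_logits = cfg.lambda_bin * w * (sig - b) / (B * d)
    return cfg.lambda_reg * l_reg + cfg.lambda_bin * l_bin, g_out, g_logits


class _AdamW:
    """Decoupled-weight-decay Adam applied uniformly to every parameter."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, wd: float):
        self.lr, self.wd = lr, wd
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        bc1 = 1 - _ADAM_B1 ** self.t
        bc2 = 1 - _ADAM_B2 ** self.t
        for k, g in grads.items():
            self.m[k] = _ADAM_B1 * self.m[k] + (1 - _ADAM_B1) * g
            self.v[k] = _ADAM_B2 * self.v[k] + (1 - _ADAM_B2) * g * g
            params[k] -= self.lr * self.wd * params[k]
            params[k] -= self.lr * (self.m[k] / bc1) / (
                np.sqrt(self.v[k] / bc2) + _ADAM_EPS)


@dataclass
class TrainedModel:
    network: DualLossMLP
    input_dim: int
    config: ModelConfig
    panel: ExpressionPanel | None = None
    norm_meta: dict = field(default_factory=dict)
    log: pd.DataFrame | None = None
    best_epoch: int = -1
    best_val_loss: float = float("nan")


def fit(features: np.ndarray, y: np.ndarray, b: np.ndarray | None,
        cfg: ModelConfig, panel: ExpressionPanel | None = None,
        norm_meta: dict | None = None) -> TrainedModel:
    """Train the regressor with AdamW, a seeded validation split and early
    stopping on the validation loss; returns the best-validation weights.

    ``features`` is cells x input_dim, ``y`` the normalized cells x genes
    labels, ``b`` the expressed/silent labels (``y > 0`` when omitted).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features and labels must be 2-d with matching rows")
    b = (y > 0).astype(float) if b is None else np.asarray(b, dtype=float)
    n, d = y.shape
    rng = np.random.default_rng(cfg.seed)
    net = build_network(cfg, X.shape[1], d)
    opt = _AdamW(net.params, cfg.lr, cfg.weight_decay)
    w_all = regression_weights(y, cfg.w_pos, cfg.w_neg)

    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    batch = cfg.batch_size
    if train_idx.size < 2 * batch:
        warnings.warn(
            f"{train_idx.size} training cells < 2 batches of {batch}; "
            "training full-batch", stacklevel=2)
        batch = max(1, train_idx.size)

    def eval_loss(idx) -> float:
        out, logits, _ = net.forward(X[idx], training=False)
        loss, _, _ = _loss_and_grads(out, logits, y[idx], b[idx], w_all[idx], cfg)
        return loss

    best = (np.inf, net.snapshot(), 0)
    log_rows = []
    stale = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(train_idx)
        train_losses = []
        for start in range(0, order.size, batch):
            sel = order[start:start + batch]
            out, logits, cache = net.forward(X[sel], training=True, rng=rng)
            loss, g_out, g_logits = _loss_and_grads(
                out, logits, y[sel], b[sel], w_all[sel], cfg)
            grads = net.backward(
                cache, g_out, g_logits if cfg.two_head else None) \
                if cfg.two_head else net.backward(cache, g_out + g_logits, None)
            opt.step(net.params, grads)
            train_losses.append(loss)
        val_loss = eval_loss(val_idx)
        log_rows.append({"epoch": epoch, "train_loss": float(np.mean(train_losses)),
                         "val_loss": val_loss})
        if val_loss < best[0]:
            best = (val_loss, net.snapshot(), epoch)
            stale = 0
        else:
            stale += 1
            if stale >= cfg.early_stop_patience:
                break
    net.restore(best[1])
    return TrainedModel(network=net, input_dim=X.shape[1], config=cfg,
                        panel=panel, norm_meta=dict(norm_meta or {}),
                        log=pd.DataFrame(log_rows),
                        best_epoch=best[2], best_val_loss=best[0])


def predict_cells(model: TrainedModel, features: np.ndarray,
                  batch: int = 4096):
    """Inference pass: dropout off, batch-norm running statistics.

    Returns ``(y_hat, p_expressed)`` -- the regression output clipped below
    at zero, and the sigmoid expression probability.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.input_dim:
        raise ValueError(
            f"features must be 2-d with {model.input_dim} columns, "
            f"got shape {X.shape}")
    outs, ps = [], []
    for start in range(0, X.shape[0], batch):
        out, logits, _ = model.network.forward(X[start:start + batch],
                                               training=False)
        outs.append(np.maximum(out, 0.0))
        ps.append(1.0 / (1.0 + np.exp(-logits)))
    return np.vstack(outs), np.vstack(ps)


def export_h5ad(y_hat: np.ndarray, p_expressed: np.ndarray,
                coords: np.ndarray, panel: ExpressionPanel, path,
                gate: bool = False, metadata: dict | None = None) -> Path:
    """Write predictions as an h5ad cell x gene matrix.

    X holds denormalized expression ``expm1(y_hat)`` (inverse of the log1p
    label transform; no per-cell library rescaling since predicted cells
    carry no observed library size), optionally zeroed where
    ``p_expressed < 0.5`` when ``gate`` is set. The normalized predictions
    and the expression probabilities are kept as layers; cell coordinates go
    to ``obs``.
    """
    y_hat = np.asarray(y_hat, dtype=float)
    p = np.asarray(p_expressed, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if y_hat.shape != p.shape or y_hat.shape[1] != len(panel.genes):
        raise ValueError("prediction shapes do not match the panel")
    denorm = np.expm1(y_hat)
    if gate:
        denorm = np.where(p < 0.5, 0.0, denorm)
    adata = ad.AnnData(
        X=denorm,
        obs=pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1]},
                         index=[f"cell_{i:05d}" for i in range(y_hat.shape[0])]),
        var=pd.DataFrame(index=pd.Index(panel.genes, name="gene")),
        layers={"normalized": y_hat, "p_expressed": p},
    )
    adata.uns["normalization"] = {"target_sum": panel.target_sum,
                                  "log1p": panel.log1p, "gate": gate}
    if metadata:
        adata.uns["run"] = metadata
    path = Path(path)
    adata.write_h5ad(path)
    return path


# ---- checkpointing ----------------------------------------------------------

def save_model(model: TrainedModel, path) -> Path:
    """Single-file .npz checkpoint: weights, running stats, config, panel,
    normalization metadata and a content hash."""
    path = Path(path)
    meta = {
        "input_dim": model.input_dim,
        "d_genes": model.network.d_genes,
        "config": asdict(model.config),
        "norm_meta": model.norm_meta,
        "panel": None,
    }
    if model.panel is not None:
        meta["panel"] = {
            "genes": model.panel.genes,
            "stats": model.panel.stats.to_dict(orient="list"),
            "p_adj_max": model.panel.p_adj_max,
            "min_abs_log2fc": model.panel.min_abs_log2fc,
            "target_sum": model.panel.target_sum,
            "log1p": model.panel.log1p,
        }
    arrays = {f"param__{k}": v for k, v in model.network.params.items()}
    arrays.update({f"state__{k}": v for k, v in model.network.state.items()})
    buf = _io.BytesIO()
    np.savez(buf, **arrays)
    meta["content_hash"] = hashlib.sha256(buf.getvalue()).hexdigest()
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    if model.log is not None:
        arrays["log_csv"] = np.frombuffer(
            model.log.to_csv(index=False).encode(), dtype=np.uint8)
    np.savez(path, **arrays)
    return path


def load_model(path) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        cfg = ModelConfig(**{**meta["config"],
                             "hidden_sizes": tuple(meta["config"]["hidden_sizes"])})
        net = build_network(cfg, meta["input_dim"], meta["d_genes"])
        net.params = {k[len("param__"):]: data[k] for k in data.files
                      if k.startswith("param__")}
        net.state = {k[len("state__"):]: data[k] for k in data.files
                     if k.startswith("state__")}
        panel = None
        if meta["panel"] is not None:
            p = meta["panel"]
            panel = ExpressionPanel(
                genes=p["genes"], stats=pd.DataFrame(p["stats"]),
                p_adj_max=p["p_adj_max"], min_abs_log2fc=p["min_abs_log2fc"],
                target_sum=p["target_sum"], log1p=p["log1p"])
        log = None
        if "log_csv" in data.files:
            log = pd.read_csv(_io.BytesIO(bytes(data["log_csv"])))
    return TrainedModel(network=net, input_dim=meta["input_dim"], config=cfg,
                        panel=panel, norm_meta=meta["norm_meta"], log=log)
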