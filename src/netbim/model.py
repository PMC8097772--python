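"""Dual-input convolutional + attention network, in pure NumPy.

The predictor takes two inputs per HLA-peptide pair: the 9 x 21 BLOSUM50
peptide encoding and the 1 x 8 vector of scaled network centralities.  Each
input passes through its own 1-D convolution (ReLU, dropout), is flattened,
concatenated with ``n_copies`` identical copies of itself and sent through
two fully connected layers (64 then 4 units).  In parallel an attention
module scores the 9 peptide position vectors with a shared single-hidden-
layer network, softmaxes the scores and returns the weighted average of the
position vectors.  The two convolutional outputs and the attention context
are concatenated and a final dense layer with a sigmoid produces the scalar
prediction in [0, 1].

The same architecture serves two tasks: binding-affinity regression (MSE
loss, Adam) and immunogenicity classification (binary cross-entropy,
RMSprop).  Ablations: ``pep_only`` removes the metrics branch entirely;
``drop_metric:<name>`` removes one of the 8 centrality features.

Implemented directly on NumPy arrays with hand-derived backpropagation;
gradients are verified against finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Iterable

import numpy as np

FEATURE_NAMES = (
    "HLA_degree",
    "HLA_closeness",
    "HLA_betweenness",
    "HLA_eigenvector",
    "PEP_degree",
    "PEP_closeness",
    "PEP_betweenness",
    "PEP_eigenvector",
)


@dataclass
class ModelConfig:
    task: str = "binding"  # "binding" | "immunogenic"
    n_filters: int = 256
    stride: int = 1
    kernel_peptide: int = 3
    kernel_metrics: int = 3
    dropout: float = 0.7
    fc_dims: tuple[int, int] = (64, 4)
    n_copies: int = 4
    attention_hidden: int = 32
    batch_size: int = 256
    optimizer: str | None = None  # defaults by task
    loss: str | None = None  # defaults by task
    learning_rate: float = 1e-3
    epochs: int = 200
    patience: int = 10
    val_fraction: float = 0.1
    seed: int = 0
    ablation: str = "none"  # "none" | "pep_only" | "drop_metric:<name>"

    def __post_init__(self):
        if self.task not in ("binding", "immunogenic"):
            raise ValueError(f"unknown task {self.task!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.optimizer is None:
            self.optimizer = "adam" if self.task == "binding" else "rmsprop"
        if self.loss is None:
            self.loss = "mse" if self.task == "binding" else "bce"
        if self.optimizer not in ("adam", "rmsprop"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.loss not in ("mse", "bce"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.ablation not in ("none", "pep_only") and not self.ablation.startswith(
            "drop_metric:"
        ):
            raise ValueError(f"unknown ablation {self.ablation!r}")
        if self.ablation.startswith("drop_metric:"):
            name = self.ablation.split(":", 1)[1]
            if name not in FEATURE_NAMES:
                raise ValueError(f"unknown metric {name!r}")

    @property
    def pep_only(self) -> bool:
        return self.ablation == "pep_only"

    @property
    def dropped_metric(self) -> int | None:
        if self.ablation.startswith("drop_metric:"):
            return FEATURE_NAMES.index(self.ablation.split(":", 1)[1])
        return None

    @property
    def n_metric_features(self) -> int:
        if self.pep_only:
            return 0
        return 7 if self.dropped_metric is not None else 8


# ---------------------------------------------------------------------------
# layer primitives


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(B, L, C) -> (B, L_out, k*C) sliding windows."""
    b, length, c = x.shape
    l_out = (length - k) // stride + 1
    cols = np.empty((b, l_out, k * c), dtype=x.dtype)
    for t in range(l_out):
        cols[:, t, :] = x[:, t * stride : t * stride + k, :].reshape(b, k * c)
    return cols


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _ConvBranch:
    """conv1d -> ReLU -> dropout -> flatten -> tile -> FC(64) -> FC(4)."""

    def __init__(self, name, rng, in_len, in_ch, cfg: ModelConfig, kernel):
        self.name = name
        self.k = min(kernel, in_len)
        self.stride = cfg.stride
        self.l_out = (in_len - self.k) // self.stride + 1
        self.n_filters = cfg.n_filters
        self.dropout = cfg.dropout
        self.tile = 1 + cfg.n_copies
        flat = self.l_out * self.n_filters
        d1, d2 = cfg.fc_dims
        self.out_dim = d2
        self.params = {
            f"{name}_Wc": _glorot(rng, (self.k * in_ch, self.n_filters)),
            f"{name}_bc": np.zeros(self.n_filters),
            f"{name}_W1": _glorot(rng, (self.tile * flat, d1)),
            f"{name}_b1": np.zeros(d1),
            f"{name}_W2": _glorot(rng, (d1, d2)),
            f"{name}_b2": np.zeros(d2),
        }

    def forward(self, params, x, rng=None, train=False):
        n = self.name
        cache = {}
        cols = _im2col(x, self.k, self.stride)
        z = cols @ params[f"{n}_Wc"] + params[f"{n}_bc"]
        a = np.maximum(z, 0.0)
        if train and self.dropout > 0.0:
            keep = 1.0 - self.dropout
            mask = (rng.random(a.shape) < keep) / keep
        else:
            mask = 1.0
        d = a * mask
        b = x.shape[0]
        flat = d.reshape(b, -1)
        tiled = np.tile(flat, (1, self.tile))
        h1_pre = tiled @ params[f"{n}_W1"] + params[f"{n}_b1"]
        h1 = np.maximum(h1_pre, 0.0)
        h2_pre = h1 @ params[f"{n}_W2"] + params[f"{n}_b2"]
        h2 = np.maximum(h2_pre, 0.0)
        cache.update(cols=cols, z=z, mask=mask, flat=flat, tiled=tiled, h1=h1, h2=h2)
        return h2, cache

    def backward(self, params, cache, d_h2, grads):
        n = self.name
        b = cache["flat"].shape[0]
        dz2 = d_h2 * (cache["h2"] > 0)
        grads[f"{n}_W2"] = cache["h1"].T @ dz2
        grads[f"{n}_b2"] = dz2.sum(axis=0)
        dh1 = dz2 @ params[f"{n}_W2"].T
        dz1 = dh1 * (cache["h1"] > 0)
        grads[f"{n}_W1"] = cache["tiled"].T @ dz1
        grads[f"{n}_b1"] = dz1.sum(axis=0)
        dtiled = dz1 @ params[f"{n}_W1"].T
        dflat = dtiled.reshape(b, self.tile, -1).sum(axis=1)
        dd = dflat.reshape(b, self.l_out, self.n_filters)
        da = dd * cache["mask"]
        dz = da * (cache["z"] > 0)
        kc = cache["cols"].shape[-1]
        grads[f"{n}_Wc"] = cache["cols"].reshape(-1, kc).T @ dz.reshape(-1, self.n_filters)
        grads[f"{n}_bc"] = dz.sum(axis=(0, 1))


class _AttentionBranch:
    """Shared single-hidden-layer scorer over the 9 position vectors."""

    def __init__(self, rng, n_pos, in_ch, hidden):
        self.out_dim = in_ch
        self.params = {
            "att_Wa": _glorot(rng, (in_ch, hidden)),
            "att_ba": np.zeros(hidden),
            "att_va": _glorot(rng, (hidden, 1))[:, 0],
            "att_ca": np.zeros(1),
        }

    def forward(self, params, x):
        pre = x @ params["att_Wa"] + params["att_ba"]  # (B, T, H)
        u = np.tanh(pre)
        e = u @ params["att_va"] + params["att_ca"][0]  # (B, T)
        e = e - e.max(axis=1, keepdims=True)
        ex = np.exp(e)
        alpha = ex / ex.sum(axis=1, keepdims=True)
        ctx = np.einsum("bt,btc->bc", alpha, x)
        return ctx, {"x": x, "u": u, "alpha": alpha}

    def backward(self, params, cache, d_ctx, grads):
        x, u, alpha = cache["x"], cache["u"], cache["alpha"]
        d_alpha = np.einsum("bc,btc->bt", d_ctx, x)
        de = alpha * (d_alpha - (alpha * d_alpha).sum(axis=1, keepdims=True))
        grads["att_va"] = np.einsum("bth,bt->h", u, de)
        grads["att_ca"] = np.array([de.sum()])
        du = de[..., None] * params["att_va"]
        dpre = du * (1.0 - u**2)
        grads["att_Wa"] = np.einsum("btc,bth->ch", x, dpre)
        grads["att_ba"] = dpre.sum(axis=(0, 1))


# ---------------------------------------------------------------------------
# the model


class NetBimModel:
    """The dual-input CNN + attention predictor (see module docstring)."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.pep_branch = _ConvBranch("pep", rng, 9, 21, cfg, cfg.kernel_peptide)
        self.branches = [self.pep_branch]
        self.attention = _AttentionBranch(rng, 9, 21, cfg.attention_hidden)
        self.met_branch = None
        if not cfg.pep_only:
            self.met_branch = _ConvBranch(
                "met", rng, cfg.n_metric_features, 1, cfg, cfg.kernel_metrics
            )
            self.branches.append(self.met_branch)
        concat_dim = sum(b.out_dim for b in self.branches) + self.attention.out_dim
        self.params: dict[str, np.ndarray] = {}
        for b in self.branches:
            self.params.update(b.params)
        self.params.update(self.attention.params)
        self.params["head_W"] = _glorot(rng, (concat_dim, 1))
        self.params["head_b"] = np.zeros(1)
        self.history: list[dict] = []
        self.preprocessing: dict = {}

    # -- input handling ----------------------------------------------------

    def _metrics_input(self, x_net: np.ndarray | None) -> np.ndarray | None:
        if self.cfg.pep_only:
            return None
        if x_net is None:
            raise ValueError("this model requires the 8 network metric features")
        x = np.asarray(x_net, dtype=float)
        if x.ndim != 2:
            raise ValueError("metric features must be (n, 8)")
        if x.shape[1] == 8 and self.cfg.dropped_metric is not None:
            x = np.delete(x, self.cfg.dropped_metric, axis=1)
        if x.shape[1] != self.cfg.n_metric_features:
            raise ValueError(
                f"expected {self.cfg.n_metric_features} metric features, got {x.shape[1]}"
            )
        return x[:, :, None]  # (B, M, 1) sequence for the 1-D conv

    # -- forward / backward ------------------------------------------------

    def _forward(self, x_pep, x_met, rng=None, train=False):
        caches = {}
        parts = []
        out, caches["pep"] = self.pep_branch.forward(
            self.params, x_pep, rng=rng, train=train
        )
        parts.append(out)
        if self.met_branch is not None:
            out, caches["met"] = self.met_branch.forward(
                self.params, x_met, rng=rng, train=train
            )
            parts.append(out)
        ctx, caches["att"] = self.attention.forward(self.params, x_pep)
        parts.append(ctx)
        concat = np.concatenate(parts, axis=1)
        z = concat @ self.params["head_W"][:, 0] + self.params["head_b"][0]
        p = _sigmoid(z)
        caches["concat"] = concat
        caches["p"] = p
        return p, caches

    def _backward(self, caches, dz):
        grads = {}
        concat = caches["concat"]
        grads["head_W"] = (concat.T @ dz)[:, None]
        grads["head_b"] = np.array([dz.sum()])
        dconcat = dz[:, None] * self.params["head_W"][:, 0][None, :]
        i = 0
        seg = {}
        for b in self.branches:
            seg[b.name] = dconcat[:, i : i + b.out_dim]
            i += b.out_dim
        d_ctx = dconcat[:, i:]
        self.pep_branch.backward(self.params, caches["pep"], seg["pep"], grads)
        if self.met_branch is not None:
            self.met_branch.backward(self.params, caches["met"], seg["met"], grads)
        self.attention.backward(self.params, caches["att"], d_ctx, grads)
        return grads

    def _loss_and_dz(self, p, y):
        n = len(y)
        if self.cfg.loss == "mse":
            loss = float(np.mean((p - y) ** 2))
            dz = 2.0 * (p - y) * p * (1.0 - p) / n
        else:
            pc = np.clip(p, 1e-12, 1.0 - 1e-12)
            loss = float(-np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc)))
            dz = (p - y) / n
        return loss, dz

    def loss_on(self, x_pep, x_net, y) -> float:
        p, _ = self._forward(np.asarray(x_pep, float), self._metrics_input(x_net))
        return self._loss_and_dz(p, np.asarray(y, float))[0]

    def predict(self, x_pep, x_net=None, batch_size: int = 4096) -> np.ndarray:
        """Deterministic scores in [0, 1] (dropout off)."""
        x_pep = np.asarray(x_pep, dtype=float)
        x_met = self._metrics_input(x_net)
        out = np.empty(len(x_pep))
        for i in range(0, len(x_pep), batch_size):
            sl = slice(i, i + batch_size)
            m = None if x_met is None else x_met[sl]
            out[sl], _ = self._forward(x_pep[sl], m)
        return out

    def predict_category(self, x_pep, x_net=None, threshold: float = 0.5) -> np.ndarray:
        """Binary immunogenic call: 1{score >= threshold}."""
        return (self.predict(x_pep, x_net) >= threshold).astype(int)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "config": asdict(self.cfg),
            "history": self.history,
            "preprocessing": self.preprocessing,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path) -> "NetBimModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg_d = meta["config"]
            cfg_d["fc_dims"] = tuple(cfg_d["fc_dims"])
            model = cls(ModelConfig(**cfg_d))
            for k in model.params:
                model.params[k] = data[k]
            model.history = meta["history"]
            model.preprocessing = meta["preprocessing"]
        return model


def build_model(cfg: ModelConfig) -> NetBimModel:
    """Instantiate an untrained model with seeded weight initialisation."""
    return NetBimModel(cfg)


# ---------------------------------------------------------------------------
# optimisers


class _Adam:
    def __init__(self, params, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _RMSprop:
    def __init__(self, params, lr, rho=0.9, eps=1e-8):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads):
        for k, g in grads.items():
            self.v[k] = self.rho * self.v[k] + (1 - self.rho) * g * g
            params[k] -= self.lr * g / (np.sqrt(self.v[k]) + self.eps)


# ---------------------------------------------------------------------------
# training


def train(
    model: NetBimModel,
    x_pep: np.ndarray,
    x_net: np.ndarray | None,
    y: np.ndarray,
    x_val: tuple | None = None,
) -> NetBimModel:
    """Train in place with minibatch SGD, early stopping on validation loss.

    If ``x_val`` (x_pep, x_net, y) is not given, a seeded ``val_fraction``
    split is carved off the training data.  Fully reproducible given the
    config seed.  Raises on NaN loss.
    """
    cfg = model.cfg
    rng = np.random.default_rng(cfg.seed + 1)
    x_pep = np.asarray(x_pep, dtype=float)
    y = np.asarray(y, dtype=float)
    x_met = model._metrics_input(x_net)

    n = len(y)
    if x_val is None:
        n_val = max(1, int(round(cfg.val_fraction * n))) if n >= 5 else 0
        order = rng.permutation(n)
        val_idx, tr_idx = order[:n_val], order[n_val:]
    else:
        tr_idx, val_idx = np.arange(n), np.array([], dtype=int)

    def subset(idx):
        return (
            x_pep[idx],
            None if x_met is None else x_met[idx],
            y[idx],
        )

    xp_tr, xm_tr, y_tr = subset(tr_idx)
    if x_val is not None:
        xp_va = np.asarray(x_val[0], dtype=float)
        xm_va = model._metrics_input(x_val[1])
        y_va = np.asarray(x_val[2], dtype=float)
    elif len(val_idx):
        xp_va, xm_va, y_va = subset(val_idx)
    else:
        xp_va = None

    opt_cls = _Adam if cfg.optimizer == "adam" else _RMSprop
    opt = opt_cls(model.params, cfg.learning_rate)

    best_loss = np.inf
    best_params = None
    stale = 0
    model.history = []
    n_tr = len(y_tr)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n_tr)
        epoch_loss = 0.0
        for i in range(0, n_tr, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb = xp_tr[idx]
            mb = None if xm_tr is None else xm_tr[idx]
            p, caches = model._forward(xb, mb, rng=rng, train=True)
            loss, dz = model._loss_and_dz(p, y_tr[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={cfg.learning_rate}, optimizer={cfg.optimizer})"
                )
            grads = model._backward(caches, dz)
            opt.step(model.params, grads)
            epoch_loss += loss * len(idx)
        epoch_loss /= n_tr

        if xp_va is not None:
            p_va, _ = model._forward(xp_va, xm_va)
            val_loss, _ = model._loss_and_dz(p_va, y_va)
        else:
            val_loss = epoch_loss
        model.history.append(
            {"epoch": epoch, "train_loss": epoch_loss, "val_loss": val_loss}
        )
        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    if best_params is not None:
        model.params = best_params
    return model


def grid_search(
    cfg_grid: Iterable[ModelConfig],
    train_data: tuple[np.ndarray, np.ndarray | None, np.ndarray],
    test_data: tuple[np.ndarray, np.ndarray | None, np.ndarray],
) -> tuple[ModelConfig, "object"]:
    """Exhaustively train every config and return the one with the lowest
    test loss (ties go to the first in grid order), plus the results table."""
    import pandas as pd

    grid = list(cfg_grid)
    if not grid:
        raise ValueError("empty grid")
    rows = []
    best_cfg, best_loss = None, np.inf
    for i, cfg in enumerate(grid):
        model = build_model(cfg)
        train(model, *train_data)
        loss = model.loss_on(*test_data)
        rows.append({"index": i, "ablation": cfg.ablation, "loss": loss,
                     "kernel_peptide": cfg.kernel_peptide,
                     "kernel_metrics": cfg.kernel_metrics,
                     "n_filters": cfg.n_filters})
        if loss < best_loss:
            best_loss, best_cfg = loss, cfg
    return best_cfg, pd.DataFrame(rows)
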