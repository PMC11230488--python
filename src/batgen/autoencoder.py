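"""A 3D-latent autoencoder over vBAT features.

The encoder compresses the n_f-dimensional feature vector through the fixed
schedule n_f → n_f/4 → n_f/8 → n_f/16 → n_f/32 → n_f/64 → n_f/64 → latent
(floor division), and the decoder mirrors it in reverse.  All linear layers
omit bias units; LeakyReLU follows every layer except the final layer of each
half; elementwise layer normalization (gain + shift) follows the first hidden
layer of the encoder and dropout (rate 0.1) the second; the decoder carries
no normalization or dropout.  Weights are Xavier-uniform initialized.
Training minimizes the Smooth L1 reconstruction loss with Adam on randomly
drawn mini-batches.

The network is small enough that a plain numpy implementation with explicit
backpropagation trains in seconds on one CPU for the feature sizes the tests
use, and every source of randomness (init, batching, dropout) flows from a
single integer seed, so loss histories are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainedModel",
    "layer_widths",
    "build_model",
    "count_parameters",
    "smooth_l1_loss",
    "train",
    "encode",
    "decode",
    "save_model",
    "load_model",
]

_LN_EPS = 1e-5


@dataclass
class ModelConfig:
    n_f: int
    latent_dim: int = 3
    negative_slope: float = 0.01  # LeakyReLU slope
    dropout_rate: float = 0.1

    def __post_init__(self):
        if self.n_f < 64:
            raise ValueError(
                f"n_f must be >= 64 so every scheduled width is >= 1, got {self.n_f}")


@dataclass
class TrainConfig:
    """Adam training setup.

    lr_schedule is a list of (iteration, learning rate) pairs; each rate
    applies from its iteration onward.  The default halves the rate from
    0.002 to 0.001 after 5,000 iterations.
    """

    iterations: int = 5000
    batch_size: int = 200
    beta: float = 1.0  # Smooth L1 quadratic/linear transition point
    lr_schedule: list = field(default_factory=lambda: [(0, 0.002), (5000, 0.001)])
    seed: int = 0
    validation_interval: int = 50
    adam_betas: tuple = (0.9, 0.999)
    adam_eps: float = 1e-8

    def lr_at(self, iteration: int) -> float:
        lr = self.lr_schedule[0][1]
        for start, rate in self.lr_schedule:
            if iteration >= start:
                lr = rate
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        return lr


def layer_widths(n_f: int, latent_dim: int = 3) -> list:
    """Encoder width schedule with floor division; the decoder is its mirror."""
    return [n_f, n_f // 4, n_f // 8, n_f // 16, n_f // 32, n_f // 64,
            n_f // 64, latent_dim]


@dataclass
class TrainedModel:
    config: ModelConfig
    enc_weights: list  # (out, in) matrices, encoder order
    dec_weights: list  # (out, in) matrices, decoder order
    ln_gain: np.ndarray
    ln_shift: np.ndarray
    feat_mean: np.ndarray | None = None
    feat_scale: np.ndarray | None = None
    train_loss: list = field(default_factory=list)
    valid_loss: list = field(default_factory=list)  # (iteration, loss) pairs
    topology_hash: str = ""


def build_model(config: ModelConfig, seed: int = 0) -> TrainedModel:
    """Construct an untrained model with Xavier-uniform weights."""
    widths = layer_widths(config.n_f, config.latent_dim)
    rng = np.random.default_rng(seed)

    def xavier(fan_out, fan_in):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_out, fan_in))

    enc = [xavier(widths[t + 1], widths[t]) for t in range(len(widths) - 1)]
    rev = widths[::-1]
    dec = [xavier(rev[t + 1], rev[t]) for t in range(len(rev) - 1)]
    ln_w = widths[1]
    return TrainedModel(
        config=config, enc_weights=enc, dec_weights=dec,
        ln_gain=np.ones(ln_w), ln_shift=np.zeros(ln_w),
    )


def count_parameters(model: TrainedModel) -> int:
    """Exact count of trainable scalars: weights plus layer-norm gain/shift."""
    return (sum(w.size for w in model.enc_weights)
            + sum(w.size for w in model.dec_weights)
            + model.ln_gain.size + model.ln_shift.size)


def smooth_l1_loss(x: np.ndarray, y: np.ndarray, beta: float = 1.0) -> float:
    """Mean Smooth L1: quadratic below β, linear above, continuous at β."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    d = np.abs(np.asarray(x, dtype=float) - np.asarray(y, dtype=float))
    per = np.where(d < beta, d * d / (2.0 * beta), d - 0.5 * beta)
    return float(per.mean())


def _smooth_l1_grad(y, x, beta):
    """d loss / d y for the mean-reduced Smooth L1."""
    d = y - x
    g = np.clip(d / beta, -1.0, 1.0)
    return g / d.size


def _leaky(a, slope):
    return np.where(a > 0, a, slope * a)


def _leaky_grad(a, slope):
    return np.where(a > 0, 1.0, slope)


class _Forward:
    """Forward pass with caches for backpropagation."""

    def __init__(self, model: TrainedModel, training: bool, rng=None):
        self.m = model
        self.training = training
        self.rng = rng
        self.slope = model.config.negative_slope
        self.cache = {}

    def encoder(self, z):
        m, c = self.m, self.cache
        c["enc_in"], c["enc_pre"], c["enc_out"] = [], [], []
        h = z
        for t, w in enumerate(m.enc_weights):
            c["enc_in"].append(h)
            a = h @ w.T
            c["enc_pre"].append(a)
            last = t == len(m.enc_weights) - 1
            h = a if last else _leaky(a, self.slope)
            if t == 0:
                h = self._layer_norm(h)
            elif t == 1 and self.training and m.config.dropout_rate > 0:
                p = m.config.dropout_rate
                mask = (self.rng.random(h.shape) >= p) / (1.0 - p)
                c["drop_mask"] = mask
                h = h * mask
            c["enc_out"].append(h)
        return h

    def decoder(self, h):
        m, c = self.m, self.cache
        c["dec_in"], c["dec_pre"] = [], []
        for t, w in enumerate(m.dec_weights):
            c["dec_in"].append(h)
            a = h @ w.T
            c["dec_pre"].append(a)
            h = a if t == len(m.dec_weights) - 1 else _leaky(a, self.slope)
        return h

    def _layer_norm(self, x):
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + _LN_EPS)
        xhat = (x - mu) * inv
        self.cache["ln_xhat"], self.cache["ln_inv"] = xhat, inv
        return xhat * self.m.ln_gain + self.m.ln_shift

    # ---- backward ----

    def backward(self, d_out):
        """Gradient of the loss w.r.t. all weights, given d loss / d output."""
        m, c, slope = self.m, self.cache, self.slope
        g_dec = [None] * len(m.dec_weights)
        g = d_out
        for t in reversed(range(len(m.dec_weights))):
            if t != len(m.dec_weights) - 1:
                g = g * _leaky_grad(c["dec_pre"][t], slope)
            g_dec[t] = g.T @ c["dec_in"][t]
            g = g @ m.dec_weights[t]
        g_enc = [None] * len(m.enc_weights)
        g_ln_gain = g_ln_shift = None
        for t in reversed(range(len(m.enc_weights))):
            if t == 1 and "drop_mask" in c:
                g = g * c["drop_mask"]
            if t == 0:
                xhat, inv = c["ln_xhat"], c["ln_inv"]
                g_ln_gain = (g * xhat).sum(axis=0)
                g_ln_shift = g.sum(axis=0)
                gx = g * m.ln_gain
                g = inv * (gx - gx.mean(axis=1, keepdims=True)
                           - xhat * (gx * xhat).mean(axis=1, keepdims=True))
            if t != len(m.enc_weights) - 1:
                g = g * _leaky_grad(c["enc_pre"][t], slope)
            g_enc[t] = g.T @ c["enc_in"][t]
            g = g @ m.enc_weights[t]
        return g_enc, g_dec, g_ln_gain, g_ln_shift


class _Adam:
    def __init__(self, params, betas, eps):
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0

    def step(self, params, grads, lr):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _standardize(model, feats):
    return (feats - model.feat_mean) / model.feat_scale


def train(model: TrainedModel, training_features: np.ndarray,
          validation_features: np.ndarray, config: TrainConfig) -> TrainedModel:
    """Train in place; returns the same model with loss histories filled in.

    Per-feature standardization statistics are computed on the training set,
    stored on the model, and inverted transparently by :func:`decode`.
    """
    X = np.asarray(training_features, dtype=float)
    V = np.asarray(validation_features, dtype=float)
    if X.shape[1] != model.config.n_f:
        raise ValueError(f"features have {X.shape[1]} columns, model expects "
                         f"{model.config.n_f}")
    if config.batch_size > X.shape[0]:
        raise ValueError("batch size exceeds training-set size")
    model.feat_mean = X.mean(axis=0)
    model.feat_scale = np.maximum(X.std(axis=0), 1e-8)
    Xz = _standardize(model, X)
    Vz = _standardize(model, V)
    rng = np.random.default_rng(config.seed)
    params = (model.enc_weights + model.dec_weights
              + [model.ln_gain, model.ln_shift])
    opt = _Adam(params, config.adam_betas, config.adam_eps)
    for it in range(config.iterations):
        idx = rng.choice(Xz.shape[0], size=config.batch_size, replace=False)
        batch = Xz[idx]
        fwd = _Forward(model, training=True, rng=rng)
        out = fwd.decoder(fwd.encoder(batch))
        loss = smooth_l1_loss(batch, out, config.beta)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite training loss at iteration {it}; "
                "the learning rate is likely too high")
        model.train_loss.append(loss)
        g_enc, g_dec, g_g, g_s = fwd.backward(
            _smooth_l1_grad(out, batch, config.beta))
        opt.step(params, g_enc + g_dec + [g_g, g_s], config.lr_at(it))
        if it % config.validation_interval == 0 or it == config.iterations - 1:
            fwd_v = _Forward(model, training=False)
            v_out = fwd_v.decoder(fwd_v.encoder(Vz))
            model.valid_loss.append((it, smooth_l1_loss(Vz, v_out, config.beta)))
    return model


def encode(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Map features to latent points (dropout off, deterministic)."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.config.n_f:
        raise ValueError("feature dimension mismatch")
    if model.feat_mean is not None:
        X = _standardize(model, X)
    return _Forward(model, training=False).encoder(X)


def decode(model: TrainedModel, latent: np.ndarray) -> np.ndarray:
    """Map latent points back to (de-standardized) feature vectors."""
    Z = np.atleast_2d(np.asarray(latent, dtype=float))
    if Z.shape[1] != model.config.latent_dim:
        raise ValueError("latent dimension mismatch")
    out = _Forward(model, training=False).decoder(Z)
    if model.feat_mean is not None:
        out = out * model.feat_scale + model.feat_mean
    return out


def save_model(path, model: TrainedModel) -> None:
    arrays = {f"enc_{t}": w for t, w in enumerate(model.enc_weights)}
    arrays.update({f"dec_{t}": w for t, w in enumerate(model.dec_weights)})
    arrays.update(ln_gain=model.ln_gain, ln_shift=model.ln_shift)
    if model.feat_mean is not None:
        arrays.update(feat_mean=model.feat_mean, feat_scale=model.feat_scale)
    np.savez(
        path,
        meta=np.array([model.config.n_f, model.config.latent_dim]),
        meta_f=np.array([model.config.negative_slope, model.config.dropout_rate]),
        topo_hash=np.array(model.topology_hash),
        **arrays,
    )


def load_model(path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as data:
        n_f, latent = (int(v) for v in data["meta"])
        slope, drop = (float(v) for v in data["meta_f"])
        config = ModelConfig(n_f, latent, slope, drop)
        n_layers = len(layer_widths(n_f, latent)) - 1
        model = TrainedModel(
            config=config,
            enc_weights=[data[f"enc_{t}"] for t in range(n_layers)],
            dec_weights=[data[f"dec_{t}"] for t in range(n_layers)],
            ln_gain=data["ln_gain"], ln_shift=data["ln_shift"],
            topology_hash=str(data["topo_hash"]),
        )
        if "feat_mean" in data:
            model.feat_mean = data["feat_mean"]
            model.feat_scale = data["feat_scale"]
    return model
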