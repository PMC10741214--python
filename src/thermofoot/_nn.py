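"""Minimal numpy neural nets for dropout-based input-feature selection.

Two gated multilayer perceptrons share a backbone (two hidden ReLU layers with
ordinary dropout between them, softmax cross-entropy head) and differ in the
input gate:

* **Concrete gate** — each input x_i is multiplied by a relaxed-Bernoulli mask
  m_i = sigmoid((logit(p_i) + logit(u)) / t), u ~ U(0,1), with learnable
  keep-probability p_i and temperature t. An L0-style penalty lambda * sum p_i
  is added to the loss, so uninformative inputs are driven toward p_i -> 0
  while inputs the classifier needs keep p_i near 1. Relevance score: p_i.

* **Variational Gaussian gate** — each input is multiplied by xi_i ~ N(1,
  alpha_i) with learnable log alpha_i, trained against the sparsifying
  KL approximation of Molchanov et al. (2017): large alpha marks a prunable
  input. Relevance score: -log alpha_i.

Training is plain mini-batch Adam with manual backprop; the nets are small
(hundreds of samples, ~10^2 features) so numpy is entirely adequate.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    """Adam over a flat dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class MLPBackbone:
    """input -> 128 -> 64 -> 2 MLP, ReLU, dropout between hidden layers."""

    def __init__(self, n_in: int, rng: np.random.Generator,
                 hidden: tuple[int, int] = (128, 64), dropout: float = 0.5):
        h1, h2 = hidden
        self.dropout = dropout
        self.params = {
            "W1": rng.standard_normal((n_in, h1)) * np.sqrt(2.0 / n_in),
            "b1": np.zeros(h1),
            "W2": rng.standard_normal((h1, h2)) * np.sqrt(2.0 / h1),
            "b2": np.zeros(h2),
            "W3": rng.standard_normal((h2, 2)) * np.sqrt(2.0 / h2),
            "b3": np.zeros(2),
        }

    def forward(self, z: np.ndarray, rng: np.random.Generator | None, train: bool) -> tuple:
        p = self.params
        a1 = z @ p["W1"] + p["b1"]
        h1 = np.maximum(a1, 0.0)
        if train and self.dropout > 0:
            d1 = (rng.random(h1.shape) >= self.dropout) / (1.0 - self.dropout)
            h1d = h1 * d1
        else:
            d1 = None
            h1d = h1
        a2 = h1d @ p["W2"] + p["b2"]
        h2 = np.maximum(a2, 0.0)
        if train and self.dropout > 0:
            d2 = (rng.random(h2.shape) >= self.dropout) / (1.0 - self.dropout)
            h2d = h2 * d2
        else:
            d2 = None
            h2d = h2
        logits = h2d @ p["W3"] + p["b3"]
        cache = (z, a1, h1d, d1, a2, h2d, d2)
        return logits, cache

    def backward(self, dlogits: np.ndarray, cache: tuple) -> tuple[dict, np.ndarray]:
        z, a1, h1d, d1, a2, h2d, d2 = cache
        p = self.params
        grads = {}
        grads["W3"] = h2d.T @ dlogits
        grads["b3"] = dlogits.sum(axis=0)
        dh2d = dlogits @ p["W3"].T
        dh2 = dh2d * d2 if d2 is not None else dh2d
        da2 = dh2 * (a2 > 0)
        grads["W2"] = h1d.T @ da2
        grads["b2"] = da2.sum(axis=0)
        dh1d = da2 @ p["W2"].T
        dh1 = dh1d * d1 if d1 is not None else dh1d
        da1 = dh1 * (a1 > 0)
        grads["W1"] = z.T @ da1
        grads["b1"] = da1.sum(axis=0)
        dz = da1 @ p["W1"].T
        return grads, dz


def _softmax_ce(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. logits."""
    shifted = logits - logits.max(axis=1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    logp = shifted - logz
    n = len(y)
    loss = -logp[np.arange(n), y].mean()
    dlogits = np.exp(logp)
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


class ConcreteGateNet:
    """MLP with a concrete (relaxed-Bernoulli) input gate and L0-style penalty."""

    def __init__(self, n_in: int, rng: np.random.Generator, temperature: float = 0.1,
                 l0_weight: float | None = None, hidden_dropout: float = 0.5):
        self.backbone = MLPBackbone(n_in, rng, dropout=hidden_dropout)
        self.temperature = temperature
        self.l0_weight = l0_weight  # resolved to 1/n_train at fit time if None
        self.params = dict(self.backbone.params)
        self.params["phi"] = np.zeros(n_in)  # logit of keep-probability, p=0.5 at init
        self.backbone.params = self.params

    @property
    def keep_prob(self) -> np.ndarray:
        return _sigmoid(self.params["phi"])

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray,
                       rng: np.random.Generator, l0_weight: float) -> tuple[float, dict]:
        t = self.temperature
        u = np.clip(rng.random(X.shape), 1e-7, 1 - 1e-7)
        pre = (self.params["phi"] + np.log(u) - np.log1p(-u)) / t
        m = _sigmoid(pre)
        z = X * m
        logits, cache = self.backbone.forward(z, rng, train=True)
        ce, dlogits = _softmax_ce(logits, y)
        grads, dz = self.backbone.backward(dlogits, cache)
        # gate path: dm/dphi = m(1-m)/t
        dphi = (dz * X * m * (1.0 - m) / t).sum(axis=0)
        p = self.keep_prob
        penalty = l0_weight * p.sum()
        dphi += l0_weight * p * (1.0 - p)
        grads["phi"] = dphi
        return ce + penalty, grads


# Molchanov et al. (2017) sparsifying-KL approximation constants
_K1, _K2, _K3 = 0.63576, 1.87320, 1.48695
LOG_ALPHA_MIN, LOG_ALPHA_MAX = np.log(1e-8), np.log(1e4)


def _kl_and_grad(log_alpha: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature KL(q||p) of the log-uniform variational dropout posterior."""
    sig = _sigmoid(_K2 + _K3 * log_alpha)
    kl = -(_K1 * sig - 0.5 * np.log1p(np.exp(-log_alpha)) - _K1)
    dkl = -(_K1 * _K3 * sig * (1.0 - sig) + 0.5 * _sigmoid(-log_alpha))
    return kl, dkl


class VariationalGateNet:
    """MLP with multiplicative Gaussian input noise xi ~ N(1, alpha), alpha learned."""

    def __init__(self, n_in: int, rng: np.random.Generator,
                 init_log_alpha: float = -1.0, hidden_dropout: float = 0.5):
        self.backbone = MLPBackbone(n_in, rng, dropout=hidden_dropout)
        self.params = dict(self.backbone.params)
        self.params["log_alpha"] = np.full(n_in, init_log_alpha)
        self.backbone.params = self.params

    @property
    def log_alpha(self) -> np.ndarray:
        return self.params["log_alpha"]

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray,
                       rng: np.random.Generator, kl_weight: float) -> tuple[float, dict]:
        la = self.params["log_alpha"]
        sd = np.exp(0.5 * la)
        eps = rng.standard_normal(X.shape)
        z = X * (1.0 + sd * eps)
        logits, cache = self.backbone.forward(z, rng, train=True)
        ce, dlogits = _softmax_ce(logits, y)
        grads, dz = self.backbone.backward(dlogits, cache)
        dla = (dz * X * 0.5 * sd * eps).sum(axis=0)
        kl, dkl = _kl_and_grad(la)
        dla += kl_weight * dkl
        grads["log_alpha"] = dla
        return ce + kl_weight * kl.sum(), grads

    def clip(self) -> None:
        np.clip(self.params["log_alpha"], LOG_ALPHA_MIN, LOG_ALPHA_MAX,
                out=self.params["log_alpha"])


def train_gated_net(
    net: ConcreteGateNet | VariationalGateNet,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    lr: float,
    epochs: int = 500,
    batch_size: int = 32,
    beta1: float = 0.9,
    beta2: float = 0.999,
) -> None:
    """Mini-batch Adam training loop shared by both gated nets."""
    n = len(y)
    reg_weight = 1.0 / n  # L0 / KL weight relative to the mean cross-entropy
    if isinstance(net, ConcreteGateNet) and net.l0_weight is not None:
        reg_weight = net.l0_weight
    opt = Adam(net.params, lr=lr, beta1=beta1, beta2=beta2)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            loss, grads = net.loss_and_grads(X[idx], y[idx], rng, reg_weight)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss ({loss}) at step {opt.t}"
                )
            opt.step(grads)
            if isinstance(net, VariationalGateNet):
                net.clip()
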