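"""Minimal NumPy feed-forward networks for the deep survival learners.

Implements exactly what the survival models need: dense layers with SELU
activations and (inverted) dropout, reverse-mode gradients, an Adam
optimizer with decoupled weight decay, the negative Cox partial
log-likelihood (Breslow ties, batch risk sets) with its analytic
gradient, and the unbiased squared RBF-kernel MMD with gradients with
respect to both samples.
"""

from __future__ import annotations

import numpy as np

_SELU_LAMBDA = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


def selu(x: np.ndarray) -> np.ndarray:
    return _SELU_LAMBDA * np.where(x > 0, x, _SELU_ALPHA * (np.exp(np.minimum(x, 0)) - 1))


def selu_grad(x: np.ndarray) -> np.ndarray:
    return _SELU_LAMBDA * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(np.minimum(x, 0)))


class MLP:
    """Dense network: hidden layers with SELU, linear output layer.

    ``sizes`` includes input and output widths, e.g. ``(p, 32, 32, 1)``.
    An empty hidden list gives a plain linear map.
    """

    def __init__(self, sizes: tuple[int, ...], seed: int = 0, dropout: float = 0.0):
        if len(sizes) < 2:
            raise ValueError("need at least input and output sizes")
        self.sizes = tuple(int(s) for s in sizes)
        self.dropout = float(dropout)
        rng = np.random.default_rng(seed)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(self.sizes[:-1], self.sizes[1:]):
            # LeCun-normal init (pairs with SELU)
            self.W.append(rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return self.W + self.b

    def set_parameters(self, params: list[np.ndarray]) -> None:
        k = len(self.W)
        self.W = [p.copy() for p in params[:k]]
        self.b = [p.copy() for p in params[k:]]

    # -- forward / backward -------------------------------------------------
    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Return (output, cache); cache feeds :meth:`backward`."""
        h = np.asarray(X, dtype=float)
        pre, acts, masks = [], [h], []
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            pre.append(z)
            if i < last:
                h = selu(z)
                if train and self.dropout > 0:
                    mask = (rng.uniform(size=h.shape) >= self.dropout) / (1 - self.dropout)
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            else:
                h = z
            acts.append(h)
        return h, (pre, acts, masks)

    def backward(self, cache, d_out: np.ndarray):
        """Gradients of a scalar loss given d(loss)/d(output).

        Returns ``(grads, d_input)`` with grads ordered like
        :meth:`parameters`.
        """
        pre, acts, masks = cache
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = np.asarray(d_out, dtype=float)
        for i in range(len(self.W) - 1, -1, -1):
            if i < len(self.W) - 1:
                if masks[i] is not None:
                    delta = delta * masks[i]
                delta = delta * selu_grad(pre[i])
            gW[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            delta = delta @ self.W[i].T
        return gW + gb, delta


class AdamW:
    """Adam with decoupled weight decay (weight decay skips bias vectors)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 weight_decay: float = 0.0, betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.wd > 0 and p.ndim == 2:   # decoupled decay on weight matrices
                p -= self.lr * self.wd * p


def cox_npll(risk: np.ndarray, times: np.ndarray, events: np.ndarray):
    """Negative Cox partial log-likelihood (Breslow ties) and its gradient.

    Risk sets are formed within the given batch; the loss is normalized by
    the number of events.  Returns ``(loss, d_loss/d_risk)``.
    """
    risk = np.asarray(risk, dtype=float).ravel()
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    d = events.sum()
    if d == 0:
        return 0.0, np.zeros_like(risk)
    order = np.argsort(-times, kind="stable")   # descending time
    r = risk[order]
    e = events[order]
    t = times[order]
    m = r.max()
    cum = np.cumsum(np.exp(r - m))              # sum over risk set {j: t_j >= t_i}
    # Breslow: ties share one denominator — the cumsum at the last tied index
    last_idx = np.empty_like(cum, dtype=int)
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        last_idx[i:j + 1] = j
        i = j + 1
    denom = cum[last_idx]
    log_denom = np.log(denom) + m
    loss = -(r[e == 1].sum() - log_denom[e == 1].sum()) / d

    # gradient: dL/dr_k = -(1/d) * (e_k - exp(r_k) * sum_{events i with k in risk set i} 1/denom_i)
    inv = np.where(e == 1, 1.0 / denom, 0.0)
    grad_sorted = -(e - np.exp(r - m) * _tail_sum(inv, last_idx)) / d
    grad = np.empty_like(grad_sorted)
    grad[order] = grad_sorted
    return float(loss), grad


def _tail_sum(inv: np.ndarray, last_idx: np.ndarray) -> np.ndarray:
    """For each position k (descending-time order), sum of ``inv`` over event
    positions i ≥ first index of k's tie block (risk-set membership)."""
    n = len(inv)
    tail = np.concatenate([np.cumsum(inv[::-1])[::-1], [0.0]])
    first_idx = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = last_idx[i]
        first_idx[i:j + 1] = i
        i = j + 1
    return tail[first_idx]


def mmd2_rbf(x: np.ndarray, y: np.ndarray, bandwidth: float | None = None,
             with_grad: bool = False):
    """Unbiased squared MMD with an RBF kernel (median-heuristic bandwidth).

    With ``with_grad=True`` returns ``(value, dx, dy)``; the bandwidth is
    treated as a constant in the gradient.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[1] != y.shape[1]:
        raise ValueError("dimension mismatch")
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("empty sample")

    def sqdist(a, b):
        return np.maximum(
            (a**2).sum(1)[:, None] + (b**2).sum(1)[None, :] - 2 * a @ b.T, 0.0)

    dxx, dyy, dxy = sqdist(x, x), sqdist(y, y), sqdist(x, y)
    if bandwidth is None:
        pooled = np.concatenate([
            dxx[np.triu_indices(m, 1)] if m > 1 else np.empty(0),
            dyy[np.triu_indices(n, 1)] if n > 1 else np.empty(0),
            dxy.ravel(),
        ])
        med = np.median(pooled[pooled > 0]) if np.any(pooled > 0) else 1.0
        bandwidth = float(np.sqrt(med / 2.0)) if med > 0 else 1.0
    g = 1.0 / (2.0 * bandwidth**2)
    kxx, kyy, kxy = np.exp(-g * dxx), np.exp(-g * dyy), np.exp(-g * dxy)

    term_xx = (kxx.sum() - m) / (m * (m - 1)) if m > 1 else 0.0
    term_yy = (kyy.sum() - n) / (n * (n - 1)) if n > 1 else 0.0
    term_xy = kxy.mean()
    val = float(term_xx + term_yy - 2 * term_xy)
    if not with_grad:
        return val

    # d k(a,b) / d a = -2 g k(a,b) (a - b)
    dx = np.zeros_like(x)
    dy = np.zeros_like(y)
    if m > 1:
        w = kxx / (m * (m - 1))
        np.fill_diagonal(w, 0.0)
        dx += -2 * g * 2 * (w.sum(1)[:, None] * x - w @ x)
    if n > 1:
        w = kyy / (n * (n - 1))
        np.fill_diagonal(w, 0.0)
        dy += -2 * g * 2 * (w.sum(1)[:, None] * y - w @ y)
    w = kxy / (m * n)
    dx -= 2 * (-2 * g) * (w.sum(1)[:, None] * x - w @ y)
    dy -= 2 * (-2 * g) * (w.sum(0)[:, None] * y - w.T @ x)
    return val, dx, dy


def sinkhorn_distance(x: np.ndarray, y: np.ndarray, epsilon: float = 0.1,
                      n_iter: int = 200) -> float:
    """Entropic-regularized optimal transport cost (squared-Euclidean ground cost)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[1] != y.shape[1]:
        raise ValueError("dimension mismatch")
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("empty sample")
    C = ((x[:, None, :] - y[None, :, :]) ** 2).sum(-1)
    K = np.exp(-C / max(epsilon, 1e-12))
    u = np.full(m, 1.0 / m)
    v = np.full(n, 1.0 / n)
    a, b = np.full(m, 1.0 / m), np.full(n, 1.0 / n)
    for _ in range(n_iter):
        u = a / np.maximum(K @ v, 1e-300)
        v = b / np.maximum(K.T @ u, 1e-300)
    P = u[:, None] * K * v[None, :]
    return float((P * C).sum())
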