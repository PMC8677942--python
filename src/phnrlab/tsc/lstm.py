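"""A small stacked-LSTM binary classifier implemented in NumPy.

The waveform is fed stepwise (one scalar per time step) through stacked
LSTM layers with inter-layer dropout during training; the final hidden
state of the top layer feeds a logistic output unit trained with binary
cross-entropy via full backpropagation through time and Adam updates.
Default hyperparameters: 3 layers, hidden size 16, dropout 0.6, batch
size 6, learning rate 1e-3, 100 epochs.

Inputs are standardized by the training set's global mean/SD for numerical
stability; gradients are clipped to a global norm of 5.  The implementation
is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LSTMClassifier"]


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _LSTMLayer:
    """One LSTM layer; weights stored as a single (4H, D+H+1) matrix with
    gate order input, forget, cell, output and the bias in the last column."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        self.input_dim, self.hidden = input_dim, hidden
        scale = 1.0 / np.sqrt(hidden)
        self.W = rng.uniform(-scale, scale, size=(4 * hidden, input_dim + hidden + 1))
        self.W[hidden:2 * hidden, -1] += 1.0  # forget-gate bias init

    def forward(self, X: np.ndarray):
        """X: (T, N, D) -> hidden states (T, N, H) plus caches for BPTT."""
        T, N, _ = X.shape
        H = self.hidden
        h = np.zeros((N, H))
        c = np.zeros((N, H))
        hs = np.empty((T, N, H))
        caches = []
        for t in range(T):
            z = np.concatenate([X[t], h, np.ones((N, 1))], axis=1) @ self.W.T
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[t] = h
            caches.append((X[t], i, f, g, o, c_prev, tc))
        return hs, caches

    def backward(self, dhs: np.ndarray, hs: np.ndarray, caches):
        """dhs: gradient w.r.t. every hidden state (T, N, H).  Returns
        (dX, dW) where dX is the gradient w.r.t. the layer inputs."""
        T, N, H = dhs.shape
        dW = np.zeros_like(self.W)
        dX = np.empty((T, N, self.input_dim))
        dh_next = np.zeros((N, H))
        dc_next = np.zeros((N, H))
        for t in range(T - 1, -1, -1):
            x_t, i, f, g, o, c_prev, tc = caches[t]
            dh = dhs[t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g**2),
                do * o * (1.0 - o),
            ], axis=1)
            h_prev = hs[t - 1] if t > 0 else np.zeros((N, H))
            inp = np.concatenate([x_t, h_prev, np.ones((N, 1))], axis=1)
            dW += dz.T @ inp
            dinp = dz @ self.W
            dX[t] = dinp[:, :self.input_dim]
            dh_next = dinp[:, self.input_dim:self.input_dim + H]
        return dX, dW


class LSTMClassifier:
    def __init__(self, n_layers: int = 3, hidden_dims: int = 16,
                 dropout: float = 0.6, batch_size: int = 6,
                 learning_rate: float = 1e-3, n_epochs: int = 100,
                 seed: int = 0, clip_norm: float = 5.0):
        self.n_layers = n_layers
        self.hidden_dims = hidden_dims
        self.dropout = dropout
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.seed = seed
        self.clip_norm = clip_norm
        self._fitted = False

    # -- parameter plumbing -------------------------------------------------
    def _params(self):
        return [layer.W for layer in self.layers] + [self.w_out]

    def _init(self, rng: np.random.Generator):
        self.layers = []
        dim = 1
        for _ in range(self.n_layers):
            self.layers.append(_LSTMLayer(dim, self.hidden_dims, rng))
            dim = self.hidden_dims
        self.w_out = rng.uniform(-0.25, 0.25, size=self.hidden_dims + 1)
        self._adam_m = [np.zeros_like(p) for p in self._params()]
        self._adam_v = [np.zeros_like(p) for p in self._params()]
        self._adam_t = 0

    def _adam_step(self, grads, beta1=0.9, beta2=0.999, eps=1e-8):
        norm = np.sqrt(sum(float((g**2).sum()) for g in grads))
        if self.clip_norm and norm > self.clip_norm:
            grads = [g * (self.clip_norm / norm) for g in grads]
        self._adam_t += 1
        params = self._params()
        for p, g, m, v in zip(params, grads, self._adam_m, self._adam_v):
            m[:] = beta1 * m + (1 - beta1) * g
            v[:] = beta2 * v + (1 - beta2) * g**2
            mhat = m / (1 - beta1**self._adam_t)
            vhat = v / (1 - beta2**self._adam_t)
            p -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)

    # -- training -----------------------------------------------------------
    def fit(self, X, y):
        """X: (N, T) series; y: labels in {-1, +1} (or {0, 1})."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y01 = (np.asarray(y, dtype=float) > 0).astype(float)
        rng = np.random.default_rng(self.seed)
        self._mu, self._sd = float(X.mean()), float(X.std() or 1.0)
        Xs = (X - self._mu) / self._sd
        self._init(rng)
        n = X.shape[0]
        for _ in range(self.n_epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                self._train_batch(Xs[idx], y01[idx], rng)
        self._fitted = True
        return self

    def _train_batch(self, Xb, yb, rng):
        T = Xb.shape[1]
        a = Xb.T[:, :, None]  # (T, N, 1)
        layer_io = []
        masks = []
        for li, layer in enumerate(self.layers):
            hs, caches = layer.forward(a)
            out = hs
            mask = None
            if self.dropout > 0 and li < self.n_layers - 1:
                mask = (rng.random(out.shape) >= self.dropout) / (1.0 - self.dropout)
                out = out * mask
            layer_io.append((hs, caches))
            masks.append(mask)
            a = out
        h_final = a[T - 1]  # (N, H)
        logits = h_final @ self.w_out[:-1] + self.w_out[-1]
        p = _sigmoid(logits)
        dlogit = (p - yb) / Xb.shape[0]  # BCE gradient
        dw_out = np.concatenate([h_final.T @ dlogit, [dlogit.sum()]])
        dh = np.zeros_like(a)
        dh[T - 1] = dlogit[:, None] * self.w_out[:-1][None, :]
        layer_grads = [None] * self.n_layers
        for li in range(self.n_layers - 1, -1, -1):
            if masks[li] is not None:
                dh = dh * masks[li]
            hs, caches = layer_io[li]
            dh, dW = self.layers[li].backward(dh, hs, caches)
            layer_grads[li] = dW
        self._adam_step(layer_grads + [dw_out])

    # -- inference ----------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("classifier is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        a = ((X - self._mu) / self._sd).T[:, :, None]
        for layer in self.layers:
            hs, _ = layer.forward(a)
            a = hs  # no dropout at inference
        logits = a[-1] @ self.w_out[:-1] + self.w_out[-1]
        return _sigmoid(logits)

    def predict(self, X) -> np.ndarray:
        """Labels in {-1, +1}."""
        return np.where(self.predict_proba(X) >= 0.5, 1, -1)
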