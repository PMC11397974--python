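"""Seeded LSTM regression models in pure numpy.

This module implements the package's sequence models: stacked LSTM layers,
a linear regression head, mean-squared-error loss, Adam updates, and full
backpropagation through time.  Two head modes are supported:

``"last"``
    sequence-to-one — the head reads the final hidden state (used to map a
    heart-rate window to one hysteresivity value);
``"sequence"``
    sequence-to-sequence — the head reads every hidden state (used for HR
    window forecasting and ECG lead-to-lead prediction).

The head optionally includes a linear skip connection from the input (the
window mean in ``"last"`` mode, the current sample in ``"sequence"`` mode),
a residual-regression design that stabilizes identity-like mappings.  All
randomness (initialization, batch shuffling) flows from one integer seed, so
training is bit-reproducible.  Gradients are exact (verified against finite
differences in the test suite).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError, TrainingError

__all__ = ["LSTMRegressor"]

#: Internal compute dtype; single precision is ample for gradient training.
DTYPE = np.float32


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # inputs are bounded by the clip below, so the plain form is stable
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


class _LSTMLayer:
    """One LSTM layer; gate order in the fused weight matrices is i, f, o, g
    (the three sigmoid gates contiguous, the tanh candidate last)."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        scale_x = 1.0 / np.sqrt(input_dim + hidden)
        self.wx = rng.uniform(-scale_x, scale_x, size=(input_dim, 4 * hidden)).astype(DTYPE)
        self.wh = rng.uniform(-scale_x, scale_x, size=(hidden, 4 * hidden)).astype(DTYPE)
        self.b = np.zeros(4 * hidden, dtype=DTYPE)
        self.b[hidden:2 * hidden] = 1.0  # forget-gate bias (order i, f, o, g)
        self.hidden = hidden

    def params(self):
        return [self.wx, self.wh, self.b]

    def forward(self, x: np.ndarray):
        """x: (B, T, D) -> h: (B, T, H); caches activations for backward."""
        b_, t_, _ = x.shape
        hn = self.hidden
        h = np.zeros((b_, t_, hn), dtype=DTYPE)
        # input contribution to all gates for all timesteps in one matmul
        xw = (x.reshape(b_ * t_, -1) @ self.wx).reshape(b_, t_, 4 * hn) + self.b
        cache = []
        h_prev = np.zeros((b_, hn), dtype=DTYPE)
        c_prev = np.zeros((b_, hn), dtype=DTYPE)
        for t in range(t_):
            a = xw[:, t] + h_prev @ self.wh
            gates = _sigmoid(a[:, :3 * hn])
            i = gates[:, :hn]
            f = gates[:, hn:2 * hn]
            o = gates[:, 2 * hn:]
            g = np.tanh(a[:, 3 * hn:])
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_t = o * tc
            h[:, t] = h_t
            cache.append((h_prev, c_prev, i, f, g, o, tc))
            h_prev, c_prev = h_t, c
        self._cache = cache
        self._x = x
        return h

    def backward(self, dh: np.ndarray):
        """dh: (B, T, H) gradient on the layer's outputs -> (dx, grads)."""
        cache = self._cache
        x = self._x
        t_ = len(cache)
        hn = self.hidden
        b_ = dh.shape[0]
        da_all = np.zeros((b_, t_, 4 * hn), dtype=DTYPE)
        dwh = np.zeros_like(self.wh)
        dh_next = np.zeros((b_, hn), dtype=DTYPE)
        dc_next = np.zeros((b_, hn), dtype=DTYPE)
        for t in range(t_ - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = cache[t]
            dh_t = dh[:, t] + dh_next
            do = dh_t * tc
            dc = dh_t * o * (1.0 - tc * tc) + dc_next
            da = da_all[:, t]
            da[:, :hn] = dc * g * i * (1.0 - i)
            da[:, hn:2 * hn] = dc * c_prev * f * (1.0 - f)
            da[:, 2 * hn:3 * hn] = do * o * (1.0 - o)
            da[:, 3 * hn:] = dc * i * (1.0 - g * g)
            dwh += h_prev.T @ da
            dh_next = da @ self.wh.T
            dc_next = dc * f
        flat = da_all.reshape(b_ * t_, 4 * hn)
        dwx = x.reshape(b_ * t_, -1).T @ flat
        db = flat.sum(axis=0)
        dx = (flat @ self.wx.T).reshape(b_, t_, -1)
        return dx, [dwx, dwh, db]


@dataclass
class _FitLog:
    """Training trajectory returned to the caller."""

    loss: list[float] = field(default_factory=list)
    epochs_run: int = 0
    stopped_early: bool = False


class LSTMRegressor:
    """Stacked-LSTM regression with a linear head and Adam training.

    Parameters
    ----------
    input_dim:
        Number of input features per timestep.
    hidden_units, n_layers:
        Size and depth of the recurrent stack.
    output_mode:
        ``"last"`` (sequence-to-one) or ``"sequence"`` (per-timestep output).
    skip_connection:
        Include a direct linear term from the input in the head.
    seed:
        Fixes initialization and batch shuffling.
    """

    def __init__(self, input_dim: int = 1, hidden_units: int = 50,
                 n_layers: int = 1, output_mode: str = "last",
                 skip_connection: bool = True, seed: int = 0):
        if hidden_units < 1 or n_layers < 1:
            raise InvalidArgumentError("hidden_units and n_layers must be >= 1")
        if output_mode not in ("last", "sequence"):
            raise InvalidArgumentError("output_mode must be 'last' or 'sequence'")
        self.input_dim = input_dim
        self.hidden_units = hidden_units
        self.n_layers = n_layers
        self.output_mode = output_mode
        self.skip_connection = skip_connection
        self.seed = seed

        rng = np.random.default_rng(seed)
        self.layers = []
        d = input_dim
        for _ in range(n_layers):
            self.layers.append(_LSTMLayer(d, hidden_units, rng))
            d = hidden_units
        # zero-initialized head: the recurrent contribution grows only where
        # it reduces the loss.  Sequence mode starts from the identity skip
        # (inputs and targets are z-scored, so y = x is the natural prior and
        # the recurrent stack learns the correction).
        self.wy = np.zeros((hidden_units, 1), dtype=DTYPE)
        self.ws = np.zeros((input_dim, 1), dtype=DTYPE)
        if output_mode == "sequence" and skip_connection and input_dim == 1:
            self.ws[0, 0] = 1.0
        self.by = np.zeros(1, dtype=DTYPE)
        self._rng = rng
        self.fit_log = _FitLog()

    # -- parameter bookkeeping ------------------------------------------------
    def _params(self):
        p = []
        for layer in self.layers:
            p.extend(layer.params())
        p.extend([self.wy, self.ws, self.by])
        return p

    # -- forward / backward ---------------------------------------------------
    def _forward(self, x: np.ndarray):
        h = x
        for layer in self.layers:
            h = layer.forward(h)
        if self.output_mode == "last":
            hy = h[:, -1]                     # (B, H)
            skip = x.mean(axis=1)             # (B, D)
            y = hy @ self.wy + self.by
            if self.skip_connection:
                y = y + skip @ self.ws
            self._head_cache = (hy, skip, x.shape)
            return y[:, 0]                    # (B,)
        # sequence mode: per-timestep head
        y = h @ self.wy + self.by             # (B, T, 1)
        if self.skip_connection:
            y = y + x @ self.ws
        self._head_cache = (h, x, x.shape)
        return y[..., 0]                      # (B, T)

    def _backward(self, dy: np.ndarray):
        grads_head = []
        if self.output_mode == "last":
            hy, skip, shape = self._head_cache
            b_, t_, _ = shape
            dyc = dy[:, None]                 # (B, 1)
            dwy = hy.T @ dyc
            dby = dyc.sum(axis=0)
            dws = skip.T @ dyc if self.skip_connection else np.zeros_like(self.ws)
            dh = np.zeros((b_, t_, self.hidden_units), dtype=DTYPE)
            dh[:, -1] = dyc @ self.wy.T
            dx_skip = np.zeros((b_, t_, self.input_dim), dtype=DTYPE)
            if self.skip_connection:
                dx_skip += (dyc @ self.ws.T)[:, None, :] / t_
        else:
            h, x, shape = self._head_cache
            b_, t_, _ = shape
            dyc = dy[..., None]               # (B, T, 1)
            dwy = np.tensordot(h, dyc, axes=([0, 1], [0, 1]))
            dby = dyc.sum(axis=(0, 1))
            dws = (np.tensordot(x, dyc, axes=([0, 1], [0, 1]))
                   if self.skip_connection else np.zeros_like(self.ws))
            dh = dyc @ self.wy.T
            dx_skip = (dyc @ self.ws.T) if self.skip_connection else 0.0

        grads_head = [dwy, dws, dby]
        dcur = dh
        grads_layers = []
        for layer in reversed(self.layers):
            dcur, g = layer.backward(dcur)
            grads_layers = g + grads_layers
        dcur = dcur + dx_skip
        return grads_layers + grads_head

    def _loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        pred = self._forward(x)
        err = pred - y
        loss = float(np.mean(err ** 2))
        dy = 2.0 * err / err.size
        return loss, self._backward(dy)

    # -- training -------------------------------------------------------------
    def fit(self, x: np.ndarray, y: np.ndarray, max_epochs: int = 200,
            learning_rate: float = 1e-3, batch_size: int | None = None,
            patience: int = 20, min_rel_improvement: float = 1e-5,
            lr_decay: float = 0.99, shuffle: bool = True) -> "LSTMRegressor":
        """Train by Adam on mean squared error.

        The learning rate is annealed exponentially (``lr_decay`` per epoch)
        so late-stage Adam dithering shrinks with it.  Stops early when the
        epoch loss has not improved relatively by ``min_rel_improvement``
        for ``patience`` epochs.  Raises :class:`TrainingError` on NaN/Inf
        loss.
        """
        x = np.asarray(x, dtype=DTYPE)
        y = np.asarray(y, dtype=DTYPE)
        if x.ndim == 2:
            x = x[..., None]
        if x.shape[0] == 0:
            raise InvalidArgumentError("fit: empty training set")
        if x.shape[-1] != self.input_dim:
            raise InvalidArgumentError(
                f"fit: expected input_dim {self.input_dim}, got {x.shape[-1]}"
            )
        n = x.shape[0]
        batch_size = batch_size or n

        # fresh model: start the output bias at the target mean so the head
        # only has to learn deviations from it
        if self.fit_log.epochs_run == 0 and self.by[0] == 0.0:
            self.by[0] = y.mean()

        params = self._params()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_loss = np.inf
        stale = 0
        self.fit_log = _FitLog()

        for epoch in range(max_epochs):
            lr_t = learning_rate * lr_decay ** epoch
            order = self._rng.permutation(n) if shuffle else np.arange(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                loss, grads = self._loss_and_grads(x[idx], y[idx])
                if not np.isfinite(loss):
                    raise TrainingError(
                        f"training diverged at epoch {epoch}: loss = {loss}",
                        {"epoch": epoch, "loss_history": self.fit_log.loss},
                    )
                epoch_loss += loss * idx.size
                step += 1
                for p, g, m_i, v_i in zip(params, grads, m, v):
                    m_i *= beta1
                    m_i += (1 - beta1) * g
                    v_i *= beta2
                    v_i += (1 - beta2) * g * g
                    mhat = m_i / (1 - beta1 ** step)
                    vhat = v_i / (1 - beta2 ** step)
                    p -= lr_t * mhat / (np.sqrt(vhat) + eps)
            epoch_loss /= n
            self.fit_log.loss.append(epoch_loss)
            self.fit_log.epochs_run = epoch + 1
            if epoch_loss < best_loss * (1.0 - min_rel_improvement):
                best_loss = epoch_loss
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    self.fit_log.stopped_early = True
                    break
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predict (B,) in ``"last"`` mode or (B, T) in ``"sequence"`` mode."""
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim == 2:
            x = x[..., None]
        if x.shape[0] == 0:
            raise InvalidArgumentError("predict: empty input")
        return np.asarray(self._forward(x), dtype=float)

    # -- serialization --------------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self._params()]

    def set_weights(self, weights) -> None:
        for p, w in zip(self._params(), weights):
            p[...] = np.asarray(w, dtype=DTYPE)

    def save(self, path) -> None:
        """Write config + weights to an .npz checkpoint."""
        config = dict(input_dim=self.input_dim, hidden_units=self.hidden_units,
                      n_layers=self.n_layers, output_mode=self.output_mode,
                      skip_connection=self.skip_connection, seed=self.seed)
        arrays = {f"w{i}": w for i, w in enumerate(self.get_weights())}
        np.savez(path, config=np.array([json.dumps(config)]), **arrays)

    @classmethod
    def load(cls, path) -> "LSTMRegressor":
        data = np.load(path, allow_pickle=False)
        config = json.loads(str(data["config"][0]))
        model = cls(**config)
        model.set_weights([data[f"w{i}"] for i in range(len(data.files) - 1)])
        return model
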