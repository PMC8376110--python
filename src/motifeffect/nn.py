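"""A small numpy implementation of the sequence convolutional network.

Each ensemble member is a two-layer 1-D convolutional network over
one-hot DNA input: conv -> ReLU -> conv -> ReLU -> global max pooling
over positions -> dense layer with one sigmoid output per class
(multi-task). Training minimizes mean binary cross-entropy with Adam.
The implementation is deliberately minimal — exactly the forward pass,
the gradients (including gradients with respect to the input, needed
for per-base importance scores), and mini-batch training with early
stopping — and is single-threaded and deterministic for a fixed seed.

Convolutions are computed by im2col: a strided sliding-window view of
the input reshaped so each output position is one row of a matrix
product. Filter shapes are (n_filters, width, in_channels).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1 - eps)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def _im2col(x: np.ndarray, width: int) -> np.ndarray:
    """(B, L, C) -> (B, P, width*C) with P = L - width + 1."""
    # sliding over axis=1 gives (B, P, C, width); put width before channels
    win = sliding_window_view(x, width, axis=1)
    b, p = win.shape[0], win.shape[1]
    return win.transpose(0, 1, 3, 2).reshape(b, p, width * win.shape[2])


def _col2im(dcols: np.ndarray, length: int, width: int, channels: int) -> np.ndarray:
    """Scatter-add (B, P, width, C) gradients back onto a (B, L, C) input."""
    b, p = dcols.shape[0], dcols.shape[1]
    dx = np.zeros((b, length, channels))
    for j in range(width):
        dx[:, j : j + p, :] += dcols[:, :, j, :]
    return dx


class _Adam:
    def __init__(self, shapes, lr=1e-3, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


class ConvNet:
    """One ensemble member: conv/ReLU x2, global max pool, sigmoid dense."""

    def __init__(
        self,
        window_length: int,
        n_classes: int,
        conv1_shape: tuple[int, int],
        conv2_shape: tuple[int, int],
        rng: np.random.Generator,
        learning_rate: float = 1e-3,
    ):
        f1, w1 = conv1_shape
        f2, w2 = conv2_shape
        if w1 > window_length or w2 > window_length - w1 + 1:
            raise ValueError("filter width exceeds available sequence length")
        self.window_length = window_length
        self.n_classes = n_classes
        self.w1, self.w2 = w1, w2
        # He-style init scaled by fan-in
        self.W1 = rng.normal(0, np.sqrt(2.0 / (w1 * 4)), size=(f1, w1, 4))
        self.b1 = np.zeros(f1)
        self.W2 = rng.normal(0, np.sqrt(2.0 / (w2 * f1)), size=(f2, w2, f1))
        self.b2 = np.zeros(f2)
        self.W3 = rng.normal(0, np.sqrt(1.0 / f2), size=(f2, n_classes))
        self.b3 = np.zeros(n_classes)
        self.learning_rate = learning_rate
        self._opt: _Adam | None = None

    @property
    def params(self):
        return [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]

    # ---- forward ------------------------------------------------------

    def _forward(self, x: np.ndarray) -> dict:
        cols1 = _im2col(x, self.w1)  # (B, P1, w1*4)
        f1 = self.W1.shape[0]
        z1 = cols1 @ self.W1.reshape(f1, -1).T + self.b1  # (B, P1, F1)
        a1 = np.maximum(z1, 0.0)
        cols2 = _im2col(a1, self.w2)  # (B, P2, w2*F1)
        f2 = self.W2.shape[0]
        z2 = cols2 @ self.W2.reshape(f2, -1).T + self.b2  # (B, P2, F2)
        a2 = np.maximum(z2, 0.0)
        pool_idx = a2.argmax(axis=1)  # (B, F2)
        pooled = np.take_along_axis(a2, pool_idx[:, None, :], axis=1)[:, 0, :]
        logits = pooled @ self.W3 + self.b3
        return {
            "x": x, "cols1": cols1, "z1": z1, "a1": a1,
            "cols2": cols2, "z2": z2, "a2": a2,
            "pool_idx": pool_idx, "pooled": pooled, "logits": logits,
        }

    def predict(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Per-class probabilities for one-hot input of shape (B, L, 4)."""
        out = np.empty((x.shape[0], self.n_classes))
        for lo in range(0, x.shape[0], batch_size):
            sl = slice(lo, lo + batch_size)
            out[sl] = sigmoid(self._forward(x[sl])["logits"])
        return out

    # ---- backward -----------------------------------------------------

    def _backward(self, cache: dict, dlogits: np.ndarray, to_input: bool = False):
        """Gradients of a scalar objective given d(objective)/d(logits).

        Returns (param_grads, dx); dx is None unless ``to_input``.
        """
        pooled, pool_idx = cache["pooled"], cache["pool_idx"]
        dW3 = pooled.T @ dlogits
        db3 = dlogits.sum(axis=0)
        dpooled = dlogits @ self.W3.T  # (B, F2)
        da2 = np.zeros_like(cache["a2"])
        np.put_along_axis(da2, pool_idx[:, None, :], dpooled[:, None, :], axis=1)
        dz2 = da2 * (cache["z2"] > 0)
        f2 = self.W2.shape[0]
        b, p2 = dz2.shape[0], dz2.shape[1]
        dW2 = np.tensordot(dz2, cache["cols2"], axes=([0, 1], [0, 1])).reshape(self.W2.shape)
        db2 = dz2.sum(axis=(0, 1))
        dcols2 = dz2 @ self.W2.reshape(f2, -1)  # (B, P2, w2*F1)
        f1 = self.W1.shape[0]
        da1 = _col2im(
            dcols2.reshape(b, p2, self.w2, f1), cache["a1"].shape[1], self.w2, f1
        )
        dz1 = da1 * (cache["z1"] > 0)
        dW1 = np.tensordot(dz1, cache["cols1"], axes=([0, 1], [0, 1])).reshape(self.W1.shape)
        db1 = dz1.sum(axis=(0, 1))
        dx = None
        if to_input:
            dcols1 = dz1 @ self.W1.reshape(f1, -1)
            dx = _col2im(
                dcols1.reshape(b, dz1.shape[1], self.w1, 4),
                self.window_length, self.w1, 4,
            )
        return [dW1, db1, dW2, db2, dW3, db3], dx

    def input_gradient(self, x: np.ndarray, dlogits: np.ndarray) -> np.ndarray:
        """d(objective)/d(input) for a given d(objective)/d(logits)."""
        cache = self._forward(x)
        _, dx = self._backward(cache, dlogits, to_input=True)
        return dx

    # ---- training -----------------------------------------------------

    def train_batch(self, x: np.ndarray, y: np.ndarray) -> float:
        if self._opt is None:
            self._opt = _Adam([p.shape for p in self.params], lr=self.learning_rate)
        cache = self._forward(x)
        p = sigmoid(cache["logits"])
        # d(mean BCE)/d(logits) = (p - y) / (B*C)
        dlogits = (p - y) / y.size
        grads, _ = self._backward(cache, dlogits)
        self._opt.step(self.params, grads)
        return bce_loss(p, y)

    def loss(self, x: np.ndarray, y: np.ndarray) -> float:
        return bce_loss(self.predict(x), y)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w


def fit_member(
    net: ConvNet,
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray | None,
    val_y: np.ndarray | None,
    epochs: int,
    batch_size: int,
    patience: int,
    rng: np.random.Generator,
) -> list[dict]:
    """Mini-batch training with validation-loss early stopping.

    Stops when validation loss has failed to improve for ``patience``
    consecutive epochs and restores the best-epoch weights. Without a
    validation set, runs all epochs. Returns the per-epoch log.
    """
    log: list[dict] = []
    has_val = val_x is not None and len(val_x) > 0
    best_loss, best_weights, bad_epochs = np.inf, None, 0
    n = train_x.shape[0]
    for epoch in range(1, epochs + 1):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, batch_size):
            idx = order[lo : lo + batch_size]
            losses.append(net.train_batch(train_x[idx], train_y[idx]))
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if has_val:
            vloss = net.loss(val_x, val_y)
            entry["val_loss"] = vloss
            if vloss < best_loss - 1e-12:
                best_loss, best_weights, bad_epochs = vloss, net.get_weights(), 0
            else:
                bad_epochs += 1
        log.append(entry)
        if has_val and bad_epochs >= patience:
            break
    if best_weights is not None:
        net.set_weights(best_weights)
    return log
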