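"""A compact convolutional network for desk-scale tile classification.

Pure-numpy implementation of a small CNN:
two 3x3 convolution + ReLU + 2x2 max-pool blocks, dropout, a dense
ReLU layer, and a softmax head, trained with Adam on cross-entropy.
Training uses mini-batches (default 16), early stopping on validation
loss (patience 6, best weights restored) and a
reduce-learning-rate-on-plateau schedule — the standard callbacks for
small-sample image classifiers.

The implementation favours clarity over speed: convolutions run as
im2col matrix products, which is comfortably fast for the 32x32 tiles
used in seeded experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*k*k) patches for a same-padded k x k conv."""
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    n, c, h, w, _, _ = win.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back to the input."""
    n, c, h, w = x_shape
    pad = k // 2
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    d = dcols.reshape(n, h, w, c, k, k)
    for di in range(k):
        for dj in range(k):
            dxp[:, :, di:di + h, dj:dj + w] += d[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
    return dxp[:, :, pad:pad + h, pad:pad + w]


class _Adam:
    def __init__(self, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict[int, np.ndarray] = {}
        self.v: dict[int, np.ndarray] = {}
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            m = self.m.setdefault(i, np.zeros_like(p))
            v = self.v.setdefault(i, np.zeros_like(p))
            m[:] = self.b1 * m + (1 - self.b1) * g
            v[:] = self.b2 * v + (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    stopped_epoch: int | None = None


class SmallCNN:
    """conv(3x3, f1) -> pool -> conv(3x3, f2) -> pool -> dropout ->
    dense(hidden) -> dense(n_classes) with softmax output."""

    def __init__(
        self,
        input_shape: tuple[int, int, int],  # (channels, H, W)
        n_classes: int,
        filters: tuple[int, int] = (8, 16),
        hidden: int = 64,
        dropout: float = 0.25,
        seed: int = 0,
    ):
        c, h, w = input_shape
        if h % 4 or w % 4:
            raise ValueError("tile side must be divisible by 4 (two 2x2 pools)")
        self.input_shape = input_shape
        self.n_classes = n_classes
        self.dropout = dropout
        f1, f2 = filters
        rng = np.random.default_rng(seed)
        k = 3
        flat = f2 * (h // 4) * (w // 4)

        def he(shape, fan_in):
            return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

        self.W1 = he((f1, c * k * k), c * k * k)
        self.b1 = np.zeros(f1)
        self.W2 = he((f2, f1 * k * k), f1 * k * k)
        self.b2 = np.zeros(f2)
        self.W3 = he((hidden, flat), flat)
        self.b3 = np.zeros(hidden)
        self.W4 = he((n_classes, hidden), hidden)
        self.b4 = np.zeros(n_classes)
        self._drop_rng = np.random.default_rng(rng.integers(2**31))

    # -- parameter plumbing -------------------------------------------------

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2,
                self.W3, self.b3, self.W4, self.b4]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[:] = w

    # -- forward / backward -------------------------------------------------

    @staticmethod
    def _pool(x):
        n, f, h, w = x.shape
        r = x.reshape(n, f, h // 2, 2, w // 2, 2)
        out = r.max(axis=(3, 5))
        mask = r == out[:, :, :, None, :, None]
        return out, mask

    @staticmethod
    def _unpool(dout, mask):
        n, f, h2, _, w2, _ = mask.shape
        d = mask * dout[:, :, :, None, :, None]
        return d.reshape(n, f, h2 * 2, w2 * 2)

    def forward(self, x: np.ndarray, train: bool = False) -> tuple[np.ndarray, dict]:
        cache: dict = {"x": x}
        n = len(x)
        c, h, w = self.input_shape

        cols1 = _im2col(x, 3)
        z1 = (cols1 @ self.W1.T + self.b1).transpose(0, 2, 1).reshape(n, -1, h, w)
        a1 = np.maximum(z1, 0)
        p1, m1 = self._pool(a1)

        cols2 = _im2col(p1, 3)
        h2, w2 = h // 2, w // 2
        z2 = (cols2 @ self.W2.T + self.b2).transpose(0, 2, 1).reshape(n, -1, h2, w2)
        a2 = np.maximum(z2, 0)
        p2, m2 = self._pool(a2)

        flat = p2.reshape(n, -1)
        if train and self.dropout > 0:
            keep = self._drop_rng.random(flat.shape) >= self.dropout
            flat = flat * keep / (1.0 - self.dropout)
            cache["keep"] = keep
        z3 = flat @ self.W3.T + self.b3
        a3 = np.maximum(z3, 0)
        logits = a3 @ self.W4.T + self.b4

        cache.update(
            cols1=cols1, z1=z1, m1=m1, p1=p1, cols2=cols2, z2=z2, m2=m2,
            p2_shape=p2.shape, flat=flat, z3=z3, a3=a3,
        )
        return logits, cache

    @staticmethod
    def softmax(logits: np.ndarray) -> np.ndarray:
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def loss_and_grads(
        self, x: np.ndarray, y_onehot: np.ndarray, train: bool = True
    ) -> tuple[float, list[np.ndarray]]:
        logits, cache = self.forward(x, train=train)
        n = len(x)
        p = self.softmax(logits)
        loss = float(-np.sum(y_onehot * np.log(np.clip(p, 1e-12, None))) / n)

        dlogits = (p - y_onehot) / n
        dW4 = dlogits.T @ cache["a3"]
        db4 = dlogits.sum(axis=0)
        da3 = dlogits @ self.W4
        dz3 = da3 * (cache["z3"] > 0)
        dW3 = dz3.T @ cache["flat"]
        db3 = dz3.sum(axis=0)
        dflat = dz3 @ self.W3
        if train and self.dropout > 0:
            dflat = dflat * cache["keep"] / (1.0 - self.dropout)
        dp2 = dflat.reshape(cache["p2_shape"])

        da2 = self._unpool(dp2, cache["m2"])
        dz2 = da2 * (cache["z2"] > 0)
        nfhw = dz2.reshape(n, dz2.shape[1], -1).transpose(0, 2, 1)  # (N, HW, F)
        dW2 = np.einsum("npf,npk->fk", nfhw, cache["cols2"])
        db2 = nfhw.sum(axis=(0, 1))
        dcols2 = nfhw @ self.W2
        dp1 = _col2im(dcols2, cache["p1"].shape, 3)

        da1 = self._unpool(dp1, cache["m1"])
        dz1 = da1 * (cache["z1"] > 0)
        nfhw1 = dz1.reshape(n, dz1.shape[1], -1).transpose(0, 2, 1)
        dW1 = np.einsum("npf,npk->fk", nfhw1, cache["cols1"])
        db1 = nfhw1.sum(axis=(0, 1))

        return loss, [dW1, db1, dW2, db2, dW3, db3, dW4, db4]

    def predict_proba(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch):
            logits, _ = self.forward(x[i:i + batch], train=False)
            out.append(self.softmax(logits))
        return np.concatenate(out)

    def evaluate_loss(self, x: np.ndarray, y_onehot: np.ndarray) -> float:
        p = self.predict_proba(x)
        return float(
            -np.sum(y_onehot * np.log(np.clip(p, 1e-12, None))) / len(x)
        )


def train_network(
    model: SmallCNN,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    epochs: int = 50,
    batch_size: int = 16,
    lr: float = 1e-3,
    patience: int = 6,
    lr_patience: int = 3,
    lr_factor: float = 0.5,
    min_lr: float = 1e-5,
    augment: bool = True,
    seed: int = 0,
) -> TrainLog:
    """Mini-batch Adam training with early stopping on validation loss
    (best weights restored) and LR reduction on plateau.

    With ``augment`` on, each batch is randomly rotated by a multiple
    of 90 degrees and possibly mirrored — label-preserving symmetries
    for tissue tiles, which have no preferred orientation.
    """
    n_classes = model.n_classes
    y_tr = np.eye(n_classes)[y_train]
    y_va = np.eye(n_classes)[y_val]
    opt = _Adam(lr=lr)
    rng = np.random.default_rng(seed)
    log = TrainLog()
    best_loss = np.inf
    best_weights = model.get_weights()
    wait = lr_wait = 0
    for epoch in range(epochs):
        order = rng.permutation(len(x_train))
        losses = []
        for i in range(0, len(order), batch_size):
            idx = order[i:i + batch_size]
            xb = x_train[idx]
            if augment:
                k = int(rng.integers(4))
                if k:
                    xb = np.rot90(xb, k, axes=(2, 3))
                if rng.random() < 0.5:
                    xb = xb[:, :, :, ::-1]
                xb = np.ascontiguousarray(xb)
            loss, grads = model.loss_and_grads(xb, y_tr[idx], train=True)
            opt.step(model.params, grads)
            losses.append(loss)
        val_loss = model.evaluate_loss(x_val, y_va)
        log.train_loss.append(float(np.mean(losses)))
        log.val_loss.append(val_loss)
        log.lr.append(opt.lr)
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_weights = model.get_weights()
            wait = lr_wait = 0
        else:
            wait += 1
            lr_wait += 1
            if lr_wait >= lr_patience and opt.lr > min_lr:
                opt.lr = max(min_lr, opt.lr * lr_factor)
                lr_wait = 0
            if wait >= patience:
                log.stopped_epoch = epoch
                break
    model.set_weights(best_weights)
    return log
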