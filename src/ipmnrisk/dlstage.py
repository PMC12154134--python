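"""Probability-producing image-classifier stage.

A compact, fully seeded 3D convolutional network implemented in NumPy:
three stride-2 conv+ReLU blocks, global mean+std pooling (the std channel
makes within-ROI heterogeneity — the class signal — directly visible to
the head), and a sigmoid output.  Training is plain SGD with momentum 0.9
and batch size 2; the learning rate starts at 0.001 and is divided by 10
every 30 epochs, with 200 epochs by default (``DLConfig.desk()`` switches
to the 32-cubed, 30-epoch configuration used for desk-scale experiments).

The stage is interchangeable with :func:`load_external_scores`: both yield
a P(high risk) vector aligned to the subject order, so externally computed
deep-learning probabilities can be fused without retraining.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["DLConfig", "CNNScorer", "train_cnn_scorer", "load_external_scores"]


@dataclass
class DLConfig:
    input_shape: tuple[int, int, int] = (96, 96, 96)
    optimizer: str = "sgd"
    momentum: float = 0.9
    batch_size: int = 2
    epochs: int = 200
    lr: float = 0.001
    lr_step_epochs: int = 30
    lr_factor: float = 0.1
    architecture: str = "tiny3dcnn"
    channels: tuple[int, ...] = (4, 8, 16)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @classmethod
    def desk(cls, **kw) -> "DLConfig":
        """Desk-scale defaults: 32-cubed inputs, 30 epochs."""
        kw.setdefault("input_shape", (32, 32, 32))
        kw.setdefault("epochs", 30)
        return cls(**kw)

    def dump(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# layers


class _Conv3d:
    """3x3x3 stride-2 convolution with edge zero-padding 1, im2col based."""

    K, S, P = 3, 2, 1

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * self.K**3
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        self.b = np.zeros(c_out)
        self.vW = np.zeros_like(self.W)
        self.vb = np.zeros_like(self.b)
        self.c_in, self.c_out = c_in, c_out

    def _cols(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        # x: (c_in, D, H, W)
        p = self.P
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
        view = sliding_window_view(xp, (self.K, self.K, self.K), axis=(1, 2, 3))
        view = view[:, :: self.S, :: self.S, :: self.S]  # (c_in, Do,Ho,Wo, K,K,K)
        out_sp = view.shape[1:4]
        cols = view.reshape(self.c_in, -1, self.K**3)  # (c_in, N, K3)
        cols = np.moveaxis(cols, 1, 2).reshape(self.c_in * self.K**3, -1)
        return cols, (xp.shape, out_sp)

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, (xp_shape, out_sp) = self._cols(x)
        self._cache = (cols, xp_shape, out_sp, x.shape)
        out = self.W @ cols + self.b[:, None]
        return out.reshape(self.c_out, *out_sp)

    def backward(self, dout: np.ndarray, lr_unused=None) -> np.ndarray:
        cols, xp_shape, out_sp, x_shape = self._cache
        d2 = dout.reshape(self.c_out, -1)
        self.dW = d2 @ cols.T
        self.db = d2.sum(axis=1)
        dcols = self.W.T @ d2  # (c_in*K3, N)
        dcols = dcols.reshape(self.c_in, self.K**3, *out_sp)
        dxp = np.zeros(xp_shape)
        k = 0
        for ki in range(self.K):
            for kj in range(self.K):
                for kk in range(self.K):
                    dxp[
                        :,
                        ki : ki + self.S * out_sp[0] : self.S,
                        kj : kj + self.S * out_sp[1] : self.S,
                        kk : kk + self.S * out_sp[2] : self.S,
                    ] += dcols[:, k]
                    k += 1
        p = self.P
        return dxp[:, p : p + x_shape[1], p : p + x_shape[2], p : p + x_shape[3]]

    def step(self, lr: float, momentum: float) -> None:
        self.vW = momentum * self.vW - lr * self.dW
        self.vb = momentum * self.vb - lr * self.db
        self.W += self.vW
        self.b += self.vb


class _Net:
    EPS = 1e-6

    def __init__(self, config: DLConfig):
        rng = np.random.default_rng(config.seed)
        chans = (1, *config.channels)
        self.convs = [
            _Conv3d(chans[i], chans[i + 1], rng) for i in range(len(config.channels))
        ]
        nf = 2 * config.channels[-1]  # mean + std pooling
        self.w = rng.normal(0.0, 1.0 / np.sqrt(nf), size=nf)
        self.bias = 0.0
        self.vw = np.zeros_like(self.w)
        self.vbias = 0.0

    def forward(self, x: np.ndarray) -> float:
        h = x[None]  # (1, D, H, W)
        self._relu_masks = []
        for conv in self.convs:
            h = conv.forward(h)
            mask = h > 0
            h = h * mask
            self._relu_masks.append(mask)
        c = h.shape[0]
        flat = h.reshape(c, -1)
        mu = flat.mean(axis=1)
        var = flat.var(axis=1)
        sd = np.sqrt(var + self.EPS)
        self._pool_cache = (h, flat, mu, sd)
        feat = np.concatenate([mu, sd])
        self._feat = feat
        return float(feat @ self.w + self.bias)

    def backward(self, dlogit: float) -> None:
        h, flat, mu, sd = self._pool_cache
        c, n = flat.shape
        self.dw = dlogit * self._feat
        self.dbias = dlogit
        dfeat = dlogit * self.w
        dmu, dsd = dfeat[:c], dfeat[c:]
        dflat = dmu[:, None] / n + dsd[:, None] * (flat - mu[:, None]) / (n * sd[:, None])
        dh = dflat.reshape(h.shape)
        for conv, mask in zip(reversed(self.convs), reversed(self._relu_masks)):
            dh = dh * mask
            dh = conv.backward(dh)

    def step(self, lr: float, momentum: float) -> None:
        for conv in self.convs:
            conv.step(lr, momentum)
        self.vw = momentum * self.vw - lr * self.dw
        self.vbias = momentum * self.vbias - lr * self.dbias
        self.w += self.vw
        self.bias += self.vbias


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


class CNNScorer:
    """Trained network wrapper: volumes -> P(high risk) in [0, 1]."""

    def __init__(self, net: _Net, config: DLConfig):
        self._net = net
        self.config = config

    def __call__(self, volumes) -> np.ndarray:
        probs = []
        for v in volumes:
            arr = _standardize(np.asarray(getattr(v, "data", v), dtype=float))
            logit = self._net.forward(arr)
            probs.append(1.0 / (1.0 + np.exp(-logit)))
        return np.asarray(probs)


def train_cnn_scorer(volumes, labels, config: DLConfig | None = None) -> CNNScorer:
    """Train the seeded 3D CNN; returns a probability scorer.

    ``volumes`` are ROI crops already resized to ``config.input_shape``
    (see :func:`ipmnrisk.prep.crop_resize_roi`).  The configured SGD
    momentum / batch-size / step-LR schedule is applied as given.
    """

    config = config or DLConfig()
    labels = np.asarray(labels, dtype=int)
    for cls in (0, 1):
        if (labels == cls).sum() < 2:
            raise ValueError("need at least 2 subjects per class")
    X = [
        _standardize(np.asarray(getattr(v, "data", v), dtype=float)) for v in volumes
    ]
    for x in X:
        if x.shape != tuple(config.input_shape):
            raise ValueError(
                f"volume shape {x.shape} != configured input {config.input_shape}"
            )

    net = _Net(config)
    rng = np.random.default_rng(config.seed + 1)
    n = len(X)
    for epoch in range(config.epochs):
        lr = config.lr * config.lr_factor ** (epoch // config.lr_step_epochs)
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            grads_accumulated = False
            for i in batch:
                logit = net.forward(X[i])
                p = 1.0 / (1.0 + np.exp(-logit))
                dlogit = (p - labels[i]) / len(batch)  # BCE-with-logits gradient
                if grads_accumulated:
                    dw, dbias = net.dw.copy(), net.dbias
                    dconv = [(c.dW.copy(), c.db.copy()) for c in net.convs]
                    net.backward(dlogit)
                    net.dw += dw
                    net.dbias += dbias
                    for c, (dW0, db0) in zip(net.convs, dconv):
                        c.dW += dW0
                        c.db += db0
                else:
                    net.backward(dlogit)
                    grads_accumulated = True
            net.step(lr, config.momentum)
    return CNNScorer(net, config)


def load_external_scores(
    scores: str | pd.DataFrame, subject_table: pd.DataFrame
) -> np.ndarray:
    """Load externally computed probabilities aligned to subject order.

    ``scores`` is a CSV path or DataFrame with columns subject_id, prob.
    Missing subjects, duplicate ids, or probabilities outside [0, 1] raise.
    """

    df = pd.read_csv(scores) if isinstance(scores, str) else scores
    if not {"subject_id", "prob"} <= set(df.columns):
        raise ValueError("scores must have columns subject_id, prob")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject id(s): {sorted(set(dup))}")
    lut = df.set_index("subject_id")["prob"]
    out = []
    for sid in subject_table["subject_id"]:
        if sid not in lut.index:
            raise ValueError(f"missing score for subject {sid}")
        p = float(lut[sid])
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"probability {p} for subject {sid} outside [0, 1]")
        out.append(p)
    return np.asarray(out)
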