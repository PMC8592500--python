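"""Convolutional epileptic seizure predictor (CESP).

A deliberately small CNN: three blocks of [3x3 stride-1 convolution, ReLU,
2x2 max pooling] with 126, 64 and 64 filters, then fully connected layers of
width 32 and 2, both with sigmoid activations.  The two output units are
independent sigmoids trained with binary cross-entropy against one-hot
targets (interictal, pre-ictal); the pre-ictal unit's score is the ranking
statistic for ROC analysis.  Training uses stratified k-fold cross-validation
for reporting (k=10 by default) and the deployed model is refit on the full
training split.

Note the 126-filter first block is kept as printed in the architecture it
follows, not rounded to 128; it is config-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import nn
from .preprocess import SpectrogramImage, images_to_array
from .synthetic import LABELS, PREICTAL

#: class order for one-hot targets; pre-ictal is output unit 1
CLASS_ORDER = LABELS


@dataclass(frozen=True)
class CESPConfig:
    conv_filters: tuple = (126, 64, 64)
    kernel: int = 3
    fc_sizes: tuple = (32, 2)
    lr: float = 1e-4
    folds: int = 10
    epochs: int = 50
    batch_size: int = 32
    patience: int = 10            # early stop on fold-validation loss
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.fc_sizes[-1] != 2:
            raise ValueError("final FC size must equal the number of classes (2)")


#: scaled-down configuration for fast CPU runs on 64x64 images; the higher
#: learning rate compensates for the far smaller model and epoch budget
DESK_CESP = CESPConfig(conv_filters=(16, 16, 16), folds=3, epochs=20, lr=1e-3)


def build_cesp(cfg: CESPConfig, in_size: int,
               rng: np.random.Generator | None = None) -> nn.Sequential:
    """(batch, 3, S, S) -> (batch, 2) independent sigmoid scores in (0, 1)."""
    n_pools = len(cfg.conv_filters)
    if in_size % (2 ** n_pools):
        raise ValueError(f"input side {in_size} not divisible by {2 ** n_pools}")
    rng = rng or np.random.default_rng(0)
    layers: list[nn.Layer] = []
    c_prev, side = 3, in_size
    for f in cfg.conv_filters:
        # He-scaled init so the signal survives three ReLU conv blocks
        std = float(np.sqrt(2.0 / (c_prev * cfg.kernel**2)))
        layers += [nn.Conv2d(c_prev, f, cfg.kernel, 1, rng, init_std=std),
                   nn.ReLU(), nn.MaxPool2x2()]
        c_prev, side = f, side // 2
    layers.append(nn.Flatten())
    d_prev = c_prev * side * side
    for d in cfg.fc_sizes:
        std = float(np.sqrt(2.0 / d_prev))
        layers += [nn.Dense(d_prev, d, rng, init_std=std), nn.Sigmoid()]
        d_prev = d
    return nn.Sequential(layers)


@dataclass
class TrainedCESP:
    model: nn.Sequential
    config: CESPConfig
    in_size: int
    fold_val_accuracy: list[float] = field(default_factory=list)
    fold_val_loss: list[float] = field(default_factory=list)
    fold_assignments: list[np.ndarray] = field(default_factory=list)
    history: list[float] = field(default_factory=list)  # final-fit epoch losses


def _one_hot(labels: list[str]) -> np.ndarray:
    t = np.zeros((len(labels), 2), dtype=nn.DTYPE)
    for i, lab in enumerate(labels):
        t[i, CLASS_ORDER.index(lab)] = 1.0
    return t


def _fit(model: nn.Sequential, x: np.ndarray, t: np.ndarray, cfg: CESPConfig,
         rng: np.random.Generator, epochs: int,
         val: tuple[np.ndarray, np.ndarray] | None = None,
         ) -> tuple[list[float], list[float]]:
    opt = nn.Adam(model.params(), lr=cfg.lr)
    n = x.shape[0]
    bs = min(cfg.batch_size, n)
    losses, val_losses = [], []
    best, since_best = np.inf, 0
    for _ in range(epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        nb = 0
        for s in range(0, n - bs + 1, bs):
            idx = order[s:s + bs]
            opt.zero_grad()
            p = model.forward(x[idx], train=True)
            ep_loss += nn.bce(p, t[idx])
            model.backward(nn.bce_grad(p, t[idx]))
            opt.step()
            nb += 1
        losses.append(ep_loss / max(nb, 1))
        if val is not None:
            vl = nn.bce(model.forward(val[0], train=False), val[1])
            val_losses.append(vl)
            if vl < best - 1e-5:
                best, since_best = vl, 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
    return losses, val_losses


def train_kfold(data: list[SpectrogramImage], cfg: CESPConfig) -> TrainedCESP:
    """Stratified k-fold CV for reporting, then a final fit on all the data."""
    labels = [im.label for im in data]
    if len(set(labels)) < 2:
        raise ValueError("training data must contain both classes")
    if len(data) < cfg.folds:
        raise ValueError(f"need at least folds={cfg.folds} samples")
    x = images_to_array(data).transpose(0, 3, 1, 2)
    t = _one_hot(labels)
    y = t[:, 1].astype(int)
    in_size = x.shape[2]
    out = TrainedCESP(model=build_cesp(cfg, in_size,
                                       np.random.default_rng(cfg.seed)),
                      config=cfg, in_size=in_size)
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    for f, (tr, va) in enumerate(skf.split(x, y)):
        out.fold_assignments.append(va.copy())
        m = build_cesp(cfg, in_size, np.random.default_rng(cfg.seed + 1 + f))
        _, vls = _fit(m, x[tr], t[tr], cfg, np.random.default_rng(cfg.seed + 1 + f),
                      cfg.epochs, val=(x[va], t[va]))
        p = m.forward(x[va], train=False)
        acc = float(np.mean(p.argmax(axis=1) == y[va]))
        out.fold_val_accuracy.append(acc)
        out.fold_val_loss.append(min(vls) if vls else np.nan)
    losses, _ = _fit(out.model, x, t, cfg, np.random.default_rng(cfg.seed),
                     cfg.epochs)
    out.history = losses
    return out


def train_plain(data: list[SpectrogramImage], cfg: CESPConfig) -> TrainedCESP:
    """Fit without cross-validation (used where CV reporting is not needed)."""
    labels = [im.label for im in data]
    if len(set(labels)) < 2:
        raise ValueError("training data must contain both classes")
    x = images_to_array(data).transpose(0, 3, 1, 2)
    t = _one_hot(labels)
    in_size = x.shape[2]
    out = TrainedCESP(model=build_cesp(cfg, in_size,
                                       np.random.default_rng(cfg.seed)),
                      config=cfg, in_size=in_size)
    out.history, _ = _fit(out.model, x, t, cfg, np.random.default_rng(cfg.seed),
                          cfg.epochs)
    return out


def predict(trained: TrainedCESP, images: list[SpectrogramImage],
            normalize: bool = False) -> np.ndarray:
    """Pre-ictal score per image: the raw sigmoid of the pre-ictal unit, or
    (with ``normalize=True``) that score divided by the two-unit sum."""
    if not images:
        return np.zeros(0)
    x = images_to_array(images).transpose(0, 3, 1, 2)
    if x.shape[2] != trained.in_size:
        raise ValueError(f"image side {x.shape[2]} != model side {trained.in_size}")
    scores = []
    for s in range(0, x.shape[0], 128):
        p = trained.model.forward(x[s:s + 128], train=False)
        pre = p[:, CLASS_ORDER.index(PREICTAL)]
        if normalize:
            pre = pre / np.clip(p.sum(axis=1), 1e-12, None)
        scores.append(pre)
    return np.concatenate(scores).astype(np.float64)
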