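"""One-class SVM screening of generated spectrograms.

A nu-parameterized one-class SVM with an RBF kernel is fitted on features of
real spectrograms; generated samples falling outside the learned support
region (negative decision value) are discarded.  The decision function is
sign(sum_i beta_i K(x_i, x) - rho) with K(x, y) = exp(-gamma ||x - y||^2);
nu upper-bounds the fraction of training points treated as outliers.

Features: the 3 replicated image channels are averaged, the result is
bilinearly downsampled to ``feature_downsample`` square and flattened.  The
image representation fed to the SVM is a free choice here and is
config-exposed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as sk_resize
from sklearn.svm import OneClassSVM

from .preprocess import SpectrogramImage


@dataclass(frozen=True)
class SelectorConfig:
    nu: float = 0.1
    gamma: float | str = "scale"   # 1 / (d * Var[x]) heuristic, or a number
    feature_downsample: int = 32

    def __post_init__(self):
        if not (0 < self.nu <= 1):
            raise ValueError("nu must be in (0, 1]")
        if not isinstance(self.gamma, str) and self.gamma <= 0:
            raise ValueError("numeric gamma must be > 0")


@dataclass
class SelectorModel:
    support_vectors: np.ndarray   # (n_sv, d)
    coefficients: np.ndarray      # beta_i, (n_sv,)
    rho: float                    # offset
    gamma: float
    config: SelectorConfig

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """sum_i beta_i exp(-gamma ||x_i - x||^2) - rho for each row of X."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        d2 = ((X[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.gamma * d2) @ self.coefficients - self.rho


@dataclass
class SelectionResult:
    accepted: list[SpectrogramImage]
    rejected: list[SpectrogramImage]

    @property
    def acceptance_rate(self) -> float:
        n = len(self.accepted) + len(self.rejected)
        return len(self.accepted) / n if n else 0.0


def featurize(img: SpectrogramImage, cfg: SelectorConfig) -> np.ndarray:
    """Channel mean -> bilinear downsample -> flat vector of length ds^2."""
    mono = img.pixels.mean(axis=2)
    ds = cfg.feature_downsample
    small = sk_resize(mono, (ds, ds), order=1, mode="edge",
                      anti_aliasing=True, preserve_range=True)
    return small.ravel().astype(np.float64)


def fit_features(X: np.ndarray, cfg: SelectorConfig) -> SelectorModel:
    """Fit the nu-one-class SVM on raw feature vectors."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 10:
        raise ValueError("need a 2-D feature matrix with >= 10 rows")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("all training features identical; add jitter or "
                         "check the inputs")
    # tight solver tolerance keeps decisions permutation-invariant and the
    # training-outlier fraction close to nu; nu=1 exactly is degenerate in
    # libsvm (every point a bounded SV), so it is clamped just below 1
    nu = min(cfg.nu, 1.0 - 1e-3)
    svm = OneClassSVM(kernel="rbf", nu=nu, gamma=cfg.gamma, tol=1e-6)
    svm.fit(X)
    return SelectorModel(support_vectors=svm.support_vectors_.copy(),
                         coefficients=svm.dual_coef_.ravel().copy(),
                         rho=float(-svm.intercept_[0]),
                         gamma=float(svm._gamma),
                         config=cfg)


def fit_ocsvm(real: list[SpectrogramImage], cfg: SelectorConfig) -> SelectorModel:
    """Fit the selector on features of real spectrogram images."""
    if len(real) < 10:
        raise ValueError("need at least 10 real training images")
    X = np.stack([featurize(im, cfg) for im in real])
    return fit_features(X, cfg)


def filter_samples(model: SelectorModel,
                   generated: list[SpectrogramImage]) -> SelectionResult:
    """Partition generated images by the sign of the decision function."""
    if not generated:
        return SelectionResult([], [])
    X = np.stack([featurize(im, model.config) for im in generated])
    dec = model.decision_values(X)
    accepted, rejected = [], []
    for im, v in zip(generated, dec):
        im.accepted = bool(v >= 0)
        (accepted if v >= 0 else rejected).append(im)
    return SelectionResult(accepted, rejected)


def save_selector(model: SelectorModel, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "selector.npz", support_vectors=model.support_vectors,
             coefficients=model.coefficients)
    meta = {"rho": model.rho, "gamma": model.gamma,
            "config": {"nu": model.config.nu, "gamma": model.config.gamma,
                       "feature_downsample": model.config.feature_downsample}}
    (out / "selector.json").write_text(json.dumps(meta, indent=1))
    return out


def load_selector(in_dir: str | Path) -> SelectorModel:
    root = Path(in_dir)
    meta = json.loads((root / "selector.json").read_text())
    with np.load(root / "selector.npz") as z:
        sv, coef = z["support_vectors"], z["coefficients"]
    return SelectorModel(sv, coef, meta["rho"], meta["gamma"],
                         SelectorConfig(**meta["config"]))
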