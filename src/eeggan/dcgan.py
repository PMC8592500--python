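"""Deep convolutional GAN for spectrogram images.

The generator maps 100-dimensional standard-Gaussian latents through a dense
layer (4096 units in the full-size preset, reshaped to 4x4x256) and a stack of
stride-2 5x5 transposed convolutions, doubling the spatial side per layer
(4 * 2^n_deconv = S), followed by a stride-1 5x5 convolution to 3 channels
with a tanh head.  The discriminator is four stride-2 5x5 convolutions
(256/128/64/32 filters in the full preset) with a single sigmoid score.

Loss bookkeeping.  The discriminator objective is the classic two-term value
   d_value = (1/n) sum [log D(x) + log(1 - D(G(z)))]
which the discriminator ascends; as a minimized training loss this is the
binary cross-entropy over real/fake batches, d_bce = -d_value / 2.  The
generator uses the non-saturating loss g = -(1/n) sum log D(G(z)).  The
training history and the early-stopping comparison use (d_bce, g), which are
on a common positive scale; ``d_loss``/``g_loss`` expose the raw formulas.

Early stopping: after every batch, if the discriminator's loss exceeds the
generator's the violation streak is incremented, otherwise it resets to zero;
training stops once the streak reaches ``k`` (default 15) consecutive batches.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .preprocess import SpectrogramImage, images_to_array

LATENT_DIM = 100


@dataclass(frozen=True)
class GeneratorConfig:
    latent_dim: int = LATENT_DIM
    dense_out: int = 4096
    reshape_to: tuple = (4, 4, 256)          # (H, W, C) after the dense layer
    deconv_filters: tuple = (256, 128, 128, 128, 128, 128)
    kernel: int = 5
    stride: int = 2
    output_channels: int = 3
    batchnorm: bool = True

    @property
    def n_deconv(self) -> int:
        return len(self.deconv_filters)

    @property
    def out_size(self) -> int:
        return self.reshape_to[0] * self.stride ** self.n_deconv

    def validate(self, out_size: int) -> None:
        if int(np.prod(self.reshape_to)) != self.dense_out:
            raise ValueError(f"dense_out={self.dense_out} != prod{self.reshape_to}")
        if self.out_size != out_size:
            need = int(np.log2(out_size / self.reshape_to[0]))
            raise ValueError(
                f"{self.n_deconv} stride-{self.stride} deconv layers from side "
                f"{self.reshape_to[0]} give {self.out_size}, not {out_size}; "
                f"need n_deconv={need}")


@dataclass(frozen=True)
class DiscriminatorConfig:
    conv_filters: tuple = (256, 128, 64, 32)
    kernel: int = 5
    stride: int = 2
    leak: float = 0.2
    batchnorm: bool = False

    def validate(self, in_size: int) -> None:
        div = self.stride ** len(self.conv_filters)
        if in_size % div:
            raise ValueError(f"input side {in_size} not divisible by {div}")


#: small configurations for 64x64 images (filters scaled down from the
#: full 256x256 preset so unit tests and CPU runs stay fast)
DESK_GENERATOR = GeneratorConfig(dense_out=4 * 4 * 64, reshape_to=(4, 4, 64),
                                 deconv_filters=(32, 16, 16, 8))
DESK_DISCRIMINATOR = DiscriminatorConfig(conv_filters=(16, 16, 8, 8))


def build_generator(cfg: GeneratorConfig, out_size: int,
                    rng: np.random.Generator | None = None) -> nn.Sequential:
    """Latent (batch, latent_dim) -> images (batch, 3, S, S) in [-1, 1]."""
    cfg.validate(out_size)
    rng = rng or np.random.default_rng(0)
    h, w, c = cfg.reshape_to
    layers: list[nn.Layer] = [nn.Dense(cfg.latent_dim, cfg.dense_out, rng),
                              nn.Reshape((c, h, w))]
    if cfg.batchnorm:
        layers.append(nn.BatchNorm(c))
    layers.append(nn.ReLU())
    c_prev = c
    for f in cfg.deconv_filters:
        layers.append(nn.ConvTranspose2d(c_prev, f, cfg.kernel, cfg.stride, rng))
        if cfg.batchnorm:
            layers.append(nn.BatchNorm(f))
        layers.append(nn.ReLU())
        c_prev = f
    layers += [nn.Conv2d(c_prev, cfg.output_channels, cfg.kernel, 1, rng), nn.Tanh()]
    return nn.Sequential(layers)


def build_discriminator(cfg: DiscriminatorConfig, in_size: int,
                        rng: np.random.Generator | None = None) -> nn.Sequential:
    """Images (batch, 3, S, S) -> probability-of-real (batch, 1) in (0, 1)."""
    cfg.validate(in_size)
    rng = rng or np.random.default_rng(0)
    layers: list[nn.Layer] = []
    c_prev, side = 3, in_size
    for i, f in enumerate(cfg.conv_filters):
        layers.append(nn.Conv2d(c_prev, f, cfg.kernel, cfg.stride, rng))
        if cfg.batchnorm and i > 0:
            layers.append(nn.BatchNorm(f))
        layers.append(nn.LeakyReLU(cfg.leak))
        c_prev, side = f, side // cfg.stride
    layers += [nn.Flatten(), nn.Dense(c_prev * side * side, 1, rng), nn.Sigmoid()]
    return nn.Sequential(layers)


def d_loss(d_real: np.ndarray, d_fake: np.ndarray) -> float:
    """Two-term discriminator value: (1/n) sum [log D(x) + log(1 - D(G(z)))].

    The discriminator maximizes this (equivalently minimizes -value/2, the
    binary cross-entropy over the real and fake batches).
    """
    d_real = np.asarray(d_real, dtype=np.float64).ravel()
    d_fake = np.asarray(d_fake, dtype=np.float64).ravel()
    if d_real.size == 0 or d_fake.size == 0:
        raise ValueError("empty probability batch")
    pr = np.clip(d_real, nn.EPS_PROB, 1 - nn.EPS_PROB)
    pf = np.clip(d_fake, nn.EPS_PROB, 1 - nn.EPS_PROB)
    return float(np.mean(np.log(pr) + np.log(1.0 - pf)))


def g_loss(d_fake: np.ndarray) -> float:
    """Non-saturating generator loss -(1/n) sum log D(G(z)), minimized by G."""
    d_fake = np.asarray(d_fake, dtype=np.float64).ravel()
    if d_fake.size == 0:
        raise ValueError("empty probability batch")
    pf = np.clip(d_fake, nn.EPS_PROB, 1 - nn.EPS_PROB)
    return float(-np.mean(np.log(pf)))


@dataclass
class TrainState:
    epoch: int = 0
    batch: int = 0
    d_loss: float = np.nan          # minimized (BCE) form
    g_loss: float = np.nan
    violation_streak: int = 0
    stopped_early: bool = False
    seed: int = 0
    history: list = field(default_factory=list)  # (d_loss, g_loss) per batch

    def update(self, d: float, g: float, k: int) -> None:
        self.batch += 1
        self.d_loss, self.g_loss = d, g
        self.history.append((d, g))
        if d > g:
            self.violation_streak += 1
        else:
            self.violation_streak = 0
        if self.violation_streak >= k:
            self.stopped_early = True


def replay_early_stop(history: list[tuple[float, float]], k: int) -> int | None:
    """Reference early-stop replay: 1-based index of the stopping batch, or None."""
    streak = 0
    for i, (d, g) in enumerate(history, start=1):
        streak = streak + 1 if d > g else 0
        if streak >= k:
            return i
    return None


@dataclass
class GANModelPair:
    generator: nn.Sequential
    discriminator: nn.Sequential
    gen_cfg: GeneratorConfig
    disc_cfg: DiscriminatorConfig
    out_size: int
    label: str = "preictal"          # class the GAN is trained on
    train_state: TrainState = field(default_factory=TrainState)
    trained: bool = False


def build_gan(gen_cfg: GeneratorConfig, disc_cfg: DiscriminatorConfig,
              out_size: int, label: str = "preictal", seed: int = 0) -> GANModelPair:
    rng = np.random.default_rng(seed)
    return GANModelPair(build_generator(gen_cfg, out_size, rng),
                        build_discriminator(disc_cfg, out_size, rng),
                        gen_cfg, disc_cfg, out_size, label,
                        TrainState(seed=seed))


def train(data: list[SpectrogramImage], gan: GANModelPair, batch_size: int = 32,
          k: int = 15, lr: float = 1e-3, beta1: float = 0.5,
          max_epochs: int = 100, seed: int | None = None) -> GANModelPair:
    """Alternating one-D-step / one-G-step training with early stopping.

    Records the minimized (BCE-form) discriminator loss and the
    non-saturating generator loss per batch; stops when ``d > g`` holds on
    ``k`` consecutive batches or ``max_epochs`` is reached.
    """
    if len(data) < 1:
        raise ValueError("need at least one training image")
    x = images_to_array(data).transpose(0, 3, 1, 2)  # NCHW
    if x.shape[2] != gan.out_size:
        raise ValueError(f"data side {x.shape[2]} != model side {gan.out_size}")
    seed = gan.train_state.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    st = gan.train_state
    st.seed = seed
    g_net, d_net = gan.generator, gan.discriminator
    opt_d = nn.Adam(d_net.params(), lr=lr, beta1=beta1)
    opt_g = nn.Adam(g_net.params(), lr=lr, beta1=beta1)
    n = x.shape[0]
    bs = min(batch_size, n)
    latent = gan.gen_cfg.latent_dim
    for epoch in range(max_epochs):
        st.epoch = epoch + 1
        order = rng.permutation(n)
        for start in range(0, n - bs + 1, bs):
            idx = order[start:start + bs]
            real = x[idx]
            # --- discriminator step
            z = rng.standard_normal((bs, latent)).astype(nn.DTYPE)
            fake = g_net.forward(z, train=True)
            d_in = np.concatenate([real, fake], axis=0)
            targets = np.concatenate([np.ones((bs, 1)), np.zeros((bs, 1))]).astype(nn.DTYPE)
            opt_d.zero_grad()
            p = d_net.forward(d_in, train=True)
            d_bce = nn.bce(p, targets)
            d_net.backward(nn.bce_grad(p, targets))
            opt_d.step()
            # --- generator step (fresh forward through D)
            z = rng.standard_normal((bs, latent)).astype(nn.DTYPE)
            opt_g.zero_grad()
            fake = g_net.forward(z, train=True)
            pf = d_net.forward(fake, train=True)
            g_val = g_loss(pf)
            ones = np.ones_like(pf)
            dfake = d_net.backward(nn.bce_grad(pf, ones))
            g_net.backward(dfake)
            opt_g.step()
            if not (np.isfinite(d_bce) and np.isfinite(g_val)):
                raise FloatingPointError(
                    f"non-finite loss at epoch {st.epoch} batch {st.batch + 1}: "
                    f"d={d_bce}, g={g_val}")
            st.update(d_bce, g_val, k)
            if st.stopped_early:
                break
        # probe invariants on a tiny batch once per epoch
        probe = g_net.forward(rng.standard_normal((2, latent)).astype(nn.DTYPE),
                              train=False)
        assert probe.shape[1:] == (3, gan.out_size, gan.out_size)
        assert np.abs(probe).max() <= 1.0 + 1e-6
        if st.stopped_early:
            break
    gan.trained = True
    return gan


def sample(gan: GANModelPair, n: int, seed: int = 0) -> list[SpectrogramImage]:
    """Draw n images from the generator; z ~ N(0, I_latent)."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, gan.gen_cfg.latent_dim)).astype(nn.DTYPE)
    out = []
    for start in range(0, n, 64):
        imgs = gan.generator.forward(z[start:start + 64], train=False)
        imgs = np.clip(imgs, -1.0, 1.0)
        for im in imgs:
            out.append(SpectrogramImage(im.transpose(1, 2, 0), gan.label,
                                        source="generated"))
    return out


# ---------------------------------------------------------------------------
# checkpointing


def save_gan(gan: GANModelPair, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "generator.npz", *gan.generator.get_weights())
    np.savez(out / "discriminator.npz", *gan.discriminator.get_weights())
    meta = {"gen_cfg": dataclasses.asdict(gan.gen_cfg),
            "disc_cfg": dataclasses.asdict(gan.disc_cfg),
            "out_size": gan.out_size, "label": gan.label,
            "trained": gan.trained,
            "train_state": {f.name: getattr(gan.train_state, f.name)
                            for f in dataclasses.fields(TrainState)}}
    (out / "model.json").write_text(json.dumps(meta, indent=1))
    np.savetxt(out / "loss_history.csv",
               np.asarray(gan.train_state.history or np.zeros((0, 2))),
               delimiter=",", header="d_loss,g_loss", comments="")
    return out


def load_gan(in_dir: str | Path) -> GANModelPair:
    root = Path(in_dir)
    meta = json.loads((root / "model.json").read_text())
    gcfg = GeneratorConfig(**{k: tuple(v) if isinstance(v, list) else v
                              for k, v in meta["gen_cfg"].items()})
    dcfg = DiscriminatorConfig(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in meta["disc_cfg"].items()})
    gan = build_gan(gcfg, dcfg, meta["out_size"], meta["label"])
    with np.load(root / "generator.npz") as z:
        gan.generator.set_weights([z[f] for f in z.files])
    with np.load(root / "discriminator.npz") as z:
        gan.discriminator.set_weights([z[f] for f in z.files])
    ts = meta["train_state"]
    ts["history"] = [tuple(h) for h in ts["history"]]
    gan.train_state = TrainState(**ts)
    gan.trained = meta["trained"]
    return gan
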