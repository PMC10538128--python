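"""Learned reconstruction: fully connected network and conditional GAN.

Both networks map the imaginary channel of the normalized capacitance
measurements to the normalized conductivity image (sigma / sigma_max, in
[0, 1]) of the 1856 FOV pixels.

The FCNN is deliberately shallow: input batch normalization, one hidden
affine layer with batch normalization and ReLU, one output affine layer.

The cGAN follows the image-to-image translation recipe: a U-Net generator
conditioned on the 32 x 32 measurement-matrix view (no latent vector;
dropout in the decoder provides stochasticity during training), a
convolutional discriminator scoring (condition, image) pairs, and a
generator loss combining the adversarial binary cross-entropy with heavily
weighted L2 and L1 image terms:

    L_G = BCE(l_p, l_r) + 100 * MSE(y_r, y_p) + 100 * |y_r - y_p|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .geometry import FOVMask, MeasurementIndex
from .dataset import add_noise_array, split_train_val, to_matrix_view

F32 = np.float32


# --------------------------------------------------------------------- FCNN

@dataclass
class FcnnConfig:
    input_size: int = 992
    hidden_size: int = 1856
    output_size: int = 1856
    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 100
    seed: int = 0


def build_fcnn(cfg: FcnnConfig) -> nn.Sequential:
    """Input normalization -> affine -> normalization -> ReLU -> affine."""
    rng = np.random.default_rng(cfg.seed)
    return nn.Sequential(
        nn.BatchNorm(cfg.input_size),
        nn.Dense(cfg.input_size, cfg.hidden_size, rng),
        nn.BatchNorm(cfg.hidden_size),
        nn.ReLU(),
        nn.Dense(cfg.hidden_size, cfg.output_size, rng),
    )


def fcnn_parameter_count(cfg: FcnnConfig) -> int:
    """Trainable parameters: two affine stages plus both normalizations."""
    affine = cfg.input_size * cfg.hidden_size + cfg.hidden_size
    affine += cfg.hidden_size * cfg.output_size + cfg.output_size
    norm = 2 * cfg.input_size + 2 * cfg.hidden_size
    return affine + norm


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)


class DivergenceError(RuntimeError):
    pass


def train_fcnn(
    x: np.ndarray,
    y: np.ndarray,
    cfg: FcnnConfig,
    snr_db: float | None = None,
    val_ratio: float = 0.25,
) -> tuple[nn.Sequential, TrainHistory]:
    """Minimize MSE between predicted and true FOV vectors with Adam.

    ``x`` is (n, 992) measurement vectors, ``y`` is (n, 1856) normalized
    conductivity targets.  ``snr_db`` injects fresh measurement noise into
    each training batch.  Fully seeded and deterministic.
    """
    rng = np.random.default_rng(cfg.seed)
    model = build_fcnn(cfg)
    opt = nn.Adam(model.params(), lr=cfg.lr)
    x = np.asarray(x, dtype=F32)
    y = np.asarray(y, dtype=F32)
    learn_idx, val_idx = split_train_val(len(x), 1.0 - val_ratio, rng)
    xl, yl = x[learn_idx], y[learn_idx]
    xv, yv = x[val_idx], y[val_idx]
    hist = TrainHistory()
    nb = max(1, len(xl) // cfg.batch_size)
    for _ in range(cfg.epochs):
        perm = rng.permutation(len(xl))
        total = 0.0
        for b in range(nb):
            idx = perm[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            xb = xl[idx]
            if snr_db is not None and np.isfinite(snr_db):
                xb = add_noise_array(xb, snr_db, rng).astype(F32)
            pred = model.forward(xb, training=True)
            loss, grad = nn.mse_loss(pred, yl[idx])
            model.backward(grad)
            opt.step()
            total += loss
        hist.train_loss.append(total / nb)
        if len(xv):
            vloss, _ = nn.mse_loss(model.forward(xv, training=False), yv)
            hist.val_loss.append(vloss)
            if not np.isfinite(vloss):
                raise DivergenceError("validation loss diverged (NaN)")
    return model, hist


# --------------------------------------------------------------------- cGAN

@dataclass
class CganConfig:
    enc_channels: tuple = (32, 64, 128, 256)
    dropout: float = 0.5
    lr: float = 2e-4
    betas: tuple = (0.5, 0.999)
    batch_size: int = 64
    epochs: int = 100
    seed: int = 0
    w_adv: float = 1.0
    w_mse: float = 100.0
    w_l1: float = 100.0
    # discriminator pacing: with small datasets the discriminator overfits
    # and destabilizes training; a lower rate and sparser updates help
    d_lr: float | None = None
    d_every: int = 1
    # bottleneck style: "dense" inserts the linear layer between encoder and
    # decoder (measurement space and image space are not spatially aligned,
    # so a dense map at the bottleneck is what actually transports
    # information between them); "conv" keeps a fully convolutional U-Net
    # with skip connections
    bottleneck: str = "dense"
    dense_width: int = 4096  # linear-layer output, reshaped to 8 x 8 tiles
    # linear learning-rate decay to zero over the second half of training
    # (the standard image-to-image translation schedule); stabilizes the
    # adversarial endpoint
    lr_decay: bool = True


@dataclass(frozen=True)
class GanLossTerms:
    """Inputs of the generator loss: discriminator probability l_p with its
    reference label l_r, and the reference / predicted images."""

    l_r: float
    l_p: np.ndarray
    y_r: np.ndarray
    y_p: np.ndarray


def generator_loss(
    terms: GanLossTerms, w_adv: float = 1.0, w_mse: float = 100.0, w_l1: float = 100.0
) -> float:
    """Adversarial + weighted L2 and L1 image terms (means over pixels)."""
    l_p = np.asarray(terms.l_p, dtype=np.float64)
    if np.any(l_p <= 0) or np.any(l_p >= 1):
        raise ValueError("discriminator probability must lie in (0, 1)")
    target = np.full_like(l_p, terms.l_r)
    bce, _ = nn.bce_loss(l_p, target, eps=0.0 if 0 < terms.l_r < 1 else 1e-12)
    mse = float(np.mean((terms.y_r - terms.y_p) ** 2))
    l1 = float(np.mean(np.abs(terms.y_r - terms.y_p)))
    return w_adv * bce + w_mse * mse + w_l1 * l1


class UnetGenerator(nn.Layer):
    """U-Net: 32x32 condition in, 64x64 image out, sigmoid output.

    Encoder halves the spatial size per block; the decoder mirrors it with
    transposed convolutions, dropout and skip connections, then upsamples
    twice more to reach 64 x 64.
    """

    def __init__(self, cfg: CganConfig, rng: np.random.Generator):
        c1, c2, c3, c4 = cfg.enc_channels
        self.e1 = nn.Sequential(nn.Conv2d(1, c1, 4, 2, 1, rng), nn.LeakyReLU())
        self.e2 = nn.Sequential(
            nn.Conv2d(c1, c2, 4, 2, 1, rng), nn.BatchNorm(c2), nn.LeakyReLU()
        )
        self.e3 = nn.Sequential(
            nn.Conv2d(c2, c3, 4, 2, 1, rng), nn.BatchNorm(c3), nn.LeakyReLU()
        )
        self.e4 = nn.Sequential(
            nn.Conv2d(c3, c4, 4, 2, 1, rng), nn.BatchNorm(c4), nn.LeakyReLU()
        )
        self.d1 = nn.Sequential(
            nn.ConvTranspose2d(c4, c3, 4, 2, 1, rng),
            nn.BatchNorm(c3),
            nn.Dropout(cfg.dropout, rng),
            nn.ReLU(),
        )
        self.d2 = nn.Sequential(
            nn.ConvTranspose2d(2 * c3, c2, 4, 2, 1, rng),
            nn.BatchNorm(c2),
            nn.Dropout(cfg.dropout, rng),
            nn.ReLU(),
        )
        self.d3 = nn.Sequential(
            nn.ConvTranspose2d(2 * c2, c1, 4, 2, 1, rng),
            nn.BatchNorm(c1),
            nn.ReLU(),
        )
        self.d4 = nn.Sequential(
            nn.ConvTranspose2d(2 * c1, 16, 4, 2, 1, rng),
            nn.BatchNorm(16),
            nn.ReLU(),
        )
        self.d5 = nn.Sequential(
            nn.ConvTranspose2d(16, 8, 4, 2, 1, rng),
            nn.BatchNorm(8),
            nn.ReLU(),
        )
        self.out = nn.Sequential(nn.Conv2d(8, 1, 3, 1, 1, rng), nn.Sigmoid())
        self._blocks = {
            "e1": self.e1, "e2": self.e2, "e3": self.e3, "e4": self.e4,
            "d1": self.d1, "d2": self.d2, "d3": self.d3, "d4": self.d4,
            "d5": self.d5, "out": self.out,
        }

    def forward(self, x, training=False):
        a1 = self.e1.forward(x, training)   # 16
        a2 = self.e2.forward(a1, training)  # 8
        a3 = self.e3.forward(a2, training)  # 4
        a4 = self.e4.forward(a3, training)  # 2
        u1 = self.d1.forward(a4, training)  # 4
        u2 = self.d2.forward(np.concatenate([u1, a3], axis=1), training)  # 8
        u3 = self.d3.forward(np.concatenate([u2, a2], axis=1), training)  # 16
        u4 = self.d4.forward(np.concatenate([u3, a1], axis=1), training)  # 32
        u5 = self.d5.forward(u4, training)  # 64
        self._c = (a1.shape[1], a2.shape[1], a3.shape[1])
        return self.out.forward(u5, training)

    def backward(self, grad):
        c1, c2, c3 = self._c
        g = self.out.backward(grad)
        g = self.d5.backward(g)
        g = self.d4.backward(g)
        g, g_a1 = g[:, :-c1], g[:, -c1:]
        g = self.d3.backward(g)
        g, g_a2 = g[:, :-c2], g[:, -c2:]
        g = self.d2.backward(g)
        g, g_a3 = g[:, :-c3], g[:, -c3:]
        g = self.d1.backward(g)
        g = self.e4.backward(g)
        g = self.e3.backward(g + g_a3)
        g = self.e2.backward(g + g_a2)
        return self.e1.backward(g + g_a1)

    def params(self):
        out = []
        for bname, block in self._blocks.items():
            out.extend((f"{bname}.{n}", p, g) for n, p, g in block.params())
        return out

    def state(self):
        return {
            f"{bname}.{n}": v
            for bname, block in self._blocks.items()
            for n, v in block.state().items()
        }

    def load_state(self, state, prefix=""):
        for bname, block in self._blocks.items():
            sub = {
                n[len(f"{prefix}{bname}.") :]: v
                for n, v in state.items()
                if n.startswith(f"{prefix}{bname}.")
            }
            block.load_state(sub)


class PatchDiscriminator(nn.Layer):
    """Scores (condition, image) pairs with a scalar realness probability."""

    def __init__(self, rng: np.random.Generator):
        self.img_head = nn.Sequential(nn.Conv2d(1, 16, 4, 2, 1, rng), nn.LeakyReLU())
        self.trunk = nn.Sequential(
            nn.Conv2d(17, 32, 4, 2, 1, rng),
            nn.BatchNorm(32),
            nn.LeakyReLU(),
            nn.Conv2d(32, 64, 4, 2, 1, rng),
            nn.BatchNorm(64),
            nn.LeakyReLU(),
            nn.Flatten(),
            nn.Dense(64 * 8 * 8, 1, rng),
            nn.Sigmoid(),
        )

    def forward(self, cond_img, training=False):
        cond, img = cond_img
        h = self.img_head.forward(img, training)  # (B, 16, 32, 32)
        z = np.concatenate([h, cond], axis=1)
        return self.trunk.forward(z, training)

    def backward(self, grad):
        g = self.trunk.backward(grad)
        g_img = self.img_head.backward(g[:, :-1])
        g_cond = g[:, -1:]
        return (g_cond, g_img)

    def params(self):
        out = [(f"img_head.{n}", p, g) for n, p, g in self.img_head.params()]
        out += [(f"trunk.{n}", p, g) for n, p, g in self.trunk.params()]
        return out

    def state(self):
        out = {f"img_head.{n}": v for n, v in self.img_head.state().items()}
        out.update({f"trunk.{n}": v for n, v in self.trunk.state().items()})
        return out

    def load_state(self, state, prefix=""):
        self.img_head.load_state(
            {n[len(prefix) + 9 :]: v for n, v in state.items() if n.startswith(prefix + "img_head.")}
        )
        self.trunk.load_state(
            {n[len(prefix) + 6 :]: v for n, v in state.items() if n.startswith(prefix + "trunk.")}
        )


class DenseBottleneckGenerator(nn.Layer):
    """Encoder K-blocks, a linear bottleneck, and a deconvolution decoder.

    The 32 x 32 measurement-matrix condition is encoded with strided
    convolutions, flattened through a dense layer that maps measurement
    features into image space, and decoded with transposed-convolution
    blocks up to the 64 x 64 image.  No skip connections: encoder feature
    maps live in measurement coordinates and do not align with image
    pixels.
    """

    def __init__(self, cfg: CganConfig, rng: np.random.Generator):
        c1, c2, c3, c4 = cfg.enc_channels
        self.enc = nn.Sequential(
            nn.Conv2d(1, c1, 4, 2, 1, rng),
            nn.LeakyReLU(),
            nn.Conv2d(c1, c2, 4, 2, 1, rng),
            nn.BatchNorm(c2),
            nn.LeakyReLU(),
            nn.Conv2d(c2, c3, 4, 2, 1, rng),
            nn.BatchNorm(c3),
            nn.LeakyReLU(),
            nn.Conv2d(c3, c4, 4, 2, 1, rng),
            nn.BatchNorm(c4),
            nn.LeakyReLU(),
            nn.Flatten(),
        )
        width = cfg.dense_width
        if width % 64:
            raise ValueError("dense_width must be divisible by 64 (8 x 8 tiles)")
        self._dec_c = width // 64
        self.bottleneck = nn.Sequential(
            nn.Dense(c4 * 4, width, rng), nn.BatchNorm(width), nn.ReLU()
        )
        dc = self._dec_c
        self.dec = nn.Sequential(
            nn.ConvTranspose2d(dc, 32, 4, 2, 1, rng),  # 8 -> 16
            nn.BatchNorm(32),
            nn.Dropout(cfg.dropout, rng),
            nn.ReLU(),
            nn.ConvTranspose2d(32, 16, 4, 2, 1, rng),  # 16 -> 32
            nn.BatchNorm(16),
            nn.Dropout(cfg.dropout, rng),
            nn.ReLU(),
            nn.ConvTranspose2d(16, 8, 4, 2, 1, rng),  # 32 -> 64
            nn.BatchNorm(8),
            nn.ReLU(),
            nn.Conv2d(8, 1, 3, 1, 1, rng),
            nn.Sigmoid(),
        )
        self._blocks = {"enc": self.enc, "bottleneck": self.bottleneck, "dec": self.dec}

    def forward(self, x, training=False):
        z = self.bottleneck.forward(self.enc.forward(x, training), training)
        B = z.shape[0]
        return self.dec.forward(z.reshape(B, self._dec_c, 8, 8), training)

    def backward(self, grad):
        g = self.dec.backward(grad)
        g = self.bottleneck.backward(g.reshape(g.shape[0], -1))
        return self.enc.backward(g)

    def params(self):
        out = []
        for bname, block in self._blocks.items():
            out.extend((f"{bname}.{n}", p, g) for n, p, g in block.params())
        return out

    def state(self):
        return {
            f"{bname}.{n}": v
            for bname, block in self._blocks.items()
            for n, v in block.state().items()
        }

    def load_state(self, state, prefix=""):
        for bname, block in self._blocks.items():
            sub = {
                n[len(f"{prefix}{bname}.") :]: v
                for n, v in state.items()
                if n.startswith(f"{prefix}{bname}.")
            }
            block.load_state(sub)


def build_generator(cfg: CganConfig, rng: np.random.Generator) -> nn.Layer:
    if cfg.bottleneck == "dense":
        return DenseBottleneckGenerator(cfg, rng)
    if cfg.bottleneck == "conv":
        return UnetGenerator(cfg, rng)
    raise ValueError(f"unknown bottleneck style {cfg.bottleneck!r}")


class ModeCollapseError(RuntimeError):
    pass


def measurements_to_condition(x: np.ndarray, index: MeasurementIndex) -> np.ndarray:
    """(B, M) imaginary-channel vectors -> (B, 1, K, K) condition images."""
    view = to_matrix_view(np.asarray(x, dtype=F32), index)
    return view.m[:, None]


def train_cgan(
    x: np.ndarray,
    y: np.ndarray,
    fov: FOVMask,
    index: MeasurementIndex,
    cfg: CganConfig,
    snr_db: float | None = None,
    epoch_callback=None,
) -> tuple[UnetGenerator, TrainHistory]:
    """Alternating generator/discriminator training.

    ``x`` (n, M) measurement vectors, ``y`` (n, n_fov) normalized
    conductivity targets.  The discriminator minimizes BCE on (condition,
    image) pairs; the generator minimizes the adversarial term plus the
    weighted L1/L2 FOV-pixel terms.  Aborts if the discriminator collapses
    (loss < 1e-4 for 5 consecutive epochs).
    """
    rng = np.random.default_rng(cfg.seed)
    G = build_generator(cfg, rng)
    D = PatchDiscriminator(rng)
    optG = nn.Adam(G.params(), lr=cfg.lr, betas=cfg.betas)
    optD = nn.Adam(D.params(), lr=cfg.d_lr if cfg.d_lr is not None else cfg.lr, betas=cfg.betas)
    x = np.asarray(x, dtype=F32)
    y = np.asarray(y, dtype=F32)
    n = len(x)
    mask = fov.mask
    n_fov = fov.n_fov
    hist = TrainHistory()
    nb = max(1, n // cfg.batch_size)
    collapse_run = 0
    step = 0
    half = cfg.epochs // 2
    for epoch in range(cfg.epochs):
        if cfg.lr_decay and epoch >= half:
            scale = (cfg.epochs - epoch) / max(1, cfg.epochs - half)
            optG.lr = cfg.lr * scale
            optD.lr = (cfg.d_lr if cfg.d_lr is not None else cfg.lr) * scale
        perm = rng.permutation(n)
        g_total = d_total = 0.0
        for b in range(nb):
            idx = perm[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            xb = x[idx]
            if snr_db is not None and np.isfinite(snr_db):
                xb = add_noise_array(xb, snr_db, rng).astype(F32)
            cond = measurements_to_condition(xb, index)
            B = len(idx)
            y_img = np.zeros((B, 1, mask.shape[0], mask.shape[1]), dtype=F32)
            y_img[:, 0, mask] = y[idx]

            # --- generator step (one shared generator forward; the fake is
            # reused, detached, for the discriminator update below)
            fake = G.forward(cond, training=True)
            p = D.forward((cond, fake), training=True)
            adv, grad_adv = nn.bce_loss(p, np.ones_like(p))
            _, g_img = D.backward(cfg.w_adv * grad_adv)
            fake_fov = fake[:, 0, mask]
            diff = fake_fov - y[idx]
            mse = float(np.mean(diff**2))
            l1 = float(np.mean(np.abs(diff)))
            g_fov = cfg.w_mse * (2.0 / diff.size) * diff + cfg.w_l1 * np.sign(diff) / diff.size
            g_total_img = g_img.astype(F32)
            g_total_img[:, 0, mask] += g_fov.astype(F32)
            G.backward(g_total_img)
            optG.step()
            g_total += cfg.w_adv * adv + cfg.w_mse * mse + cfg.w_l1 * l1

            # --- discriminator step
            step += 1
            if step % cfg.d_every:
                d_total += hist.val_loss[-1] if hist.val_loss else 2 * np.log(2)
                continue
            p_real = D.forward((cond, y_img), training=True)
            loss_r, grad_r = nn.bce_loss(p_real, np.ones_like(p_real))
            D.backward(grad_r)
            gr = [g.copy() for _, _, g in D.params()]
            p_fake = D.forward((cond, fake), training=True)
            loss_f, grad_f = nn.bce_loss(p_fake, np.zeros_like(p_fake))
            D.backward(grad_f)
            for (_, _, g), extra in zip(D.params(), gr):
                g += extra
            optD.step()
            d_total += loss_r + loss_f
        hist.train_loss.append(g_total / nb)
        hist.val_loss.append(d_total / nb)
        if d_total / nb < 1e-4:
            collapse_run += 1
            if collapse_run >= 5:
                raise ModeCollapseError("discriminator loss collapsed")
        else:
            collapse_run = 0
        if not np.isfinite(g_total):
            raise DivergenceError("generator loss diverged")
        if epoch_callback is not None:
            epoch_callback(epoch, G)
    return G, hist


def reconstruct_fcnn(model: nn.Sequential, x: np.ndarray) -> np.ndarray:
    """Deterministic FCNN inference: (B, M) -> (B, n_fov)."""
    return model.forward(np.asarray(x, dtype=F32), training=False)


def reconstruct_cgan(
    G: nn.Layer, x: np.ndarray, fov: FOVMask, index: MeasurementIndex,
    batch_size: int = 256,
) -> np.ndarray:
    """Deterministic cGAN inference (dropout off): (B, M) -> (B, n_fov)."""
    x = np.asarray(x, dtype=F32)
    outs = []
    for i in range(0, len(x), batch_size):
        cond = measurements_to_condition(x[i : i + batch_size], index)
        img = G.forward(cond, training=False)
        outs.append(img[:, 0, fov.mask])
    return np.concatenate(outs, axis=0)


# ------------------------------------------------------------ persistence

def save_model(path: str, kind: str, model: nn.Layer, cfg) -> None:
    """Persist a model's weights and config to an .npz file."""
    import json
    from dataclasses import asdict

    arrays = {f"state/{k}": v for k, v in model.state().items()}
    np.savez(
        path,
        kind=np.array(kind),
        config=np.array(json.dumps(asdict(cfg))),
        **arrays,
    )


def load_model(path: str):
    """Rebuild a model saved with :func:`save_model`; returns (kind, model, cfg)."""
    import json

    from .diagnostic import ClassifierConfig, build_classifier

    data = np.load(path, allow_pickle=False)
    kind = str(data["kind"])
    cfg_dict = json.loads(str(data["config"]))
    state = {k[len("state/") :]: data[k] for k in data.files if k.startswith("state/")}
    for key in ("enc_channels", "betas", "channels"):
        if key in cfg_dict and isinstance(cfg_dict[key], list):
            cfg_dict[key] = tuple(cfg_dict[key])
    if kind == "fcnn":
        cfg = FcnnConfig(**cfg_dict)
        model = build_fcnn(cfg)
    elif kind == "cgan":
        cfg = CganConfig(**cfg_dict)
        model = build_generator(cfg, np.random.default_rng(cfg.seed))
    elif kind == "classifier":
        cfg = ClassifierConfig(**cfg_dict)
        model = build_classifier(cfg)
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    model.load_state(state)
    return kind, model, cfg
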