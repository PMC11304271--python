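"""Conditional-GAN backbone: encoder -> 1-D bottleneck profile -> decoder.

The generator condenses a bright-field image into a 1-D bottleneck vector
(the morphological profile) and reconstructs/translates it into a
quantitative phase image through a transposed-convolution decoder with
optional skip connections; a patch-level discriminator on (BF, QPI) pairs
provides the adversarial feedback.  Pre-training (reconstruction MSE +
adversarial term) yields the *no-CytoMAD* stage; the distillation stage
(:mod:`cytomad.distillator`) upgrades it to the *CytoMAD* stage.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import nn
from .nn import Tensor
from .synthetic import Dataset

__all__ = [
    "BackboneConfig",
    "TrainConfig",
    "MorphProfile",
    "BackboneModel",
    "build_backbone",
    "pretrain_backbone",
    "translate",
    "encode_profile",
    "encode_profiles",
    "save_model",
    "load_model",
]


@dataclass
class BackboneConfig:
    image_size_px: int = 64
    bottleneck_dim: int = 256
    n_levels: int = 3
    base_filters: int = 16
    skip_connections: bool = True
    mode: str = "translate"  # "translate" | "autoencode"

    def __post_init__(self):
        if self.image_size_px % (2**self.n_levels) != 0:
            raise ValueError("image_size_px must be divisible by 2**n_levels")
        if self.bottleneck_dim < 8:
            raise ValueError("bottleneck_dim must be >= 8")
        if self.mode not in ("translate", "autoencode"):
            raise ValueError("mode must be 'translate' or 'autoencode'")


@dataclass
class TrainConfig:
    epochs: int = 20
    minibatch_size: int = 16
    learning_rate: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    seed: int = 0
    deterministic_mode: bool = True

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class MorphProfile:
    """The 1-D bottleneck feature vector(s) of one or more cells."""

    values: np.ndarray
    stage: str = "no_cytomad"  # "no_cytomad" | "cytomad"


class _Generator(nn.Module):
    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        ch = [min(cfg.base_filters * 2**i, cfg.base_filters * 4) for i in range(cfg.n_levels)]
        self.channels = ch
        self.enc_convs: list[nn.Module] = []
        self.enc_bns: list[nn.Module] = []
        c_in = 1
        for i, c in enumerate(ch):
            conv = nn.Conv2d(c_in, c, rng)
            self.enc_convs.append(conv)
            self._modules[f"enc{i}"] = conv
            bn = nn.BatchNorm(c) if i > 0 else None
            self.enc_bns.append(bn)
            if bn is not None:
                self._modules[f"enc_bn{i}"] = bn
            c_in = c
        self.spatial = cfg.image_size_px // 2**cfg.n_levels
        flat = ch[-1] * self.spatial**2
        self.fc_enc = nn.Linear(flat, cfg.bottleneck_dim, rng)
        self.fc_dec = nn.Linear(cfg.bottleneck_dim, flat, rng)
        self.dec_convs: list[nn.Module] = []
        self.dec_bns: list[nn.Module] = []
        for j in range(cfg.n_levels):
            src = ch[cfg.n_levels - 1 - j]
            skip_c = (
                ch[cfg.n_levels - 1 - j]
                if (cfg.skip_connections and j >= 1)
                else 0
            )
            dst = 1 if j == cfg.n_levels - 1 else ch[cfg.n_levels - 2 - j]
            deconv = nn.ConvTranspose2d(src + skip_c, dst, rng)
            self.dec_convs.append(deconv)
            self._modules[f"dec{j}"] = deconv
            bn = nn.BatchNorm(dst) if j < cfg.n_levels - 1 else None
            self.dec_bns.append(bn)
            if bn is not None:
                self._modules[f"dec_bn{j}"] = bn

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Return (bottleneck profile, output image), both as Tensors."""
        acts = []
        h = x
        for i, conv in enumerate(self.enc_convs):
            h = conv(h)
            if self.enc_bns[i] is not None:
                h = self.enc_bns[i](h)
            h = h.leaky_relu(0.2)
            acts.append(h)
        n = h.shape[0]
        profile = self.fc_enc(h.reshape(n, -1))
        h = self.fc_dec(profile).relu()
        h = h.reshape(n, self.channels[-1], self.spatial, self.spatial)
        L = self.cfg.n_levels
        for j, deconv in enumerate(self.dec_convs):
            if self.cfg.skip_connections and j >= 1:
                h = nn.concat([h, acts[L - 1 - j]], axis=1)
            h = deconv(h)
            if self.dec_bns[j] is not None:
                h = self.dec_bns[j](h).relu()
        return profile, h.sigmoid()


class _Discriminator(nn.Module):
    """Patch-level real/fake classifier on (BF, candidate QPI) pairs."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        super().__init__()
        f = cfg.base_filters
        self.c1 = nn.Conv2d(2, f, rng)
        self.c2 = nn.Conv2d(f, 2 * f, rng)
        self.bn2 = nn.BatchNorm(2 * f)
        self.c3 = nn.Conv2d(2 * f, 1, rng, k=4, stride=1, pad=1)

    def forward(self, bf: Tensor, qpi: Tensor) -> Tensor:
        h = nn.concat([bf, qpi], axis=1)
        h = self.c1(h).leaky_relu(0.2)
        h = self.bn2(self.c2(h)).leaky_relu(0.2)
        return self.c3(h)


class BackboneModel(nn.Module):
    """Generator + discriminator pair with a stage tag."""

    def __init__(self, cfg: BackboneConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.generator = _Generator(cfg, rng)
        self.discriminator = _Discriminator(cfg, rng)
        self.stage = "no_cytomad"

    # numpy-facing inference helpers -------------------------------------
    def _check(self, bf: np.ndarray) -> np.ndarray:
        bf = np.asarray(bf, dtype=np.float32)
        single = bf.ndim == 2
        if single:
            bf = bf[None]
        if bf.ndim != 3 or bf.shape[1] != self.cfg.image_size_px or bf.shape[2] != self.cfg.image_size_px:
            raise ValueError(
                f"expected (n, {self.cfg.image_size_px}, {self.cfg.image_size_px}) "
                f"bright-field input, got {bf.shape}"
            )
        return bf, single

    def infer(self, bf: np.ndarray, batch: int = 64) -> tuple[np.ndarray, np.ndarray]:
        """Profiles and translated images for a stack of BF images."""
        bf, single = self._check(bf)
        was_training = self.training
        self.eval()
        profs, outs = [], []
        for i in range(0, len(bf), batch):
            p, y = self.generator(Tensor(bf[i : i + batch, None]))
            profs.append(p.data)
            outs.append(y.data[:, 0])
        self.train(was_training)
        prof = np.concatenate(profs)
        out = np.concatenate(outs)
        if single:
            return prof[0], out[0]
        return prof, out


def build_backbone(cfg: BackboneConfig, seed: int = 0) -> BackboneModel:
    """Seeded construction of the generator/discriminator pair."""
    return BackboneModel(cfg, seed)


def translate(model: BackboneModel, bf: np.ndarray) -> np.ndarray:
    """Predicted QPI for a BF image (or stack); values in [0, 1]."""
    return model.infer(bf)[1]


def encode_profile(model: BackboneModel, bf: np.ndarray) -> MorphProfile:
    """Bottleneck profile of one BF image."""
    return MorphProfile(values=model.infer(bf)[0], stage=model.stage)


def encode_profiles(model: BackboneModel, bf_stack: np.ndarray) -> MorphProfile:
    """Bottleneck profiles of a stack of BF images, shape (n, bottleneck_dim)."""
    return MorphProfile(values=model.infer(bf_stack)[0], stage=model.stage)


def _training_arrays(model: BackboneModel, dataset: Dataset):
    bf = dataset.bf.astype(np.float32)
    if model.cfg.mode == "autoencode":
        target = bf
    else:
        target = dataset.qpi_clean.astype(np.float32)
    if bf.shape[0] == 0:
        raise ValueError("dataset is empty")
    return bf[:, None], target[:, None]


def pretrain_backbone(
    model: BackboneModel,
    dataset: Dataset,
    tc: TrainConfig,
    loss_weights: tuple[float, float] = (100.0, 1.0),
) -> tuple[BackboneModel, pd.DataFrame]:
    """Alternating discriminator/generator pre-training for contrast translation.

    Generator objective: ``W_gen * MSE(prediction, target) + W_dis * adversarial``.
    Returns the model (stage stays ``no_cytomad``) and a per-epoch history of
    the component losses.
    """
    w_gen, w_dis = loss_weights
    x, t = _training_arrays(model, dataset)
    rng = np.random.default_rng(tc.seed)
    opt_g = nn.Adam(model.generator.parameters(), tc.learning_rate, tc.beta1, tc.beta2)
    opt_d = nn.Adam(model.discriminator.parameters(), tc.learning_rate, tc.beta1, tc.beta2)
    history = []
    n = x.shape[0]
    for epoch in range(tc.epochs):
        order = rng.permutation(n)
        ep = {"epoch": epoch, "gen_mse": 0.0, "gen_adv": 0.0, "gen_total": 0.0, "disc_loss": 0.0}
        nb = 0
        for i in range(0, n, tc.minibatch_size):
            idx = order[i : i + tc.minibatch_size]
            if len(idx) < 2:  # batch norm needs at least 2 samples
                continue
            xb = Tensor(x[idx])
            tb = x_t = t[idx]
            # discriminator step
            _, fake = model.generator(xb)
            d_real = model.discriminator(xb, Tensor(x_t))
            d_fake = model.discriminator(xb, fake.detach())
            d_loss = nn.sigmoid_bce_with_logits(d_real, 1.0) + nn.sigmoid_bce_with_logits(d_fake, 0.0)
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()
            # generator step
            _, fake = model.generator(xb)
            g_mse = nn.mse_loss(fake, tb)
            d_out = model.discriminator(xb, fake)
            g_adv = nn.sigmoid_bce_with_logits(d_out, 1.0)
            g_loss = w_gen * g_mse + w_dis * g_adv
            opt_g.zero_grad()
            model.discriminator.zero_grad()
            g_loss.backward()
            opt_g.step()
            ep["gen_mse"] += float(g_mse.data)
            ep["gen_adv"] += float(g_adv.data)
            ep["gen_total"] += float(g_loss.data)
            ep["disc_loss"] += float(d_loss.data)
            nb += 1
        for k in ("gen_mse", "gen_adv", "gen_total", "disc_loss"):
            ep[k] /= max(nb, 1)
        history.append(ep)
    cols = ["epoch", "gen_mse", "gen_adv", "gen_total", "disc_loss"]
    return model, pd.DataFrame(history, columns=cols)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------
def save_model(model: BackboneModel, path: str) -> None:
    """Single-file npz archive with a JSON config sidecar."""
    state = model.state_dict()
    np.savez(path, **state)
    meta = {"config": asdict(model.cfg), "stage": model.stage}
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_model(path: str) -> BackboneModel:
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    model = BackboneModel(BackboneConfig(**meta["config"]))
    p = str(path)
    if not p.endswith(".npz"):
        p = p + ".npz"
    with np.load(p) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    model.stage = meta["stage"]
    return model
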