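"""Classifier-guided batch-aware morphology distillation.

Frozen batch classifiers and cell-type/state classifiers — at the bottleneck
profile and at the output image — steer further generator training so batch
information is removed while biological information is preserved.  The
composite objective is

    L_total = L_GAN + L_cnn + L_nn
    L_GAN   = W_gen * L_gen  + W_dis * L_dis
    L_cnn   = W_Bcnn * L_Bcnn + W_Ccnn * L_Ccnn     (image-level classifiers)
    L_nn    = W_Bnn * L_Bnn  + W_Cnn * L_Cnn        (bottleneck classifiers)

where the batch terms are, by default, *confusion* losses (cross-entropy of
the frozen batch classifier's output against the uniform distribution over
batches — minimized exactly when the classifier cannot tell batches apart),
and the type terms are ordinary cross-entropy against the true labels.  A
gradient-reversal-style negated cross-entropy is available via
``batch_loss="negated"``.

The bottleneck batch classifier is split into M mini-classifiers over equal
contiguous profile segments; batch classifiers are periodically re-fitted on
the current generator outputs (default every 10 epochs) and re-frozen.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .nn import Tensor
from .backbone import BackboneModel, TrainConfig
from .synthetic import Dataset

__all__ = [
    "LossWeights",
    "LossBundle",
    "ClassifierTrainConfig",
    "ClassifierSet",
    "DenseClassifier",
    "ConvClassifier",
    "pretrain_classifiers",
    "batch_confusion_loss",
    "assemble_loss",
    "train_cytomad",
    "classifier_hashes",
]

EPS = 1e-12


# ---------------------------------------------------------------------------
# classifier architectures
# ---------------------------------------------------------------------------
class DenseClassifier(nn.Module):
    """3 dense layers (75/50/25 nodes, rectifier) + softmax output."""

    def __init__(self, n_in: int, n_classes: int, rng: np.random.Generator,
                 hidden: tuple[int, int, int] = (75, 50, 25)):
        super().__init__()
        h1, h2, h3 = hidden
        self.net = nn.Sequential(
            nn.Linear(n_in, h1, rng), nn.ReLU(),
            nn.Linear(h1, h2, rng), nn.ReLU(),
            nn.Linear(h2, h3, rng), nn.ReLU(),
            nn.Linear(h3, n_classes, rng),
        )
        self.n_in, self.n_classes = n_in, n_classes

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        was = self.training
        self.eval()
        p = nn.softmax(self.net(Tensor(np.asarray(x, dtype=np.float32))).data)
        self.train(was)
        return p

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)


class ConvClassifier(nn.Module):
    """5-block CNN (conv + batch norm + leaky rectifier + max-pool) + softmax."""

    def __init__(self, image_size: int, n_classes: int, rng: np.random.Generator,
                 base_filters: int = 8, n_blocks: int = 5):
        super().__init__()
        layers: list[nn.Module] = []
        c_in = 1
        size = image_size
        for i in range(n_blocks):
            if size < 2:
                break
            c_out = min(base_filters * 2**i, base_filters * 4)
            layers += [
                nn.Conv2d(c_in, c_out, rng, k=3, stride=1, pad=1),
                nn.BatchNorm(c_out),
                nn.LeakyReLU(0.2),
                nn.MaxPool2(),
            ]
            c_in = c_out
            size //= 2
        layers += [nn.Flatten(), nn.Linear(c_in * size * size, n_classes, rng)]
        self.net = nn.Sequential(*layers)
        self.image_size, self.n_classes = image_size, n_classes

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)

    def predict_proba(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        was = self.training
        self.eval()
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        out = [
            nn.softmax(self.net(Tensor(x[i : i + batch])).data)
            for i in range(0, len(x), batch)
        ]
        self.train(was)
        return np.concatenate(out)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)


# ---------------------------------------------------------------------------
# loss containers
# ---------------------------------------------------------------------------
@dataclass
class LossWeights:
    # The bottleneck batch-confusion term carries the heaviest weight: its
    # gradient shrinks as the frozen classifiers get fooled, and with clean
    # translation targets the output images hold little batch signal, so the
    # image-level terms stay light to protect reconstruction fidelity.
    W_gen: float = 100.0
    W_dis: float = 1.0
    W_Bcnn: float = 2.0
    W_Ccnn: float = 2.0
    W_Bnn: float = 20.0
    W_Cnn: float = 5.0

    def __post_init__(self):
        for name in ("W_gen", "W_dis", "W_Bcnn", "W_Ccnn", "W_Bnn", "W_Cnn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class LossBundle:
    """Component losses and their weighted composites."""

    weights: LossWeights
    L_gen: float
    L_dis: float
    L_Bcnn: float
    L_Ccnn: float
    L_Bnn: float
    L_Cnn: float
    L_GAN: float
    L_cnn: float
    L_nn: float
    L_total: float

    def as_dict(self) -> dict[str, float]:
        return {
            k: getattr(self, k)
            for k in (
                "L_gen", "L_dis", "L_Bcnn", "L_Ccnn", "L_Bnn", "L_Cnn",
                "L_GAN", "L_cnn", "L_nn", "L_total",
            )
        }


def assemble_loss(components: dict[str, float], weights: LossWeights) -> LossBundle:
    """Combine the six component losses into the weighted composites."""
    vals = {k: float(components[k]) for k in
            ("L_gen", "L_dis", "L_Bcnn", "L_Ccnn", "L_Bnn", "L_Cnn")}
    if not np.isfinite(list(vals.values())).all():
        raise ValueError("loss components must be finite")
    w = weights
    L_GAN = w.W_gen * vals["L_gen"] + w.W_dis * vals["L_dis"]
    L_cnn = w.W_Bcnn * vals["L_Bcnn"] + w.W_Ccnn * vals["L_Ccnn"]
    L_nn = w.W_Bnn * vals["L_Bnn"] + w.W_Cnn * vals["L_Cnn"]
    return LossBundle(
        weights=w, L_GAN=L_GAN, L_cnn=L_cnn, L_nn=L_nn,
        L_total=L_GAN + L_cnn + L_nn, **vals,
    )


def batch_confusion_loss(probs: np.ndarray) -> float:
    """Mean cross-entropy of batch-probability vectors against uniform.

    ``-(1/K) * sum_k log p_k`` averaged over samples; minimized (= ln K)
    exactly when every vector is uniform.  Zero probabilities are clamped
    at 1e-12 before the log.
    """
    p = np.asarray(probs, dtype=float)
    if p.ndim != 2:
        raise ValueError("expected (n_samples, K) probability vectors")
    if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("rows must sum to 1")
    k = p.shape[1]
    return float(-(np.log(np.clip(p, EPS, None)).sum(axis=1) / k).mean())


# ---------------------------------------------------------------------------
# the classifier set
# ---------------------------------------------------------------------------
@dataclass
class ClassifierTrainConfig:
    epochs: int = 30
    minibatch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    n_minis: int = 4
    balance: bool = False
    refit_epochs: int = 20  # warm-start budget for periodic batch-classifier refits


class ClassifierSet(nn.Module):
    """Frozen batch/type classifiers at the bottleneck and the image output."""

    def __init__(
        self,
        bottleneck_dim: int,
        image_size: int,
        batch_classes: list,
        type_classes: list,
        cfg: ClassifierTrainConfig,
        seed: int = 0,
    ):
        super().__init__()
        rng = np.random.default_rng(seed)
        m = cfg.n_minis
        edges = np.linspace(0, bottleneck_dim, m + 1).astype(int)
        self.segments = [(int(edges[i]), int(edges[i + 1])) for i in range(m)]
        if any(b - a < 1 for a, b in self.segments):
            raise ValueError("bottleneck_dim too small for the number of minis")
        self.batch_classes = list(batch_classes)
        self.type_classes = list(type_classes)
        kb, kt = len(self.batch_classes), len(self.type_classes)
        self.bottleneck_batch_minis: list[DenseClassifier] = []
        for i, (a, b) in enumerate(self.segments):
            c = DenseClassifier(b - a, kb, rng)
            self.bottleneck_batch_minis.append(c)
            self._modules[f"mini{i}"] = c
        self.bottleneck_type = DenseClassifier(bottleneck_dim, kt, rng)
        self.image_batch = ConvClassifier(image_size, kb, rng)
        self.image_type = ConvClassifier(image_size, kt, rng)
        self.frozen = False
        self.cfg = cfg

    # label helpers ------------------------------------------------------
    def batch_onehot(self, labels) -> np.ndarray:
        return _onehot(labels, self.batch_classes)

    def type_onehot(self, labels) -> np.ndarray:
        return _onehot(labels, self.type_classes)

    def mini_inputs(self, profiles: np.ndarray) -> list[np.ndarray]:
        return [profiles[:, a:b] for a, b in self.segments]

    def freeze(self) -> None:
        self.frozen = True
        self.eval()

    def batch_accuracy_on_profiles(self, profiles: np.ndarray, labels) -> float:
        y = np.asarray([self.batch_classes.index(b) for b in labels])
        votes = np.mean(
            [
                c.predict_proba(seg)
                for c, seg in zip(self.bottleneck_batch_minis, self.mini_inputs(profiles))
            ],
            axis=0,
        )
        return float((votes.argmax(axis=1) == y).mean())

    def type_accuracy_on_profiles(self, profiles: np.ndarray, labels) -> float:
        y = np.asarray([self.type_classes.index(t) for t in labels])
        return float((self.bottleneck_type.predict(profiles) == y).mean())


def _onehot(labels, classes: list) -> np.ndarray:
    idx = np.asarray([list(classes).index(v) for v in labels])
    return np.eye(len(classes), dtype=np.float32)[idx]


def _balance_downsample(labels, rng: np.random.Generator) -> np.ndarray:
    """Index subset where every class keeps at most the minority-class count."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    n_keep = counts.min()
    keep = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if len(idx) > n_keep:
            idx = rng.choice(idx, size=n_keep, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def _fit_classifier(
    clf, x: np.ndarray, onehot: np.ndarray, cfg: ClassifierTrainConfig,
    rng: np.random.Generator, epochs: int | None = None,
) -> None:
    is_conv = isinstance(clf, ConvClassifier)
    x = np.asarray(x, dtype=np.float32)
    if is_conv and x.ndim == 3:
        x = x[:, None]
    opt = nn.Adam(clf.parameters(), cfg.learning_rate, 0.9, 0.999)
    n = len(x)
    clf.train(True)
    for _ in range(cfg.epochs if epochs is None else epochs):
        order = rng.permutation(n)
        for i in range(0, n, cfg.minibatch_size):
            idx = order[i : i + cfg.minibatch_size]
            if len(idx) < 2:
                continue
            loss = nn.softmax_cross_entropy(clf(Tensor(x[idx])), onehot[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
    clf.eval()


def pretrain_classifiers(
    profiles: np.ndarray,
    images: np.ndarray,
    batch_labels,
    type_labels,
    cfg: ClassifierTrainConfig | None = None,
) -> ClassifierSet:
    """Train the distillator's classifier duo on no-CytoMAD profiles/images.

    With ``cfg.balance`` the majority class is downsampled before type-
    classifier training (needed when one population dominates, as with the
    EpCAM-Vim- fraction of heterogeneous biopsies).  Returns the set with
    ``frozen=False``; call :meth:`ClassifierSet.freeze` (done automatically
    by :func:`train_cytomad`) before distillation.
    """
    cfg = cfg or ClassifierTrainConfig()
    profiles = np.asarray(profiles, dtype=np.float32)
    images = np.asarray(images, dtype=np.float32)
    batch_classes = sorted(set(batch_labels))
    type_classes = sorted(set(type_labels))
    if len(batch_classes) < 2:
        raise ValueError("need at least 2 batches")
    if len(type_classes) < 2:
        raise ValueError("need at least 2 cell types/states")
    cs = ClassifierSet(
        profiles.shape[1], images.shape[-1], batch_classes, type_classes,
        cfg, seed=cfg.seed,
    )
    rng = np.random.default_rng(cfg.seed)
    b_onehot = cs.batch_onehot(batch_labels)
    t_onehot = cs.type_onehot(type_labels)
    type_idx = np.arange(len(profiles))
    if cfg.balance:
        type_idx = _balance_downsample(np.asarray(type_labels), rng)
    for clf, seg in zip(cs.bottleneck_batch_minis, cs.mini_inputs(profiles)):
        _fit_classifier(clf, seg, b_onehot, cfg, rng)
    _fit_classifier(cs.bottleneck_type, profiles[type_idx], t_onehot[type_idx], cfg, rng)
    _fit_classifier(cs.image_batch, images, b_onehot, cfg, rng)
    _fit_classifier(cs.image_type, images[type_idx], t_onehot[type_idx], cfg, rng)
    return cs


def classifier_hashes(cs: ClassifierSet) -> dict[str, str]:
    """SHA-256 of every classifier's parameters+buffers (freezing audit)."""
    out = {}
    for name, mod in cs._modules.items():
        h = hashlib.sha256()
        for k in sorted(mod.state_dict()):
            h.update(mod.state_dict()[k].tobytes())
        out[name] = h.hexdigest()
    return out


# ---------------------------------------------------------------------------
# distillation training
# ---------------------------------------------------------------------------
def train_cytomad(
    model: BackboneModel,
    classifier_set: ClassifierSet,
    dataset: Dataset,
    tc: TrainConfig,
    weights: LossWeights | None = None,
    retrain_interval_epochs: int = 10,
    batch_loss: str = "confusion",
    freeze_callback=None,
) -> tuple[BackboneModel, pd.DataFrame]:
    """Distill the pretrained backbone against the frozen classifier set.

    Per epoch only the generator and discriminator are updated against the
    composite loss; every ``retrain_interval_epochs`` the batch classifiers
    (minis and image-level) are re-fitted on the current generator outputs
    from their existing parameters, then re-frozen.  ``freeze_callback``
    (if given) is invoked with the classifier hash dict after every
    generator update — used by the freezing audit.
    """
    if batch_loss not in ("confusion", "negated"):
        raise ValueError("batch_loss must be 'confusion' or 'negated'")
    w = weights or LossWeights()
    cs = classifier_set
    if cs.bottleneck_type.n_in != model.cfg.bottleneck_dim:
        raise ValueError("classifier/backbone bottleneck dimension mismatch")
    if cs.image_batch.image_size != model.cfg.image_size_px:
        raise ValueError("classifier/backbone image size mismatch")
    cs.freeze()
    bf = dataset.bf.astype(np.float32)[:, None]
    target = (
        bf if model.cfg.mode == "autoencode"
        else dataset.qpi_clean.astype(np.float32)[:, None]
    )
    batch_labels = dataset.meta["batch_id"].to_numpy()
    type_labels = dataset.meta["cell_type"].to_numpy()
    b_onehot = cs.batch_onehot(batch_labels)
    t_onehot = cs.type_onehot(type_labels)
    kb = len(cs.batch_classes)
    uniform = np.full((1, kb), 1.0 / kb, dtype=np.float32)

    rng = np.random.default_rng(tc.seed)
    opt_g = nn.Adam(model.generator.parameters(), tc.learning_rate, tc.beta1, tc.beta2)
    opt_d = nn.Adam(model.discriminator.parameters(), tc.learning_rate, tc.beta1, tc.beta2)
    n = len(bf)
    history = []
    for epoch in range(tc.epochs):
        if epoch > 0 and retrain_interval_epochs > 0 and epoch % retrain_interval_epochs == 0:
            _refit_batch_classifiers(model, cs, bf, b_onehot, rng)
        order = rng.permutation(n)
        acc = {k: 0.0 for k in ("L_gen", "L_dis", "L_Bcnn", "L_Ccnn", "L_Bnn", "L_Cnn")}
        nb = 0
        for i in range(0, n, tc.minibatch_size):
            idx = order[i : i + tc.minibatch_size]
            if len(idx) < 2:
                continue
            xb = Tensor(bf[idx])
            tb = target[idx]
            # discriminator step
            _, fake = model.generator(xb)
            d_loss = nn.sigmoid_bce_with_logits(model.discriminator(xb, Tensor(tb)), 1.0) + \
                nn.sigmoid_bce_with_logits(model.discriminator(xb, fake.detach()), 0.0)
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()
            # generator step against the composite objective
            profile, fake = model.generator(xb)
            l_gen = nn.mse_loss(fake, tb)
            l_dis = nn.sigmoid_bce_with_logits(model.discriminator(xb, fake), 1.0)
            bt = (
                np.repeat(uniform, len(idx), axis=0)
                if batch_loss == "confusion" else b_onehot[idx]
            )
            sign = 1.0 if batch_loss == "confusion" else -1.0
            minis = [
                nn.softmax_cross_entropy(c(_segment(profile, a, b)), bt)
                for c, (a, b) in zip(cs.bottleneck_batch_minis, cs.segments)
            ]
            l_bnn = minis[0]
            for m_ in minis[1:]:
                l_bnn = l_bnn + m_
            l_bnn = l_bnn * (1.0 / len(minis))
            l_cnn_type = nn.softmax_cross_entropy(cs.bottleneck_type(profile), t_onehot[idx])
            l_bcnn = nn.softmax_cross_entropy(cs.image_batch(fake), bt)
            l_ccnn = nn.softmax_cross_entropy(cs.image_type(fake), t_onehot[idx])
            total = (
                w.W_gen * l_gen + w.W_dis * l_dis
                + sign * w.W_Bcnn * l_bcnn + w.W_Ccnn * l_ccnn
                + sign * w.W_Bnn * l_bnn + w.W_Cnn * l_cnn_type
            )
            opt_g.zero_grad()
            model.discriminator.zero_grad()
            cs.zero_grad()
            total.backward()
            opt_g.step()  # classifier parameters receive no update: frozen
            if freeze_callback is not None:
                freeze_callback(classifier_hashes(cs))
            acc["L_gen"] += float(l_gen.data)
            acc["L_dis"] += float(l_dis.data)
            acc["L_Bnn"] += float(l_bnn.data)
            acc["L_Cnn"] += float(l_cnn_type.data)
            acc["L_Bcnn"] += float(l_bcnn.data)
            acc["L_Ccnn"] += float(l_ccnn.data)
            nb += 1
        comp = {k: v / max(nb, 1) for k, v in acc.items()}
        bundle = assemble_loss(comp, w)
        profiles_now, images_now = model.infer(bf[:, 0])
        row = {"epoch": epoch, **bundle.as_dict()}
        row["batch_acc_profile"] = cs.batch_accuracy_on_profiles(profiles_now, batch_labels)
        row["type_acc_profile"] = cs.type_accuracy_on_profiles(profiles_now, type_labels)
        history.append(row)
    model.stage = "cytomad"
    return model, pd.DataFrame(history)


def _segment(profile: Tensor, a: int, b: int) -> Tensor:
    # contiguous column slice of the bottleneck profile, autodiff-aware
    w = np.zeros((profile.shape[1], b - a), dtype=np.float32)
    w[a:b] = np.eye(b - a, dtype=np.float32)
    return profile.matmul(Tensor(w))


def _refit_batch_classifiers(
    model: BackboneModel, cs: ClassifierSet, bf: np.ndarray,
    b_onehot: np.ndarray, rng: np.random.Generator,
) -> None:
    """Warm-start re-fit of the batch classifiers on current outputs, then re-freeze."""
    profiles, images = model.infer(bf[:, 0])
    cfg = cs.cfg
    for clf, seg in zip(cs.bottleneck_batch_minis, cs.mini_inputs(profiles)):
        _fit_classifier(clf, seg, b_onehot, cfg, rng, epochs=cfg.refit_epochs)
    _fit_classifier(cs.image_batch, images, b_onehot, cfg, rng, epochs=cfg.refit_epochs)
    cs.freeze()
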