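"""Synthetic paired BF/QPI single-cell image generator with injectable batch effects.

Emulates what a multi-modal imaging flow cytometer delivers for one cell: a
quantitative phase image (QPI, proportional to dry-mass density), the paired
bright-field image (BF), and the cell-body mask — for several cell types
across several acquisition batches.  Batch effects model the technical
variation of real instruments: illumination gain/offset drift (laser power
instability), additive photodetection noise, defocus blur, geometric shear
from microfluidic flow, and high-spatial-frequency stripe noise.

The clean (pre-photometric-distortion) QPI of every cell is retained so the
translation backbone has a well-defined, batch-invariant target.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "CellParams",
    "BatchEffectParams",
    "TypeDistribution",
    "SimConfig",
    "ImagePair",
    "Dataset",
    "render_cell",
    "apply_batch_effect",
    "generate_dataset",
    "default_sim_config",
]

BF_ATTENUATION = 0.9  # default BF = 1 - alpha * QPI


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------
@dataclass
class CellParams:
    """Morphological parameters of one synthetic cell."""

    cell_type: str
    radius_px: float
    eccentricity: float = 0.0
    orientation_rad: float = 0.0
    peak_phase: float = 0.6
    texture_granularity: float = 2.0
    texture_amplitude: float = 0.0
    marker_label: str | None = None

    def __post_init__(self):
        if not np.isfinite(
            [self.radius_px, self.eccentricity, self.orientation_rad,
             self.peak_phase, self.texture_granularity, self.texture_amplitude]
        ).all():
            raise ValueError("cell parameters must be finite")
        if self.radius_px < 3:
            raise ValueError("radius_px must be >= 3")
        if not (0 <= self.eccentricity < 1):
            raise ValueError("eccentricity must lie in [0, 1)")
        if not (0 < self.peak_phase <= 1):
            raise ValueError("peak_phase must lie in (0, 1]")
        if self.texture_granularity <= 0:
            raise ValueError("texture_granularity must be positive")
        if self.texture_amplitude < 0:
            raise ValueError("texture_amplitude must be >= 0")


@dataclass
class BatchEffectParams:
    """Per-batch technical distortion parameters."""

    batch_id: str
    gain: float = 1.0
    offset: float = 0.0
    noise_sigma: float = 0.0
    psf_sigma: float = 0.0
    shear: float = 0.0
    stripe_amplitude: float = 0.0
    stripe_period_px: float = 4.0

    def __post_init__(self):
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.noise_sigma < 0 or self.psf_sigma < 0:
            raise ValueError("noise_sigma and psf_sigma must be >= 0")
        if self.stripe_period_px < 2:
            raise ValueError("stripe_period_px must be >= 2")

    def is_neutral(self) -> bool:
        return (
            self.gain == 1.0
            and self.offset == 0.0
            and self.noise_sigma == 0.0
            and self.psf_sigma == 0.0
            and self.shear == 0.0
            and self.stripe_amplitude == 0.0
        )


@dataclass
class TypeDistribution:
    """Sampling distribution of :class:`CellParams` for one cell type."""

    radius_mean: float = 9.0
    radius_sd: float = 1.0
    eccentricity_max: float = 0.4
    peak_phase_mean: float = 0.6
    peak_phase_sd: float = 0.05
    texture_granularity: float = 2.0
    texture_amplitude: float = 0.05
    marker_probs: dict[str, float] | None = None

    def sample(self, cell_type: str, rng: np.random.Generator) -> CellParams:
        radius = float(np.clip(rng.normal(self.radius_mean, self.radius_sd), 3.0, None))
        ecc = float(rng.uniform(0.0, self.eccentricity_max))
        peak = float(np.clip(rng.normal(self.peak_phase_mean, self.peak_phase_sd), 0.05, 1.0))
        marker = None
        if self.marker_probs:
            labels = list(self.marker_probs)
            p = np.asarray([self.marker_probs[k] for k in labels], dtype=float)
            marker = str(rng.choice(labels, p=p / p.sum()))
        return CellParams(
            cell_type=cell_type,
            radius_px=radius,
            eccentricity=ecc,
            orientation_rad=float(rng.uniform(0, np.pi)),
            peak_phase=peak,
            texture_granularity=self.texture_granularity,
            texture_amplitude=self.texture_amplitude,
            marker_label=marker,
        )


@dataclass
class SimConfig:
    image_size_px: int = 32
    n_cells_per_type_per_batch: int = 50
    cell_type_param_distributions: dict[str, TypeDistribution] = field(default_factory=dict)
    batches: list[BatchEffectParams] = field(default_factory=list)
    seed: int = 0
    bf_attenuation: float = BF_ATTENUATION
    target: str = "clean"  # translation target: "clean" | "distorted"
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)

    def validate(self) -> None:
        if self.image_size_px < 32:
            raise ValueError("image_size_px must be >= 32")
        if self.n_cells_per_type_per_batch < 1:
            raise ValueError("n_cells_per_type_per_batch must be positive")
        if len(self.batches) < 2 or len(self.cell_type_param_distributions) < 2:
            raise ValueError(
                "need at least 2 batches and 2 cell types for distillation"
            )
        if self.target not in ("clean", "distorted"):
            raise ValueError("target must be 'clean' or 'distorted'")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")


# ---------------------------------------------------------------------------
# image containers
# ---------------------------------------------------------------------------
@dataclass
class ImagePair:
    """One cell's BF image, QPI image and segmentation mask with metadata.

    ``qpi_clean`` keeps the pre-photometric-distortion QPI (geometric warp
    retained) so translation targets stay free of batch character.
    """

    bf: np.ndarray
    qpi: np.ndarray
    mask: np.ndarray
    qpi_clean: np.ndarray
    meta: dict = field(default_factory=dict)

    def copy(self) -> "ImagePair":
        return ImagePair(
            self.bf.copy(), self.qpi.copy(), self.mask.copy(),
            self.qpi_clean.copy(), dict(self.meta),
        )


class Dataset:
    """A list of :class:`ImagePair` aligned with a metadata table."""

    def __init__(self, pairs: list[ImagePair], meta: pd.DataFrame):
        if len(pairs) != len(meta):
            raise ValueError(
                f"image count ({len(pairs)}) != metadata rows ({len(meta)})"
            )
        self.pairs = pairs
        self.meta = meta.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)

    def stack(self, channel: str) -> np.ndarray:
        return np.stack([getattr(p, channel) for p in self.pairs])

    @property
    def bf(self) -> np.ndarray:
        return self.stack("bf")

    @property
    def qpi(self) -> np.ndarray:
        return self.stack("qpi")

    @property
    def qpi_clean(self) -> np.ndarray:
        return self.stack("qpi_clean")

    @property
    def masks(self) -> np.ndarray:
        return self.stack("mask")

    def subset(self, index) -> "Dataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return Dataset(
            [self.pairs[i] for i in index], self.meta.iloc[index]
        )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------
def render_cell(
    params: CellParams,
    image_size_px: int,
    rng: np.random.Generator,
    bf_attenuation: float = BF_ATTENUATION,
) -> ImagePair:
    """Render one clean cell: parabolic elliptical phase cap + band-limited texture.

    The QPI is ``peak_phase * (1 - rho^2)`` inside the elliptical support
    (``rho`` the normalized elliptical radius), optionally plus a Gaussian
    random texture field of the requested correlation length, clipped to
    [0, 1] and exactly zero outside the mask.  BF is the attenuation map
    ``1 - alpha * QPI`` with mild smoothing, making BF -> QPI a learnable
    deterministic mapping.
    """
    n = int(image_size_px)
    a = params.radius_px
    b = a * np.sqrt(1.0 - params.eccentricity**2)
    if a + 2 > n / 2:
        raise ValueError("cell exceeds field of view")
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    x = xx - c
    y = yy - c
    ct, st = np.cos(params.orientation_rad), np.sin(params.orientation_rad)
    xr = ct * x + st * y
    yr = -st * x + ct * y
    rho2 = (xr / a) ** 2 + (yr / b) ** 2
    mask = rho2 < 1.0
    qpi = params.peak_phase * np.clip(1.0 - rho2, 0.0, None)
    if params.texture_amplitude > 0:
        noise = rng.standard_normal((n, n))
        fieldn = ndi.gaussian_filter(noise, params.texture_granularity)
        sd = fieldn.std()
        if sd > 0:
            fieldn = fieldn / sd
        qpi = qpi + params.texture_amplitude * fieldn * mask
    qpi = np.clip(qpi, 0.0, 1.0) * mask
    bf = np.clip(1.0 - bf_attenuation * qpi, 0.0, 1.0)
    bf = ndi.gaussian_filter(bf, 0.5)
    return ImagePair(
        bf=bf.astype(np.float32),
        qpi=qpi.astype(np.float32),
        mask=mask,
        qpi_clean=qpi.astype(np.float32),
        meta={"cell_type": params.cell_type, "marker_label": params.marker_label},
    )


def _shear_warp(img: np.ndarray, shear: float, order: int) -> np.ndarray:
    """Affine shear about the image center (x' = x + shear * y)."""
    n = img.shape[0]
    c = (n - 1) / 2.0
    # inverse map: source coords for each output coord
    mat = np.array([[1.0, 0.0], [-shear, 1.0]])  # rows are (y, x)
    offset = np.array([c, c]) - mat @ np.array([c, c])
    return ndi.affine_transform(
        img.astype(float), mat, offset=offset, order=order, mode="constant",
        cval=float(img.reshape(-1)[0]) if order else 0.0,
    )


def apply_batch_effect(
    pair: ImagePair, effect: BatchEffectParams, rng: np.random.Generator
) -> ImagePair:
    """Distort one image pair: shear warp, PSF blur, gain/offset, stripes, noise.

    Both channels get ``clip(gain * blur(warp(x)) + offset + stripes + noise, 0, 1)``;
    the mask is warped by the same geometric transform; ``qpi_clean`` keeps the
    geometrically-warped but photometrically-clean QPI.
    """
    n = pair.qpi.shape[0]

    def geometric(img, order):
        if effect.shear != 0.0:
            return _shear_warp(img, effect.shear, order)
        return img.astype(float)

    warped_qpi = geometric(pair.qpi, 1)
    warped_bf = geometric(pair.bf, 1)
    warped_mask = geometric(pair.mask.astype(float), 0) > 0.5

    stripes = 0.0
    if effect.stripe_amplitude != 0.0:
        yy = np.arange(n)[:, None]
        stripes = effect.stripe_amplitude * np.sin(
            2 * np.pi * yy / effect.stripe_period_px
        ) * np.ones((1, n))

    def photometric(img):
        out = img
        if effect.psf_sigma > 0:
            out = ndi.gaussian_filter(out, effect.psf_sigma)
        out = effect.gain * out + effect.offset + stripes
        if effect.noise_sigma > 0:
            out = out + rng.normal(0.0, effect.noise_sigma, size=out.shape)
        return np.clip(out, 0.0, 1.0).astype(np.float32)

    meta = dict(pair.meta)
    meta["batch_id"] = effect.batch_id
    return ImagePair(
        bf=photometric(warped_bf),
        qpi=photometric(warped_qpi),
        mask=warped_mask,
        qpi_clean=np.clip(warped_qpi, 0.0, 1.0).astype(np.float32),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------
def generate_dataset(cfg: SimConfig) -> Dataset:
    """Generate the full (type x batch) grid of distorted image pairs."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    pairs: list[ImagePair] = []
    rows = []
    cell_id = 0
    fr_train, fr_val, _ = cfg.split_fractions
    for effect in cfg.batches:
        for cell_type, dist in cfg.cell_type_param_distributions.items():
            n = cfg.n_cells_per_type_per_batch
            n_train = int(round(fr_train * n))
            n_val = int(round(fr_val * n))
            for i in range(n):
                params = dist.sample(cell_type, rng)
                max_r = cfg.image_size_px / 2 - 2.5
                if params.radius_px > max_r:  # keep cell inside the field
                    params = dataclasses.replace(params, radius_px=max_r)
                clean = render_cell(
                    params, cfg.image_size_px, rng, cfg.bf_attenuation
                )
                pair = apply_batch_effect(clean, effect, rng)
                if cfg.target == "distorted":
                    pair.qpi_clean = pair.qpi.copy()
                split = (
                    "train" if i < n_train
                    else ("val" if i < n_train + n_val else "test")
                )
                pair.meta.update(cell_id=cell_id, split=split)
                pairs.append(pair)
                rows.append(
                    {
                        "cell_id": cell_id,
                        "batch_id": effect.batch_id,
                        "cell_type": cell_type,
                        "marker_label": params.marker_label,
                        "split": split,
                        "radius_px": params.radius_px,
                        "peak_phase": params.peak_phase,
                    }
                )
                cell_id += 1
    return Dataset(pairs, pd.DataFrame(rows))


def default_sim_config(
    n_cells_per_type_per_batch: int = 50,
    image_size_px: int = 32,
    seed: int = 0,
    **overrides,
) -> SimConfig:
    """The package's reference study conditions.

    Two morphologically distinct cell types imaged in three batches whose
    photometric character differs (gain/offset drift, defocus blur, detector
    noise, mild shear and stripe noise on two of the three).
    """
    types = {
        "typeA": TypeDistribution(
            radius_mean=7.0, radius_sd=1.0, eccentricity_max=0.4,
            peak_phase_mean=0.5, peak_phase_sd=0.05,
            texture_granularity=1.5, texture_amplitude=0.05,
            marker_probs={"EpCAM+": 0.7, "EpCAM+Vim+": 0.2, "EpCAM-Vim-": 0.1},
        ),
        "typeB": TypeDistribution(
            radius_mean=11.0, radius_sd=1.0, eccentricity_max=0.6,
            peak_phase_mean=0.75, peak_phase_sd=0.05,
            texture_granularity=2.5, texture_amplitude=0.08,
            marker_probs={"EpCAM+": 0.2, "EpCAM+Vim+": 0.5, "EpCAM-Vim-": 0.3},
        ),
    }
    batches = [
        BatchEffectParams("batch0", gain=1.0, offset=0.0, noise_sigma=0.01),
        BatchEffectParams(
            "batch1", gain=1.15, offset=0.08, noise_sigma=0.02,
            psf_sigma=0.8, shear=0.05, stripe_amplitude=0.02, stripe_period_px=3.0,
        ),
        BatchEffectParams(
            "batch2", gain=0.85, offset=-0.06, noise_sigma=0.03,
            psf_sigma=1.2, shear=-0.05, stripe_amplitude=0.03, stripe_period_px=4.0,
        ),
    ]
    cfg = SimConfig(
        image_size_px=image_size_px,
        n_cells_per_type_per_batch=n_cells_per_type_per_batch,
        cell_type_param_distributions=types,
        batches=batches,
        seed=seed,
    )
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise TypeError(f"unknown SimConfig field: {k}")
        setattr(cfg, k, v)
    return cfg


def config_to_dict(cfg: SimConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["split_fractions"] = list(cfg.split_fractions)
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    d["cell_type_param_distributions"] = {
        k: TypeDistribution(**v) if isinstance(v, dict) else v
        for k, v in d.get("cell_type_param_distributions", {}).items()
    }
    d["batches"] = [
        BatchEffectParams(**b) if isinstance(b, dict) else b
        for b in d.get("batches", [])
    ]
    if "split_fractions" in d:
        d["split_fractions"] = tuple(d["split_fractions"])
    return SimConfig(**d)
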