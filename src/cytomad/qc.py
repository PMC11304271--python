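"""Data-quality pipeline: cell segmentation, focus factors, and gating.

Out-of-focus cells and debris are excluded before any model training.  Each
cell gets a :class:`FocusReport` per channel (gradient energy, Laplacian
variance, masked intensity variance, 64-bin masked entropy, mask area);
gates are absolute or percentile bounds over those metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, measure, morphology

from .synthetic import Dataset

__all__ = [
    "FocusReport",
    "GateSpec",
    "segment_cell",
    "focus_factors",
    "focus_table",
    "gate_dataset",
]


@dataclass(frozen=True)
class FocusReport:
    gradient_energy: float
    laplacian_variance: float
    mask_intensity_variance: float
    mask_entropy: float
    mask_area_px: int

    def __post_init__(self):
        vals = [
            self.gradient_energy,
            self.laplacian_variance,
            self.mask_intensity_variance,
            self.mask_entropy,
        ]
        if not np.isfinite(vals).all() or min(vals) < -1e-9:
            raise ValueError("focus metrics must be finite and nonnegative")
        if self.mask_area_px <= 0:
            raise ValueError("zero-area mask is not representable")


def segment_cell(image: np.ndarray) -> np.ndarray:
    """Largest connected foreground component after Otsu thresholding.

    Foreground polarity is the side of the threshold with the higher mean
    absolute deviation from the image-border median; the binary image is
    closed (radius 2) and hole-filled before the largest component is kept.
    """
    img = np.asarray(image, dtype=float)
    if not np.isfinite(img).all():
        raise ValueError("image must be finite")
    if img.max() == img.min():
        raise ValueError("no cell found")
    t = filters.threshold_otsu(img)
    border = np.concatenate([img[0], img[-1], img[:, 0], img[:, -1]])
    ref = np.median(border)
    hi, lo = img > t, img <= t
    if not hi.any() or not lo.any():
        raise ValueError("no cell found")
    dev_hi = np.abs(img[hi] - ref).mean()
    dev_lo = np.abs(img[lo] - ref).mean()
    fg = hi if dev_hi >= dev_lo else lo
    fg = morphology.closing(fg, morphology.disk(2))
    fg = ndi.binary_fill_holes(fg)
    labels = measure.label(fg)
    if labels.max() == 0:
        raise ValueError("no cell found")
    counts = np.bincount(labels.ravel())[1:]
    return labels == (np.argmax(counts) + 1)


def _channel_report(img: np.ndarray, mask: np.ndarray) -> FocusReport:
    gy = ndi.sobel(img, axis=0)
    gx = ndi.sobel(img, axis=1)
    grad_energy = float(((gx**2 + gy**2)[mask]).mean())
    lap = ndi.laplace(img)
    lap_var = float(lap[mask].var())
    vals = img[mask]
    var = float(vals.var())
    hist, _ = np.histogram(vals, bins=64, range=(0.0, 1.0))
    p = hist[hist > 0] / hist.sum()
    entropy = float(-(p * np.log2(p)).sum())
    return FocusReport(
        gradient_energy=grad_energy,
        laplacian_variance=lap_var,
        mask_intensity_variance=var,
        mask_entropy=entropy,
        mask_area_px=int(mask.sum()),
    )


def focus_factors(
    bf: np.ndarray, qpi: np.ndarray, mask: np.ndarray
) -> dict[str, FocusReport]:
    """Per-channel focus metrics computed over mask pixels only."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if bf.shape != qpi.shape or bf.shape != mask.shape:
        raise ValueError("shape mismatch between images and mask")
    return {
        "bf": _channel_report(np.asarray(bf, dtype=float), mask),
        "qpi": _channel_report(np.asarray(qpi, dtype=float), mask),
    }


_METRICS = (
    "gradient_energy",
    "laplacian_variance",
    "mask_intensity_variance",
    "mask_entropy",
)


def focus_table(dataset: Dataset) -> pd.DataFrame:
    """One row per cell; columns ``<metric>_<channel>`` plus ``mask_area_px``."""
    rows = []
    for pair in dataset.pairs:
        reports = focus_factors(pair.bf, pair.qpi, pair.mask)
        row = {"cell_id": pair.meta.get("cell_id")}
        for ch, rep in reports.items():
            for m in _METRICS:
                row[f"{m}_{ch}"] = getattr(rep, m)
        row["mask_area_px"] = reports["qpi"].mask_area_px
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class GateSpec:
    """Lower/upper bounds on focus metrics; absolute or dataset percentiles.

    ``bounds`` maps a focus-table column to ``(lo, hi)`` absolute values;
    ``percentile_bounds`` maps a column to ``(plo, phi)`` percentiles that
    are resolved once on the dataset being gated (pass ``None`` for an open
    side).  Area limits are absolute pixel counts.
    """

    bounds: dict[str, tuple[float | None, float | None]] = field(default_factory=dict)
    percentile_bounds: dict[str, tuple[float | None, float | None]] = field(
        default_factory=dict
    )
    min_area_px: int | None = None
    max_area_px: int | None = None

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"lower bound > upper bound for {name}")

    def resolve(self, table: pd.DataFrame) -> "GateSpec":
        """Turn percentile bounds into absolute ones for the given table."""
        bounds = dict(self.bounds)
        for name, (plo, phi) in self.percentile_bounds.items():
            if name not in table.columns:
                raise KeyError(f"unknown focus metric: {name}")
            lo = float(np.percentile(table[name], plo)) if plo is not None else None
            hi = float(np.percentile(table[name], phi)) if phi is not None else None
            bounds[name] = (lo, hi)
        return GateSpec(
            bounds=bounds,
            min_area_px=self.min_area_px,
            max_area_px=self.max_area_px,
        )


def gate_dataset(
    dataset: Dataset, gates: GateSpec
) -> tuple[Dataset, pd.DataFrame]:
    """Keep exactly the cells satisfying all bounds; order preserved.

    Returns the filtered dataset and a QC summary (per-metric pass counts
    plus the overall survivor count).
    """
    table = focus_table(dataset)
    resolved = gates.resolve(table)
    keep = np.ones(len(dataset), dtype=bool)
    summary_rows = []
    for name, (lo, hi) in resolved.bounds.items():
        if name not in table.columns:
            raise KeyError(f"unknown focus metric: {name}")
        ok = np.ones(len(dataset), dtype=bool)
        if lo is not None:
            ok &= table[name].to_numpy() >= lo
        if hi is not None:
            ok &= table[name].to_numpy() <= hi
        summary_rows.append(
            {"metric": name, "lower": lo, "upper": hi, "n_pass": int(ok.sum())}
        )
        keep &= ok
    area = table["mask_area_px"].to_numpy()
    ok = np.ones(len(dataset), dtype=bool)
    if resolved.min_area_px is not None:
        ok &= area >= resolved.min_area_px
    if resolved.max_area_px is not None:
        ok &= area <= resolved.max_area_px
    if resolved.min_area_px is not None or resolved.max_area_px is not None:
        summary_rows.append(
            {
                "metric": "mask_area_px",
                "lower": resolved.min_area_px,
                "upper": resolved.max_area_px,
                "n_pass": int(ok.sum()),
            }
        )
    keep &= ok
    summary_rows.append(
        {"metric": "ALL", "lower": None, "upper": None, "n_pass": int(keep.sum())}
    )
    if keep.sum() == 0:
        import warnings

        warnings.warn("gating excluded every cell", stacklevel=2)
    return dataset.subset(keep), pd.DataFrame(summary_rows)
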