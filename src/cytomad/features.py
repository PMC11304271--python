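"""Hierarchical hand-crafted biophysical feature catalog (84 features).

Three tiers, mirroring how label-free imaging cytometry profiles cells:

* **bulk** — mask geometry and integrated quantities (area, circularity,
  dry mass, ...);
* **global** — masked-intensity statistics of the whole cell on each
  channel (phase statistics and dry-mass distribution on QPI, opacity and
  attenuation statistics on BF);
* **local** — statistics of derived texture maps: a local-entropy map
  (disk radius 3), a multi-scale ridge/fiber-enhancement map, a polynomial
  fit-texture residual map, a gradient-magnitude map, and gray-level
  co-occurrence contrast at pixel offsets 1..4.

QPI pixel values are normalized phase; dry mass is the integrated phase
over the mask times a calibration constant (1.0 by default, i.e. arbitrary
units).  Opacity is ``1 - BF``.  All statistics are computed over mask
pixels only — background never leaks into a profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as sstats
from skimage import filters, measure, morphology, util
from skimage.filters import rank

__all__ = [
    "FeatureDef",
    "BiophysicalProfile",
    "feature_registry",
    "extract_features",
    "extract_features_table",
    "profile_feature_correlation",
    "PHOTOMETRIC_FEATURES",
]

_STATS = ("Mean", "Variance", "Skewness", "Kurtosis", "CentroidDisplacement")
_ECC_UNDEFINED = 0.05  # below this, orientation is flagged undefined


@dataclass(frozen=True)
class FeatureDef:
    name: str
    tier: str  # bulk | global | local
    channel: str  # bf | qpi | mask
    formula_id: str


def _local_map_defs() -> list[FeatureDef]:
    defs = []
    maps = [
        ("QPEntropy", "qpi", "entropy_map"),
        ("QPFiber", "qpi", "fiber_map"),
        ("FitTexture", "qpi", "fit_texture_map"),
        ("BFEntropy", "bf", "entropy_map"),
        ("BFFiber", "bf", "fiber_map"),
        ("BFFitTexture", "bf", "fit_texture_map"),
    ]
    for prefix, ch, fid in maps:
        for stat in _STATS:
            # "BFEntropy" (no suffix) is the conventional name of the mean
            name = prefix if (stat == "Mean" and prefix == "BFEntropy") else prefix + stat
            defs.append(FeatureDef(name, "local", ch, f"{fid}:{stat.lower()}"))
        defs.append(
            FeatureDef(prefix + "RadialDistribution", "local", ch, f"{fid}:radial")
        )
    for ch, prefix in (("qpi", "QPGradient"), ("bf", "BFGradient")):
        defs.append(FeatureDef(prefix + "Mean", "local", ch, "gradient_map:mean"))
        defs.append(FeatureDef(prefix + "Variance", "local", ch, "gradient_map:variance"))
    for n in range(1, 5):
        defs.append(FeatureDef(f"DMDContrast{n}", "local", "qpi", f"glcm_contrast:{n}"))
        defs.append(FeatureDef(f"BFContrast{n}", "local", "bf", f"glcm_contrast:{n}"))
    return defs


def feature_registry() -> list[FeatureDef]:
    """The ordered 84-feature catalog."""
    bulk = [
        FeatureDef("Area", "bulk", "mask", "area"),
        FeatureDef("Perimeter", "bulk", "mask", "perimeter"),
        FeatureDef("Circularity", "bulk", "mask", "circularity"),
        FeatureDef("Eccentricity", "bulk", "mask", "eccentricity"),
        FeatureDef("CellOrientation", "bulk", "mask", "orientation"),
        FeatureDef("MajorAxisLength", "bulk", "mask", "major_axis"),
        FeatureDef("MinorAxisLength", "bulk", "mask", "minor_axis"),
        FeatureDef("AspectRatio", "bulk", "mask", "aspect_ratio"),
        FeatureDef("EquivalentDiameter", "bulk", "mask", "equivalent_diameter"),
        FeatureDef("Solidity", "bulk", "mask", "solidity"),
        FeatureDef("Extent", "bulk", "mask", "extent"),
        FeatureDef("ConvexArea", "bulk", "mask", "convex_area"),
    ]
    global_qpi = [
        FeatureDef("PhaseMean", "global", "qpi", "masked_mean"),
        FeatureDef("PhaseVariance", "global", "qpi", "masked_variance"),
        FeatureDef("PhaseSkewness", "global", "qpi", "masked_skewness"),
        FeatureDef("PhaseKurtosis", "global", "qpi", "masked_kurtosis"),
        FeatureDef("PhaseRange", "global", "qpi", "masked_range"),
        FeatureDef("PhaseMedian", "global", "qpi", "masked_median"),
        FeatureDef("PhaseIQR", "global", "qpi", "masked_iqr"),
        FeatureDef("PhaseEntropy", "global", "qpi", "masked_entropy64"),
        FeatureDef("DryMass", "global", "qpi", "dry_mass"),
        FeatureDef("DryMassDensity", "global", "qpi", "dry_mass_density"),
        FeatureDef("DryMassVariance", "global", "qpi", "dry_mass_variance"),
        FeatureDef("DryMassRadialDistribution", "global", "qpi", "radial_distribution"),
        FeatureDef("PhaseCentroidDisplacement", "global", "qpi", "centroid_displacement"),
    ]
    global_bf = [
        FeatureDef("OpacityMean", "global", "bf", "masked_mean"),
        FeatureDef("OpacityVariance", "global", "bf", "masked_variance"),
        FeatureDef("OpacitySkewness", "global", "bf", "masked_skewness"),
        FeatureDef("OpacityKurtosis", "global", "bf", "masked_kurtosis"),
        FeatureDef("OpacityRange", "global", "bf", "masked_range"),
        FeatureDef("OpacityMedian", "global", "bf", "masked_median"),
        FeatureDef("OpacityIQR", "global", "bf", "masked_iqr"),
        FeatureDef("AttenuationDensity", "global", "bf", "dry_mass_density"),
        FeatureDef("AttenuationMass", "global", "bf", "dry_mass"),
        FeatureDef("OpacityRadialDistribution", "global", "bf", "radial_distribution"),
        FeatureDef("OpacityCentroidDisplacement", "global", "bf", "centroid_displacement"),
    ]
    defs = bulk + global_qpi + global_bf + _local_map_defs()
    names = [d.name for d in defs]
    assert len(names) == len(set(names)) == 84, len(names)
    return defs


@dataclass
class BiophysicalProfile:
    """Named feature vector of one cell."""

    values: pd.Series
    cell_id: object = None
    provenance: str = "original"  # "original" | "cytomad"
    flags: dict = None


PHOTOMETRIC_FEATURES = [
    # features directly driven by the photometric (gain/offset/noise/blur)
    # component of a batch effect: intensity levels and spreads
    "PhaseMean", "PhaseVariance", "PhaseRange", "PhaseMedian", "PhaseIQR",
    "DryMass", "DryMassDensity", "DryMassVariance",
    "OpacityMean", "OpacityVariance", "OpacityRange", "OpacityMedian",
    "OpacityIQR", "AttenuationDensity", "AttenuationMass",
    "QPGradientMean", "BFGradientMean", "DMDContrast3", "DMDContrast4",
]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------
def _masked_stats(vals: np.ndarray) -> dict[str, float]:
    v = vals.astype(float)
    var = float(v.var())
    out = {
        "mean": float(v.mean()),
        "variance": var,
        "range": float(v.max() - v.min()),
        "median": float(np.median(v)),
        "iqr": float(np.percentile(v, 75) - np.percentile(v, 25)),
    }
    if var > 1e-18:
        out["skewness"] = float(sstats.skew(v))
        out["kurtosis"] = float(sstats.kurtosis(v))  # Fisher (excess)
    else:
        out["skewness"] = 0.0
        out["kurtosis"] = 0.0
    return out


def _entropy64(vals: np.ndarray) -> float:
    hist, _ = np.histogram(vals, bins=64, range=(0.0, 1.0))
    p = hist[hist > 0] / hist.sum()
    return float(-(p * np.log2(p)).sum())


def _centroid_displacement(weights: np.ndarray, mask: np.ndarray) -> float:
    """|weighted centroid - mask centroid| / equivalent radius."""
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    w = weights[mask].astype(float)
    w = w - w.min()
    tot = w.sum()
    if tot <= 1e-12:
        return 0.0
    wy = (ys * w).sum() / tot
    wx = (xs * w).sum() / tot
    r_eq = np.sqrt(mask.sum() / np.pi)
    return float(np.hypot(wy - cy, wx - cx) / r_eq)


def _radial_distribution(weights: np.ndarray, mask: np.ndarray) -> float:
    """Mass-weighted mean radius normalized by the equivalent radius."""
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    r = np.hypot(ys - cy, xs - cx)
    w = weights[mask].astype(float)
    tot = w.sum()
    if tot <= 1e-12:
        return 0.0
    r_eq = np.sqrt(mask.sum() / np.pi)
    return float((r * w).sum() / tot / r_eq)


def _entropy_map(img: np.ndarray) -> np.ndarray:
    u8 = util.img_as_ubyte(np.clip(img, 0, 1))
    return rank.entropy(u8, morphology.disk(3)).astype(float)


def _fiber_map(img: np.ndarray) -> np.ndarray:
    if img.max() == img.min():
        return np.zeros_like(img, dtype=float)
    return filters.sato(img.astype(float), sigmas=(1.0, 2.0), black_ridges=False)


def _fit_texture_map(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Residual of a 2nd-order polynomial surface fitted within the mask."""
    ys, xs = np.nonzero(mask)
    n = img.shape[0]
    y = (ys - n / 2) / n
    x = (xs - n / 2) / n
    design = np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])
    coef, *_ = np.linalg.lstsq(design, img[mask].astype(float), rcond=None)
    out = np.zeros_like(img, dtype=float)
    out[mask] = img[mask] - design @ coef
    return out


def _gradient_map(img: np.ndarray) -> np.ndarray:
    gy = ndi.sobel(img.astype(float), axis=0)
    gx = ndi.sobel(img.astype(float), axis=1)
    return np.hypot(gy, gx)


def _glcm_contrast(img: np.ndarray, mask: np.ndarray, offset: int) -> float:
    """Masked co-occurrence contrast at pixel offset n (horizontal+vertical).

    Pixels are quantized to 32 gray levels on the absolute [0, 1] scale and
    only pixel pairs that both fall inside the mask contribute.
    """
    q = np.floor(np.clip(img, 0, 1) * 31.999).astype(int)
    total, count = 0.0, 0
    for dy, dx in ((0, offset), (offset, 0)):
        a = q[: q.shape[0] - dy, : q.shape[1] - dx]
        b = q[dy:, dx:]
        valid = mask[: q.shape[0] - dy, : q.shape[1] - dx] & mask[dy:, dx:]
        if valid.any():
            diff = (a[valid].astype(float) - b[valid]) ** 2
            total += diff.sum()
            count += valid.sum()
    return float(total / count) if count else 0.0


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------
def extract_features(
    bf: np.ndarray,
    qpi: np.ndarray,
    mask: np.ndarray,
    calibration: float = 1.0,
    cell_id=None,
    provenance: str = "original",
) -> BiophysicalProfile:
    """Extract the full 84-feature profile of one cell."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    bf = np.asarray(bf, dtype=float)
    qpi = np.asarray(qpi, dtype=float)
    if not (np.isfinite(bf).all() and np.isfinite(qpi).all()):
        raise ValueError("images must be finite")
    opacity = 1.0 - bf
    flags: dict[str, str] = {}
    vals: dict[str, float] = {}

    # ---- bulk ----------------------------------------------------------
    props = measure.regionprops(mask.astype(int))[0]
    area = float(props.area)
    perim = float(props.perimeter)
    vals["Area"] = area
    vals["Perimeter"] = perim
    vals["Circularity"] = 4 * np.pi * area / perim**2 if perim > 0 else 0.0
    vals["Eccentricity"] = float(props.eccentricity)
    if props.eccentricity < _ECC_UNDEFINED:
        vals["CellOrientation"] = 0.0
        flags["CellOrientation"] = "undefined"
    else:
        vals["CellOrientation"] = float(props.orientation)
    vals["MajorAxisLength"] = float(props.axis_major_length)
    vals["MinorAxisLength"] = float(props.axis_minor_length)
    vals["AspectRatio"] = (
        float(props.axis_major_length / props.axis_minor_length)
        if props.axis_minor_length > 0 else 1.0
    )
    vals["EquivalentDiameter"] = float(props.equivalent_diameter_area)
    vals["Solidity"] = float(props.solidity)
    vals["Extent"] = float(props.extent)
    vals["ConvexArea"] = float(props.area_convex)

    # ---- global --------------------------------------------------------
    for prefix, img in (("Phase", qpi), ("Opacity", opacity)):
        s = _masked_stats(img[mask])
        vals[f"{prefix}Mean"] = s["mean"]
        vals[f"{prefix}Variance"] = s["variance"]
        vals[f"{prefix}Skewness"] = s["skewness"]
        vals[f"{prefix}Kurtosis"] = s["kurtosis"]
        vals[f"{prefix}Range"] = s["range"]
        vals[f"{prefix}Median"] = s["median"]
        vals[f"{prefix}IQR"] = s["iqr"]
    vals["PhaseEntropy"] = _entropy64(qpi[mask])
    dm = float(qpi[mask].sum()) * calibration
    vals["DryMass"] = dm
    vals["DryMassDensity"] = dm / area
    vals["DryMassVariance"] = float((qpi[mask] * calibration).var())
    vals["DryMassRadialDistribution"] = _radial_distribution(qpi, mask)
    vals["PhaseCentroidDisplacement"] = _centroid_displacement(qpi, mask)
    am = float(opacity[mask].sum()) * calibration
    vals["AttenuationMass"] = am
    vals["AttenuationDensity"] = am / area
    vals["OpacityRadialDistribution"] = _radial_distribution(opacity, mask)
    vals["OpacityCentroidDisplacement"] = _centroid_displacement(opacity, mask)

    # ---- local ---------------------------------------------------------
    maps = {
        ("QPEntropy", "qpi"): _entropy_map(qpi),
        ("QPFiber", "qpi"): _fiber_map(qpi),
        ("FitTexture", "qpi"): _fit_texture_map(qpi, mask),
        ("BFEntropy", "bf"): _entropy_map(bf),
        ("BFFiber", "bf"): _fiber_map(bf),
        ("BFFitTexture", "bf"): _fit_texture_map(bf, mask),
    }
    for (prefix, _ch), m in maps.items():
        s = _masked_stats(m[mask])
        mean_name = prefix if prefix == "BFEntropy" else prefix + "Mean"
        vals[mean_name] = s["mean"]
        vals[prefix + "Variance"] = s["variance"]
        vals[prefix + "Skewness"] = s["skewness"]
        vals[prefix + "Kurtosis"] = s["kurtosis"]
        vals[prefix + "CentroidDisplacement"] = _centroid_displacement(m, mask)
        vals[prefix + "RadialDistribution"] = _radial_distribution(np.abs(m), mask)
    for prefix, img in (("QPGradient", qpi), ("BFGradient", bf)):
        g = _gradient_map(img)
        vals[prefix + "Mean"] = float(g[mask].mean())
        vals[prefix + "Variance"] = float(g[mask].var())
    for n in range(1, 5):
        vals[f"DMDContrast{n}"] = _glcm_contrast(qpi, mask, n)
        vals[f"BFContrast{n}"] = _glcm_contrast(bf, mask, n)

    order = [d.name for d in feature_registry()]
    series = pd.Series([vals[k] for k in order], index=order, dtype=float)
    if not np.isfinite(series.to_numpy()).all():
        raise ValueError("non-finite feature value")
    return BiophysicalProfile(series, cell_id=cell_id, provenance=provenance, flags=flags)


def extract_features_table(
    bf_stack: np.ndarray,
    qpi_stack: np.ndarray,
    mask_stack: np.ndarray,
    calibration: float = 1.0,
    cell_ids=None,
    provenance: str = "original",
) -> pd.DataFrame:
    """Feature table, one row per cell, columns in registry order."""
    rows = []
    ids = cell_ids if cell_ids is not None else range(len(bf_stack))
    for i, cid in zip(range(len(bf_stack)), ids):
        prof = extract_features(
            bf_stack[i], qpi_stack[i], mask_stack[i], calibration, cid, provenance
        )
        rows.append(prof.values.rename(cid))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# profile/feature correlation
# ---------------------------------------------------------------------------
def profile_feature_correlation(
    profiles: np.ndarray,
    biophysical: pd.DataFrame,
    selected_dims=None,
    n_clusters: int = 5,
    type_labels=None,
    n_top: int = 20,
    seed: int = 0,
):
    """|Pearson r| between bottleneck dimensions and biophysical features.

    ``selected_dims`` may be given explicitly; otherwise they are chosen by
    impurity-based feature importance of a random forest trained to predict
    ``type_labels`` from the profiles.  The selected dimensions are grouped
    by average-linkage hierarchical clustering of their correlation rows.

    Returns ``(corr_df, cluster_labels, flags)`` where ``flags`` marks
    zero-variance columns whose correlation was defined as 0.
    """
    profiles = np.asarray(profiles, dtype=float)
    if len(profiles) != len(biophysical):
        raise ValueError("profiles and feature table must cover the same cells")
    if selected_dims is None:
        if type_labels is None:
            raise ValueError("need selected_dims or type_labels")
        from sklearn.ensemble import RandomForestClassifier

        rf = RandomForestClassifier(n_estimators=100, random_state=seed)
        rf.fit(profiles, np.asarray(type_labels))
        selected_dims = np.argsort(rf.feature_importances_)[::-1][:n_top]
    selected_dims = np.asarray(selected_dims)
    feats = biophysical.to_numpy(dtype=float)
    flags = {}
    corr = np.zeros((len(selected_dims), feats.shape[1]))
    for i, d in enumerate(selected_dims):
        pv = profiles[:, d]
        for j in range(feats.shape[1]):
            fv = feats[:, j]
            if pv.std() < 1e-12 or fv.std() < 1e-12:
                corr[i, j] = 0.0
                flags[(int(d), biophysical.columns[j])] = "zero_variance"
            else:
                corr[i, j] = abs(np.corrcoef(pv, fv)[0, 1])
    corr_df = pd.DataFrame(
        corr, index=[f"dim_{d}" for d in selected_dims], columns=biophysical.columns
    )
    from scipy.cluster.hierarchy import fcluster, linkage

    if len(selected_dims) >= 2:
        z = linkage(corr, method="average")
        clusters = fcluster(z, t=min(n_clusters, len(selected_dims)), criterion="maxclust")
    else:
        clusters = np.ones(len(selected_dims), dtype=int)
    return corr_df, clusters, flags
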