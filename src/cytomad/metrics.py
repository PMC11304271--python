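"""Assessment suite: cell-region image-quality metrics, batch distance,
correction ratio, hold-out-batch classification, effect sizes, subpopulation
z-scores, bootstrap sample-level AUC and 2-D embedding with batch purity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

__all__ = [
    "ssim_cell",
    "rmse_cell",
    "batch_distance",
    "correction_ratio",
    "AcrossBatchResult",
    "across_batch_classify",
    "cohens_d",
    "subpopulation_zscores",
    "sample_level_auc",
    "embed_2d",
    "batch_purity",
]

_EPSILON = 1e-12


def _check_pair(pred, truth, mask):
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if pred.shape != truth.shape or pred.shape != mask.shape:
        raise ValueError("pred, truth and mask shapes must match")
    if not mask.any():
        raise ValueError("empty mask")
    return pred, truth, mask


def ssim_cell(
    pred: np.ndarray, truth: np.ndarray, mask: np.ndarray, mode: str = "windowed"
) -> float:
    """Structural similarity restricted to the cell region.

    ``windowed`` (default): per-pixel SSIM map with an 11x11 Gaussian window
    (sigma 1.5), K1=0.01, K2=0.03, dynamic range 1, averaged over mask
    pixels.  ``global``: the SSIM formula evaluated once on the masked
    pixel population.
    """
    pred, truth, mask = _check_pair(pred, truth, mask)
    c1, c2 = 0.01**2, 0.03**2
    if mode == "windowed":
        _, smap = structural_similarity(
            truth,
            pred,
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            K1=0.01,
            K2=0.03,
            data_range=1.0,
            full=True,
            use_sample_covariance=False,
        )
        return float(smap[mask].mean())
    if mode == "global":
        a, b = truth[mask], pred[mask]
        mu_a, mu_b = a.mean(), b.mean()
        va, vb = a.var(), b.var()
        cov = ((a - mu_a) * (b - mu_b)).mean()
        return float(
            (2 * mu_a * mu_b + c1) * (2 * cov + c2)
            / ((mu_a**2 + mu_b**2 + c1) * (va + vb + c2))
        )
    raise ValueError("mode must be 'windowed' or 'global'")


def rmse_cell(pred: np.ndarray, truth: np.ndarray, mask: np.ndarray) -> float:
    """Root-mean-square pixel error over the cell region."""
    pred, truth, mask = _check_pair(pred, truth, mask)
    return float(np.sqrt(((pred - truth) ** 2)[mask].mean()))


def batch_distance(feature_table: pd.DataFrame, batch_ids) -> pd.Series:
    """Per-feature difference in batch means.

    Two batches: ``|mean_1 - mean_2|``; more: the mean of pairwise absolute
    mean differences over all unordered batch pairs.
    """
    batch_ids = np.asarray(batch_ids)
    batches = pd.unique(batch_ids)
    if len(batches) < 2:
        raise ValueError("need at least 2 batches")
    means = []
    for b in batches:
        sel = batch_ids == b
        if not sel.any():
            raise ValueError(f"batch {b} has no cells")
        means.append(feature_table.loc[sel].mean(axis=0))
    means = pd.DataFrame(means)
    dists = []
    for i in range(len(batches)):
        for j in range(i + 1, len(batches)):
            dists.append((means.iloc[i] - means.iloc[j]).abs())
    return pd.concat(dists, axis=1).mean(axis=1)


def correction_ratio(distance_before, distance_after):
    """Fractional reduction of batch distance: (before - after) / before.

    Positive means reduced batch distance.  Where ``before`` is ~0 the ratio
    is undefined and reported as 0 with a flag.  Accepts scalars or aligned
    Series; returns ``(ratio, undefined_flag)`` of the same kind.
    """
    before = np.asarray(distance_before, dtype=float)
    after = np.asarray(distance_after, dtype=float)
    if (before < 0).any() or (after < 0).any():
        raise ValueError("batch distances must be nonnegative")
    undefined = before < _EPSILON
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(undefined, 0.0, (before - after) / np.where(undefined, 1.0, before))
    if isinstance(distance_before, pd.Series):
        return (
            pd.Series(ratio, index=distance_before.index),
            pd.Series(undefined, index=distance_before.index),
        )
    if np.ndim(distance_before) == 0:
        return float(ratio), bool(undefined)
    return ratio, undefined


@dataclass
class AcrossBatchResult:
    confusion_matrix: pd.DataFrame  # rows true class, columns predicted
    overall_accuracy: float
    train_batches: list
    test_batches: list

    def row_normalized(self) -> pd.DataFrame:
        cm = self.confusion_matrix
        return cm.div(cm.sum(axis=1).replace(0, np.nan), axis=0)


def across_batch_classify(
    x: np.ndarray,
    class_labels,
    batch_ids,
    train_batches,
    per_class_train_n: int | None = None,
    epochs: int = 100,
    minibatch_size: int = 32,
    learning_rate: float = 1e-3,
    seed: int = 0,
    balance: bool = False,
) -> AcrossBatchResult:
    """Train on selected batches only; evaluate on all cells of unseen batches.

    Vector inputs get the 3-dense-layer (75/50/25) classifier; image inputs
    (n, H, W) get the 5-block convolutional classifier.  Test batches are
    all batches not in ``train_batches`` and are never touched during
    training.
    """
    from .distillator import ConvClassifier, DenseClassifier, _fit_classifier, \
        _balance_downsample, ClassifierTrainConfig, _onehot

    x = np.asarray(x, dtype=np.float32)
    class_labels = np.asarray(class_labels)
    batch_ids = np.asarray(batch_ids)
    train_batches = list(train_batches)
    all_batches = list(pd.unique(batch_ids))
    test_batches = [b for b in all_batches if b not in train_batches]
    if not test_batches:
        raise ValueError("no unseen batches left for testing")
    train_sel = np.isin(batch_ids, train_batches)
    test_sel = ~train_sel
    classes = sorted(set(class_labels))
    rng = np.random.default_rng(seed)

    idx = np.flatnonzero(train_sel)
    if balance:
        idx = idx[_balance_downsample(class_labels[idx], rng)]
    if per_class_train_n is not None:
        chosen = []
        for c in classes:
            ci = idx[class_labels[idx] == c]
            if len(ci) > per_class_train_n:
                ci = rng.choice(ci, size=per_class_train_n, replace=False)
            chosen.append(ci)
        idx = np.sort(np.concatenate(chosen))
    x_train, y_train = x[idx], class_labels[idx]
    if len(set(y_train)) < 2:
        raise ValueError("training set must contain at least 2 classes")

    cfg = ClassifierTrainConfig(
        epochs=epochs, minibatch_size=minibatch_size,
        learning_rate=learning_rate, seed=seed,
    )
    if x.ndim >= 3:
        clf = ConvClassifier(x.shape[-1], len(classes), rng)
    else:
        clf = DenseClassifier(x.shape[1], len(classes), rng)
    _fit_classifier(clf, x_train, _onehot(y_train, classes), cfg, rng)

    x_test, y_test = x[test_sel], class_labels[test_sel]
    missing = [c for c in classes if c not in set(y_test)]
    if missing:
        import warnings

        warnings.warn(f"classes absent from test batches: {missing}", stacklevel=2)
    pred = np.asarray(classes)[clf.predict(x_test)]
    cm = pd.DataFrame(0, index=classes, columns=classes)
    for t, p in zip(y_test, pred):
        cm.loc[t, p] += 1
    return AcrossBatchResult(
        confusion_matrix=cm,
        overall_accuracy=float((pred == y_test).mean()),
        train_batches=train_batches,
        test_batches=test_batches,
    )


def cohens_d(sample_a, sample_b) -> float:
    """Pooled-SD standardized mean difference."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs n >= 2")
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled <= 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled)


def subpopulation_zscores(
    feature_table: pd.DataFrame, subpop_assignments
) -> pd.DataFrame:
    """z = (subpopulation mean - overall mean) / overall SD, per feature.

    Zero-overall-SD features are flagged by a 0 z-score.
    """
    sub = np.asarray(subpop_assignments)
    if len(sub) != len(feature_table):
        raise ValueError("assignments must align with the feature table")
    overall_mean = feature_table.mean(axis=0)
    overall_sd = feature_table.std(axis=0, ddof=0)
    rows = {}
    for s in pd.unique(sub):
        sel = sub == s
        if not sel.any():
            raise ValueError(f"empty subpopulation {s}")
        diff = feature_table.loc[sel].mean(axis=0) - overall_mean
        z = diff.divide(overall_sd.replace(0.0, np.nan)).fillna(0.0)
        rows[s] = z
    return pd.DataFrame(rows).T


def sample_level_auc(
    profiles: np.ndarray,
    sample_ids,
    sample_labels: dict,
    n_boot: int = 1000,
    seed: int = 0,
    max_redraws: int = 1000,
) -> tuple[float, np.ndarray]:
    """Logistic-regression AUC on per-sample ensemble-averaged profiles.

    Cell profiles are averaged per sample; a logistic model on the sample
    means predicts the binary sample label.  The point estimate is the ROC
    AUC of leave-one-sample-out predicted probabilities; the bootstrap
    resamples *samples* with replacement ``n_boot`` times, fits on each
    draw and scores the out-of-bag samples (a draw whose training or
    out-of-bag part is single-class is redrawn, counted and capped), so
    chance-level labels honestly give AUC near 0.5.
    Returns ``(point_estimate, bootstrap_distribution)``.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score

    profiles = np.asarray(profiles, dtype=float)
    sample_ids = np.asarray(sample_ids)
    samples = list(pd.unique(sample_ids))
    means = np.stack([profiles[sample_ids == s].mean(axis=0) for s in samples])
    y = np.asarray([sample_labels[s] for s in samples])
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly 2 sample labels")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError("need >= 2 samples per label")
    ybin = (y == classes[1]).astype(int)

    def fit_auc(xm, yb, x_eval, y_eval):
        lr = LogisticRegression(max_iter=1000)
        lr.fit(xm, yb)
        return roc_auc_score(y_eval, lr.predict_proba(x_eval)[:, 1])

    n = len(samples)
    loo_scores = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        lr = LogisticRegression(max_iter=1000)
        lr.fit(means[keep], ybin[keep])
        loo_scores[i] = lr.predict_proba(means[i : i + 1])[0, 1]
    point = float(roc_auc_score(ybin, loo_scores))
    rng = np.random.default_rng(seed)
    boot = []
    redraws = 0
    for _ in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
            if (
                len(np.unique(ybin[idx])) == 2
                and len(oob) > 0
                and len(np.unique(ybin[oob])) == 2
            ):
                break
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("too many single-class bootstrap draws")
        boot.append(fit_auc(means[idx], ybin[idx], means[oob], ybin[oob]))
    return point, np.asarray(boot)


def embed_2d(profiles: np.ndarray, seed: int = 0, n_neighbors: int = 15) -> np.ndarray:
    """2-D manifold projection of profiles (delegates to umap-learn)."""
    profiles = np.asarray(profiles, dtype=float)
    if len(profiles) < 10:
        raise ValueError("need at least 10 points to embed")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from umap import UMAP

        coords = UMAP(
            n_components=2,
            n_neighbors=min(n_neighbors, len(profiles) - 1),
            random_state=seed,
        ).fit_transform(profiles)
    coords = np.asarray(coords, dtype=float)
    if not np.isfinite(coords).all():
        raise RuntimeError("embedding produced non-finite coordinates")
    return coords


def batch_purity(coords: np.ndarray, batch_ids, k: int = 15) -> float:
    """Mean fraction of each point's k nearest neighbors sharing its batch.

    For perfectly mixed batches this approaches the batch proportions
    (e.g. 1/n_batches for balanced batches); 1.0 means total segregation.
    """
    from sklearn.neighbors import NearestNeighbors

    coords = np.asarray(coords, dtype=float)
    batch_ids = np.asarray(batch_ids)
    k = min(k, len(coords) - 1)
    nbrs = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nbrs.kneighbors(coords)
    same = batch_ids[idx[:, 1:]] == batch_ids[:, None]
    return float(same.mean())
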