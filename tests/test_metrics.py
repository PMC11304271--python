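"""Evaluation metrics against brute-force oracles and protocol contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cytomad.metrics import (
    across_batch_classify,
    batch_distance,
    batch_purity,
    cohens_d,
    correction_ratio,
    embed_2d,
    rmse_cell,
    sample_level_auc,
    ssim_cell,
    subpopulation_zscores,
)


def _gaussian_kernel(sigma=1.5, truncate=3.5):
    r = int(truncate * sigma + 0.5)
    x = np.arange(-r, r + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return np.outer(k, k) / np.outer(k, k).sum(), r


def ssim_map_bruteforce(x, y):
    """Literal windowed SSIM map: per-pixel loop, reflect padding, Gaussian
    weights, population covariance, K1=0.01, K2=0.03, L=1."""
    k2d, r = _gaussian_kernel()
    xp = np.pad(x, r, mode="symmetric")
    yp = np.pad(y, r, mode="symmetric")
    c1, c2 = 0.01**2, 0.03**2
    out = np.zeros_like(x, dtype=float)
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            wx = xp[i : i + 2 * r + 1, j : j + 2 * r + 1]
            wy = yp[i : i + 2 * r + 1, j : j + 2 * r + 1]
            mx = (k2d * wx).sum()
            my = (k2d * wy).sum()
            vx = (k2d * wx * wx).sum() - mx * mx
            vy = (k2d * wy * wy).sum() - my * my
            cxy = (k2d * wx * wy).sum() - mx * my
            out[i, j] = ((2 * mx * my + c1) * (2 * cxy + c2)) / (
                (mx * mx + my * my + c1) * (vx + vy + c2)
            )
    return out


@pytest.fixture
def random_pairs(rng):
    out = []
    for _ in range(10):
        a = rng.random((24, 24))
        b = np.clip(a + rng.normal(0, 0.1, size=a.shape), 0, 1)
        mask = rng.random((24, 24)) > 0.4
        mask[10:14, 10:14] = True  # keep non-empty
        out.append((a, b, mask))
    return out


class TestSSIM:
    def test_identity_gives_one(self, disk_pair):
        assert ssim_cell(disk_pair.qpi, disk_pair.qpi, disk_pair.mask) == pytest.approx(1.0)

    def test_inverted_cell_is_negative(self, disk_pair):
        inv = 1.0 - disk_pair.qpi
        assert ssim_cell(inv, disk_pair.qpi, disk_pair.mask) < 0

    def test_matches_bruteforce_windowed_formula(self, random_pairs):
        for a, b, mask in random_pairs:
            mine = ssim_cell(b, a, mask)
            oracle = ssim_map_bruteforce(a, b)[mask].mean()
            assert mine == pytest.approx(oracle, abs=1e-8)

    def test_background_perturbation_changes_nothing_global_mode(self, disk_pair, rng):
        pred = np.clip(disk_pair.qpi + rng.normal(0, 0.05, disk_pair.qpi.shape), 0, 1)
        base = ssim_cell(pred, disk_pair.qpi, disk_pair.mask, mode="global")
        pred2, truth2 = pred.copy(), disk_pair.qpi.copy()
        pred2[~disk_pair.mask] = rng.random((~disk_pair.mask).sum())
        truth2[~disk_pair.mask] = rng.random((~disk_pair.mask).sum())
        assert ssim_cell(pred2, truth2, disk_pair.mask, mode="global") == pytest.approx(base)

    def test_empty_mask_rejected(self, disk_pair):
        with pytest.raises(ValueError, match="empty mask"):
            ssim_cell(disk_pair.qpi, disk_pair.qpi, np.zeros_like(disk_pair.mask))


class TestRMSE:
    def test_identity_and_constant_offset(self, disk_pair):
        assert rmse_cell(disk_pair.qpi, disk_pair.qpi, disk_pair.mask) == 0.0
        shifted = disk_pair.qpi + 0.05  # deliberately unclipped
        assert rmse_cell(shifted, disk_pair.qpi, disk_pair.mask) == pytest.approx(0.05)

    def test_matches_bruteforce_loop(self, random_pairs):
        for a, b, mask in random_pairs:
            total, count = 0.0, 0
            for i in range(a.shape[0]):
                for j in range(a.shape[1]):
                    if mask[i, j]:
                        total += (a[i, j] - b[i, j]) ** 2
                        count += 1
            assert rmse_cell(a, b, mask) == pytest.approx(
                np.sqrt(total / count), abs=1e-10
            )

    def test_background_independence(self, disk_pair, rng):
        pred = np.clip(disk_pair.qpi + 0.1, 0, 1)
        base = rmse_cell(pred, disk_pair.qpi, disk_pair.mask)
        pred2 = pred.copy()
        pred2[~disk_pair.mask] += rng.random((~disk_pair.mask).sum())
        assert rmse_cell(pred2, disk_pair.qpi, disk_pair.mask) == base


class TestBatchDistance:
    def test_two_and_three_batch_hand_values(self):
        table = pd.DataFrame({"f": [1.0, 1.0, 1.5, 1.5]})
        d = batch_distance(table, ["a", "a", "b", "b"])
        assert d["f"] == pytest.approx(0.5)
        table3 = pd.DataFrame({"f": [0.0, 1.0, 2.0]})
        d3 = batch_distance(table3, ["a", "b", "c"])
        assert d3["f"] == pytest.approx(4 / 3)

    def test_identical_batches_give_zero(self, rng):
        vals = rng.random(30)
        table = pd.DataFrame({"f": np.concatenate([vals, vals])})
        d = batch_distance(table, ["a"] * 30 + ["b"] * 30)
        assert abs(d["f"]) < 1e-12

    def test_permutation_invariance(self, rng):
        table = pd.DataFrame({"f": rng.random(60), "g": rng.random(60)})
        ids = np.array(["a", "b", "c"] * 20)
        d1 = batch_distance(table, ids)
        relabel = {"a": "c", "b": "a", "c": "b"}
        d2 = batch_distance(table, [relabel[i] for i in ids])
        pd.testing.assert_series_equal(d1, d2)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            batch_distance(pd.DataFrame({"f": [1.0]}), ["a"])


class TestCorrectionRatio:
    def test_hand_values(self):
        assert correction_ratio(0.5, 0.1)[0] == pytest.approx(0.8)
        assert correction_ratio(0.5, 0.7)[0] == pytest.approx(-0.4)
        ratio, flag = correction_ratio(0.0, 0.3)
        assert ratio == 0.0 and flag

    @given(st.floats(1e-6, 10), st.floats(0, 10))
    def test_never_exceeds_one(self, before, after):
        ratio, _ = correction_ratio(before, after)
        assert ratio <= 1.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            correction_ratio(-0.1, 0.1)


class TestCohensD:
    def test_construction_and_identity(self, rng):
        a = rng.normal(1, 1, size=20000)
        b = rng.normal(0, 1, size=20000)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.05)
        x = rng.normal(size=50)
        assert cohens_d(x, x) == 0.0

    def test_matches_hand_computation_five_vs_five(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 2.5, 3.5, 4.5, 6.0])
        pooled = np.sqrt(((4 * a.var(ddof=1)) + (4 * b.var(ddof=1))) / 8)
        assert cohens_d(a, b) == pytest.approx((a.mean() - b.mean()) / pooled, abs=1e-12)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])


class TestSubpopulationZScores:
    def test_whole_population_zscore_is_zero(self, rng):
        table = pd.DataFrame(rng.random((40, 3)), columns=list("abc"))
        z = subpopulation_zscores(table, ["all"] * 40)
        assert np.abs(z.to_numpy()).max() < 1e-12

    def test_shifted_subpopulation_and_bruteforce(self, rng):
        # a small subpopulation shifted by 2 overall SD barely moves the
        # overall statistics, so its z-score approaches 2
        x = rng.normal(size=2000)
        sub = np.array(["s1"] * 1980 + ["s2"] * 20)
        x[sub == "s2"] += 2 * x.std()
        table = pd.DataFrame({"f": x})
        z = subpopulation_zscores(table, sub)
        expected = (x[sub == "s2"].mean() - x.mean()) / x.std()
        assert z.loc["s2", "f"] == pytest.approx(expected, abs=1e-12)
        assert z.loc["s2", "f"] == pytest.approx(2.0, abs=0.3)

    def test_zero_sd_feature_flagged_zero(self):
        table = pd.DataFrame({"const": np.ones(10)})
        z = subpopulation_zscores(table, ["a"] * 5 + ["b"] * 5)
        assert (z["const"] == 0).all()


class TestAcrossBatchClassify:
    def test_informative_features_give_perfect_accuracy(self, rng):
        labels = np.array(["t0", "t1"] * 60)
        x = np.eye(2, dtype=np.float32)[(labels == "t1").astype(int)]
        batches = np.repeat(["b0", "b1", "b2"], 40)
        res = across_batch_classify(x, labels, batches, ["b0"], epochs=40, seed=0)
        assert res.overall_accuracy == 1.0

    def test_batch_only_features_give_chance_accuracy(self, rng):
        labels = np.array(["t0", "t1"] * 60)
        batches = np.repeat(["b0", "b1", "b2"], 40)
        x = np.eye(3, dtype=np.float32)[
            pd.Categorical(batches).codes
        ] + rng.normal(0, 0.01, size=(120, 3)).astype(np.float32)
        res = across_batch_classify(x, labels, batches, ["b0"], epochs=30, seed=0)
        assert abs(res.overall_accuracy - 0.5) < 0.1

    def test_train_and_test_batches_always_disjoint(self, rng):
        labels = np.array(["t0", "t1"] * 30)
        batches = np.repeat(["b0", "b1", "b2"], 20)
        x = rng.random((60, 4)).astype(np.float32)
        res = across_batch_classify(x, labels, batches, ["b1"], epochs=2, seed=0)
        assert not set(res.train_batches) & set(res.test_batches)
        assert set(res.test_batches) == {"b0", "b2"}

    def test_confusion_matrix_counts_test_cells_only(self, rng):
        labels = np.array(["t0", "t1"] * 30)
        batches = np.repeat(["b0", "b1", "b2"], 20)
        x = rng.random((60, 4)).astype(np.float32)
        res = across_batch_classify(x, labels, batches, ["b0"], epochs=2, seed=0)
        assert res.confusion_matrix.to_numpy().sum() == 40


class TestSampleLevelAUC:
    def _profiles(self, rng, separated):
        n_samples, cells = 20, 15
        labels = {}
        profs, sids = [], []
        for s in range(n_samples):
            lab = s % 2
            labels[f"s{s}"] = "tumor" if lab else "normal"
            mu = (2.0 * lab) if separated else 0.0
            profs.append(rng.normal(mu, 1, size=(cells, 6)))
            sids += [f"s{s}"] * cells
        return np.concatenate(profs), np.array(sids), labels

    def test_perfect_separation_gives_auc_one(self, rng):
        profs, sids, labels = self._profiles(rng, separated=True)
        point, boot = sample_level_auc(profs, sids, labels, n_boot=50, seed=0)
        assert point == 1.0

    def test_permuted_labels_give_chance_auc(self, rng):
        profs, sids, labels = self._profiles(rng, separated=False)
        point, boot = sample_level_auc(profs, sids, labels, n_boot=200, seed=1)
        assert abs(boot.mean() - 0.5) < 0.15

    def test_fixed_seed_reproduces_bootstrap(self, rng):
        profs, sids, labels = self._profiles(rng, separated=True)
        _, b1 = sample_level_auc(profs, sids, labels, n_boot=30, seed=5)
        _, b2 = sample_level_auc(profs, sids, labels, n_boot=30, seed=5)
        np.testing.assert_array_equal(b1, b2)


class TestEmbedding:
    def test_shape_finite_and_class_structure(self, rng):
        x = np.concatenate([
            rng.normal(0, 0.3, size=(40, 8)),
            rng.normal(5, 0.3, size=(40, 8)),
        ])
        coords = embed_2d(x, seed=0)
        assert coords.shape == (80, 2)
        assert np.isfinite(coords).all()
        from sklearn.metrics import silhouette_score

        labels = np.array([0] * 40 + [1] * 40)
        assert silhouette_score(coords, labels) > 0

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            embed_2d(rng.random((5, 4)))

    def test_batch_purity_of_mixed_labels_near_baseline(self, rng):
        coords = rng.random((300, 2))
        batches = rng.integers(0, 3, size=300)
        purity = batch_purity(coords, batches)
        assert abs(purity - 1 / 3) < 0.08

    def test_batch_purity_of_segregated_batches_is_high(self, rng):
        coords = np.concatenate([
            rng.normal(0, 0.1, size=(50, 2)), rng.normal(10, 0.1, size=(50, 2)),
        ])
        batches = np.array(["a"] * 50 + ["b"] * 50)
        assert batch_purity(coords, batches) > 0.95
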