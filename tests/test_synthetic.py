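"""Synthetic image generator: rendering, batch effects, dataset assembly."""

import numpy as np
import pytest
from scipy import integrate

from cytomad.synthetic import (
    BatchEffectParams,
    CellParams,
    apply_batch_effect,
    default_sim_config,
    generate_dataset,
    render_cell,
)


def _params(**kw):
    base = dict(
        cell_type="A", radius_px=8.0, eccentricity=0.0, orientation_rad=0.0,
        peak_phase=0.6, texture_granularity=2.0, texture_amplitude=0.0,
    )
    base.update(kw)
    return CellParams(**base)


class TestRenderCell:
    def test_radially_symmetric_peak_at_center(self):
        pair = render_cell(_params(peak_phase=0.7), 32, np.random.default_rng(0))
        assert pair.qpi.max() == pytest.approx(0.7, abs=0.02)
        # symmetry: rotating the image by 90 degrees changes nothing
        np.testing.assert_allclose(pair.qpi, np.rot90(pair.qpi), atol=1e-6)

    def test_same_rng_state_gives_bit_identical_pair(self):
        p = _params(texture_amplitude=0.1)
        a = render_cell(p, 32, np.random.default_rng(42))
        b = render_cell(p, 32, np.random.default_rng(42))
        np.testing.assert_array_equal(a.qpi, b.qpi)
        np.testing.assert_array_equal(a.bf, b.bf)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_integrated_phase_matches_analytic_integral(self):
        # independent oracle: numerically integrate the continuous radial
        # profile peak * (1 - (r/R)^2) over the disk
        peak, radius = 0.8, 10.0
        pair = render_cell(
            _params(radius_px=radius, peak_phase=peak), 32, np.random.default_rng(0)
        )
        analytic, _ = integrate.quad(
            lambda r: peak * (1 - (r / radius) ** 2) * 2 * np.pi * r, 0, radius
        )
        assert pair.qpi.sum() == pytest.approx(analytic, rel=0.02)

    def test_background_exactly_zero_and_bf_learnable(self):
        pair = render_cell(_params(), 32, np.random.default_rng(1))
        assert (pair.qpi[~pair.mask] == 0).all()
        assert pair.bf.min() >= 0 and pair.bf.max() <= 1

    def test_cell_larger_than_field_raises(self):
        with pytest.raises(ValueError, match="exceeds field of view"):
            render_cell(_params(radius_px=15.0), 32, np.random.default_rng(0))

    @pytest.mark.parametrize(
        "kw", [dict(radius_px=2.0), dict(peak_phase=0.0), dict(eccentricity=1.0),
               dict(texture_amplitude=-0.1)]
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            _params(**kw)


class TestApplyBatchEffect:
    def test_neutral_parameters_are_identity(self, disk_pair):
        eff = BatchEffectParams("b0")
        out = apply_batch_effect(disk_pair, eff, np.random.default_rng(0))
        np.testing.assert_allclose(out.qpi, disk_pair.qpi, atol=1e-6)
        np.testing.assert_allclose(out.bf, disk_pair.bf, atol=1e-6)
        np.testing.assert_array_equal(out.mask, disk_pair.mask)
        assert out.meta["batch_id"] == "b0"

    def test_offset_shifts_unclipped_mean_exactly(self, disk_pair):
        eff = BatchEffectParams("b1", offset=0.1)
        out = apply_batch_effect(disk_pair, eff, np.random.default_rng(0))
        unclipped = disk_pair.qpi + 0.1 < 1.0
        np.testing.assert_allclose(
            out.qpi[unclipped] - disk_pair.qpi[unclipped], 0.1, atol=1e-6
        )

    def test_blur_reduces_gradient_energy_focus_factor(self, disk_pair):
        from cytomad.qc import focus_factors

        blurred = apply_batch_effect(
            disk_pair, BatchEffectParams("b2", psf_sigma=2.0), np.random.default_rng(0)
        )
        f_sharp = focus_factors(disk_pair.bf, disk_pair.qpi, disk_pair.mask)
        f_blur = focus_factors(blurred.bf, blurred.qpi, blurred.mask)
        assert f_blur["qpi"].gradient_energy < f_sharp["qpi"].gradient_energy

    def test_clean_target_has_no_photometric_distortion(self, disk_pair):
        eff = BatchEffectParams("b3", gain=1.3, offset=0.1, noise_sigma=0.05)
        out = apply_batch_effect(disk_pair, eff, np.random.default_rng(0))
        np.testing.assert_allclose(out.qpi_clean, disk_pair.qpi, atol=1e-6)

    def test_metadata_labels_never_altered(self, disk_pair):
        disk_pair.meta["cell_type"] = "X"
        disk_pair.meta["marker_label"] = "EpCAM+"
        eff = BatchEffectParams("b4", gain=1.2, noise_sigma=0.1, shear=0.1)
        out = apply_batch_effect(disk_pair, eff, np.random.default_rng(0))
        assert out.meta["cell_type"] == "X"
        assert out.meta["marker_label"] == "EpCAM+"


class TestGenerateDataset:
    def test_counts_and_metadata_alignment(self):
        cfg = default_sim_config(5, 32, seed=0)
        ds = generate_dataset(cfg)
        assert len(ds) == 2 * 3 * 5
        assert len(ds.meta) == len(ds.pairs)
        counts = ds.meta.groupby(["batch_id", "cell_type"]).size()
        assert (counts == 5).all()

    def test_same_seed_reproduces_everything(self):
        a = generate_dataset(default_sim_config(4, 32, seed=5))
        b = generate_dataset(default_sim_config(4, 32, seed=5))
        assert a.meta.equals(b.meta)
        np.testing.assert_array_equal(a.qpi, b.qpi)

    def test_type_radius_distributions_separate_mask_areas(self):
        cfg = default_sim_config(50, 48, seed=3)
        cfg.cell_type_param_distributions["typeA"].radius_mean = 8.0
        cfg.cell_type_param_distributions["typeB"].radius_mean = 14.0
        ds = generate_dataset(cfg)
        areas = ds.masks.reshape(len(ds), -1).sum(axis=1)
        ta = areas[(ds.meta.cell_type == "typeA").to_numpy()]
        tb = areas[(ds.meta.cell_type == "typeB").to_numpy()]
        pooled_sd = np.sqrt((ta.var() + tb.var()) / 2)
        assert abs(tb.mean() - ta.mean()) > 3 * pooled_sd

    def test_neutral_batches_have_near_zero_batch_distance(self):
        from cytomad.metrics import batch_distance
        import pandas as pd

        cfg = default_sim_config(60, 32, seed=11)
        cfg.batches = [BatchEffectParams(f"b{i}") for i in range(3)]
        ds = generate_dataset(cfg)
        qpi_mean = ds.qpi.reshape(len(ds), -1).mean(axis=1)
        table = pd.DataFrame({"qpi_mean": qpi_mean})
        d = batch_distance(table, ds.meta.batch_id.to_numpy())
        # zero up to sampling error of the cell-parameter distributions
        assert d["qpi_mean"] < 3 * qpi_mean.std() / np.sqrt(60)

    def test_inconsistent_config_rejected(self):
        cfg = default_sim_config(5, 32)
        cfg.batches = cfg.batches[:1]
        with pytest.raises(ValueError):
            generate_dataset(cfg)
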