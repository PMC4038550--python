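"""Field synthesis: placement geometry, rendering arithmetic, camera noise."""

import numpy as np
import pytest

import darkbench as db
from darkbench.imaging import _bin_labels_majority, _rasterize


def pairwise_gap_bruteforce(geoms, shape):
    """Oracle: minimum boundary gap from independently rasterized footprints."""
    masks = [_rasterize([g], shape) > 0 for g in geoms]
    coords = [np.argwhere(m).astype(float) for m in masks]
    best = np.inf
    for i in range(len(geoms)):
        for j in range(i + 1, len(geoms)):
            d = np.sqrt(((coords[i][:, None, :] - coords[j][None, :, :]) ** 2
                         ).sum(-1)).min()
            best = min(best, d)
    return best


class TestPlaceCells:
    def test_zero_cells(self, small_spec):
        assert db.place_cells(small_spec, 0, seed=0) == []

    def test_min_gap_respected(self, small_spec):
        geoms = db.place_cells(small_spec, 10, seed=3)
        assert len(geoms) == 10
        gap = pairwise_gap_bruteforce(geoms,
                                      (small_spec.height_px, small_spec.width_px))
        # rasterized-footprint gap can undershoot the continuous gap by ~1 px
        assert gap >= small_spec.min_gap_px - 1.5

    def test_saturation_warns_and_returns_fewer(self):
        spec = db.FieldSpec(width_px=128, height_px=128, n_cells_target=500)
        with pytest.warns(UserWarning, match="saturated"):
            geoms = db.place_cells(spec, 500, seed=1, max_attempts_per_cell=20)
        assert 0 < len(geoms) < 500

    def test_deterministic(self, small_spec):
        a = db.place_cells(small_spec, 15, seed=7)
        b = db.place_cells(small_spec, 15, seed=7)
        assert a == b


class TestRenderField:
    def test_empty_field_uniform(self, small_spec, quiet_camera):
        img = db.render_field(np.empty(0), [], small_spec, quiet_camera, seed=0)
        expected = quiet_camera.offset + quiet_camera.gain * small_spec.fluor_bg_level
        assert np.all(img.fluorescence == expected)

    def test_single_cell_exact_level(self, quiet_camera):
        spec = db.FieldSpec(width_px=128, height_px=128, psf_sigma_px=0.0)
        geoms = db.place_cells(spec, 1, seed=2)
        v = 150.0
        img = db.render_field([v], geoms, spec, quiet_camera, seed=0)
        inside = img.truth_mask == 1
        level = quiet_camera.offset + quiet_camera.gain * (spec.fluor_bg_level + v)
        assert img.fluorescence[inside] == pytest.approx(level)
        assert img.brightfield[inside] == pytest.approx(
            quiet_camera.offset + quiet_camera.gain * spec.brightfield_bg_level
            * (1 - spec.brightfield_cell_contrast))

    def test_value_count_mismatch(self, small_spec, quiet_camera):
        geoms = db.place_cells(small_spec, 3, seed=1)
        with pytest.raises(ValueError, match="one intensity value per cell"):
            db.render_field([1.0, 2.0], geoms, small_spec, quiet_camera, seed=0)

    def test_shot_noise_variance_closed_form(self):
        """Flat field: pixel variance = gain^2 * level + read_noise^2."""
        spec = db.FieldSpec(width_px=400, height_px=400, psf_sigma_px=0.0,
                            fluor_bg_level=50.0)
        cam = db.CameraModel(shot_noise=True, read_noise_sd=5.0, gain=4.0,
                             binning=1)
        img = db.render_field(np.empty(0), [], spec, cam, seed=11)
        expected = cam.gain ** 2 * spec.fluor_bg_level + cam.read_noise_sd ** 2
        assert img.fluorescence.var() == pytest.approx(expected, rel=0.05)

    def test_binning_halves_dims_and_averages(self, catalogue):
        spec = db.FieldSpec(width_px=128, height_px=128)
        cam1 = db.CameraModel(shot_noise=False, read_noise_sd=0, binning=1)
        cam2 = db.CameraModel(shot_noise=False, read_noise_sd=0, binning=2)
        geoms = db.place_cells(spec, 2, seed=5)
        img1 = db.render_field([50.0, 80.0], geoms, spec, cam1, seed=0)
        img2 = db.render_field([50.0, 80.0], geoms, spec, cam2, seed=0)
        assert img2.fluorescence.shape == (64, 64)
        manual = img1.fluorescence.reshape(64, 2, 64, 2).mean(axis=(1, 3))
        np.testing.assert_allclose(img2.fluorescence, manual)

    def test_truth_labels_consecutive(self, rendered_field):
        labels = np.unique(rendered_field.truth_mask)
        assert labels[0] == 0
        np.testing.assert_array_equal(labels[1:], np.arange(1, labels.max() + 1))

    def test_deterministic(self, small_spec):
        geoms = db.place_cells(small_spec, 5, seed=1)
        cam = db.CameraModel()
        vals = np.full(5, 100.0)
        a = db.render_field(vals, geoms, small_spec, cam, seed=9)
        b = db.render_field(vals, geoms, small_spec, cam, seed=9)
        np.testing.assert_array_equal(a.fluorescence, b.fluorescence)
        np.testing.assert_array_equal(a.brightfield, b.brightfield)


class TestLabelBinning:
    def test_majority_rule(self):
        lab = np.zeros((4, 4), dtype=np.int32)
        lab[0:2, 0:2] = 1          # block fully label 1 -> 1
        lab[0, 2] = 2              # block 1/4 label 2 -> background majority
        lab[2:4, 0:2] = [[3, 3], [3, 0]]   # 3 of 4 -> label 3
        lab[2:4, 2:4] = [[4, 4], [5, 5]]   # 2-2 tie -> background
        out = _bin_labels_majority(lab, 2)
        np.testing.assert_array_equal(out, [[1, 0], [3, 0]])


class TestFieldIO:
    def test_write_field_layout(self, rendered_field, tmp_path):
        paths = db.write_field(rendered_field, tmp_path / "run", stem="field3")
        for tag in ("bf", "fl", "mask", "truth"):
            assert tag in paths
        from darkbench.imaging import read_image
        back = read_image(paths["fl"])
        assert back.shape == rendered_field.fluorescence.shape
        np.testing.assert_allclose(back, np.round(rendered_field.fluorescence))
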