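"""Prediction maps, accuracy harness, demosaicing ablation."""

import numpy as np
import pandas as pd
import pytest

from speclive.cnn import build_model
from speclive.dataset import SampleSpectra
from speclive.demosaic import demosaic_msfa
from speclive.evalmap import (demosaic_ablation, evaluate_accuracy,
                              per_spectrum_accuracy, prediction_map)
from speclive.grids import DEFAULT_GRID
from speclive.materials import MaterialSpec, smooth_random_spectrum
from speclive.region import reference_vector, select_flat_region
from speclive.scene import make_face_scene, make_gradient_scene
from speclive.sensor import render_mosaic


def _stub_model(target_class):
    """Model that predicts `target_class` for every input."""
    m = build_model(seed=0)
    m.params["W_o"][:] = 0.0
    m.params["b_o"][:] = 0.0
    m.params["b_o"][target_class] = 5.0
    return m


@pytest.fixture(scope="module")
def skin_capture(sensor, operator):
    scene = make_face_scene(96, 96, skin=MaterialSpec("skin", seed=21), seed=13)
    mosaic = render_mosaic(sensor, scene, noise_on=True, seed=2, quantize=False)
    cube = demosaic_msfa(mosaic)
    ref = reference_vector(cube, scene.face_box)
    mask = select_flat_region(cube, scene.face_box, ref)
    return scene, cube, mask


class TestPredictionMap:
    def test_uniform_skin_scene_all_cells_one_class(self, skin_capture, operator, sensor):
        scene, cube, mask = skin_capture
        stub = _stub_model(1)
        pmap = prediction_map(cube, mask, operator, stub, sensor.grid, cell=10)
        selected = pmap.cell_labels[pmap.cell_labels != -1]
        assert selected.size > 0
        assert np.all(selected == 1)
        assert pmap.majority_label == 1
        assert pmap.proportions[1] == pytest.approx(1.0)

    def test_single_cell_equals_whole_region(self, skin_capture, operator, sensor):
        scene, cube, mask = skin_capture
        stub = _stub_model(2)
        pmap = prediction_map(cube, mask, operator, stub, sensor.grid, cell=96)
        assert pmap.cell_labels.shape == (1, 1)
        assert pmap.majority_label == 2

    def test_empty_mask_gives_unselected_map(self, skin_capture, operator, sensor):
        scene, cube, mask = skin_capture
        empty = type(mask)(mask=np.zeros_like(mask.mask), box=mask.box,
                           threshold=mask.threshold)
        pmap = prediction_map(cube, empty, operator, _stub_model(0),
                              sensor.grid)
        assert pmap.majority_label is None
        assert pmap.n_selected == 0

    def test_composite_scene_proportions_match_area_fractions(self, sensor, operator):
        # half-skin / half-print composite: per-class shares of the map must
        # track the geometric area fractions (the geometry oracle)
        skin_scene = make_face_scene(96, 96, skin=MaterialSpec("skin", seed=5),
                                     seed=6)
        print_scene = make_face_scene(
            96, 96,
            skin=MaterialSpec("print2d", dip_depth_542=0.0, dip_depth_577=0.0,
                              seed=7),
            seed=6)
        for scene in (skin_scene, print_scene):  # face material everywhere
            scene.material_index[:] = 1
            scene.illum[:] = 1.0
        cube_a = demosaic_msfa(render_mosaic(sensor, skin_scene, seed=1,
                                             quantize=False))
        cube_b = demosaic_msfa(render_mosaic(sensor, print_scene, seed=1,
                                             quantize=False))
        planes = cube_a.planes.copy()
        seam = 50  # aligned with the 10-px cell grid so no cell straddles it
        planes[:, :, seam:] = cube_b.planes[:, :, seam:]
        composite = type(cube_a)(planes=planes)
        box = skin_scene.face_box
        mask_arr = np.zeros((96, 96), dtype=bool)
        mask_arr[box.slices()] = True
        from speclive.region import RegionMask
        mask = RegionMask(mask=mask_arr, box=box, threshold=np.inf)

        # reference-spectrum classifier: nearest of the two known materials
        import speclive.grids as g
        refs = []
        for scene in (print_scene, skin_scene):
            rows = np.array([box.top + 2]); cols = np.array([box.left + 2])
            truth = scene.true_spectra(rows, cols)
            from speclive.sensor import project_spectrum
            from speclive.reconstruct import reconstruct_batch
            rec = reconstruct_batch(operator, project_spectrum(sensor, truth))
            rec = g.normalize_rows(np.clip(rec, 0, None), "max1")
            _, rec = g.crop_columns(sensor.grid, rec, 450, 700)
            refs.append(rec[0])

        class NearestRef:
            def forward(self, X):
                d = np.stack([np.linalg.norm(X - r, axis=1) for r in refs], axis=1)
                logits = np.full((X.shape[0], 3), -50.0)
                logits[:, :2] = -d
                return logits

        pmap = prediction_map(composite, mask, operator, NearestRef(),
                              sensor.grid, cell=10)
        # area fractions of the two halves inside the face box
        left = (seam - box.left) / box.width    # skin share
        assert pmap.proportions[1] == pytest.approx(left, abs=0.05)
        assert pmap.proportions[0] == pytest.approx(1 - left, abs=0.05)

    def test_proportions_sum_to_one_over_selected(self, skin_capture, operator, sensor):
        scene, cube, mask = skin_capture
        pmap = prediction_map(cube, mask, operator, build_model(seed=3),
                              sensor.grid, cell=10)
        assert pmap.proportions.sum() == pytest.approx(1.0)


class TestEvaluateAccuracy:
    def _samples(self, rng, n=4):
        return [SampleSpectra(f"t{g}{i}", g, rng.random((50, 126)) + 0.05)
                for g in (0, 1, 2) for i in range(n)]

    def test_perfect_stub_reaches_100(self, rng):
        samples = [SampleSpectra("t1", 1, rng.random((50, 126)) + 0.05)]
        report = evaluate_accuracy(_stub_model(1), samples, repeats=2)
        row = report[report.group == "Real"].iloc[0]
        assert row.accuracy_pct == pytest.approx(100.0)
        assert row.rmse_pct == pytest.approx(0.0)

    def test_missing_group_reported_as_nan(self, rng):
        samples = [SampleSpectra("t0", 0, rng.random((50, 126)) + 0.05)]
        report = evaluate_accuracy(_stub_model(0), samples)
        assert np.isnan(report[report.group == "3D"].accuracy_pct.iloc[0])

    def test_random_classifier_near_one_third(self, rng):
        # untrained-model argmax over random inputs ~ uniform within MC error
        samples = self._samples(rng, n=6)
        report = evaluate_accuracy(build_model(seed=7), samples, repeats=1)
        overall = np.nanmean(report.accuracy_pct)
        assert abs(overall - 100.0 / 3.0) < 15.0


class TestDemosaicAblation:
    def _scenes(self, n, size=32, gradient=True):
        out = []
        for i in range(n):
            a = smooth_random_spectrum(DEFAULT_GRID, seed=50 + 2 * i)
            b = smooth_random_spectrum(DEFAULT_GRID, seed=51 + 2 * i)
            if not gradient:
                b = a
            out.append(make_gradient_scene(size, size, a, b))
        return out

    def test_gradient_scenes_strict_improvement(self, sensor, operator):
        table = demosaic_ablation(self._scenes(3), sensor, operator, seed=1)
        for scene_id, sub in table.groupby("scene"):
            on = sub[sub["mode"] == "demosaic"].iloc[0]
            off = sub[sub["mode"] == "replicate"].iloc[0]
            assert on.mean_fidelity > off.mean_fidelity
            assert on.mean_rmse < off.mean_rmse

    def test_uniform_scenes_equal_metrics(self, sensor, operator):
        table = demosaic_ablation(self._scenes(2, gradient=False), sensor,
                                  operator, seed=2, noise_on=False)
        for scene_id, sub in table.groupby("scene"):
            on = sub[sub["mode"] == "demosaic"].iloc[0]
            off = sub[sub["mode"] == "replicate"].iloc[0]
            assert on.mean_fidelity == pytest.approx(off.mean_fidelity, abs=1e-9)
            assert on.mean_rmse == pytest.approx(off.mean_rmse, abs=1e-9)

    def test_table_shape_one_row_per_scene_per_mode(self, sensor, operator):
        table = demosaic_ablation(self._scenes(4), sensor, operator, seed=3)
        assert len(table) == 8
        assert set(table["mode"]) == {"demosaic", "replicate"}
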