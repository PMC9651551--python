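"""Goodness-of-fit banding, optimum selection and the deformation sweep."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from maskfit import (
    DeformationLevel,
    GoFThresholds,
    gof_metrics,
    make_face,
    make_mask,
    predict_fit,
    run_delta_sweep,
    select_delta_optimum,
    tissue_displacement,
)
from maskfit.scenes import SceneParams, make_scene

from test_distances import make_map

# Published per-participant conformity sweeps (percent area within +/-1 mm
# of the loaded face, levels delta_1..delta_8 then rigid) and the level
# each participant's selection should land on.
CONFORMITY_SWEEPS = {
    "ID1": ([64.5, 66.5, 65.7, 61.7, 53.9, 48.1, 45.1, 43.1, 30.5], 2, 66.5),
    "ID2": ([68.2, 70.5, 73.8, 68.1, 53.7, 46.5, 43.9, 41.9, 36.3], 3, 73.8),
    "ID3": ([52.2, 52.7, 53.3, 47.9, 46.4, 45.7, 46.0, 45.8, 44.7], 3, 53.3),
    "ID4": ([56.4, 58.2, 62.1, 67.6, 63.4, 56.8, 54.1, 52.6, 45.8], 4, 67.6),
    "ID5": ([54.9, 55.0, 56.2, 55.5, 53.7, 53.2, 52.7, 52.3, 51.5], 3, 56.2),
    "ID6": ([50.5, 51.4, 53.1, 49.6, 42.9, 39.9, 38.1, 37.0, 35.8], 3, 53.1),
    "ID7": ([65.4, 70.7, 72.5, 56.3, 39.2, 32.8, 30.7, 29.9, 20.8], 3, 72.5),
    "ID8": ([54.8, 57.2, 62.2, 73.3, 71.8, 67.1, 63.6, 62.3, 55.3], 4, 73.3),
}


class TestGoFMetrics:
    def test_hand_counted_bands(self):
        report = gof_metrics(make_map([-4.0, -2.0, -1.0, 1.0]))
        assert report.pct_indent == pytest.approx(25.0)
        assert report.pct_seal == pytest.approx(50.0)
        assert report.pct_gap == pytest.approx(25.0)
        assert report.pct_conform == pytest.approx(50.0)

    def test_all_seal(self):
        report = gof_metrics(make_map([-2.9, -0.5, 0.0, -3.0]))
        assert report.pct_seal == pytest.approx(100.0)
        assert report.pct_gap == 0.0
        assert report.pct_indent == 0.0

    def test_boundary_conventions(self):
        # 0 and -3 are seal; strictly above 0 is gap, strictly below -3
        # is indentation; conformity band is closed at +/-1
        report = gof_metrics(make_map([0.0, -3.0, 1e-9, -3.0 - 1e-9, 1.0]))
        assert report.pct_seal == pytest.approx(40.0)
        assert report.pct_gap == pytest.approx(40.0)
        assert report.pct_indent == pytest.approx(20.0)
        assert report.pct_conform == pytest.approx(60.0)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_bands_partition_to_100(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 200))
        dmap = make_map(
            rng.uniform(-8, 8, size=n), rng.uniform(0.1, 4.0, size=n)
        )
        report = gof_metrics(dmap)
        total = report.pct_gap + report.pct_indent + report.pct_seal
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            GoFThresholds(gap_min=-4.0, indent_max=-3.0)


class TestSelectDeltaOptimum:
    @pytest.mark.parametrize(
        "column,expected_index,expected_conformity",
        [v for v in CONFORMITY_SWEEPS.values()],
        ids=list(CONFORMITY_SWEEPS),
    )
    def test_published_sweeps(self, column, expected_index, expected_conformity):
        level, conformity = select_delta_optimum(column)
        assert level.index == expected_index
        assert conformity == pytest.approx(expected_conformity)

    def test_single_level(self):
        level, conformity = select_delta_optimum([55.0])
        assert level.index == 1
        assert conformity == 55.0

    def test_tie_broken_by_ci_width(self):
        conformities = [70.0, 70.02, 50.0, 40.0, 30.0, 20.0, 15.0, 10.0, 5.0]
        ci = [5.0, 4.0, 6.0, 6.0, 6.0, 6.0, 6.0, 6.0, 6.0]
        level, _ = select_delta_optimum(conformities, ci)
        assert level.index == 2

    def test_remaining_tie_prefers_stiffer_level(self):
        conformities = [70.0, 70.0, 10.0]
        ci = [5.0, 5.0, 9.0]
        level, _ = select_delta_optimum(conformities, ci)
        assert level.index == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_delta_optimum([])


@pytest.fixture(scope="module")
def small_quiet_sweep():
    params = SceneParams(resolution=44, indent_depth=0.0, bulge_height=0.0)
    face, _ = make_face(params)
    internal, _ = make_mask(face, params)
    return run_delta_sweep(internal, face, face), face, internal


class TestDeltaSweep:
    def test_softest_level_most_conforming(self, small_quiet_sweep):
        sweep, _, _ = small_quiet_sweep
        conformities = np.array([r.pct_conform for r in sweep.reports])
        assert conformities[0] >= conformities.max() - 0.05

    def test_rigid_level_equals_rigid_pipeline(self, small_quiet_sweep):
        sweep, face, internal = small_quiet_sweep
        rigid_only = run_delta_sweep(
            internal, face, face, levels=[DeformationLevel.rigid()]
        )
        assert rigid_only.reports[0].pct_conform == pytest.approx(
            sweep.reports[-1].pct_conform
        )
        assert rigid_only.optimum.is_rigid

    def test_sweep_frame_layout(self, small_quiet_sweep):
        sweep, _, _ = small_quiet_sweep
        frame = sweep.to_frame()
        assert len(frame) == 9
        assert list(frame.level[:2]) == ["delta1", "delta2"]
        assert frame.is_optimum.sum() == 1


class TestPredictFit:
    def test_uniformly_indented_mask_seals_everywhere(self):
        params = SceneParams(
            resolution=44, mask_offset=-1.0, mask_bridge_gap=0.0,
            rim_offset=None,
        )
        face, _ = make_face(params)
        internal, _ = make_mask(face, params)
        report = predict_fit(face, internal, DeformationLevel.rigid())
        assert report.pct_seal == pytest.approx(100.0, abs=0.5)

    def test_uniformly_gapped_mask_gaps_everywhere(self):
        params = SceneParams(
            resolution=44, mask_offset=2.0, mask_bridge_gap=0.0,
            rim_offset=None,
        )
        face, _ = make_face(params)
        internal, _ = make_mask(face, params)
        report = predict_fit(face, internal, DeformationLevel.rigid())
        assert report.pct_gap == pytest.approx(100.0, abs=0.5)

    def test_bands_partition(self):
        params = SceneParams(resolution=44)
        face, _ = make_face(params)
        internal, _ = make_mask(face, params)
        report = predict_fit(face, internal, DeformationLevel.from_index(3))
        total = report.pct_gap + report.pct_indent + report.pct_seal
        assert total == pytest.approx(100.0, abs=1e-9)


class TestTissueDisplacement:
    def test_identical_scans_zero_displacement(self):
        params = SceneParams(resolution=44)
        face, _ = make_face(params)
        _, summary = tissue_displacement(face, face.copy())
        assert summary.p_low == pytest.approx(0.0, abs=1e-9)
        assert summary.p_high == pytest.approx(0.0, abs=1e-9)

    def test_indentation_only_scene(self):
        scene = make_scene(
            SceneParams(resolution=60, indent_depth=5.0, bulge_height=0.0)
        )
        _, summary = tissue_displacement(
            scene.unloaded_face, scene.loaded_face
        )
        assert summary.p_low == pytest.approx(-5.0, abs=0.3)
        assert abs(summary.p_high) < 0.3

    def test_bulge_only_scene(self):
        scene = make_scene(
            SceneParams(resolution=60, indent_depth=0.0, bulge_height=4.0)
        )
        _, summary = tissue_displacement(
            scene.unloaded_face, scene.loaded_face
        )
        assert summary.p_high == pytest.approx(4.0, abs=0.3)
        assert abs(summary.p_low) < 0.3
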