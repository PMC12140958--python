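"""Block-matching speckle tracking: correctness, invariances, determinism."""

import numpy as np
import pytest

from wallstrain.tracking import (
    DisplacementField,
    TrackingParams,
    accumulate,
    regularize,
    track_cine,
    track_pair,
)


@pytest.fixture(scope="module")
def frame(fast_cine):
    cine, _ = fast_cine
    return np.asarray(cine.frames[0], dtype=float)


@pytest.fixture(scope="module")
def wall_points(fast_mesh, fast_config):
    return fast_mesh.nodes / fast_config.pixel_spacing


class TestTrackPair:
    def test_identity(self, frame, wall_points):
        disp, scores, valid = track_pair(frame, frame, wall_points, TrackingParams())
        assert np.allclose(disp, 0.0, atol=1e-6)
        assert np.all(scores > 0.999)
        assert valid.all()

    def test_pure_integer_shift(self, frame, wall_points):
        shifted = np.roll(frame, 3, axis=1)
        # keep clear of the wrapped columns
        pts = wall_points[(wall_points[:, 0] > 25) & (wall_points[:, 0] < 100)]
        disp, scores, _ = track_pair(frame, shifted, pts, TrackingParams(),
                                     pixel_spacing=0.5)
        assert np.allclose(disp[:, 0], 3 * 0.5, atol=0.01)
        assert np.allclose(disp[:, 1], 0.0, atol=0.01)
        assert np.median(scores) > 0.99

    def test_translation_equivariance(self, frame, wall_points):
        shifted_a = np.roll(frame, 5, axis=0)
        shifted_b = np.roll(np.roll(frame, 3, axis=1), 5, axis=0)
        pts = wall_points[
            (wall_points[:, 0] > 25) & (wall_points[:, 0] < 100)
            & (wall_points[:, 1] > 25) & (wall_points[:, 1] < 100)
        ]
        d1, _, _ = track_pair(frame, np.roll(frame, 3, axis=1), pts, TrackingParams())
        d2, _, _ = track_pair(shifted_a, shifted_b, pts + [0, 5], TrackingParams())
        assert np.allclose(d1, d2, atol=0.02)

    def test_flat_block_flagged(self, wall_points):
        flat = np.zeros((128, 128))
        disp, scores, valid = track_pair(flat, flat, wall_points[:5], TrackingParams())
        assert not valid.any()
        assert np.all(scores == 0.0)
        assert np.allclose(disp, 0.0)

    def test_search_center_offsets_fold_into_displacement(self, frame, wall_points):
        shifted = np.roll(frame, 6, axis=1)
        pts = wall_points[(wall_points[:, 0] > 25) & (wall_points[:, 0] < 100)][:20]
        d_direct, _, _ = track_pair(frame, shifted, pts, TrackingParams())
        d_guided, _, _ = track_pair(frame, shifted, pts, TrackingParams(),
                                    search_center=pts + [6, 0])
        assert np.allclose(d_direct, d_guided, atol=0.02)

    def test_median_increment_error_on_synthetic_cine(self, fast_cine, fast_mesh,
                                                      fast_config):
        cine, truth = fast_cine
        ps = fast_config.pixel_spacing
        pts = fast_mesh.nodes / ps
        t = truth.eps_max_frame  # steepest motion is near the upstroke
        u_t = truth.displacement_at(fast_mesh.nodes, t - 1)
        u_t1 = truth.displacement_at(fast_mesh.nodes, t)
        disp, _, _ = track_pair(
            np.asarray(cine.frames[t - 1], float), np.asarray(cine.frames[t], float),
            pts + np.rint(u_t / ps), TrackingParams(), pixel_spacing=ps,
        )
        err_px = np.linalg.norm(disp - (u_t1 - u_t), axis=1) / ps
        assert np.median(err_px) < 0.2


class TestRegularize:
    def test_zero_weight_identity(self, fast_mesh):
        rng = np.random.default_rng(0)
        inc = rng.normal(size=(len(fast_mesh.nodes), 2))
        params = TrackingParams(smoothing_weight=0.0, smoothing_iters=5)
        out = regularize(inc, np.ones(len(inc)), np.ones(len(inc), bool),
                         fast_mesh, params)
        assert np.allclose(out, inc)

    def test_constant_field_is_fixed_point(self, fast_mesh):
        inc = np.tile([0.3, -0.2], (len(fast_mesh.nodes), 1))
        out = regularize(inc, np.ones(len(inc)), np.ones(len(inc), bool),
                         fast_mesh, TrackingParams())
        assert np.allclose(out, inc, atol=1e-9)

    def test_rigid_rotation_field_preserved(self, fast_mesh):
        """Smoothing must not turn a rotation's radial gradient into shear."""
        center = fast_mesh.nodes.mean(axis=0)
        rel = fast_mesh.nodes - center
        theta = 0.02
        rot = theta * np.column_stack((-rel[:, 1], rel[:, 0]))
        out = regularize(rot, np.ones(len(rot)), np.ones(len(rot), bool),
                         fast_mesh, TrackingParams())
        assert np.allclose(out, rot, atol=1e-6)

    def test_outlier_pulled_toward_constant(self, fast_mesh):
        inc = np.tile([0.5, 0.0], (len(fast_mesh.nodes), 1))
        inc[7] = [5.0, -4.0]
        out = regularize(inc, np.ones(len(inc)), np.ones(len(inc), bool),
                         fast_mesh, TrackingParams())
        before = np.abs(inc - [0.5, 0.0]).max()
        after = np.abs(out - np.median(out, axis=0)).max()
        assert after < before

    def test_low_score_nodes_filled_from_neighbors(self, fast_mesh):
        inc = np.tile([1.0, 2.0], (len(fast_mesh.nodes), 1))
        inc[3] = [99.0, 99.0]
        scores = np.ones(len(inc))
        scores[3] = 0.1  # below min_correlation
        out = regularize(inc, scores, np.ones(len(inc), bool), fast_mesh,
                         TrackingParams())
        assert np.allclose(out[3], [1.0, 2.0], atol=1e-6)


class TestAccumulate:
    def test_zero_increments(self):
        cum = accumulate(np.zeros((5, 10, 2)))
        assert cum.shape == (6, 10, 2)
        assert np.all(cum == 0.0)

    def test_constant_increment_sums(self):
        inc = np.ones((5, 4, 2))
        cum = accumulate(inc)
        assert np.allclose(cum[0], 0.0)
        assert np.allclose(cum[5], 5.0)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            accumulate(np.zeros((5, 10, 3)))


class TestTrackCine:
    def test_deterministic(self, fast_cine, fast_mesh):
        cine, _ = fast_cine
        f1 = track_cine(cine, fast_mesh)
        f2 = track_cine(cine, fast_mesh)
        assert np.array_equal(f1.displacements, f2.displacements)
        assert np.array_equal(f1.scores, f2.scores)

    def test_frame_zero_is_reference(self, fast_cine, fast_mesh):
        cine, _ = fast_cine
        field = track_cine(cine, fast_mesh)
        assert np.all(field.displacements[0] == 0.0)
        assert field.n_frames == cine.n_frames
        assert field.n_nodes == len(fast_mesh.nodes)

    def test_cycle_closure(self, fast_cine, fast_mesh, fast_config):
        """The wall returns to end-diastole; so must the tracked field."""
        cine, truth = fast_cine
        field = track_cine(cine, fast_mesh)
        final_true = truth.displacement_at(fast_mesh.nodes, cine.n_frames - 1)
        err_px = np.linalg.norm(field.displacements[-1] - final_true, axis=1)
        assert np.median(err_px) / fast_config.pixel_spacing < 0.3

    def test_incremental_mode_runs(self, fast_cine, fast_mesh):
        cine, _ = fast_cine
        field = track_cine(cine, fast_mesh, TrackingParams(mode="incremental"))
        assert np.all(np.isfinite(field.displacements))


def test_displacement_field_validation():
    with pytest.raises(ValueError):
        DisplacementField(displacements=np.ones((3, 4, 2)), scores=np.ones((3, 4)))
    with pytest.raises(ValueError):
        DisplacementField(displacements=np.zeros((3, 4, 2)), scores=np.ones((2, 4)))


def test_tracking_params_validation():
    with pytest.raises(ValueError):
        TrackingParams(block_halfwidth=1)
    with pytest.raises(ValueError):
        TrackingParams(subpixel="spline")
    with pytest.raises(ValueError):
        TrackingParams(mode="optical-flow")
    with pytest.raises(ValueError):
        TrackingParams(smoothing_weight=1.5)
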