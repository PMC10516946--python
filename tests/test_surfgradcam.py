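import numpy as np
import pytest

from cleftgrade.mesh_io import TriangleMesh, normalize_pose
from cleftgrade.model import ModelConfig, MultiViewCNN, views_to_array
from cleftgrade.render import RenderedView, render_all
from cleftgrade.surfgradcam import (
    ClassActivationMap,
    compute_cams,
    explain,
    gradcam_view,
    pool_to_surface,
)
from cleftgrade.synthetic_shapes import build_arch, sample_params
from cleftgrade.views import Camera, icosphere_cameras

TOY = ModelConfig(resolution=32, conv_channels=(4, 6), conv_strides=(2, 2),
                  attn_dim=8)


@pytest.fixture(scope="module")
def toy_model():
    return MultiViewCNN(TOY, seed=1)


def _fake_view(face_id, camera=None):
    H, W = face_id.shape
    channels = np.zeros((H, W, 4))
    channels[:, :, 3] = np.where(face_id >= 0, 0.5, 1.0)
    cam = camera or Camera(np.array([0, 0, 3.0]), np.zeros(3),
                           np.array([0, 1.0, 0]), 40.0, 0)
    return RenderedView(channels=channels, face_id=face_id, camera=cam)


class TestGradcamView:
    def test_channel_weights_match_finite_differences(self, toy_model, rng):
        """alpha_k from backprop equals central finite differences of the
        class logit w.r.t. the final conv maps."""
        x = rng.random((3, 4, 32, 32)).astype(np.float32)
        maps, _ = toy_model.encode(x)
        maps = maps.astype(np.float64)
        grads = toy_model.grad_logit_wrt_maps(maps, target_class=2, n_views=3)

        def logit(mp):
            l, _, _ = toy_model.head(mp, 3)
            return l[0, 2]

        worst = 0.0
        for _ in range(40):
            idx = tuple(rng.integers(0, s) for s in maps.shape)
            eps = 1e-3
            up, down = maps.copy(), maps.copy()
            up[idx] += eps
            down[idx] -= eps
            fd = (logit(up) - logit(down)) / (2 * eps)
            denom = max(abs(fd), 1e-6)
            worst = max(worst, abs(fd - grads[idx]) / denom)
        assert worst <= 1e-4

    def test_zero_gradient_gives_zero_cam(self, rng):
        """If the class logit is independent of every view, the CAM is 0."""
        model = MultiViewCNN(TOY, seed=1)
        model.params["head_w"] = np.zeros_like(model.params["head_w"])
        x = rng.random((2, 4, 32, 32)).astype(np.float32)
        cams = compute_cams(model, x, target_class=1)
        for cam in cams:
            assert np.all(cam.values == 0)

    def test_single_channel_uniform_gradient_scales_map(self, rng):
        """One channel + positive uniform gradient: CAM = g * A (no ReLU cut)."""
        cfg = ModelConfig(resolution=32, conv_channels=(4, 1),
                          conv_strides=(2, 2), attn_dim=4)
        model = MultiViewCNN(cfg, seed=0)
        # single view: attention weight is constant 1, so the logit gradient
        # w.r.t. the map is w_c / (h*w), spatially uniform
        x = rng.random((1, 4, 32, 32)).astype(np.float32)
        maps, _ = model.encode(x)
        w_c = float(model.params["head_w"][2, 0])
        target_sign = 1.0 if w_c > 0 else -1.0
        model.params["head_w"][2, 0] = abs(w_c)  # ensure ReLU inactive
        cams = compute_cams(model, x, target_class=2, upsample_to=maps.shape[-1])
        g = abs(w_c) / maps[0, 0].size
        np.testing.assert_allclose(cams[0].values, g * maps[0, 0], rtol=1e-4,
                                   atol=1e-9)
        del target_sign

    def test_invalid_class_and_view_rejected(self, toy_model, single_triangle):
        vs = icosphere_cameras(0, 3.0)
        rendered = render_all(normalize_pose(single_triangle), vs, 32)
        with pytest.raises(ValueError):
            gradcam_view(toy_model, rendered, target_class=7, view_index=0)
        with pytest.raises(ValueError):
            gradcam_view(toy_model, rendered, target_class=1, view_index=99)

    def test_cam_non_negative(self, toy_model, rng):
        x = rng.random((4, 4, 32, 32)).astype(np.float32)
        for c in range(4):
            for cam in compute_cams(toy_model, x, c):
                assert (cam.values >= 0).all()


class TestPoolToSurface:
    def test_face_takes_max_over_its_pixels(self):
        mesh = TriangleMesh(np.eye(3), [[0, 1, 2]])
        face_id = np.full((4, 4), -1)
        face_id[1, 1] = 0
        face_id[2, 2] = 0
        cam_vals = np.zeros((4, 4))
        cam_vals[1, 1] = 0.2
        cam_vals[2, 2] = 0.7
        cam = ClassActivationMap(cam_vals, 0, 0)
        hm = pool_to_surface([cam], [_fake_view(face_id)], mesh)
        assert np.allclose(hm.vertex_values, 0.7)

    def test_across_view_max_pooling(self):
        mesh = TriangleMesh(np.eye(3), [[0, 1, 2]])
        views, cams = [], []
        for peak in (0.3, 0.9):
            face_id = np.full((4, 4), -1)
            face_id[0, 0] = 0
            vals = np.zeros((4, 4))
            vals[0, 0] = peak
            views.append(_fake_view(face_id))
            cams.append(ClassActivationMap(vals, 0, 0))
        hm = pool_to_surface(cams, views, mesh)
        assert np.allclose(hm.vertex_values, 0.9)

    def test_unseen_vertices_exactly_zero(self):
        verts = np.vstack([np.eye(3), [[5, 5, 5.0]]])
        mesh = TriangleMesh(verts, [[0, 1, 2], [1, 2, 3]])
        face_id = np.full((4, 4), -1)
        face_id[1, 1] = 0  # only face 0 visible
        vals = np.full((4, 4), 0.8)
        hm = pool_to_surface([ClassActivationMap(vals, 0, 0)],
                             [_fake_view(face_id)], mesh)
        assert hm.vertex_values[3] == 0.0
        assert hm.vertex_values[0] == 0.8

    def test_adding_views_never_decreases_face_values(self, rng):
        """Max pooling is monotone in the view set."""
        mesh = TriangleMesh(rng.normal(size=(9, 3)), [[0, 1, 2], [3, 4, 5], [6, 7, 8]])
        views, cams = [], []
        for _ in range(4):
            face_id = rng.integers(-1, 3, size=(8, 8))
            views.append(_fake_view(face_id))
            cams.append(ClassActivationMap(rng.random((8, 8)), 0, 0))
        prev = np.zeros(mesh.n_vertices)
        for k in range(1, 5):
            hm = pool_to_surface(cams[:k], views[:k], mesh)
            assert (hm.vertex_values >= prev - 1e-12).all()
            prev = hm.vertex_values

    def test_resolution_mismatch_rejected(self):
        mesh = TriangleMesh(np.eye(3), [[0, 1, 2]])
        cam = ClassActivationMap(np.zeros((8, 8)), 0, 0)
        with pytest.raises(ValueError, match="does not match"):
            pool_to_surface([cam], [_fake_view(np.full((4, 4), -1))], mesh)

    def test_all_zero_map_stays_zero_after_normalization(self):
        mesh = TriangleMesh(np.eye(3), [[0, 1, 2]])
        face_id = np.full((4, 4), 0)
        hm = pool_to_surface([ClassActivationMap(np.zeros((4, 4)), 0, 0)],
                             [_fake_view(face_id)], mesh)
        assert np.all(hm.normalized == 0)

    def test_mean_vertex_pooling_option(self, rng):
        mesh = TriangleMesh(rng.normal(size=(4, 3)), [[0, 1, 2], [1, 2, 3]])
        face_id = np.full((4, 4), -1)
        face_id[0, 0] = 0
        face_id[1, 1] = 1
        vals = np.zeros((4, 4))
        vals[0, 0] = 0.4
        vals[1, 1] = 0.8
        hm = pool_to_surface([ClassActivationMap(vals, 0, 0)],
                             [_fake_view(face_id)], mesh, vertex_pool="mean")
        # vertices 1 and 2 touch both faces -> mean of 0.4 and 0.8
        assert np.isclose(hm.vertex_values[1], 0.6)
        assert np.isclose(hm.vertex_values[0], 0.4)


class TestExplain:
    @pytest.fixture(scope="class")
    def arch(self):
        return build_arch(sample_params(3, 21))[0]

    def test_all_classes_attach_named_arrays(self, toy_model, arch):
        vs = icosphere_cameras(0, 3.0)
        out = explain(arch, toy_model, vs)
        assert set(out.vertex_scalars) == {
            f"surfgradcam_class{c}" for c in range(4)
        }
        for arr in out.vertex_scalars.values():
            assert arr.shape == (arch.n_vertices,)
            assert (arr >= 0).all() and arr.max() <= 1.0

    def test_deterministic(self, toy_model, arch):
        vs = icosphere_cameras(0, 3.0)
        a = explain(arch, toy_model, vs, target_classes=2)
        b = explain(arch, toy_model, vs, target_classes=2)
        np.testing.assert_array_equal(
            a.vertex_scalars["surfgradcam_class2"],
            b.vertex_scalars["surfgradcam_class2"],
        )

    def test_invalid_class_rejected(self, toy_model, arch):
        vs = icosphere_cameras(0, 3.0)
        with pytest.raises(ValueError, match="target class"):
            explain(arch, toy_model, vs, target_classes=9)
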