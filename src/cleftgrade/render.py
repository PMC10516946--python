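"""Software rasterization of meshes into multi-channel snapshots.

Each view is a z-buffered rasterization producing four image channels —
camera-space surface normal (x, y, z mapped to [0, 1]) and depth normalized
over the camera frustum — plus a per-pixel *face-ID buffer* recording which
mesh triangle produced each pixel.  The face-ID buffer is the exact inverse
mapping from image space back to the surface that SurfGradCAM uses to paint
class-activation values onto the mesh.

Conventions: image origin top-left, row-major storage, pixel centers at
half-integer coordinates, background face-ID sentinel ``-1`` and background
depth ``1.0``.  Shading is two-sided (normals flipped toward the camera)
because cleft surface models are open surfaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mesh_io import TriangleMesh
from .views import Camera, ViewSet

__all__ = ["RenderedView", "render_view", "render_all", "camera_basis"]

BACKGROUND_DEPTH = 1.0
BACKGROUND_FACE = -1


@dataclass
class RenderedView:
    """One rasterized snapshot: ``channels`` is H x W x 4, ``face_id`` H x W."""

    channels: np.ndarray
    face_id: np.ndarray
    camera: Camera

    @property
    def resolution(self) -> int:
        return self.face_id.shape[0]

    @property
    def depth(self) -> np.ndarray:
        return self.channels[:, :, 3]

    @property
    def foreground(self) -> np.ndarray:
        return self.face_id >= 0


def camera_basis(camera: Camera) -> tuple[np.ndarray, np.ndarray]:
    """Right-handed camera frame: columns are (right, up, backward).

    The camera looks along its -z axis; world point ``w`` maps to camera
    coordinates via ``(w - position) @ basis``.
    """
    backward = camera.position - camera.look_at
    backward = backward / np.linalg.norm(backward)
    right = np.cross(camera.up, backward)
    right = right / np.linalg.norm(right)
    up = np.cross(backward, right)
    return np.column_stack([right, up, backward]), camera.position


def render_view(
    mesh: TriangleMesh,
    camera: Camera,
    resolution: int = 128,
    projection: str = "perspective",
    near: float | None = None,
    far: float | None = None,
) -> RenderedView:
    """Rasterize ``mesh`` from ``camera`` at ``resolution`` x ``resolution``.

    The mesh is expected to be pose-normalized (unit bound at the origin);
    ``near``/``far`` default to a frustum bracketing the unit sphere at the
    camera's distance from the origin.
    """
    if resolution < 16:
        raise ValueError("resolution must be >= 16")
    mesh.validate()

    basis, pos = camera_basis(camera)
    dist = float(np.linalg.norm(camera.position - camera.look_at))
    if near is None:
        near = max(dist - 1.2, 0.05 * dist)
    if far is None:
        far = dist + 1.2

    v_cam = (mesh.vertices - pos) @ basis  # (n, 3); visible points have z < 0
    H = W = resolution

    channels = np.zeros((H, W, 4), dtype=np.float64)
    channels[:, :, 3] = BACKGROUND_DEPTH
    face_id = np.full((H, W), BACKGROUND_FACE, dtype=np.int64)
    zbuf = np.full((H, W), np.inf)  # stores camera-space distance -z

    if projection == "perspective":
        tan_half = np.tan(np.radians(camera.fov) / 2.0)
        w = -v_cam[:, 2]  # positive in front of camera
        valid_v = w > 1e-9
        ndc = np.zeros((len(v_cam), 2))
        ndc[valid_v, 0] = v_cam[valid_v, 0] / (w[valid_v] * tan_half)
        ndc[valid_v, 1] = v_cam[valid_v, 1] / (w[valid_v] * tan_half)
        inv_w = np.zeros(len(v_cam))
        inv_w[valid_v] = 1.0 / w[valid_v]
    elif projection == "orthographic":
        half_extent = dist * np.tan(np.radians(camera.fov) / 2.0)
        ndc = v_cam[:, :2] / half_extent
        w = -v_cam[:, 2]
        valid_v = w > 1e-9
        inv_w = None
    else:
        raise ValueError(f"unknown projection {projection!r}")

    # screen coordinates: origin top-left, +x right, +y down
    sx = (ndc[:, 0] + 1.0) * 0.5 * W
    sy = (1.0 - (ndc[:, 1] + 1.0) * 0.5) * H

    # two-sided flat shading in camera space
    f = mesh.faces
    n_world = mesh.face_normals()
    n_cam = n_world @ basis
    norms = np.linalg.norm(n_cam, axis=1)
    ok_normal = norms > 1e-15
    n_cam[ok_normal] = n_cam[ok_normal] / norms[ok_normal, None]
    centroid_cam = v_cam[f].mean(axis=1)
    flip = np.einsum("ij,ij->i", n_cam, -centroid_cam) < 0
    n_cam[flip] = -n_cam[flip]

    depth_scale = far - near
    any_drawn = False
    xs_f = sx[f]  # (m, 3)
    ys_f = sy[f]
    valid_f = valid_v[f].all(axis=1) & ok_normal
    # conservative integer pixel bounds per face
    x0 = np.maximum(np.floor(xs_f.min(axis=1) - 0.5).astype(int), 0)
    x1 = np.minimum(np.ceil(xs_f.max(axis=1) + 0.5).astype(int), W)
    y0 = np.maximum(np.floor(ys_f.min(axis=1) - 0.5).astype(int), 0)
    y1 = np.minimum(np.ceil(ys_f.max(axis=1) + 0.5).astype(int), H)
    valid_f &= (x1 > x0) & (y1 > y0)

    for fi in np.nonzero(valid_f)[0]:
        ax, bx, cx = xs_f[fi]
        ay, by, cy = ys_f[fi]
        area = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
        if abs(area) < 1e-12:
            continue
        gx = np.arange(x0[fi], x1[fi]) + 0.5
        gy = np.arange(y0[fi], y1[fi]) + 0.5
        px, py = np.meshgrid(gx, gy)
        w0 = ((bx - px) * (cy - py) - (by - py) * (cx - px)) / area
        w1 = ((cx - px) * (ay - py) - (cy - py) * (ax - px)) / area
        w2 = 1.0 - w0 - w1
        inside = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        if not inside.any():
            continue
        idx = f[fi]
        if projection == "perspective":
            # screen-linear interpolation of 1/w is perspective-exact
            q = w0 * inv_w[idx[0]] + w1 * inv_w[idx[1]] + w2 * inv_w[idx[2]]
            z_here = np.where(q > 1e-12, 1.0 / np.maximum(q, 1e-12), np.inf)
        else:
            z_here = w0 * w[idx[0]] + w1 * w[idx[1]] + w2 * w[idx[2]]

        rows = slice(y0[fi], y1[fi])
        cols = slice(x0[fi], x1[fi])
        closer = inside & (z_here < zbuf[rows, cols])
        if not closer.any():
            continue
        any_drawn = True
        zb = zbuf[rows, cols]
        zb[closer] = z_here[closer]
        zbuf[rows, cols] = zb
        fid = face_id[rows, cols]
        fid[closer] = fi
        face_id[rows, cols] = fid
        sub = channels[rows, cols, :]
        sub[closer, 0:3] = (n_cam[fi] + 1.0) * 0.5
        sub[closer, 3] = np.clip(
            (z_here[closer] - near) / depth_scale, 0.0, 1.0 - 1e-6
        )
        channels[rows, cols, :] = sub

    if not any_drawn:
        warnings.warn("mesh projected entirely outside the view frustum",
                      stacklevel=2)
    return RenderedView(channels=channels, face_id=face_id, camera=camera)


def render_all(
    mesh: TriangleMesh,
    viewset: ViewSet,
    resolution: int = 128,
    near: float | None = None,
    far: float | None = None,
) -> list[RenderedView]:
    """Render one view per camera, preserving camera order."""
    return [
        render_view(mesh, cam, resolution=resolution,
                    projection=viewset.projection, near=near, far=far)
        for cam in viewset
    ]
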