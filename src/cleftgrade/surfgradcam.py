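"""SurfGradCAM: class-activation heatmaps painted onto the mesh surface.

For a chosen severity class ``c`` the algorithm:

1. backpropagates the class logit to the final conv feature maps ``A^k`` of
   every view (the gradient flows through global average pooling *and* the
   attention weighting, so views the model ignores receive small gradients);
2. forms the per-view class activation map ``ReLU(sum_k alpha_k A^k)`` with
   channel weights ``alpha_k`` = spatial mean of the gradient, bilinearly
   upsampled to render resolution;
3. pools with a *max* across every pixel of every view through the face-ID
   buffer: a face's score is the largest CAM value of any pixel it produced
   in any view, and a vertex takes the max over its incident faces.

Vertices never visible in any view keep a raw value of exactly 0.  A
[0, 1]-normalized variant (per mesh, per class) is attached for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh_io import TriangleMesh, normalize_pose
from .model import MultiViewCNN
from .render import RenderedView, render_all
from .views import ViewSet

__all__ = [
    "ClassActivationMap",
    "SurfaceHeatmap",
    "gradcam_view",
    "compute_cams",
    "pool_to_surface",
    "explain",
    "SCALAR_NAME_TEMPLATE",
]

SCALAR_NAME_TEMPLATE = "surfgradcam_class{c}"


@dataclass
class ClassActivationMap:
    """Non-negative CAM for one (view, target class), at render resolution."""

    values: np.ndarray
    view_id: int
    target_class: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if (self.values < 0).any():
            raise ValueError("CAM values must be non-negative (post-ReLU)")


@dataclass
class SurfaceHeatmap:
    """Per-vertex importance for one target class."""

    vertex_values: np.ndarray  # raw, >= 0
    normalized: np.ndarray  # raw / max (all-zero stays all-zero)
    target_class: int
    provenance: dict = field(default_factory=dict)


def _bilinear_upsample(a: np.ndarray, size: int) -> np.ndarray:
    """Resize (h, w) -> (size, size) with bilinear interpolation.

    Output pixel centers are mapped into input pixel-center coordinates
    (half-integer convention), with edge clamping.
    """
    h, w = a.shape
    if (h, w) == (size, size):
        return a.copy()
    ys = (np.arange(size) + 0.5) * h / size - 0.5
    xs = (np.arange(size) + 0.5) * w / size - 0.5
    y0 = np.clip(np.floor(ys).astype(int), 0, h - 1)
    x0 = np.clip(np.floor(xs).astype(int), 0, w - 1)
    y1 = np.clip(y0 + 1, 0, h - 1)
    x1 = np.clip(x0 + 1, 0, w - 1)
    fy = np.clip(ys - y0, 0.0, 1.0)[:, None]
    fx = np.clip(xs - x0, 0.0, 1.0)[None, :]
    tl = a[np.ix_(y0, x0)]
    tr = a[np.ix_(y0, x1)]
    bl = a[np.ix_(y1, x0)]
    br = a[np.ix_(y1, x1)]
    return (
        tl * (1 - fy) * (1 - fx)
        + tr * (1 - fy) * fx
        + bl * fy * (1 - fx)
        + br * fy * fx
    )


def compute_cams(
    model: MultiViewCNN,
    views_array: np.ndarray,
    target_class: int,
    upsample_to: int | None = None,
) -> list[ClassActivationMap]:
    """CAMs for every view of one shape (``views_array``: (V, C, H, W)).

    Channel weights are the spatial average of the exact logit gradient with
    respect to each final conv map; the weighted sum is rectified and
    bilinearly upsampled to ``upsample_to`` (default: render resolution).
    """
    v = views_array.shape[0]
    size = upsample_to or views_array.shape[-1]
    maps, _ = model.encode(views_array.astype(np.float32))
    grads = model.grad_logit_wrt_maps(maps, target_class, n_views=v)
    alpha = grads.mean(axis=(2, 3))  # (V, K) channel weights
    cams = []
    for vi in range(v):
        cam = np.maximum(np.einsum("k,khw->hw", alpha[vi], maps[vi]), 0.0)
        cams.append(
            ClassActivationMap(_bilinear_upsample(cam, size), vi, target_class)
        )
    return cams


def gradcam_view(
    model: MultiViewCNN,
    rendered_views: list[RenderedView],
    target_class: int,
    view_index: int,
) -> ClassActivationMap:
    """CAM of a single view, at that view's render resolution."""
    if not 0 <= view_index < len(rendered_views):
        raise ValueError(f"view_index {view_index} out of range")
    from .model import views_to_array

    arr = views_to_array(rendered_views)
    return compute_cams(model, arr, target_class, arr.shape[-1])[view_index]


def pool_to_surface(
    cams: list[ClassActivationMap],
    views: list[RenderedView],
    mesh: TriangleMesh,
    vertex_pool: str = "max",
) -> SurfaceHeatmap:
    """Max-pool CAM pixels through the face-ID buffers onto mesh vertices.

    ``vertex_pool`` selects how a vertex combines its incident faces'
    scores: ``"max"`` (default, consistent with the across-view max) or
    ``"mean"`` over *seen* incident faces.
    """
    if len(cams) != len(views):
        raise ValueError("cams and views must align one-to-one")
    n_faces = mesh.n_faces
    face_vals = np.zeros(n_faces)
    face_seen = np.zeros(n_faces, dtype=bool)
    target_class = cams[0].target_class
    for cam, view in zip(cams, views):
        if cam.values.shape != view.face_id.shape:
            raise ValueError(
                f"CAM shape {cam.values.shape} does not match face-ID buffer "
                f"{view.face_id.shape}"
            )
        fg = view.face_id >= 0
        ids = view.face_id[fg]
        np.maximum.at(face_vals, ids, cam.values[fg])
        face_seen[ids] = True
    face_vals[~face_seen] = 0.0

    n_vert = mesh.n_vertices
    vertex_vals = np.zeros(n_vert)
    if vertex_pool == "max":
        flat = mesh.faces.ravel()
        np.maximum.at(vertex_vals, flat, np.repeat(face_vals, 3))
        seen_v = np.zeros(n_vert, dtype=bool)
        seen_v[mesh.faces[face_seen].ravel()] = True
        vertex_vals[~seen_v] = 0.0
    elif vertex_pool == "mean":
        sums = np.zeros(n_vert)
        counts = np.zeros(n_vert)
        seen_faces = np.nonzero(face_seen)[0]
        flat = mesh.faces[seen_faces].ravel()
        np.add.at(sums, flat, np.repeat(face_vals[seen_faces], 3))
        np.add.at(counts, flat, 1.0)
        nz = counts > 0
        vertex_vals[nz] = sums[nz] / counts[nz]
    else:
        raise ValueError(f"unknown vertex_pool {vertex_pool!r}")

    vmax = vertex_vals.max()
    normalized = vertex_vals / vmax if vmax > 0 else vertex_vals.copy()
    return SurfaceHeatmap(vertex_vals, normalized, target_class)


def explain(
    mesh: TriangleMesh,
    model: MultiViewCNN,
    viewset: ViewSet,
    target_classes: int | list[int] | None = None,
    vertex_pool: str = "max",
    normalized: bool = True,
) -> TriangleMesh:
    """Attach ``surfgradcam_class{c}`` scalar arrays for the requested classes.

    ``target_classes`` defaults to all severity classes; pass an int for a
    single class.  Values are display-normalized per mesh per class unless
    ``normalized=False`` (raw scale).
    """
    if target_classes is None:
        classes = list(range(model.config.n_classes))
    elif np.isscalar(target_classes):
        classes = [int(target_classes)]
    else:
        classes = [int(c) for c in target_classes]
    for c in classes:
        if not 0 <= c < model.config.n_classes:
            raise ValueError(f"target class {c} out of range")

    normed = normalize_pose(mesh)
    rendered = render_all(normed, viewset, model.config.resolution)
    from .model import views_to_array

    arr = views_to_array(rendered)

    out = mesh.copy()
    for c in classes:
        cams = compute_cams(model, arr, c)
        hm = pool_to_surface(cams, rendered, normed, vertex_pool=vertex_pool)
        out.vertex_scalars[SCALAR_NAME_TEMPLATE.format(c=c)] = (
            hm.normalized if normalized else hm.vertex_values
        )
    return out
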