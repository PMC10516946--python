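"""Camera viewpoints sampled on a sphere around a pose-normalized mesh.

The "fly-by" acquisition renders the shape from cameras placed at the vertices
of a subdivided icosahedron, each looking at the origin.  Subdivision level
``L`` gives ``10 * 4**L + 2`` evenly spread viewpoints (12, 42, 162, ...).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = ["Camera", "ViewSet", "icosphere_cameras"]

_POLE_TOL = 1e-8


@dataclass(frozen=True)
class Camera:
    """Perspective (or orthographic) pinhole camera looking at the origin."""

    position: np.ndarray
    look_at: np.ndarray
    up: np.ndarray
    fov: float  # full vertical field of view, degrees (perspective only)
    id: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=np.float64))
        object.__setattr__(self, "look_at", np.asarray(self.look_at, dtype=np.float64))
        object.__setattr__(self, "up", np.asarray(self.up, dtype=np.float64))
        d = self.position - self.look_at
        if np.linalg.norm(d) < _POLE_TOL:
            raise ValueError("camera position coincides with look_at point")
        d = d / np.linalg.norm(d)
        if np.linalg.norm(np.cross(self.up, d)) < _POLE_TOL:
            raise ValueError("up vector parallel to view direction")


@dataclass
class ViewSet:
    """Ordered camera collection at fixed radius from the origin."""

    cameras: list[Camera]
    radius: float
    subdivision_level: int
    projection: str = "perspective"
    extra: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.cameras)

    def __iter__(self):
        return iter(self.cameras)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "radius": self.radius,
            "subdivision_level": self.subdivision_level,
            "projection": self.projection,
            "cameras": [
                {
                    "id": c.id,
                    "position": c.position.tolist(),
                    "look_at": c.look_at.tolist(),
                    "up": c.up.tolist(),
                    "fov": c.fov,
                }
                for c in self.cameras
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ViewSet":
        payload = json.loads(Path(path).read_text())
        cams = [
            Camera(
                np.array(c["position"]),
                np.array(c["look_at"]),
                np.array(c["up"]),
                c["fov"],
                c["id"],
            )
            for c in payload["cameras"]
        ]
        return cls(
            cams,
            payload["radius"],
            payload["subdivision_level"],
            payload.get("projection", "perspective"),
        )


def _up_vector(direction: np.ndarray) -> np.ndarray:
    """Global +z projected perpendicular to the view direction.

    At the two poles (view direction parallel to z) falls back to +y.
    """
    z = np.array([0.0, 0.0, 1.0])
    proj = z - np.dot(z, direction) * direction
    norm = np.linalg.norm(proj)
    if norm < 1e-6:
        return np.array([0.0, 1.0, 0.0])
    return proj / norm


def default_fov(radius: float, fill_fraction: float = 0.9) -> float:
    """Field of view at which the unit sphere spans ``fill_fraction`` of frame."""
    half = np.arcsin(min(1.0 / radius, 1.0)) / fill_fraction
    return float(np.degrees(2.0 * half))


def icosphere_cameras(
    subdivision_level: int = 0,
    radius: float = 3.0,
    fov: float | None = None,
    projection: str = "perspective",
) -> ViewSet:
    """Place cameras at the vertices of a subdivided icosahedron.

    Parameters
    ----------
    subdivision_level
        Loop-subdivision level; the camera count is ``10 * 4**level + 2``.
    radius
        Camera distance from the origin; must exceed 1 so every camera lies
        outside the pose-normalized unit bound.
    fov
        Vertical field of view in degrees.  Default frames the unit sphere at
        ~90% of the image height.
    """
    if subdivision_level < 0:
        raise ValueError("subdivision_level must be >= 0")
    if radius <= 1.0:
        raise ValueError("radius must be > 1 (outside the unit-normalized mesh)")
    if projection not in ("perspective", "orthographic"):
        raise ValueError(f"unknown projection {projection!r}")
    if fov is None:
        fov = default_fov(radius)

    ico = trimesh.creation.icosphere(subdivisions=subdivision_level, radius=1.0)
    verts = np.asarray(ico.vertices, dtype=np.float64)
    # impose a reproducible ordering independent of trimesh internals
    order = np.lexsort((verts[:, 0], verts[:, 1], verts[:, 2]))
    verts = verts[order]

    origin = np.zeros(3)
    cameras = []
    for i, v in enumerate(verts):
        direction = v / np.linalg.norm(v)
        cameras.append(
            Camera(
                position=direction * radius,
                look_at=origin,
                up=_up_vector(direction),
                fov=fov,
                id=i,
            )
        )
    return ViewSet(cameras, radius=radius, subdivision_level=subdivision_level,
                   projection=projection)
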