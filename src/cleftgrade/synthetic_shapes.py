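"""Parametric "cleft arch" meshes emulating the four severity grades.

Patient maxilla models are not redistributable, so this module generates a
labeled stand-in population: a horseshoe arch (elliptical cross-section swept
along a parabolic midline) deformed according to a severity grade 0-3 of the
alveolar bone defect:

* **0** - a carved *buccal depression* on one side (partial-thickness notch);
  the arch stays intact.
* **1** - a unilateral *complete cleft*: one full-thickness gap through the
  arch, palatal continuity preserved by a connecting strip.
* **2** - bilateral gaps isolating an anterior *premaxilla* segment that is
  displaced forward, with some palatal bone continuity (thick strips).
* **3** - as 2 but with larger projection and *small or no* palatal
  continuity; with no strip the mesh falls into three connected components
  (two posterior segments plus the premaxilla).

Every generated mesh carries a ground-truth *defect region* (vertex indices
at the carved depression, the gap rims, the palatal strips and, for grades
2-3, the premaxilla) used to score heatmap localization quantitatively.

These are geometric caricatures: no teeth, no anatomical maxilla template,
no scan noise.  They exist to exercise and test every downstream algorithm,
not to imitate CBCT-derived anatomy.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .mesh_io import TriangleMesh, write_mesh

__all__ = [
    "DefectParams",
    "DatasetRecord",
    "DatasetManifest",
    "DEFAULT_RANGES",
    "COHORT_IMBALANCE",
    "sample_params",
    "build_arch",
    "generate_dataset",
    "load_manifest",
]

GENERATOR_VERSION = "cleftgrade-arch-1"

#: class supports of the reference cohort (grades 0..3)
COHORT_IMBALANCE = (62, 45, 45, 38)


@dataclass(frozen=True)
class DefectParams:
    """Geometric parameters of one graded defect.

    ``notch_width`` is the angular width (radians along the arch sweep) of
    each full-thickness gap or carved depression; ``notch_depth_fraction`` the
    fraction of the cross-section removed (1 = through-and-through cleft);
    ``premaxilla_projection`` the forward displacement of the anterior segment
    in model units (arch half-width is ~1); ``palatal_bridge_thickness``
    scales the palatal connecting strip (0 = no palatal continuity).
    """

    severity: int
    notch_width: float
    notch_depth_fraction: float
    bilateral: bool
    premaxilla_projection: float
    palatal_bridge_thickness: float
    seed: int

    def __post_init__(self) -> None:
        if self.severity not in (0, 1, 2, 3):
            raise ValueError(f"severity must be in 0..3, got {self.severity}")


# Per-grade sampling ranges.  Widths and projections increase with grade with
# slight overlap between neighbours (the difficulty knob); grade 3 bridges are
# pinned near zero, below the grade-2 minimum.
DEFAULT_RANGES: dict[int, dict[str, tuple[float, float]]] = {
    0: {"notch_width": (0.25, 0.45), "depth": (0.30, 0.65),
        "projection": (0.0, 0.0), "bridge": (1.0, 1.0)},
    1: {"notch_width": (0.30, 0.50), "depth": (1.0, 1.0),
        "projection": (0.0, 0.0), "bridge": (0.50, 0.90)},
    2: {"notch_width": (0.40, 0.60), "depth": (1.0, 1.0),
        "projection": (0.15, 0.40), "bridge": (0.25, 0.60)},
    3: {"notch_width": (0.50, 0.75), "depth": (1.0, 1.0),
        "projection": (0.30, 0.55), "bridge": (0.0, 0.05)},
}


def sample_params(
    severity: int,
    seed: int,
    ranges: dict[int, dict[str, tuple[float, float]]] | None = None,
) -> DefectParams:
    """Draw grade-consistent defect parameters, deterministically from seed."""
    if severity not in (0, 1, 2, 3):
        raise ValueError(f"severity must be in 0..3, got {severity}")
    r = (ranges or DEFAULT_RANGES)[severity]
    rng = np.random.default_rng([severity, seed])
    u = lambda lo_hi: float(rng.uniform(*lo_hi))
    bridge = u(r["bridge"])
    if severity == 3 and bridge < 0.025:
        bridge = 0.0  # "no palatal continuity" half of grade 3
    return DefectParams(
        severity=severity,
        notch_width=u(r["notch_width"]),
        notch_depth_fraction=u(r["depth"]),
        bilateral=severity >= 2,
        premaxilla_projection=u(r["projection"]),
        palatal_bridge_thickness=bridge,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# arch construction

# sweep parameter t in [0, 1]: t=0.5 is the anterior midline, ends are
# posterior.  Midline is a parabola opening backwards in the xy-plane.
_ARCH_HALF_WIDTH = 1.0
_ARCH_DEPTH = 1.6  # anterior-posterior extent
_SECTION_RX = 0.16  # cross-section semi-axes
_SECTION_RZ = 0.22
_GAP_CENTER_UNILATERAL = 0.32  # t-position of the single (left) gap
_GAP_CENTER_BILATERAL = (0.34, 0.66)


@dataclass(frozen=True)
class _ArchGeometry:
    """Per-shape global geometry nuisance parameters.

    Arch proportions and cross-section are jittered between shapes (and the
    arch randomly mirrored left/right) so that overall size and silhouette
    carry no class information: the carved / cleft / projected features are
    the only reliable severity cues, as they are for real anatomy.
    """

    half_width: float = _ARCH_HALF_WIDTH
    depth: float = _ARCH_DEPTH
    rx: float = _SECTION_RX
    rz: float = _SECTION_RZ
    mirror: bool = False
    # defect positions along the sweep; clefts arise at varying positions in
    # the lateral-incisor/canine region, so a fixed location would let the
    # classifier learn position templates instead of defect morphology
    gap_center: float = _GAP_CENTER_UNILATERAL
    gap_centers_bilateral: tuple[float, float] = _GAP_CENTER_BILATERAL

    @classmethod
    def sample(cls, rng: np.random.Generator) -> "_ArchGeometry":
        c_uni = rng.uniform(0.26, 0.40)
        c_left = rng.uniform(0.27, 0.40)
        c_right = rng.uniform(0.60, 0.73)
        return cls(
            half_width=_ARCH_HALF_WIDTH * rng.uniform(0.88, 1.12),
            depth=_ARCH_DEPTH * rng.uniform(0.88, 1.12),
            rx=_SECTION_RX * rng.uniform(0.72, 1.28),
            rz=_SECTION_RZ * rng.uniform(0.72, 1.28),
            mirror=bool(rng.integers(0, 2)),
            gap_center=c_uni,
            gap_centers_bilateral=(c_left, c_right),
        )


def _midline(t: np.ndarray, geom: _ArchGeometry = _ArchGeometry()) -> np.ndarray:
    """Parabolic arch midline; anterior apex at t = 0.5, +y forward."""
    x = geom.half_width * (2.0 * t - 1.0)
    y = geom.depth * (1.0 - (2.0 * t - 1.0) ** 2) - geom.depth / 2.0
    return np.column_stack([x, y, np.zeros_like(x)])


def _tube_segment(
    t0: float,
    t1: float,
    n_s: int,
    n_c: int,
    jitter_rng: np.random.Generator | None,
    geom: _ArchGeometry = _ArchGeometry(),
    cap_start: bool = False,
    cap_end: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Swept elliptical tube over t in [t0, t1]; returns (verts, faces, t_of_vertex).

    ``cap_start``/``cap_end`` close the end rings with triangle fans, as the
    closed surfaces produced by segmentation are; cleft cut rims are the only
    openings left deliberately open.
    """
    t = np.linspace(t0, t1, n_s)
    center = _midline(t, geom)
    # tangent along sweep
    tang = np.gradient(center, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    up = np.array([0.0, 0.0, 1.0])
    side = np.cross(up, tang)  # horizontal, points outward (buccal)
    side /= np.linalg.norm(side, axis=1, keepdims=True)

    phi = np.linspace(0.0, 2.0 * np.pi, n_c, endpoint=False)
    ring = (
        np.cos(phi)[None, :, None] * (side[:, None, :] * geom.rx)
        + np.sin(phi)[None, :, None] * (up[None, None, :] * geom.rz)
    )
    verts = (center[:, None, :] + ring).reshape(-1, 3)
    if jitter_rng is not None:
        verts = verts + jitter_rng.normal(scale=0.004, size=verts.shape)

    faces = []
    for i in range(n_s - 1):
        for j in range(n_c):
            a = i * n_c + j
            b = i * n_c + (j + 1) % n_c
            c = (i + 1) * n_c + j
            d = (i + 1) * n_c + (j + 1) % n_c
            faces.append((a, b, c))
            faces.append((b, d, c))
    t_of_vertex = np.repeat(t, n_c)

    extra_verts, extra_t = [], []
    if cap_start:
        cidx = len(verts) + len(extra_verts)
        extra_verts.append(center[0])
        extra_t.append(t0)
        for j in range(n_c):
            faces.append((cidx, (j + 1) % n_c, j))
    if cap_end:
        cidx = len(verts) + len(extra_verts)
        base = (n_s - 1) * n_c
        extra_verts.append(center[-1])
        extra_t.append(t1)
        for j in range(n_c):
            faces.append((cidx, base + j, base + (j + 1) % n_c))
    if extra_verts:
        verts = np.vstack([verts, extra_verts])
        t_of_vertex = np.concatenate([t_of_vertex, extra_t])
    return verts, np.asarray(faces, dtype=np.int64), t_of_vertex


def _merge(
    parts: list[tuple[np.ndarray, np.ndarray]]
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    verts, faces, slices = [], [], []
    offset = 0
    for v, f in parts:
        verts.append(v)
        faces.append(f + offset)
        slices.append(np.arange(offset, offset + len(v)))
        offset += len(v)
    return np.vstack(verts), np.vstack(faces), slices


def build_arch(
    params: DefectParams,
    resolution: int = 48,
    n_circum: int = 14,
    jitter_geometry: bool = True,
) -> tuple[TriangleMesh, np.ndarray]:
    """Build the graded arch mesh; returns (mesh, defect-region vertex indices).

    ``resolution`` is the number of sweep stations along the full arch;
    ``n_circum`` the ring vertex count.  Minimum resolution guards the tube
    topology (every segment keeps >= 2 stations).
    """
    if resolution < 24 or n_circum < 8:
        raise ValueError("resolution must be >= 24 stations and >= 8 ring vertices")
    if params.notch_width >= 1.2:
        raise ValueError("notch_width too large: anterior segment vanishes")
    rng = np.random.default_rng([params.seed, 17])
    geom = _ArchGeometry.sample(rng) if jitter_geometry else _ArchGeometry()
    half_w = params.notch_width / (2.0 * np.pi) * 2.0  # angular width -> t units

    def finish(verts, faces, defect_idx):
        if geom.mirror:
            verts = verts.copy()
            verts[:, 0] = -verts[:, 0]
        return TriangleMesh(verts, faces), np.asarray(defect_idx, dtype=np.int64)

    full_thickness = params.notch_depth_fraction >= 1.0
    if not full_thickness:
        # grade 0: intact tube with a carved buccal depression
        verts, faces, t_of_v = _tube_segment(0.0, 1.0, resolution, n_circum, rng,
                                             geom, cap_start=True, cap_end=True)
        c = geom.gap_center
        center = _midline(t_of_v, geom)
        d = verts - center
        d[:, 2] = 0.0
        # buccal = outer half of each ring (offset pointing away from the
        # arch midline on the gap side)
        depth = params.notch_depth_fraction
        if depth <= 0:  # no-defect limit: intact arch
            return finish(verts, faces, np.array([], dtype=np.int64))
        buccal = d[:, 0] * np.sign(center[:, 0] + 1e-9) >= 0
        window = np.abs(t_of_v - c) < half_w / 2.0
        sel = window & buccal
        falloff = np.cos(
            np.clip((t_of_v[sel] - c) / (half_w / 2.0), -1, 1) * np.pi / 2.0
        )
        verts[sel] -= d[sel] * (depth * falloff)[:, None]
        return finish(verts, faces, np.nonzero(sel)[0])

    # grades 1-3: full-thickness gap(s); a positive palatal bridge thickness
    # keeps the tube continuous across each gap as a thin, palatally offset
    # strip, while zero thickness removes the gap interval entirely
    # clamp sampled gap centers so every tube segment keeps finite width
    margin = half_w / 2.0
    if params.bilateral:
        centers = [
            float(np.clip(geom.gap_centers_bilateral[0],
                          margin + 0.06, 0.5 - margin - 0.04)),
            float(np.clip(geom.gap_centers_bilateral[1],
                          0.5 + margin + 0.04, 1.0 - margin - 0.06)),
        ]
    else:
        centers = [
            float(np.clip(geom.gap_center, margin + 0.06, 0.5 - margin - 0.04))
        ]
    gaps = [(c - half_w / 2.0, c + half_w / 2.0) for c in centers]
    bounds = [0.0] + [b for gap in gaps for b in gap] + [1.0]
    if any(bounds[i] >= bounds[i + 1] - 1e-6 for i in range(len(bounds) - 1)):
        raise ValueError("notch_width too large: a segment vanishes")

    tau = params.palatal_bridge_thickness

    def in_gap(t: np.ndarray) -> np.ndarray:
        m = np.zeros_like(t, dtype=bool)
        for a, b in gaps:
            m |= (t >= a) & (t <= b)
        return m

    def bridge_blend(t: np.ndarray) -> np.ndarray:
        """0 outside gaps, ramping to 1 over the inner part of each gap."""
        beta = np.zeros_like(t)
        for a, b in gaps:
            u = np.clip((t - a) / (b - a), 0.0, 1.0)
            ramp = np.clip(np.minimum(u, 1.0 - u) / 0.25, 0.0, 1.0)
            inside = (t >= a) & (t <= b)
            beta[inside] = np.maximum(beta[inside], ramp[inside])
        return beta

    def premax_blend(t: np.ndarray) -> np.ndarray:
        """1 on the anterior segment, ramping to 0 across each gap."""
        lo = gaps[0][1] if params.bilateral else gaps[0][1]
        hi = gaps[1][0] if params.bilateral else 1.0
        psi = np.zeros_like(t)
        psi[(t >= lo) & (t <= hi)] = 1.0
        for a, b in gaps:
            inside = (t >= a) & (t < b + 1e-12)
            u = np.clip((t[inside] - a) / (b - a), 0.0, 1.0)
            psi[inside] = u if b <= lo + 1e-9 else 1.0 - u
        return psi

    if tau > 1e-9:
        # single continuous tube, modulated inside the gap windows
        t = np.linspace(0.0, 1.0, resolution)
        center = _midline(t, geom)
        tang = np.gradient(center, axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        up = np.array([0.0, 0.0, 1.0])
        side = np.cross(up, tang)
        side /= np.linalg.norm(side, axis=1, keepdims=True)
        beta = bridge_blend(t)
        rx = geom.rx * (1.0 - 0.5 * beta)
        rz = geom.rz * (1.0 - beta * (1.0 - 0.55 * tau))
        ring_center = center - side * (geom.rx * 0.6 * beta)[:, None]
        phi = np.linspace(0.0, 2.0 * np.pi, n_circum, endpoint=False)
        ring = (
            np.cos(phi)[None, :, None] * (side[:, None, :] * rx[:, None, None])
            + np.sin(phi)[None, :, None] * (up[None, None, :] * rz[:, None, None])
        )
        verts = (ring_center[:, None, :] + ring).reshape(-1, 3)
        verts += rng.normal(scale=0.004, size=verts.shape)
        faces = []
        for i in range(resolution - 1):
            for j in range(n_circum):
                a = i * n_circum + j
                b = i * n_circum + (j + 1) % n_circum
                c2 = (i + 1) * n_circum + j
                d2 = (i + 1) * n_circum + (j + 1) % n_circum
                faces.append((a, b, c2))
                faces.append((b, d2, c2))
        # close the posterior ends (segmented bone surfaces are closed)
        for cap_i, base in ((0, 0), (resolution - 1, (resolution - 1) * n_circum)):
            cidx = len(verts)
            verts = np.vstack([verts, ring_center[cap_i]])
            for j in range(n_circum):
                if cap_i == 0:
                    faces.append((cidx, (j + 1) % n_circum, j))
                else:
                    faces.append((cidx, base + j, base + (j + 1) % n_circum))
        faces = np.asarray(faces, dtype=np.int64)
        t_of_v = np.concatenate([np.repeat(t, n_circum), [0.0, 1.0]])
        psi = premax_blend(t_of_v)
        verts[:, 1] += params.premaxilla_projection * psi
        rim_band = 1.5 / resolution
        near_gap = in_gap(np.clip(t_of_v - rim_band, 0, 1)) | in_gap(
            np.clip(t_of_v + rim_band, 0, 1)
        )
        defect = near_gap.copy()
        if params.premaxilla_projection > 0:
            defect |= psi > 0.5
        return finish(verts, faces, np.nonzero(defect)[0])

    # tau == 0: gap intervals removed; separate tube segments per span
    parts: list[tuple[np.ndarray, np.ndarray]] = []
    seg_ts: list[tuple[float, float]] = []
    seg_tv: list[np.ndarray] = []
    for k in range(0, len(bounds), 2):
        t0, t1 = bounds[k], bounds[k + 1]
        n_s = max(int(round(resolution * (t1 - t0))), 3)
        v, f, tv = _tube_segment(t0, t1, n_s, n_circum, rng, geom,
                                 cap_start=(k == 0),
                                 cap_end=(k + 2 == len(bounds)))
        parts.append((v, f))
        seg_ts.append((t0, t1))
        seg_tv.append(tv)

    verts, faces, slices = _merge(parts)
    anterior = next(
        i for i, (a, b) in enumerate(seg_ts) if a <= 0.5 <= b
    )
    if params.premaxilla_projection > 0:
        verts[slices[anterior], 1] += params.premaxilla_projection

    defect = []
    rim_band = 1.5 / resolution
    for si, (a, b) in enumerate(seg_ts):
        tv = seg_tv[si]
        mask = np.zeros(len(tv), dtype=bool)
        if any(abs(a - g[1]) < 1e-9 for g in gaps):  # cut at segment start
            mask |= tv < a + rim_band
        if any(abs(b - g[0]) < 1e-9 for g in gaps):  # cut at segment end
            mask |= tv > b - rim_band
        defect.append(slices[si][mask])
    if params.premaxilla_projection > 0:
        defect.append(slices[anterior])
    defect_idx = (
        np.unique(np.concatenate(defect)) if defect else np.array([], dtype=int)
    )
    return finish(verts, faces, defect_idx)


# ---------------------------------------------------------------------------
# dataset generation


@dataclass
class DatasetRecord:
    mesh_path: str
    label: int
    seed: int
    defect_vertices: np.ndarray


@dataclass
class DatasetManifest:
    records: list[DatasetRecord]
    generator_version: str = GENERATOR_VERSION

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.int64)


def _record_seed(seed: int, label: int, index: int) -> int:
    h = hashlib.sha256(f"{seed}:{label}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def generate_dataset(
    n_per_class: int | tuple[int, int, int, int],
    out_dir: str | Path,
    seed: int = 0,
    resolution: int = 48,
    n_circum: int = 14,
    fmt: str = "vtk",
) -> DatasetManifest:
    """Generate a labeled arch population and write meshes + manifest CSV.

    ``n_per_class`` is either a single count or a 4-tuple; the tuple
    ``COHORT_IMBALANCE`` reproduces the reference cohort's class supports.
    Fully reproducible from ``seed``.
    """
    counts = (
        tuple(n_per_class)
        if not np.isscalar(n_per_class)
        else (n_per_class,) * 4
    )
    if len(counts) != 4 or any(c < 1 for c in counts):
        raise ValueError("n_per_class must be a positive int or 4 positive ints")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records = []
    for label in range(4):
        for i in range(counts[label]):
            rseed = _record_seed(seed, label, i)
            params = sample_params(label, rseed)
            mesh, defect = build_arch(params, resolution=resolution,
                                      n_circum=n_circum)
            name = f"arch_s{label}_{i:04d}.{fmt}"
            write_mesh(out_dir / name, mesh, fmt)
            records.append(DatasetRecord(name, label, rseed, defect))

    manifest = DatasetManifest(records)
    save_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def save_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["mesh_path", "label", "seed", "defect_vertices",
                    "generator_version"])
        for r in manifest.records:
            w.writerow([
                r.mesh_path,
                r.label,
                r.seed,
                ";".join(map(str, np.asarray(r.defect_vertices, dtype=int))),
                manifest.generator_version,
            ])


def load_manifest(path: str | Path) -> DatasetManifest:
    path = Path(path)
    records = []
    version = GENERATOR_VERSION
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            version = row.get("generator_version", version)
            dv = row["defect_vertices"]
            records.append(
                DatasetRecord(
                    row["mesh_path"],
                    int(row["label"]),
                    int(row["seed"]),
                    np.array([int(x) for x in dv.split(";")] if dv else [],
                             dtype=np.int64),
                )
            )
    return DatasetManifest(records, version)
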