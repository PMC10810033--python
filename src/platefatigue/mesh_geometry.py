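"""Critical cross-section extraction from a plate surface mesh.

The plate is sliced by a stack of cutting planes along its longitudinal
(z) axis.  Each plane-mesh intersection yields one or more closed
polylines in the section plane (two where the plane passes through a
screw hole).  Closed-form polygon moments, Varignon's theorem for the
composite centroid and the Huygens-Steiner (parallel-axis) theorem give
the centroidal second moment of area I_xx about the bending axis.  The
section with the smallest I_xx is the critical section; its width ``w``,
thickness ``t`` and hole gap ``d`` feed the notch and fatigue models.

Conventions: lengths in mm, the longitudinal axis is z, the load
(thickness) direction is y and the bending axis (width) is x.  Sections
live in the x-y plane at station z.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import trimesh
from shapely.geometry import LinearRing, Polygon

from .errors import (
    DegenerateMeshError,
    GeometryError,
    MeshFormatError,
    OrientationWarning,
    SlicingWarning,
)

__all__ = [
    "TriMesh",
    "SlicingConfig",
    "SectionPolyline",
    "SectionProperties",
    "load_mesh",
    "orient_plate",
    "slice_plate",
    "polygon_moments",
    "composite_properties",
    "critical_section",
    "critical_from_mesh",
    "extract_sections",
    "section_table",
    "critical_section_summary",
]

#: relative area below which a polyline is treated as a slicing sliver
SLIVER_RELATIVE_AREA = 1e-6

#: bounding-box edge ratio below which plate orientation is ambiguous
ORIENTATION_AMBIGUITY_RATIO = 1.05


@dataclass
class TriMesh:
    """Triangulated surface mesh of a plate (vertices in mm)."""

    vertices: np.ndarray
    faces: np.ndarray
    watertight: bool = True

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise DegenerateMeshError("vertices must be an (n, 3) array")
        if len(self.vertices) < 4:
            raise DegenerateMeshError("a solid mesh needs at least 4 vertices")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise DegenerateMeshError("faces must be an (m, 3) array")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= len(self.vertices):
            raise DegenerateMeshError("face indices out of range")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @property
    def extents(self) -> np.ndarray:
        return self.vertices.max(axis=0) - self.vertices.min(axis=0)


@dataclass
class SlicingConfig:
    """Cutting-plane stack configuration.

    ``n_planes`` equidistant planes are placed on the longitudinal test
    region ``[region_start_z, region_end_z]`` (the four-point-bending
    center span ``a``); when the region is not given it defaults to the
    central 50% of the plate length.  With ``two_pass`` the planes of a
    second pass follow the centroid polyline of the first, so curved
    plates are cut normal to their own axis.
    """

    n_planes: int = 100
    region_start_z: float | None = None
    region_end_z: float | None = None
    two_pass: bool = True

    def __post_init__(self) -> None:
        if self.n_planes < 2:
            raise GeometryError("n_planes must be at least 2")
        if (
            self.region_start_z is not None
            and self.region_end_z is not None
            and not self.region_end_z > self.region_start_z
        ):
            raise GeometryError("region_end_z must exceed region_start_z")

    def region(self, mesh: TriMesh) -> tuple[float, float]:
        zmin = float(mesh.vertices[:, 2].min())
        zmax = float(mesh.vertices[:, 2].max())
        length = zmax - zmin
        lo = self.region_start_z if self.region_start_z is not None else zmin + 0.25 * length
        hi = self.region_end_z if self.region_end_z is not None else zmax - 0.25 * length
        return float(lo), float(hi)


@dataclass
class SectionPolyline:
    """One closed, simple polyline of a cross-section (section-plane mm)."""

    vertices: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise GeometryError("polyline vertices must be an (n, 2) array")
        if len(self.vertices) >= 2 and np.allclose(self.vertices[0], self.vertices[-1]):
            self.vertices = self.vertices[:-1]
        if len(self.vertices) < 3:
            raise GeometryError("a closed polyline needs at least 3 vertices")
        if not self.closed:
            raise GeometryError("section polylines must be closed")

    def shapely_ring(self) -> LinearRing:
        return LinearRing(self.vertices)


@dataclass
class SectionProperties:
    """Composite properties of one cross-section at station z."""

    station_z: float
    area: float
    centroid: tuple[float, float]
    Ixx: float
    w: float
    t: float
    d: float
    n_polylines: int = 1

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise GeometryError("section area must be positive")
        if not self.Ixx > 0:
            raise GeometryError("section Ixx must be positive")
        if self.d < 0 or self.d > self.w:
            raise GeometryError("hole gap d must satisfy 0 <= d <= w")
        if not self.t > 0:
            raise GeometryError("thickness must be positive")


def load_mesh(path: str | Path, unit_scale: float = 1.0) -> TriMesh:
    """Read a binary or ASCII STL file into a :class:`TriMesh`.

    Units are taken as mm verbatim; pass ``unit_scale`` (e.g. 1000 for a
    mesh exported in metres) to rescale.  A non-watertight mesh is
    accepted with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"mesh file not found: {path}")
    if path.stat().st_size == 0:
        raise MeshFormatError(f"mesh file is empty: {path}")
    try:
        raw = trimesh.load(str(path), force="mesh")
    except Exception as exc:  # noqa: BLE001 - any loader failure is a format error
        raise MeshFormatError(f"could not parse mesh file {path}: {exc}") from exc
    if not isinstance(raw, trimesh.Trimesh) or len(raw.faces) == 0:
        raise DegenerateMeshError(f"mesh file {path} contains no triangles")
    watertight = bool(raw.is_watertight)
    if not watertight:
        warnings.warn(
            f"mesh {path.name} is not watertight; section contours may be open",
            SlicingWarning,
            stacklevel=2,
        )
    return TriMesh(vertices=np.asarray(raw.vertices) * float(unit_scale),
                   faces=np.asarray(raw.faces), watertight=watertight)


def orient_plate(mesh: TriMesh) -> tuple[TriMesh, np.ndarray]:
    """Rigidly align the plate: longest AABB edge to z, shortest to y.

    Returns the oriented mesh and the homogeneous 4x4 transform applied
    (a proper rotation composed with the translation that centers the
    axis-aligned bounding box at the origin).  An already-aligned,
    centered mesh gets the identity.  Near-isotropic meshes trigger an
    :class:`OrientationWarning`; ties are broken deterministically in
    the axis order z > y > x.
    """
    ext = mesh.extents
    order = np.argsort(ext)  # ascending
    if ext[order[2]] < ORIENTATION_AMBIGUITY_RATIO * ext[order[1]]:
        warnings.warn(
            "plate bounding box is nearly isotropic; longitudinal axis chosen "
            "by the deterministic tie-break z > y > x",
            OrientationWarning,
            stacklevel=2,
        )
    # Tie-break: among axes whose extent matches the extreme within 1e-12
    # relative, prefer z (2), then y (1), then x (0).
    def _pick(candidates: list[int], target: float) -> int:
        for axis in (2, 1, 0):
            if axis in candidates and abs(ext[axis] - target) <= 1e-12 * max(target, 1.0):
                return axis
        return candidates[0]

    axes = [0, 1, 2]
    long_axis = _pick(axes, ext[order[2]])
    axes.remove(long_axis)
    short_axis = _pick(axes, min(ext[a] for a in axes))
    axes.remove(short_axis)
    mid_axis = axes[0]

    # new x <- mid (width), new y <- short (thickness), new z <- long
    perm = np.zeros((3, 3))
    perm[0, mid_axis] = 1.0
    perm[1, short_axis] = 1.0
    perm[2, long_axis] = 1.0
    if np.linalg.det(perm) < 0:
        perm[0, :] *= -1.0  # keep the rotation proper; AABB is unaffected
    rotated = mesh.vertices @ perm.T
    center = 0.5 * (rotated.max(axis=0) + rotated.min(axis=0))
    transform = np.eye(4)
    transform[:3, :3] = perm
    transform[:3, 3] = -center  # expressed in the rotated frame
    oriented = TriMesh(vertices=rotated - center, faces=mesh.faces.copy(),
                       watertight=mesh.watertight)
    return oriented, transform


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane basis (u, v): u tracks global x (width), v the thickness."""
    n = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(n @ ref) > 0.99:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - (ref @ n) * n
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def _section_polylines(
    tm: trimesh.Trimesh, origin: np.ndarray, normal: np.ndarray
) -> list[SectionPolyline] | None:
    """Intersect one plane with the mesh; None when the plane misses it.

    Raises GeometryError when a contour cannot be interpreted as a
    closed simple polygon (mesh defect at this station).
    """
    section = tm.section(plane_origin=origin, plane_normal=normal)
    if section is None:
        return None
    u, v = _plane_basis(np.asarray(normal, dtype=float))
    loops: list[np.ndarray] = []
    for pts in section.discrete:
        rel = np.asarray(pts, dtype=float) - origin
        xy = np.column_stack([rel @ u, rel @ v])
        if np.allclose(xy[0], xy[-1]):
            xy = xy[:-1]
        if len(xy) < 3:
            continue
        loops.append(xy)
    if not loops:
        return None
    areas = [abs(_shoelace(xy)) for xy in loops]
    largest = max(areas)
    kept: list[SectionPolyline] = []
    for xy, area in zip(loops, areas):
        if area < SLIVER_RELATIVE_AREA * largest:
            warnings.warn(
                "dropping near-degenerate sliver polyline (plane grazing a "
                "hole edge)",
                SlicingWarning,
                stacklevel=3,
            )
            continue
        if not Polygon(xy).is_valid:
            raise GeometryError("open or self-intersecting section contour")
        kept.append(SectionPolyline(vertices=xy))
    return kept or None


def slice_plate(
    mesh: TriMesh, config: SlicingConfig
) -> list[tuple[float, list[SectionPolyline]]]:
    """Cut the plate with ``n_planes`` planes over the test region.

    Pass 1 uses equidistant planes normal to z.  When ``two_pass`` is
    set, the centroid polyline of pass 1 approximates the plate
    curvature and a second slicing is performed with the same number of
    planes, each normal to the local centroid-polyline direction
    (central differences; one-sided at the ends).

    Returns ``[(station_z, [polyline, ...]), ...]``.  Stations missed by
    their plane, or with defective contours, are excluded with a
    warning; an all-empty result is an error.
    """
    tm = mesh.to_trimesh()
    lo, hi = config.region(mesh)
    stations = np.linspace(lo, hi, config.n_planes)
    z_axis = np.array([0.0, 0.0, 1.0])

    pass1: list[tuple[float, np.ndarray, list[SectionPolyline]]] = []
    for z in stations:
        origin = np.array([0.0, 0.0, z])
        try:
            polys = _section_polylines(tm, origin, z_axis)
        except GeometryError:
            warnings.warn(f"station z={z:.3f}: defective contour rejected",
                          SlicingWarning, stacklevel=2)
            continue
        if polys is None:
            warnings.warn(f"station z={z:.3f}: cutting plane missed the mesh",
                          SlicingWarning, stacklevel=2)
            continue
        centroid3d = _composite_centroid_3d(polys, origin, z_axis)
        pass1.append((float(z), centroid3d, polys))
    if not pass1:
        raise GeometryError("no cutting plane intersected the mesh")

    if not config.two_pass or len(pass1) < 3:
        return [(z, polys) for z, _, polys in pass1]

    centroids = np.array([c for _, c, _ in pass1])
    result: list[tuple[float, list[SectionPolyline]]] = []
    for i, (_, c, _) in enumerate(pass1):
        j0 = max(i - 1, 0)
        j1 = min(i + 1, len(pass1) - 1)
        direction = centroids[j1] - centroids[j0]
        norm = np.linalg.norm(direction)
        normal = direction / norm if norm > 0 else z_axis
        try:
            polys = _section_polylines(tm, c, normal)
        except GeometryError:
            warnings.warn(f"station z={c[2]:.3f}: defective contour rejected",
                          SlicingWarning, stacklevel=2)
            continue
        if polys is None:
            warnings.warn(f"station z={c[2]:.3f}: second-pass plane missed the mesh",
                          SlicingWarning, stacklevel=2)
            continue
        result.append((float(c[2]), polys))
    if not result:
        raise GeometryError("second slicing pass produced no sections")
    return result


def _composite_centroid_3d(
    polys: Sequence[SectionPolyline], origin: np.ndarray, normal: np.ndarray
) -> np.ndarray:
    u, v = _plane_basis(np.asarray(normal, dtype=float))
    total_area = 0.0
    accum = np.zeros(2)
    for p in polys:
        area, c, _ = polygon_moments(p)
        total_area += area
        accum += area * np.asarray(c)
    c2 = accum / total_area
    return origin + c2[0] * u + c2[1] * v


def _shoelace(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * yn - xn * y))


def polygon_moments(poly: SectionPolyline) -> tuple[float, tuple[float, float], float]:
    """Closed-form (Green's theorem) area, centroid and centroidal Ixx.

    Winding is normalized, so the area is positive either way; Ixx is
    about the polygon's own centroidal x-axis (translation-invariant).
    """
    xy = poly.vertices
    if not Polygon(xy).is_valid:
        raise GeometryError("polyline is self-intersecting or degenerate")
    a_signed = _shoelace(xy)
    if a_signed == 0.0:
        raise GeometryError("polyline has zero area")
    if a_signed < 0:
        xy = xy[::-1]
        a_signed = -a_signed
    x, y = xy[:, 0], xy[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = a_signed
    cx = float(np.sum((x + xn) * cross) / (6.0 * area))
    cy = float(np.sum((y + yn) * cross) / (6.0 * area))
    ixx_origin = float(np.sum((y * y + y * yn + yn * yn) * cross) / 12.0)
    ixx = ixx_origin - area * cy * cy
    return float(area), (cx, cy), float(ixx)


def composite_properties(
    polys: Sequence[SectionPolyline], station: float
) -> SectionProperties:
    """Compose one station's polylines into :class:`SectionProperties`.

    The composite centroid is the area-weighted mean of the polyline
    centroids (Varignon); the composite Ixx adds each polyline's
    parallel-axis contribution A_i * dy_i^2 (Huygens-Steiner).  Width w
    and thickness t come from the 2-D axis-aligned bounding box of all
    section vertices; the hole gap d is the minimum distance between
    polyline pairs (0 for a single polyline).
    """
    if not polys:
        raise GeometryError("composite_properties needs at least one polyline")
    moments = [polygon_moments(p) for p in polys]
    total_area = sum(m[0] for m in moments)
    if total_area <= 0:
        raise GeometryError("zero total section area")
    cx = sum(m[0] * m[1][0] for m in moments) / total_area
    cy = sum(m[0] * m[1][1] for m in moments) / total_area
    ixx = sum(m[2] + m[0] * (m[1][1] - cy) ** 2 for m in moments)
    allpts = np.vstack([p.vertices for p in polys])
    w = float(allpts[:, 0].max() - allpts[:, 0].min())
    t = float(allpts[:, 1].max() - allpts[:, 1].min())
    if len(polys) == 1:
        d = 0.0
    else:
        if len(polys) > 2:
            warnings.warn(
                f"{len(polys)} polylines at station {station:.3f}; the "
                "downstream notch chart assumes a single circular hole",
                SlicingWarning,
                stacklevel=2,
            )
        rings = [p.shapely_ring() for p in polys]
        d = min(
            rings[i].distance(rings[j])
            for i in range(len(rings))
            for j in range(i + 1, len(rings))
        )
    return SectionProperties(
        station_z=float(station),
        area=float(total_area),
        centroid=(float(cx), float(cy)),
        Ixx=float(ixx),
        w=w,
        t=t,
        d=float(d),
        n_polylines=len(polys),
    )


def critical_section(
    sections: Sequence[SectionProperties],
) -> tuple[int, SectionProperties]:
    """Select the section with the smallest Ixx (ties: smallest station)."""
    if not sections:
        raise GeometryError("no sections to select from")
    best = min(range(len(sections)),
               key=lambda i: (sections[i].Ixx, sections[i].station_z))
    return best, sections[best]


def extract_sections(mesh: TriMesh, config: SlicingConfig) -> list[SectionProperties]:
    """Orient, slice and compose: the full per-station property table."""
    oriented, _ = orient_plate(mesh)
    sliced = slice_plate(oriented, config)
    return [composite_properties(polys, z) for z, polys in sliced]


def critical_from_mesh(
    mesh: TriMesh,
    config: SlicingConfig,
    refine: bool = True,
    refine_iters: int = 2,
    refine_planes: int = 7,
) -> tuple[SectionProperties, list[SectionProperties]]:
    """Critical section of a mesh, with sub-station bracket refinement.

    The plane stack only samples Ixx(z) at ``n_planes`` stations, so the
    discrete minimum can sit up to half a spacing away from the true
    minimal section (e.g. a hole center falling between two planes).
    When ``refine`` is set, extra planes are placed between the two
    stations neighbouring the discrete minimum and the bracket is
    narrowed iteratively; plane normals follow the local centroid-line
    direction, as in the second slicing pass.

    Returns the (refined) critical section and the full station table.
    """
    oriented, _ = orient_plate(mesh)
    sections = [
        composite_properties(polys, z)
        for z, polys in slice_plate(oriented, config)
    ]
    idx, best = critical_section(sections)
    if not refine or idx in (0, len(sections) - 1):
        return best, sections

    tm = oriented.to_trimesh()
    lo = sections[idx - 1].station_z
    hi = sections[idx + 1].station_z
    z_axis = np.array([0.0, 0.0, 1.0])

    def _local_frame(z: float) -> tuple[np.ndarray, np.ndarray]:
        """Plane origin and normal at station z from nearby centroids."""
        span = max(hi - lo, 1e-9)
        pts = []
        for dz in (-span, 0.0, span):
            polys = _section_polylines(tm, np.array([0.0, 0.0, z + dz]), z_axis)
            if polys:
                pts.append(_composite_centroid_3d(polys, np.array([0.0, 0.0, z + dz]), z_axis))
        if len(pts) < 2:
            return np.array([0.0, 0.0, z]), z_axis
        direction = pts[-1] - pts[0]
        norm = np.linalg.norm(direction)
        origin = pts[len(pts) // 2]
        origin[2] = z
        return origin, direction / norm if norm > 0 else z_axis

    evaluated: dict[float, SectionProperties] = {best.station_z: best}
    for _ in range(refine_iters):
        candidates = np.linspace(lo, hi, refine_planes + 2)[1:-1]
        for z in candidates:
            if any(abs(z - seen) < 1e-12 for seen in evaluated):
                continue
            origin, normal = _local_frame(float(z))
            try:
                polys = _section_polylines(tm, origin, normal)
            except GeometryError:
                continue
            if polys:
                evaluated[float(z)] = composite_properties(polys, float(z))
        stations = sorted(evaluated)
        values = [evaluated[z].Ixx for z in stations]
        k = int(np.argmin(values))
        lo = stations[max(k - 1, 0)]
        hi = stations[min(k + 1, len(stations) - 1)]
        best = evaluated[stations[k]]
    return best, sections


def section_table(sections: Sequence[SectionProperties]) -> pd.DataFrame:
    """Per-section table ready to be written as delimited text."""
    return pd.DataFrame(
        {
            "station_z": [s.station_z for s in sections],
            "area": [s.area for s in sections],
            "centroid_x": [s.centroid[0] for s in sections],
            "centroid_y": [s.centroid[1] for s in sections],
            "Ixx": [s.Ixx for s in sections],
            "w": [s.w for s in sections],
            "t": [s.t for s in sections],
            "d": [s.d for s in sections],
            "n_polylines": [s.n_polylines for s in sections],
        }
    )


def critical_section_summary(sections: Sequence[SectionProperties]) -> dict:
    """JSON-ready summary of the critical section."""
    idx, crit = critical_section(sections)
    return {
        "index": idx,
        "station_z_mm": crit.station_z,
        "area_mm2": crit.area,
        "centroid_mm": list(crit.centroid),
        "Ixx_mm4": crit.Ixx,
        "w_mm": crit.w,
        "t_mm": crit.t,
        "d_mm": crit.d,
        "n_polylines": crit.n_polylines,
    }


def write_section_report(
    sections: Sequence[SectionProperties], table_path: str | Path, summary_path: str | Path
) -> None:
    section_table(sections).to_csv(table_path, sep="\t", index=False)
    Path(summary_path).write_text(
        json.dumps(critical_section_summary(sections), indent=2) + "\n"
    )
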