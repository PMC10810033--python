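"""Parametric plate fixtures with exact analytic section properties.

Plates are rectangular-section bars (width w along x, thickness t along
y, length L along z, all centered on the origin) with circular through
holes drilled along y, optionally bent to a constant curvature radius
about the x-axis.  Because the geometry is this simple, every section
property the mesh pipeline extracts has a closed form, which makes the
generator the oracle for the whole geometry stack.

The module also simulates staircase fatigue campaigns from a known true
Basquin curve: starting at 90% of the proof load and stepping down a
fixed fraction per failure until one million cycles are reached without
failure (repeated on three samples), with optional lognormal scatter of
the failure cycles and an optional yield cap that makes plastic-range
records deviate from the elastic stress formula the same way real
high-load tests do.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import trimesh

from .errors import GeometryError, PlateFatigueError
from .fatigue_model import BendingSetup, LoadLine, moment_from_load
from .mesh_geometry import SectionProperties, TriMesh
from .sn_prediction import SNCurve, cycles_at_stress
from .verification import ExperimentalRecord

__all__ = [
    "SyntheticPlateParams",
    "SyntheticCampaignParams",
    "generate_plate_mesh",
    "write_stl",
    "write_fixture",
    "analytic_properties",
    "analytic_critical",
    "loads_for_cycles",
    "records_from_loads",
    "simulate_campaign",
    "runout_load_from_records",
]


@dataclass
class SyntheticPlateParams:
    """Geometry of a synthetic plate (mm); hole centers in centered z."""

    length: float
    width: float
    thickness: float
    holes: list[tuple[float, float]] = field(default_factory=list)
    curvature_radius: float | None = None
    mesh_resolution: float = 0.5

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise GeometryError("length must be positive")
        if not (self.width > 0 and self.thickness > 0):
            raise GeometryError("width and thickness must be positive")
        if not self.mesh_resolution > 0:
            raise GeometryError("mesh_resolution must be positive")
        if self.curvature_radius is not None and not math.isfinite(self.curvature_radius):
            self.curvature_radius = None
        if self.curvature_radius is not None and self.curvature_radius <= self.length / math.pi:
            raise GeometryError("curvature radius too small for the plate length")
        self.holes = sorted((float(cz), float(d)) for cz, d in self.holes)
        half = self.length / 2.0
        prev_end = -half
        for cz, d in self.holes:
            if not 0 <= d < self.width:
                raise GeometryError("hole diameter must satisfy 0 <= d < w")
            if d > 0 and (cz - d / 2.0 <= prev_end or cz + d / 2.0 >= half):
                raise GeometryError("holes overlap each other or the plate ends")
            if d > 0:
                prev_end = cz + d / 2.0


# ---------------------------------------------------------------------------
# mesh construction


def _plain_band(
    xs: np.ndarray, z0: float, z1: float, res: float,
    verts: list, tris: list,
) -> None:
    nz = max(1, int(math.ceil((z1 - z0) / res)))
    zs = np.linspace(z0, z1, nz + 1)
    base = len(verts)
    nx = len(xs) - 1
    for z in zs:
        for x in xs:
            verts.append((x, z))
    stride = nx + 1
    for k in range(nz):
        for i in range(nx):
            a = base + k * stride + i
            b = a + 1
            c = a + stride
            d = c + 1
            tris.append((a, b, d))
            tris.append((a, d, c))


def _hole_band(
    xs: np.ndarray, z0: float, z1: float, cz: float, dia: float, res: float,
    verts: list, tris: list,
) -> None:
    """Radial O-grid between the hole circle and the band rectangle.

    The band's outer boundary is sampled exactly at the global x-grid on
    its bottom/top edges (so adjacent bands share vertices) and at the
    z-grid on the free side edges; each boundary point pairs with one
    circle point at the same polar angle, giving a structured quad strip
    with optional intermediate rings.
    """
    nzb = max(1, int(math.ceil((z1 - z0) / res)))
    zsb = np.linspace(z0, z1, nzb + 1)
    w2 = xs[-1]
    loop: list[tuple[float, float]] = []
    loop += [(x, z0) for x in xs[:-1]]
    loop += [(w2, z) for z in zsb[:-1]]
    loop += [(x, z1) for x in xs[::-1][:-1]]
    loop += [(-w2, z) for z in zsb[::-1][:-1]]
    outer = np.array(loop)
    angles = np.arctan2(outer[:, 1] - cz, outer[:, 0])
    k0 = int(np.argmin(angles))
    outer = np.roll(outer, -k0, axis=0)
    angles = np.roll(angles, -k0)
    r_in = dia / 2.0
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    center = np.array([0.0, cz])
    r_out = np.linalg.norm(outer - center, axis=1)
    nr = max(1, int(math.ceil(float(np.median(r_out - r_in)) / res)))
    m = len(outer)
    ring_index = np.empty((nr + 1, m), dtype=np.int64)
    for ell in range(nr + 1):
        frac = ell / nr
        for k in range(m):
            if ell == nr:
                pt = outer[k]  # exact boundary coordinates for vertex merging
            else:
                radius = r_in + (r_out[k] - r_in) * frac
                pt = center + radius * dirs[k]
            ring_index[ell, k] = len(verts)
            verts.append((float(pt[0]), float(pt[1])))
    for ell in range(nr):
        for k in range(m):
            k2 = (k + 1) % m
            a, b = ring_index[ell, k], ring_index[ell, k2]
            c, d = ring_index[ell + 1, k2], ring_index[ell + 1, k]
            tris.append((a, b, c))
            tris.append((a, c, d))


def _cap_triangulation(params: SyntheticPlateParams) -> tuple[np.ndarray, np.ndarray]:
    w, length, res = params.width, params.length, params.mesh_resolution
    half = length / 2.0
    nx = max(2, int(math.ceil(w / res)))
    xs = np.linspace(-w / 2.0, w / 2.0, nx + 1)
    # z-band layout: plain bands between hole bands
    edges: list[tuple[float, float, tuple[float, float] | None]] = []
    cursor = -half
    for cz, dia in params.holes:
        if dia == 0:
            continue
        margin = 0.2 * dia
        z0 = max(cz - dia / 2.0 - margin, cursor)
        z1 = min(cz + dia / 2.0 + margin, half)
        if z0 >= cz - dia / 2.0 or z1 <= cz + dia / 2.0:
            raise GeometryError("holes too close together for meshing")
        if z0 > cursor:
            edges.append((cursor, z0, None))
        edges.append((z0, z1, (cz, dia)))
        cursor = z1
    if cursor < half:
        edges.append((cursor, half, None))

    verts: list[tuple[float, float]] = []
    tris: list[tuple[int, int, int]] = []
    for z0, z1, hole in edges:
        if hole is None:
            _plain_band(xs, z0, z1, res, verts, tris)
        else:
            _hole_band(xs, z0, z1, hole[0], hole[1], res, verts, tris)
    return np.array(verts), np.array(tris, dtype=np.int64)


def _boundary_edges(tris: np.ndarray) -> np.ndarray:
    edges = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    _, inverse, counts = np.unique(key, axis=0, return_inverse=True,
                                   return_counts=True)
    return edges[counts[inverse] == 1]


def generate_plate_mesh(params: SyntheticPlateParams) -> TriMesh:
    """Build a watertight triangulated plate; deterministic for fixed params."""
    cap_xy, cap_tris = _cap_triangulation(params)
    # merge duplicate cap vertices at band interfaces (exact coordinates)
    _, first, inverse = np.unique(cap_xy, axis=0, return_index=True,
                                  return_inverse=True)
    cap_xy = cap_xy[np.sort(first)]
    remap = np.empty(len(first), dtype=np.int64)
    remap[np.argsort(first)] = np.arange(len(first))
    cap_tris = remap[inverse][cap_tris]

    n = len(cap_xy)
    t2 = params.thickness / 2.0
    top = np.column_stack([cap_xy[:, 0], np.full(n, t2), cap_xy[:, 1]])
    bot = np.column_stack([cap_xy[:, 0], np.full(n, -t2), cap_xy[:, 1]])
    vertices = np.vstack([top, bot])
    faces = [cap_tris, cap_tris[:, [0, 2, 1]] + n]
    walls = []
    for a, b in _boundary_edges(cap_tris):
        walls.append((a, b, b + n))
        walls.append((a, b + n, a + n))
    faces.append(np.array(walls, dtype=np.int64))
    faces = np.vstack(faces)

    if params.curvature_radius is not None:
        radius = params.curvature_radius
        phi = vertices[:, 2] / radius
        rho = radius + vertices[:, 1]
        vertices = np.column_stack(
            [vertices[:, 0], rho * np.cos(phi) - radius, rho * np.sin(phi)]
        )

    tm = trimesh.Trimesh(vertices=vertices, faces=faces, process=True)
    tm.fix_normals()
    if tm.volume < 0:
        tm.invert()
    watertight = bool(tm.is_watertight)
    if not watertight:
        warnings.warn("generated plate mesh is not watertight", UserWarning,
                      stacklevel=2)
    return TriMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces),
                   watertight=watertight)


def write_stl(mesh: TriMesh, path: str | Path, ascii_format: bool = False) -> None:
    """Export as binary (default) or ASCII STL."""
    tm = mesh.to_trimesh()
    if ascii_format:
        Path(path).write_text(
            trimesh.exchange.stl.export_stl_ascii(tm)
        )
    else:
        tm.export(str(path))


def write_fixture(params: SyntheticPlateParams, stl_path: str | Path,
                  json_path: str | Path | None = None) -> TriMesh:
    """Write an STL fixture plus a sidecar JSON of ground-truth parameters."""
    mesh = generate_plate_mesh(params)
    write_stl(mesh, stl_path)
    if json_path is None:
        json_path = Path(stl_path).with_suffix(".json")
    crit = analytic_critical(params)
    Path(json_path).write_text(json.dumps({
        "length_mm": params.length,
        "width_mm": params.width,
        "thickness_mm": params.thickness,
        "holes": [list(h) for h in params.holes],
        "curvature_radius_mm": params.curvature_radius,
        "mesh_resolution_mm": params.mesh_resolution,
        "n_vertices": int(len(mesh.vertices)),
        "n_triangles": int(len(mesh.faces)),
        "critical_section": {
            "station_z_mm": crit.station_z, "area_mm2": crit.area,
            "Ixx_mm4": crit.Ixx, "w_mm": crit.w, "t_mm": crit.t, "d_mm": crit.d,
        },
    }, indent=2) + "\n")
    return mesh


# ---------------------------------------------------------------------------
# analytic oracle


def _chord_at(params: SyntheticPlateParams, z: float) -> float:
    for cz, dia in params.holes:
        r = dia / 2.0
        if dia > 0 and abs(z - cz) < r:
            return 2.0 * math.sqrt(r * r - (z - cz) ** 2)
    return 0.0


def analytic_properties(params: SyntheticPlateParams, z: float) -> SectionProperties:
    """Closed-form section properties at centered station z.

    A hole removes the local chord c from the width but not from the
    lever arm, so area = (w - c) t and Ixx = (w - c) t^3 / 12 for
    bending about x.  The hole gap equals the chord.
    """
    if abs(z) > params.length / 2.0:
        raise GeometryError("station outside the plate")
    chord = _chord_at(params, z)
    w, t = params.width, params.thickness
    return SectionProperties(
        station_z=float(z),
        area=(w - chord) * t,
        centroid=(0.0, 0.0),
        Ixx=(w - chord) * t**3 / 12.0,
        w=w,
        t=t,
        d=float(chord),
        n_polylines=2 if chord > 0 else 1,
    )


def analytic_critical(params: SyntheticPlateParams) -> SectionProperties:
    """The true critical section: center of the largest hole, else mid-plate."""
    if any(d > 0 for _, d in params.holes):
        cz, _ = max(params.holes, key=lambda h: h[1])
        return analytic_properties(params, cz)
    return analytic_properties(params, 0.0)


# ---------------------------------------------------------------------------
# fatigue campaign simulation


@dataclass
class SyntheticCampaignParams:
    """Staircase fatigue campaign drawn from a known true S-N curve.

    The protocol starts at ``start_fraction`` (0.9) of the proof load
    and multiplies the load by (1 - decrement_fraction) after each
    failure until one million cycles are reached without failure; the
    runout is then repeated on three samples.  ``noise_sigma_log`` is
    the standard deviation of the natural-log cycle scatter.  An
    optional ``sigma_yield_cap`` caps the true driving stress at the
    yield strength, so loads in the plastic range fail later than the
    elastic stress formula suggests.
    """

    true_curve: SNCurve
    proof_load: float
    start_fraction: float = 0.9
    decrement_fraction: float = 0.1
    noise_sigma_log: float = 0.0
    seed: int = 0
    n_runout: float = 1_000_000
    n_runout_repeats: int = 3
    sigma_yield_cap: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.decrement_fraction < 1:
            raise PlateFatigueError("decrement_fraction must lie in (0, 1)")
        if not 0 < self.start_fraction <= 1:
            raise PlateFatigueError("start_fraction must lie in (0, 1]")
        if self.noise_sigma_log < 0:
            raise PlateFatigueError("noise_sigma_log must be >= 0")
        if not self.proof_load > 0:
            raise PlateFatigueError("proof_load must be positive")


def _sigma_a_from_load(
    load: float, section: SectionProperties, setup: BendingSetup,
    line: LoadLine, sigma_yield_cap: float | None,
) -> float:
    sigma_max = moment_from_load(load, setup) * (section.t / 2.0) / section.Ixx
    if sigma_yield_cap is not None:
        sigma_max = min(sigma_max, sigma_yield_cap)
    return sigma_max * line.ra / (1.0 + line.ra)


def loads_for_cycles(
    curve: SNCurve, section: SectionProperties, setup: BendingSetup,
    line: LoadLine, cycles: Sequence[float],
) -> np.ndarray:
    """Peak loads that put each cycle count exactly on the true curve."""
    out = []
    for n in cycles:
        sigma_a = curve.A * min(float(n), curve.n_g) ** curve.b
        sigma_max = sigma_a * (1.0 + 1.0 / line.ra)
        moment = sigma_max * section.Ixx / (section.t / 2.0)
        out.append(2.0 * moment / setup.loading_span_h)
    return np.array(out)


def records_from_loads(
    curve: SNCurve,
    section: SectionProperties,
    setup: BendingSetup,
    line: LoadLine,
    loads: Sequence[float],
    noise_sigma_log: float = 0.0,
    seed: int = 0,
    sigma_yield_cap: float | None = None,
    n_runout: float = 1_000_000,
    plate_id: str = "synthetic",
) -> list[ExperimentalRecord]:
    """One fatigue record per requested load, drawn from the true curve."""
    rng = np.random.default_rng(seed)
    records = []
    for load in loads:
        sigma_a = _sigma_a_from_load(load, section, setup, line, sigma_yield_cap)
        n_true = cycles_at_stress(curve, sigma_a)
        n_obs = n_true * rng.lognormal(0.0, noise_sigma_log)
        if n_obs >= n_runout:
            records.append(ExperimentalRecord(plate_id, float(load),
                                              float(n_runout), failed=False))
        else:
            records.append(ExperimentalRecord(plate_id, float(load),
                                              max(1.0, round(n_obs)), failed=True))
    return records


def simulate_campaign(
    section: SectionProperties,
    setup: BendingSetup,
    line: LoadLine,
    params: SyntheticCampaignParams,
    plate_id: str = "synthetic",
) -> list[ExperimentalRecord]:
    """Staircase campaign: step the load down until runout, then repeat 3x.

    Deterministic for a fixed seed.  Loads whose alternating stress
    exceeds the curve's low-cycle anchor produce plastic-range failures
    below 10^3 cycles and are flagged with a warning.
    """
    rng = np.random.default_rng(params.seed)
    curve = params.true_curve
    load = params.start_fraction * params.proof_load
    records: list[ExperimentalRecord] = []
    for _ in range(500):
        sigma_a = _sigma_a_from_load(load, section, setup, line,
                                     params.sigma_yield_cap)
        if sigma_a >= curve.sigma_f:
            warnings.warn(
                f"load {load:.0f} N drives the section above the low-cycle "
                "anchor; recording a plastic-range failure below 10^3 cycles",
                UserWarning,
                stacklevel=2,
            )
        n_true = cycles_at_stress(curve, sigma_a)
        n_obs = n_true * rng.lognormal(0.0, params.noise_sigma_log)
        if n_obs >= params.n_runout:
            for _ in range(params.n_runout_repeats):
                records.append(ExperimentalRecord(plate_id, float(load),
                                                  float(params.n_runout),
                                                  failed=False))
            return records
        records.append(ExperimentalRecord(plate_id, float(load),
                                          max(1.0, round(n_obs)), failed=True))
        load *= 1.0 - params.decrement_fraction
    raise PlateFatigueError("staircase did not reach runout in 500 levels")


def runout_load_from_records(records: Sequence[ExperimentalRecord]) -> float:
    """The experimentally identified runout load: highest surviving load."""
    runouts = [r.max_load for r in records if not r.failed]
    if not runouts:
        raise PlateFatigueError("campaign contains no runout records")
    return max(runouts)
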