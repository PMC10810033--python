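"""Shared fixtures: materials, load line, setup, synthetic plates."""

from __future__ import annotations

import numpy as np
import pytest

from platefatigue import fatigue_model as fm
from platefatigue import mesh_geometry as mg
from platefatigue import synthetic_plates as sp


@pytest.fixture(scope="session")
def titanium():
    """Pure-titanium material with a representative certificate strength."""
    return fm.MaterialSpec(sigma_uts=668.0, material_class="pure_titanium",
                           sigma_yield=480.0)


@pytest.fixture(scope="session")
def load_line():
    return fm.LoadLine.from_r(0.1)


@pytest.fixture(scope="session")
def bend_setup():
    return fm.BendingSetup(center_span_a=50.0, loading_span_h=40.0,
                           frequency=5.0, n_runout_cycles=1_000_000)


@pytest.fixture(scope="session")
def rect_section():
    """Plain 10 x 3 mm rectangular section (no hole)."""
    return mg.SectionProperties(station_z=0.0, area=30.0, centroid=(0.0, 0.0),
                                Ixx=22.5, w=10.0, t=3.0, d=0.0, n_polylines=1)


@pytest.fixture(scope="session")
def holed_params():
    return sp.SyntheticPlateParams(length=100.0, width=10.0, thickness=3.0,
                                   holes=[(0.0, 4.0)], mesh_resolution=0.5)


@pytest.fixture(scope="session")
def holed_mesh(holed_params):
    return sp.generate_plate_mesh(holed_params)


@pytest.fixture(scope="session")
def plain_params():
    return sp.SyntheticPlateParams(length=100.0, width=10.0, thickness=3.0,
                                   mesh_resolution=0.8)


@pytest.fixture(scope="session")
def plain_mesh(plain_params):
    return sp.generate_plate_mesh(plain_params)


def mc_polygon_moments(vertices: np.ndarray, n_samples: int = 1_000_000,
                       seed: int = 0):
    """Monte-Carlo point-in-polygon oracle for area, centroid and Ixx.

    Independent of the closed-form path: uniform sampling over the
    bounding box, membership via shapely, moments from sample averages.
    """
    import shapely
    from shapely.geometry import Polygon

    poly = Polygon(vertices)
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = poly.bounds
    xs = rng.uniform(xmin, xmax, n_samples)
    ys = rng.uniform(ymin, ymax, n_samples)
    inside = shapely.contains_xy(poly, xs, ys)
    frac = inside.mean()
    area = frac * (xmax - xmin) * (ymax - ymin)
    cx, cy = xs[inside].mean(), ys[inside].mean()
    ixx = area * np.mean((ys[inside] - cy) ** 2)
    return area, (cx, cy), ixx
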