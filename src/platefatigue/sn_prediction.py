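"""Basquin S-N curves per criterion and the M-N prediction band.

The stress-life curve for a constant-R test is built from two anchor
points: the low-cycle point F at 10^3 cycles, with amplitude
sigma_F = 0.9 sigma_UTS (1 - R) / 2, and the fatigue-limit point G at
N_G (10^6) cycles with the criterion's amplitude sigma_D.  Basquin's
power law sigma_a = A N^b is fitted exactly through F and G; beyond N_G
the curve is treated as a flat fatigue limit.  Both criteria share the
same F point, so the Goodman (lower) and Gerber (upper) curves open a
band that has zero width at 10^3 cycles and the runout band width at
N_G.  Moments follow the elastic formula M = sigma_max Ixx / (t/2) with
sigma_max = sigma_a + sigma_m = sigma_a (1 + 1/R_a).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ExtrapolationWarning, PlateFatigueError
from .fatigue_model import LoadLine, MaterialSpec
from .mesh_geometry import SectionProperties

__all__ = [
    "SNCurve",
    "MNBand",
    "low_cycle_anchor",
    "fit_basquin",
    "stress_at_cycles",
    "cycles_at_stress",
    "band_at_cycles",
    "mn_band",
    "sn_table",
    "mn_table",
]

N_F = 1_000.0  # cycles of the low-cycle anchor F


@dataclass(frozen=True)
class SNCurve:
    """Basquin curve sigma_a = A N^b anchored at F(10^3) and G(n_g)."""

    A: float
    b: float
    sigma_f: float
    sigma_g: float
    n_g: float
    r_ratio: float
    criterion: str

    def __post_init__(self) -> None:
        if self.b > 0:
            raise PlateFatigueError("Basquin exponent b must be <= 0")
        if self.sigma_f < self.sigma_g:
            raise PlateFatigueError("sigma_F must be >= sigma_G")
        for n, sigma in ((N_F, self.sigma_f), (self.n_g, self.sigma_g)):
            if abs(self.A * n**self.b - sigma) > 1e-9 * sigma:
                raise PlateFatigueError("curve does not pass through its anchors")


@dataclass(frozen=True)
class MNBand:
    """Moment-cycles prediction band (lower: Goodman, upper: Gerber)."""

    cycles: np.ndarray
    m_lower: np.ndarray
    m_upper: np.ndarray


def low_cycle_anchor(material: MaterialSpec, line: LoadLine) -> float:
    """Amplitude at 10^3 cycles: sigma_F = 0.9 sigma_UTS (1 - R) / 2."""
    return 0.9 * material.sigma_uts * (1.0 - line.r_ratio) / 2.0


def fit_basquin(
    material: MaterialSpec,
    line: LoadLine,
    sigma_d: float,
    n_g: float = 1_000_000,
    criterion: str = "goodman",
) -> SNCurve:
    """Two-point Basquin fit through F(10^3, sigma_F) and G(n_g, sigma_D).

    b = log(sigma_D / sigma_F) / log(n_g / 10^3) and A = sigma_F / (10^3)^b,
    so the curve passes through both anchors exactly.  sigma_D above
    sigma_F signals inconsistent inputs (a rising curve) and is an
    error; equality gives a flat curve with a warning.
    """
    if not sigma_d > 0:
        raise PlateFatigueError("sigma_d must be positive")
    if not n_g > N_F:
        raise PlateFatigueError("n_g must exceed 10^3 cycles")
    sigma_f = low_cycle_anchor(material, line)
    if sigma_d > sigma_f:
        raise PlateFatigueError(
            f"sigma_D ({sigma_d:.1f} MPa) exceeds the low-cycle anchor "
            f"sigma_F ({sigma_f:.1f} MPa); the S-N curve would rise"
        )
    if sigma_d == sigma_f:
        warnings.warn("sigma_D equals sigma_F: flat S-N curve (b = 0)",
                      ExtrapolationWarning, stacklevel=2)
        b = 0.0
    else:
        b = math.log(sigma_d / sigma_f) / math.log(n_g / N_F)
    a = sigma_f / N_F**b
    return SNCurve(A=float(a), b=float(b), sigma_f=float(sigma_f),
                   sigma_g=float(sigma_d), n_g=float(n_g),
                   r_ratio=line.r_ratio, criterion=criterion)


def stress_at_cycles(curve: SNCurve, n):
    """Alternating stress sigma_a = A N^b, clamped flat beyond runout.

    Cycle counts above ``n_g`` return the fatigue limit sigma_G
    (infinite-life plateau); counts below 10^3 are evaluated by the
    power law but flagged as extrapolation outside the estimated
    region.  Accepts scalars or arrays.
    """
    arr = np.asarray(n, dtype=float)
    if np.any(arr < 1):
        raise PlateFatigueError("cycle counts must be >= 1")
    if np.any(arr < N_F):
        warnings.warn("evaluating the S-N curve below 10^3 cycles "
                      "(outside the estimated region)",
                      ExtrapolationWarning, stacklevel=2)
    if np.any(arr > curve.n_g):
        warnings.warn("cycle count beyond runout; returning the flat "
                      "fatigue limit", ExtrapolationWarning, stacklevel=2)
    sigma = curve.A * np.minimum(arr, curve.n_g) ** curve.b
    return float(sigma) if np.isscalar(n) or arr.ndim == 0 else sigma


def cycles_at_stress(curve: SNCurve, sigma_a: float) -> float:
    """Inverse Basquin: N = (sigma_a / A)^(1/b)."""
    if curve.b == 0:
        raise PlateFatigueError("flat curve has no unique cycle count")
    if not sigma_a > 0:
        raise PlateFatigueError("sigma_a must be positive")
    return float((sigma_a / curve.A) ** (1.0 / curve.b))


def _moment_from_sigma_a(sigma_a, line: LoadLine, section: SectionProperties):
    sigma_m = sigma_a / line.ra
    sigma_max = sigma_a + sigma_m
    return sigma_max * section.Ixx / (section.t / 2.0)


def band_at_cycles(
    goodman: SNCurve,
    gerber: SNCurve,
    n,
    line: LoadLine,
    section: SectionProperties,
):
    """Predicted moment band (M_goodman, M_gerber) at cycle count(s) n.

    Both curves must share the F point; per criterion the S-N amplitude
    is converted back through the load line (sigma_m = sigma_a / R_a,
    sigma_max = sigma_a + sigma_m) and the elastic bending formula.
    """
    if abs(goodman.sigma_f - gerber.sigma_f) > 1e-9 * goodman.sigma_f:
        raise PlateFatigueError("curves do not share the same F point")
    m_low = _moment_from_sigma_a(stress_at_cycles(goodman, n), line, section)
    m_high = _moment_from_sigma_a(stress_at_cycles(gerber, n), line, section)
    return m_low, m_high


def mn_band(
    goodman: SNCurve,
    gerber: SNCurve,
    line: LoadLine,
    section: SectionProperties,
    points_per_decade: int = 50,
) -> MNBand:
    """Tabulated M-N band on a log-spaced cycle grid from 10^3 to n_g."""
    decades = math.log10(goodman.n_g / N_F)
    n_pts = max(2, int(round(points_per_decade * decades)) + 1)
    cycles = np.logspace(math.log10(N_F), math.log10(goodman.n_g), n_pts)
    m_low, m_high = band_at_cycles(goodman, gerber, cycles, line, section)
    return MNBand(cycles=cycles, m_lower=np.asarray(m_low), m_upper=np.asarray(m_high))


def sn_table(goodman: SNCurve, gerber: SNCurve, points_per_decade: int = 50) -> pd.DataFrame:
    """Plot-ready S-N table (cycles, sigma_a per criterion)."""
    decades = math.log10(goodman.n_g / N_F)
    n_pts = max(2, int(round(points_per_decade * decades)) + 1)
    cycles = np.logspace(math.log10(N_F), math.log10(goodman.n_g), n_pts)
    return pd.DataFrame(
        {
            "cycles": cycles,
            "sigma_a_goodman": stress_at_cycles(goodman, cycles),
            "sigma_a_gerber": stress_at_cycles(gerber, cycles),
        }
    )


def mn_table(band: MNBand) -> pd.DataFrame:
    return pd.DataFrame(
        {"cycles": band.cycles, "m_goodman": band.m_lower, "m_gerber": band.m_upper}
    )
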