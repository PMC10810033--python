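"""Notch-corrected fatigue limits and the Goodman/Gerber runout band.

From the raw-material ultimate tensile strength and the critical
cross-section, this module walks the classical stress-life chain:

1. theoretical stress concentration K_t for transverse bending of a
   finite-width plate with a circular hole (encoded Peterson-style
   chart, bilinear interpolation);
2. fatigue notch factor K_f = 1 + q (K_t - 1), with the Neuber
   notch-sensitivity q = 1 / (1 + sqrt(rho/r)) for steels and the
   conservative q = 1 for titanium;
3. specimen fatigue limit sigma*_D-1 = 0.5 sigma_UTS, scaled by the
   correction product prod(C_i) / K_f to the component fully-reversed
   limit sigma_D-1;
4. intersection of the R-ratio load line sigma_a = R_a sigma_m with the
   Goodman line (lower bound) and the Gerber parabola (upper bound) on
   the Haigh diagram, giving sigma_m, sigma_a = sigma_D and
   sigma_max = sigma_D + sigma_m;
5. the maximum (runout) bending moment M = sigma_max * Ixx / (t/2), and
   the runout load L = 2 M / h for a four-point-bending loading span h.

All stresses in MPa, lengths in mm, moments in N*mm, loads in N.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Literal

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import ChartDomainWarning, MaterialError, PlateFatigueError
from .mesh_geometry import SectionProperties

__all__ = [
    "MaterialSpec",
    "NotchModel",
    "FatigueLimits",
    "LoadLine",
    "MeanStressSolution",
    "MomentPrediction",
    "BendingSetup",
    "peterson_kt",
    "notch_factor",
    "component_fatigue_limit",
    "mean_stress_solution",
    "runout_moment_band",
    "moment_from_load",
    "load_from_moment",
    "predict_runout",
]

MaterialClass = Literal["steel", "titanium_alloy", "pure_titanium"]

#: ratio of the specimen fatigue limit to the ultimate tensile strength
SPECIMEN_FATIGUE_RATIO = 0.5


@dataclass
class MaterialSpec:
    """Raw-material record from the plate certification.

    ``grain_size_rho`` (mm) is the Neuber material constant needed for
    the steel notch-sensitivity; it is not part of a standard material
    certificate and must be supplied by the user for steels with holes.
    """

    sigma_uts: float
    material_class: MaterialClass
    grain_size_rho: float | None = None
    sigma_yield: float | None = None
    surface_roughness: float | None = None

    def __post_init__(self) -> None:
        if not self.sigma_uts > 0:
            raise MaterialError("sigma_uts must be positive")
        if self.material_class not in ("steel", "titanium_alloy", "pure_titanium"):
            raise MaterialError(f"unknown material class {self.material_class!r}")
        if self.sigma_yield is not None and not 0 < self.sigma_yield < self.sigma_uts:
            raise MaterialError("sigma_yield must lie in (0, sigma_uts)")
        if self.grain_size_rho is not None and self.grain_size_rho < 0:
            raise MaterialError("grain_size_rho must be non-negative")


@dataclass(frozen=True)
class NotchModel:
    """K_t, notch sensitivity q and the resulting K_f = 1 + q(K_t - 1)."""

    kt: float
    q: float
    kf: float
    notch_radius_r: float

    def __post_init__(self) -> None:
        if self.kt < 1:
            raise PlateFatigueError("kt must be >= 1")
        if not 0 <= self.q <= 1:
            raise PlateFatigueError("q must lie in [0, 1]")
        if abs(self.kf - (1 + self.q * (self.kt - 1))) > 1e-12 * max(self.kf, 1.0):
            raise PlateFatigueError("kf must equal 1 + q (kt - 1)")


@dataclass(frozen=True)
class FatigueLimits:
    """Specimen and component fully-reversed fatigue limits (MPa)."""

    sigma_d_star: float
    prod_c: float
    sigma_d_minus1: float
    components: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (C_S, C_F, C_L)


@dataclass(frozen=True)
class LoadLine:
    """Constant-R load line on the Haigh diagram: sigma_a = R_a sigma_m."""

    r_ratio: float
    ra: float

    @classmethod
    def from_r(cls, r_ratio: float, paper_rounding: bool = False) -> "LoadLine":
        """R_a = (1 - R) / (1 + R); R = -1 is the fully-reversed limit.

        ``paper_rounding`` truncates R_a to two decimals (0.82 at
        R = 0.1) for comparison against hand calculations carried at
        that precision.
        """
        if not -1 <= r_ratio < 1:
            raise PlateFatigueError("r_ratio must lie in [-1, 1)")
        if r_ratio == -1:
            return cls(r_ratio=-1.0, ra=math.inf)
        ra = (1 - r_ratio) / (1 + r_ratio)
        if paper_rounding:
            ra = round(ra, 2)
        return cls(r_ratio=float(r_ratio), ra=float(ra))


@dataclass(frozen=True)
class MeanStressSolution:
    """Haigh-diagram intersection for one failure criterion (MPa)."""

    criterion: Literal["goodman", "gerber"]
    sigma_m: float
    sigma_a: float
    sigma_d: float
    sigma_max: float


@dataclass(frozen=True)
class BendingSetup:
    """Four-point-bending geometry and fatigue protocol parameters."""

    center_span_a: float
    loading_span_h: float
    frequency: float = 5.0
    n_runout_cycles: float = 1_000_000

    def __post_init__(self) -> None:
        if not (self.center_span_a > 0 and self.loading_span_h > 0):
            raise PlateFatigueError("spans must be positive")
        if not self.frequency > 0:
            raise PlateFatigueError("frequency must be positive")


@dataclass(frozen=True)
class MomentPrediction:
    """Predicted runout bending-moment band (N*mm) and load band (N)."""

    m_goodman: float
    m_gerber: float
    sigma_max_goodman: float
    sigma_max_gerber: float
    section: SectionProperties
    load_goodman: float | None = None
    load_gerber: float | None = None


# ---------------------------------------------------------------------------
# Peterson chart

_CHART_CACHE: dict[str, object] = {}


def _load_chart() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if "grid" not in _CHART_CACHE:
        text = (
            resources.files("platefatigue")
            .joinpath("data/peterson_transverse_bending.csv")
            .read_text()
        )
        rows = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
        dts = np.array([float(v) for v in rows[0].split(",")[1:]])
        dws, values = [], []
        for ln in rows[1:]:
            parts = [float(v) for v in ln.split(",")]
            dws.append(parts[0])
            values.append(parts[1:])
        _CHART_CACHE["grid"] = (np.array(dws), dts, np.array(values))
    return _CHART_CACHE["grid"]  # type: ignore[return-value]


def peterson_kt(d: float, w: float, t: float) -> float:
    """Theoretical K_t for a circular hole in transverse plate bending.

    Bilinear interpolation on the encoded chart over (d/w, d/t).  A
    section without a hole (d = 0) has no concentration: K_t = 1
    exactly.  Queries outside the chart domain are clamped to the
    nearest boundary with a :class:`ChartDomainWarning`.
    """
    if d < 0:
        raise PlateFatigueError("hole diameter d must be non-negative")
    if d == 0:
        return 1.0
    if d >= w:
        raise PlateFatigueError("hole diameter d must be smaller than width w")
    if not t > 0:
        raise PlateFatigueError("thickness t must be positive")
    dws, dts, values = _load_chart()
    dw, dt = d / w, d / t
    cdw = float(np.clip(dw, dws[0], dws[-1]))
    cdt = float(np.clip(dt, dts[0], dts[-1]))
    if cdw != dw or cdt != dt:
        warnings.warn(
            f"(d/w, d/t) = ({dw:.3f}, {dt:.3f}) outside the encoded chart; "
            "clamped to the grid boundary",
            ChartDomainWarning,
            stacklevel=2,
        )
    interp = RegularGridInterpolator((dws, dts), values, method="linear")
    return float(interp([[cdw, cdt]])[0])


def notch_factor(kt: float, material: MaterialSpec, r: float) -> NotchModel:
    """Fatigue notch factor via the notch-sensitivity index q.

    Steels use Neuber's q = 1 / (1 + sqrt(rho / r)) with the average
    grain size rho; titanium (alloyed or pure) is treated conservatively
    with q = 1 so K_f = K_t.
    """
    if kt < 1:
        raise PlateFatigueError("kt must be >= 1")
    if kt > 1 and not r > 0:
        raise PlateFatigueError("a notched section (kt > 1) needs a radius r > 0")
    if material.material_class == "steel":
        rho = material.grain_size_rho
        if rho is None:
            raise MaterialError(
                "steel notch sensitivity needs the average grain size rho "
                "(MaterialSpec.grain_size_rho, mm); it is not part of the "
                "material certificate and must be supplied"
            )
        if rho == 0 or kt == 1:
            q = 1.0
        else:
            q = 1.0 / (1.0 + math.sqrt(rho) / math.sqrt(r))
    else:
        q = 1.0
    kf = 1.0 + q * (kt - 1.0)
    return NotchModel(kt=float(kt), q=float(q), kf=float(kf),
                      notch_radius_r=float(r))


def component_fatigue_limit(
    material: MaterialSpec,
    notch: NotchModel,
    prod_c: float = 1.0,
    components: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> FatigueLimits:
    """sigma*_D-1 = 0.5 sigma_UTS; sigma_D-1 = sigma*_D-1 prod(C_i) / K_f.

    ``components`` records the individual size / surface-finish /
    loading-mode factors (C_S, C_F, C_L); ``prod_c`` is their product
    and defaults to 1 (no surface correction, 50% reliability).
    """
    if not prod_c > 0:
        raise PlateFatigueError("prod_c must be positive")
    sigma_d_star = SPECIMEN_FATIGUE_RATIO * material.sigma_uts
    sigma_d_minus1 = sigma_d_star * prod_c / notch.kf
    return FatigueLimits(
        sigma_d_star=float(sigma_d_star),
        prod_c=float(prod_c),
        sigma_d_minus1=float(sigma_d_minus1),
        components=components,
    )


def _criterion_residual(
    criterion: str, sigma_m: float, sigma_a: float, uts: float, sigma_d1: float
) -> float:
    if criterion == "goodman":
        return sigma_m / uts + sigma_a / sigma_d1
    return (sigma_m / uts) ** 2 + sigma_a / sigma_d1


def mean_stress_solution(
    limits: FatigueLimits,
    material: MaterialSpec,
    line: LoadLine,
    criterion: Literal["goodman", "gerber"],
) -> MeanStressSolution:
    """Intersect the load line with the Goodman line or Gerber parabola.

    Closed forms for sigma_m at sigma_a = R_a sigma_m:

    * Goodman: sigma_m = sigma_D-1 / (R_a + sigma_D-1 / sigma_UTS)
    * Gerber:  sigma_m = [-R_a + sqrt(R_a^2 + 4 sigma_D-1^2 / sigma_UTS^2)]
               / (2 sigma_D-1 / sigma_UTS^2)

    The fatigue limit under testing conditions is sigma_D = sigma_a and
    sigma_max = sigma_D + sigma_m.  The returned pair satisfies the
    criterion equation to 1e-9 relative (verified internally).
    """
    if criterion not in ("goodman", "gerber"):
        raise PlateFatigueError(f"unknown criterion {criterion!r}")
    sigma_d1 = limits.sigma_d_minus1
    if not sigma_d1 > 0:
        raise PlateFatigueError("sigma_D-1 must be positive")
    uts = material.sigma_uts
    if line.r_ratio == -1 or math.isinf(line.ra):
        # fully-reversed limit: zero mean stress on either criterion
        return MeanStressSolution(criterion=criterion, sigma_m=0.0,
                                  sigma_a=sigma_d1, sigma_d=sigma_d1,
                                  sigma_max=sigma_d1)
    ra = line.ra
    if criterion == "goodman":
        sigma_m = sigma_d1 / (ra + sigma_d1 / uts)
    else:
        sigma_m = (-ra + math.sqrt(ra * ra + 4.0 * sigma_d1**2 / uts**2)) / (
            2.0 * sigma_d1 / uts**2
        )
    sigma_a = ra * sigma_m
    residual = _criterion_residual(criterion, sigma_m, sigma_a, uts, sigma_d1)
    if abs(residual - 1.0) > 1e-9:
        raise PlateFatigueError(
            f"{criterion} intersection failed to satisfy its criterion "
            f"(residual {residual!r})"
        )
    return MeanStressSolution(
        criterion=criterion,
        sigma_m=float(sigma_m),
        sigma_a=float(sigma_a),
        sigma_d=float(sigma_a),
        sigma_max=float(sigma_a + sigma_m),
    )


def moment_from_load(load: float, setup: BendingSetup) -> float:
    """Four-point-bending moment M = L h / 2 (N*mm) from the peak load."""
    if load < 0:
        raise PlateFatigueError("load must be non-negative")
    return load * setup.loading_span_h / 2.0


def load_from_moment(moment: float, setup: BendingSetup) -> float:
    """Inverse of :func:`moment_from_load`: L = 2 M / h."""
    return 2.0 * moment / setup.loading_span_h


def runout_moment_band(
    goodman: MeanStressSolution,
    gerber: MeanStressSolution,
    section: SectionProperties,
    setup: BendingSetup | None = None,
) -> MomentPrediction:
    """Runout moment band M = sigma_max Ixx / (t/2) per criterion.

    Goodman is the conservative lower limit, Gerber the upper limit of
    the predicted range.  When the loading span is known the band is
    also expressed as peak loads L = 2 M / h.
    """
    if goodman.criterion != "goodman" or gerber.criterion != "gerber":
        raise PlateFatigueError("pass the goodman and gerber solutions in order")
    lever = section.t / 2.0
    m_good = goodman.sigma_max * section.Ixx / lever
    m_gerb = gerber.sigma_max * section.Ixx / lever
    load_good = load_from_moment(m_good, setup) if setup else None
    load_gerb = load_from_moment(m_gerb, setup) if setup else None
    return MomentPrediction(
        m_goodman=float(m_good),
        m_gerber=float(m_gerb),
        sigma_max_goodman=goodman.sigma_max,
        sigma_max_gerber=gerber.sigma_max,
        section=section,
        load_goodman=load_good,
        load_gerber=load_gerb,
    )


def predict_runout(
    section: SectionProperties,
    material: MaterialSpec,
    line: LoadLine,
    setup: BendingSetup | None = None,
    prod_c: float = 1.0,
) -> tuple[NotchModel, FatigueLimits, MeanStressSolution, MeanStressSolution, MomentPrediction]:
    """Chain the whole fatigue model for one critical section.

    The notch radius for the Neuber sensitivity is the hole radius
    r = d/2 (the only radius the geometry extraction provides).
    """
    kt = peterson_kt(section.d, section.w, section.t)
    notch = notch_factor(kt, material, r=section.d / 2.0 if section.d > 0 else 1.0)
    limits = component_fatigue_limit(material, notch, prod_c=prod_c)
    sol_good = mean_stress_solution(limits, material, line, "goodman")
    sol_gerb = mean_stress_solution(limits, material, line, "gerber")
    band = runout_moment_band(sol_good, sol_gerb, section, setup)
    return notch, limits, sol_good, sol_gerb, band
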