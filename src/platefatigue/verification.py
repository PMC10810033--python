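"""Verification of predicted bending moments against fatigue records.

Experimental records (peak load, cycles, failure flag) are converted to
bending moments via M = L h / 2, paired with the model's predicted
moment at the same cycle count, categorized into plastic / elastic /
runout intervals, and scored per criterion with the coefficient of
determination computed about the 45-degree identity line:

    R^2 = 1 - sum (pred_i - exp_i)^2 / sum (exp_i - mean(exp))^2

R^2 = 1 means every prediction equals its experimental moment; values
can be negative when predictions are worse than the experimental mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import PlateFatigueError
from .fatigue_model import BendingSetup, LoadLine, moment_from_load
from .mesh_geometry import SectionProperties
from .sn_prediction import N_F, SNCurve, band_at_cycles

__all__ = [
    "ExperimentalRecord",
    "PlateCase",
    "VerificationReport",
    "read_records",
    "write_records",
    "categorize_records",
    "predicted_pairs",
    "lls_r2",
    "campaign_hours",
    "hours_saved",
    "verification_report",
]

Interval = Literal["plastic", "elastic", "runout"]
INTERVALS: tuple[Interval, ...] = ("plastic", "elastic", "runout")
CRITERIA = ("goodman", "gerber")


@dataclass(frozen=True)
class ExperimentalRecord:
    """One fatigue test: peak load (N), cycles, and the failure flag."""

    plate_id: str
    max_load: float
    cycles: float
    failed: bool

    def __post_init__(self) -> None:
        if not self.max_load > 0:
            raise PlateFatigueError("max_load must be positive")
        if not self.cycles >= 1:
            raise PlateFatigueError("cycles must be >= 1")


@dataclass
class PlateCase:
    """Everything needed to verify one plate's records."""

    plate_id: str
    records: list[ExperimentalRecord]
    goodman: SNCurve
    gerber: SNCurve
    section: SectionProperties
    setup: BendingSetup
    sigma_yield: float | None = None


@dataclass
class VerificationReport:
    """Per-record comparison rows and the 2x3 criterion-interval R^2 table."""

    rows: pd.DataFrame
    r2: dict[str, dict[str, float]]
    n_skipped: int = 0

    def to_json_dict(self) -> dict:
        return {
            "r2": self.r2,
            "n_skipped_records": self.n_skipped,
            "records": self.rows.to_dict(orient="records"),
        }


def read_records(path: str | Path) -> tuple[list[ExperimentalRecord], int]:
    """Parse delimited records (header plate_id,max_load_n,cycles,failed).

    Malformed rows are skipped with a warning; returns the records and
    the skipped-row count.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise PlateFatigueError(f"records file missing or empty: {path}")
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"plate_id", "max_load_n", "cycles", "failed"}
    if not required.issubset(df.columns):
        raise PlateFatigueError(
            f"records file must have columns {sorted(required)}; got {list(df.columns)}"
        )
    records: list[ExperimentalRecord] = []
    skipped = 0
    for _, row in df.iterrows():
        try:
            failed = row["failed"]
            if isinstance(failed, str):
                failed = failed.strip().lower() in ("true", "1", "yes")
            records.append(
                ExperimentalRecord(
                    plate_id=str(row["plate_id"]),
                    max_load=float(row["max_load_n"]),
                    cycles=float(row["cycles"]),
                    failed=bool(failed),
                )
            )
        except (PlateFatigueError, TypeError, ValueError):
            skipped += 1
            warnings.warn(f"skipping malformed record row: {row.to_dict()}",
                          UserWarning, stacklevel=2)
    if not records:
        raise PlateFatigueError(f"no valid records in {path}")
    return records, skipped


def write_records(records: Sequence[ExperimentalRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "plate_id": [r.plate_id for r in records],
            "max_load_n": [r.max_load for r in records],
            "cycles": [int(r.cycles) for r in records],
            "failed": [r.failed for r in records],
        }
    ).to_csv(path, index=False)


def categorize_records(
    records: Sequence[ExperimentalRecord],
    sigma_yield: float | None,
    section: SectionProperties,
    setup: BendingSetup,
    line: LoadLine,
    n_runout: float = 1_000_000,
) -> list[Interval]:
    """Label each record plastic, elastic or runout.

    Runout: reached ``n_runout`` cycles without failing.  Otherwise the
    elastic peak stress sigma = M (t/2) / Ixx decides: above the yield
    strength the test ran in the plastic range.  The yield strength is
    a required user input whenever non-runout records are present.
    """
    labels: list[Interval] = []
    for rec in records:
        if rec.cycles >= n_runout and not rec.failed:
            labels.append("runout")
            continue
        if sigma_yield is None:
            raise PlateFatigueError(
                "sigma_yield is required to split non-runout records into "
                "plastic and elastic intervals"
            )
        moment = moment_from_load(rec.max_load, setup)
        sigma = moment * (section.t / 2.0) / section.Ixx
        labels.append("plastic" if sigma > sigma_yield else "elastic")
    return labels


def predicted_pairs(
    records: Sequence[ExperimentalRecord],
    goodman: SNCurve,
    gerber: SNCurve,
    section: SectionProperties,
    setup: BendingSetup,
    line: LoadLine,
) -> pd.DataFrame:
    """Experimental vs predicted moments at each record's cycle count.

    Runout records are evaluated at the curve's N_G; records below 10^3
    cycles fall outside the estimated S-N region and are excluded with
    a warning (flagged in the returned frame).
    """
    rows = []
    for rec in records:
        m_exp = moment_from_load(rec.max_load, setup)
        is_runout = rec.cycles >= goodman.n_g and not rec.failed
        n_eval = goodman.n_g if is_runout else rec.cycles
        if n_eval < N_F:
            warnings.warn(
                f"record at {rec.cycles:.0f} cycles is below 10^3; excluded "
                "from the verification R^2",
                UserWarning,
                stacklevel=2,
            )
            rows.append(
                dict(plate_id=rec.plate_id, cycles=rec.cycles, m_exp=m_exp,
                     m_goodman=np.nan, m_gerber=np.nan, excluded=True)
            )
            continue
        m_low, m_high = band_at_cycles(goodman, gerber, n_eval, line, section)
        rows.append(
            dict(plate_id=rec.plate_id, cycles=rec.cycles, m_exp=m_exp,
                 m_goodman=float(m_low), m_gerber=float(m_high), excluded=False)
        )
    return pd.DataFrame(rows)


def lls_r2(predicted: Sequence[float], experimental: Sequence[float]) -> float:
    """Coefficient of determination about the 45-degree identity line."""
    pred = np.asarray(predicted, dtype=float)
    exp = np.asarray(experimental, dtype=float)
    if pred.shape != exp.shape or pred.ndim != 1 or len(pred) < 2:
        raise PlateFatigueError("need two equal-length vectors of >= 2 moments")
    ss_tot = float(np.sum((exp - exp.mean()) ** 2))
    if ss_tot == 0.0:
        raise PlateFatigueError(
            "all experimental moments are identical; R^2 about the 45-degree "
            "line is undefined"
        )
    ss_res = float(np.sum((pred - exp) ** 2))
    return 1.0 - ss_res / ss_tot


def campaign_hours(n_tests: int, cycles_per_test: float, frequency: float) -> float:
    """Wall-clock hours of a fatigue campaign: n * N / f / 3600."""
    if n_tests <= 0 or cycles_per_test <= 0 or frequency <= 0:
        raise PlateFatigueError("campaign parameters must be positive")
    return n_tests * cycles_per_test / frequency / 3600.0


def hours_saved(
    planned_loads: Sequence[float],
    gerber_upper_load: float,
    cycles_per_test: float,
    frequency: float,
) -> tuple[float, int]:
    """Hours (and tests) avoidable by skipping loads above the Gerber band."""
    excluded = sum(1 for load in planned_loads if load > gerber_upper_load)
    if excluded == 0:
        return 0.0, 0
    return campaign_hours(excluded, cycles_per_test, frequency), excluded


def verification_report(
    cases: Sequence[PlateCase],
    line: LoadLine,
    n_runout: float = 1_000_000,
) -> VerificationReport:
    """Pool plates and build the per-record table plus the 2x3 R^2 table.

    Intervals are scored across all plates (as in a multi-plate
    campaign); an interval with fewer than two usable records, or with
    identical experimental moments, gets NaN with a warning.
    """
    frames = []
    for case in cases:
        pairs = predicted_pairs(case.records, case.goodman, case.gerber,
                                case.section, case.setup, line)
        labels = categorize_records(case.records, case.sigma_yield,
                                    case.section, case.setup, line, n_runout)
        pairs["interval"] = labels
        frames.append(pairs)
    rows = pd.concat(frames, ignore_index=True)
    usable = rows[~rows["excluded"]]
    r2: dict[str, dict[str, float]] = {c: {} for c in CRITERIA}
    for criterion in CRITERIA:
        for interval in INTERVALS:
            sub = usable[usable["interval"] == interval]
            try:
                r2[criterion][interval] = lls_r2(
                    sub[f"m_{criterion}"].to_numpy(), sub["m_exp"].to_numpy()
                )
            except PlateFatigueError:
                warnings.warn(
                    f"R^2 undefined for {criterion}/{interval} "
                    f"({len(sub)} usable records)",
                    UserWarning,
                    stacklevel=2,
                )
                r2[criterion][interval] = float("nan")
    return VerificationReport(rows=rows, r2=r2,
                              n_skipped=int(rows["excluded"].sum()))
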