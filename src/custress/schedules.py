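"""Stressor delivery schedules and dose-day (area-under-curve) accounting.

A treatment arm is described by the copper concentration prevailing in the
growth medium on each day of the treatment phase. Days are 1-based and each
concentration is held for exactly one day after that day's addition, so the
discrete area under the concentration-time curve is simply the sum of the
daily concentrations ("dose-days", mM*day).

The canonical experiment pairs a linear ramp over 9 days with a single step
to the final concentration on day 5. Under the daily-sum convention both
arms deliver exactly the same dose-days (5.0 mM*day at a 1 mM endpoint) and
reach the same final concentration, so they differ only in the *rate* of
stressor delivery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import IncompatibleScheduleError, InvalidParameterError

TREATMENT_LABELS = ("control", "gradual", "abrupt")

__all__ = [
    "TREATMENT_LABELS",
    "TreatmentSchedule",
    "DoseDays",
    "EquivalenceReport",
    "build_control_schedule",
    "build_gradual_schedule",
    "build_abrupt_schedule",
    "dose_days",
    "dose_days_from_conc",
    "check_equivalence",
    "read_schedule",
    "write_schedule",
]


@dataclass(frozen=True)
class TreatmentSchedule:
    """Daily stressor concentration trajectory for one treatment arm.

    Attributes
    ----------
    label:
        One of ``control``, ``gradual``, ``abrupt``.
    conc:
        Concentration (mM) prevailing during each 1-based day of the
        treatment phase; ``conc[i-1]`` is held for the whole of day ``i``.
    """

    label: str
    conc: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.label not in TREATMENT_LABELS:
            raise InvalidParameterError(
                f"schedule label must be one of {TREATMENT_LABELS}, got {self.label!r}"
            )
        conc = tuple(float(c) for c in self.conc)
        object.__setattr__(self, "conc", conc)
        if len(conc) < 1:
            raise InvalidParameterError("schedule must span at least one day")
        if any(c < 0 for c in conc):
            raise InvalidParameterError("concentrations must be non-negative")
        if any(b < a for a, b in zip(conc, conc[1:])):
            raise InvalidParameterError(
                "concentrations must be non-decreasing (copper is only added)"
            )
        if self.label == "control" and any(c != 0.0 for c in conc):
            raise InvalidParameterError("control schedule must be all zeros")

    @property
    def n_days(self) -> int:
        return len(self.conc)

    @property
    def final_conc(self) -> float:
        return self.conc[-1]


@dataclass(frozen=True)
class DoseDays:
    """Discrete area under a concentration-time schedule, in mM*day."""

    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise InvalidParameterError("dose-days cannot be negative")


@dataclass(frozen=True)
class EquivalenceReport:
    """Outcome of auditing two schedules for dose-day equivalence."""

    dose_days_a: float
    dose_days_b: float
    final_a: float
    final_b: float
    dose_days_equal: bool
    final_equal: bool

    @property
    def equivalent(self) -> bool:
        return self.dose_days_equal and self.final_equal


def build_control_schedule(n_days: int) -> TreatmentSchedule:
    """Zero-copper schedule spanning ``n_days`` (daily nutrient-only additions)."""
    if n_days < 1:
        raise InvalidParameterError(f"n_days must be >= 1, got {n_days}")
    return TreatmentSchedule("control", (0.0,) * int(n_days))


def build_gradual_schedule(final_conc: float, n_days: int) -> TreatmentSchedule:
    """Linear daily ramp reaching ``final_conc`` on the last day.

    The concentration prevailing during day ``i`` (1-based) is
    ``final_conc * i / n_days``: every 24 h the same increment is added,
    so the endpoint equals the abrupt arm's endpoint exactly.
    """
    if final_conc <= 0:
        raise InvalidParameterError(f"final_conc must be > 0, got {final_conc}")
    if n_days < 1:
        raise InvalidParameterError(f"n_days must be >= 1, got {n_days}")
    # evaluate the day fraction first so day n is exactly final_conc
    conc = tuple(final_conc * (i / n_days) for i in range(1, int(n_days) + 1))
    return TreatmentSchedule("gradual", conc)


def build_abrupt_schedule(final_conc: float, n_days: int, step_day: int) -> TreatmentSchedule:
    """Single step to ``final_conc`` at the start of ``step_day`` (1-based)."""
    if final_conc <= 0:
        raise InvalidParameterError(f"final_conc must be > 0, got {final_conc}")
    if n_days < 1:
        raise InvalidParameterError(f"n_days must be >= 1, got {n_days}")
    if not 1 <= step_day <= n_days:
        raise InvalidParameterError(
            f"step_day must lie in [1, {n_days}], got {step_day}"
        )
    conc = tuple(
        0.0 if i < step_day else float(final_conc) for i in range(1, int(n_days) + 1)
    )
    return TreatmentSchedule("abrupt", conc)


def dose_days_from_conc(conc: Iterable[float]) -> float:
    """Dose-days of a raw daily-concentration sequence (compensated sum)."""
    return math.fsum(conc)


def dose_days(schedule: TreatmentSchedule) -> DoseDays:
    """Discrete area under the schedule: each daily concentration held one day."""
    return DoseDays(dose_days_from_conc(schedule.conc))


def check_equivalence(
    a: TreatmentSchedule, b: TreatmentSchedule, tol: float = 1e-9
) -> EquivalenceReport:
    """Audit two arms for identical overall dose and identical endpoint.

    ``tol`` is a relative tolerance applied to the dose-day difference
    (scaled by the larger dose-days) and to the final concentrations.
    """
    if a.n_days != b.n_days:
        raise IncompatibleScheduleError(
            f"schedules span {a.n_days} vs {b.n_days} days; cannot compare"
        )
    da, db = dose_days(a).value, dose_days(b).value
    scale = max(abs(da), abs(db), 1.0)
    dd_equal = abs(da - db) <= tol * scale
    fscale = max(abs(a.final_conc), abs(b.final_conc), 1.0)
    f_equal = abs(a.final_conc - b.final_conc) <= tol * fscale
    return EquivalenceReport(da, db, a.final_conc, b.final_conc, dd_equal, f_equal)


def write_schedule(schedule: TreatmentSchedule, path: str | Path) -> None:
    """Serialize to a two-column plain-text table (day, concentration_mM)."""
    lines = ["day\tconcentration_mM"]
    lines += [f"{i}\t{c!r}" for i, c in enumerate(schedule.conc, start=1)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_schedule(path: str | Path, label: str) -> TreatmentSchedule:
    """Read a schedule written by :func:`write_schedule`."""
    rows = Path(path).read_text().strip().splitlines()
    if not rows or rows[0].split("\t") != ["day", "concentration_mM"]:
        raise InvalidParameterError(f"{path}: expected 'day\\tconcentration_mM' header")
    conc: list[float] = []
    for expect_day, row in enumerate(rows[1:], start=1):
        day_s, conc_s = row.split("\t")
        if int(day_s) != expect_day:
            raise InvalidParameterError(f"{path}: days must be 1..n in order")
        conc.append(float(conc_s))
    return TreatmentSchedule(label, tuple(conc))
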