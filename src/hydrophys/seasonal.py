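"""Seasonal embolism projection under a no-refilling rule.

A dated series of replicate water potentials is combined with a fitted
vulnerability curve: at each sampling day the instantaneous PLC is evaluated
from the logistic at the day's mean, minimum and maximum water potential, and
the accumulated PLC is the running maximum over days (refilling presumed not
to occur, so PLC can only increase; when tension relaxes the previous value
carries forward). The minimum-psi path feeds the maximum-PLC band and vice
versa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ValidationError
from .vulnerability import VulnerabilityFit, plc_at_pressure

__all__ = [
    "DayObservation",
    "SeasonalSeries",
    "EmbolismTrajectory",
    "summarize_day",
    "project_embolism",
    "stomatal_decline",
]


@dataclass(frozen=True)
class DayObservation:
    """Replicate measurements on one day-of-year."""

    day: int
    psis: tuple[float, ...]
    gs: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if len(self.psis) < 1:
            raise ValidationError(f"day {self.day}: at least one psi replicate")
        if any(p > 0 for p in self.psis):
            raise ValidationError(f"day {self.day}: psi replicates must be <= 0")
        if self.gs is not None and any(g < 0 for g in self.gs):
            raise ValidationError(f"day {self.day}: gs replicates must be >= 0")


@dataclass(frozen=True)
class SeasonalSeries:
    """Dated replicate water-potential (and optional gs) observations."""

    species: str
    observations: tuple[DayObservation, ...]

    def __post_init__(self) -> None:
        days = [o.day for o in self.observations]
        if len(days) == 0:
            raise ValidationError("seasonal series has no observations")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError("days must be strictly increasing")

    @property
    def days(self) -> np.ndarray:
        return np.array([o.day for o in self.observations], dtype=int)

    @property
    def has_gs(self) -> bool:
        return any(o.gs is not None and len(o.gs) > 0 for o in self.observations)


@dataclass(frozen=True)
class EmbolismTrajectory:
    """Accumulated PLC paths and per-day psi summaries (one row per day)."""

    species: str
    days: tuple[int, ...]
    plc_mean: tuple[float, ...]
    plc_min: tuple[float, ...]
    plc_max: tuple[float, ...]
    psi_mean: tuple[float, ...]
    psi_sd: tuple[float, ...]
    psi_min: tuple[float, ...]
    psi_max: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in ("plc_mean", "plc_min", "plc_max"):
            path = np.asarray(getattr(self, name))
            if np.any(np.diff(path) < -1e-9):
                raise ValidationError(f"{name} path must be non-decreasing")
            if np.any(path < 0) or np.any(path > 100):
                raise ValidationError(f"{name} outside [0, 100]")
        lo, mid, hi = map(np.asarray, (self.plc_min, self.plc_mean, self.plc_max))
        if np.any(lo > mid + 1e-9) or np.any(mid > hi + 1e-9):
            raise ValidationError("expected plc_min <= plc_mean <= plc_max")


def summarize_day(replicates) -> tuple[float, Optional[float], float, float]:
    """(mean, sd, min, max) of a day's psi replicates; sd is None for n=1."""
    reps = np.asarray(replicates, dtype=float)
    if reps.size == 0:
        raise ValidationError("no replicates for day summary")
    sd = float(np.std(reps, ddof=1)) if reps.size > 1 else None
    return float(np.mean(reps)), sd, float(np.min(reps)), float(np.max(reps))


def project_embolism(
    series: SeasonalSeries, fit: VulnerabilityFit
) -> EmbolismTrajectory:
    """Project accumulated PLC through the season (no refilling).

    For each of the day's mean, minimum and maximum water potentials the
    instantaneous PLC is evaluated on the fitted curve and accumulated as a
    running maximum. The minimum-psi statistic produces the maximum-PLC path.
    """
    if fit.species and series.species and fit.species != series.species:
        warnings.warn(
            f"projecting {series.species} series with a {fit.species} curve"
        )
    if not fit.converged:
        raise ValidationError("cannot project from a non-converged fit")
    summaries = [summarize_day(o.psis) for o in series.observations]
    psi_mean = np.array([s[0] for s in summaries])
    psi_sd = np.array([np.nan if s[1] is None else s[1] for s in summaries])
    psi_min = np.array([s[2] for s in summaries])
    psi_max = np.array([s[3] for s in summaries])

    inst_mean = plc_at_pressure(fit, psi_mean)
    inst_from_min = plc_at_pressure(fit, psi_min)  # wettest bound -> most PLC
    inst_from_max = plc_at_pressure(fit, psi_max)

    return EmbolismTrajectory(
        species=series.species,
        days=tuple(int(d) for d in series.days),
        plc_mean=tuple(np.maximum.accumulate(inst_mean)),
        plc_min=tuple(np.maximum.accumulate(inst_from_max)),
        plc_max=tuple(np.maximum.accumulate(inst_from_min)),
        psi_mean=tuple(psi_mean),
        psi_sd=tuple(psi_sd),
        psi_min=tuple(psi_min),
        psi_max=tuple(psi_max),
    )


def stomatal_decline(
    series: SeasonalSeries,
    late_window: tuple[int, int],
    early_window: Optional[tuple[int, int]] = None,
    baseline: str = "max",
) -> float:
    """Fraction of baseline stomatal conductance retained late in the season.

    ``baseline="max"`` (default) uses the seasonal maximum of daily mean gs;
    ``baseline="early"`` uses the mean over ``early_window`` (inclusive
    day-of-year bounds). Raises when gs observations are missing from the
    series or the windows.
    """
    if not series.has_gs:
        raise ValidationError("series has no stomatal-conductance observations")
    if baseline not in ("max", "early"):
        raise ValidationError(f"baseline must be 'max' or 'early', got {baseline!r}")

    day_means: dict[int, float] = {}
    for obs in series.observations:
        if obs.gs is not None and len(obs.gs) > 0:
            day_means[obs.day] = float(np.mean(obs.gs))

    def window_mean(window: tuple[int, int]) -> float:
        vals = [g for d, g in day_means.items() if window[0] <= d <= window[1]]
        if not vals:
            raise ValidationError(f"no gs observations in window {window}")
        return float(np.mean(vals))

    late = window_mean(late_window)
    if baseline == "early":
        if early_window is None:
            raise ValidationError("baseline='early' requires early_window")
        ref = window_mean(early_window)
    else:
        ref = max(day_means.values())
    if ref <= 0:
        raise ValidationError("baseline stomatal conductance is zero")
    return late / ref
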