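"""Synthetic-data generators with known ground truth.

Each generator is a pure function of its spec (which carries the seed):
calling it twice with the same spec yields identical output, so every
downstream estimator can be tested by parameter recovery.

Generating models
-----------------
* Vulnerability curves: PLC(psi) = 100 / (1 + exp(a * (psi - p50))) with
  Gaussian PLC noise truncated to [0, 100]; conductivity K = Kmax * (1 -
  PLC/100), with the zero-tension measurement equal to Kmax exactly (that
  measurement defines Kmax).
* Pressure-volume: over a descending RWC grid, psi_pi = pi0 / RWC and
  psi_p = max(0, -pi0 - epsilon * (1 - RWC)); psi = psi_pi + psi_p; fresh
  mass = Wd + RWC * (Ws - Wd); Gaussian noise on psi only (clipped at 0).
  Closed forms: RWC_TLP = 1 + pi0/epsilon, TLP = pi0 / RWC_TLP.
* Season: linear decline from psi_start to psi_min (reached at rewet_day or
  the final day), then linear recovery; replicate scatter around the trend.
* Conduits: log-normal diameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ValidationError
from .pressure_volume import PVDrydown, PVTruth
from .seasonal import DayObservation, SeasonalSeries
from .traits import ConduitSet
from .vulnerability import ConductivitySeries, logistic_plc

__all__ = [
    "VCSimSpec",
    "PVSimSpec",
    "SeasonSimSpec",
    "ConduitSimSpec",
    "simulate_vc",
    "simulate_pv",
    "simulate_season",
    "simulate_conduits",
]


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValidationError(message)


@dataclass(frozen=True)
class VCSimSpec:
    """Ground truth for logistic vulnerability-curve data."""

    true_p50: float
    slope_a: float
    tensions: tuple[float, ...] = tuple(np.arange(0.0, -6.5, -0.5))
    n_stems: int = 6
    noise_sd: float = 5.0
    kmax_range: tuple[float, float] = (2.0, 8.0)
    seed: int = 0
    species: str = "synthetic"

    def __post_init__(self) -> None:
        _require(self.true_p50 < 0, "true_p50: must be negative (MPa)")
        _require(self.slope_a > 0, "slope_a: must be positive")
        _require(self.noise_sd >= 0, "noise_sd: must be >= 0")
        _require(self.n_stems >= 1, "n_stems: must be >= 1")
        t = np.asarray(self.tensions, dtype=float)
        _require(t.size >= 3, "tensions: need at least 3 levels")
        _require(t[0] == 0.0, "tensions: must start at 0 MPa")
        _require(bool(np.all(np.diff(t) < 0)), "tensions: must strictly decrease")
        _require(
            0 < self.kmax_range[0] <= self.kmax_range[1],
            "kmax_range: need 0 < lo <= hi",
        )


@dataclass(frozen=True)
class PVSimSpec:
    """Ground truth for pressure-volume dry-downs."""

    pi0: float
    epsilon: float
    dry_weight: float = 0.5
    saturated_weight: float = 1.0
    n_points: int = 15
    psi_noise_sd: float = 0.05
    n_oversaturated: int = 0
    seed: int = 0
    species: str = "synthetic"

    def __post_init__(self) -> None:
        _require(self.pi0 < 0, "pi0: must be negative (MPa)")
        _require(self.epsilon > 0, "epsilon: must be positive (MPa)")
        if self.epsilon <= abs(self.pi0):
            raise ValidationError(
                "epsilon: must exceed |pi0|, otherwise turgor is never lost "
                "within RWC in (0, 1]"
            )
        _require(
            self.saturated_weight > self.dry_weight > 0,
            "saturated_weight: must exceed dry_weight > 0",
        )
        _require(self.n_points >= 8, "n_points: must be >= 8")
        _require(self.psi_noise_sd >= 0, "psi_noise_sd: must be >= 0")
        _require(self.n_oversaturated >= 0, "n_oversaturated: must be >= 0")

    @property
    def rwc_tlp(self) -> float:
        return 1.0 + self.pi0 / self.epsilon

    @property
    def tlp(self) -> float:
        return self.pi0 / self.rwc_tlp


@dataclass(frozen=True)
class SeasonSimSpec:
    """Ground truth for a seasonal water-potential (and optional gs) series."""

    day_range: tuple[int, int] = (100, 325)
    psi_start: float = -0.5
    psi_min: float = -2.5
    rewet_day: Optional[int] = None
    replicate_sd: float = 0.1
    n_replicates: int = 4
    step_days: int = 7
    gs_start: Optional[float] = None
    gs_end_fraction: float = 1.0
    gs_sd: float = 0.0
    seed: int = 0
    species: str = "synthetic"

    def __post_init__(self) -> None:
        _require(self.day_range[0] < self.day_range[1], "day_range: start < end")
        _require(
            self.psi_min <= self.psi_start <= 0,
            "psi_start: need psi_min <= psi_start <= 0",
        )
        _require(self.replicate_sd >= 0, "replicate_sd: must be >= 0")
        _require(self.n_replicates >= 1, "n_replicates: must be >= 1")
        _require(self.step_days >= 1, "step_days: must be >= 1")
        if self.rewet_day is not None:
            _require(
                self.day_range[0] < self.rewet_day <= self.day_range[1],
                "rewet_day: must fall inside day_range",
            )
        if self.gs_start is not None:
            _require(self.gs_start > 0, "gs_start: must be > 0")
            _require(
                0 < self.gs_end_fraction <= 1.0,
                "gs_end_fraction: must lie in (0, 1]",
            )
            _require(self.gs_sd >= 0, "gs_sd: must be >= 0")


@dataclass(frozen=True)
class ConduitSimSpec:
    """Log-normal conduit-diameter population over a sampled xylem area."""

    log_mean: float = math.log(30.0)
    log_sd: float = 0.3
    n_conduits: int = 500
    sampled_area: float = 1e-6
    seed: int = 0
    species: str = "synthetic"

    def __post_init__(self) -> None:
        _require(self.n_conduits >= 1, "n_conduits: must be >= 1")
        _require(self.sampled_area > 0, "sampled_area: must be > 0")
        _require(self.log_sd >= 0, "log_sd: must be >= 0")


def simulate_vc(spec: VCSimSpec) -> list[ConductivitySeries]:
    """Generate per-stem conductivity ladders from a logistic PLC response."""
    rng = np.random.default_rng(spec.seed)
    tensions = np.asarray(spec.tensions, dtype=float)
    stems = []
    for i in range(spec.n_stems):
        kmax = float(rng.uniform(*spec.kmax_range))
        plc = logistic_plc(tensions, spec.true_p50, spec.slope_a)
        if spec.noise_sd > 0:
            plc = plc + rng.normal(0.0, spec.noise_sd, size=tensions.size)
        plc = np.clip(plc, 0.0, 100.0)
        k = kmax * (1.0 - plc / 100.0)
        k[tensions == 0.0] = kmax  # the zero-tension measurement defines Kmax
        stems.append(
            ConductivitySeries(
                stem_id=f"stem{i + 1}",
                species=spec.species,
                tensions=tuple(tensions),
                conductivities=tuple(k),
                kmax=kmax,
            )
        )
    return stems


def _pv_model_psi(rwc: np.ndarray, pi0: float, epsilon: float) -> np.ndarray:
    osmotic = pi0 / rwc
    turgor = np.maximum(0.0, -pi0 - epsilon * (1.0 - rwc))
    return osmotic + turgor


def simulate_pv(spec: PVSimSpec, leaf_id: str = "leaf1") -> PVDrydown:
    """Generate one leaf's dry-down with closed-form ground truth attached.

    When ``n_oversaturated > 0`` the pristine full-saturation point is
    replaced by that many artificial leading points whose masses exceed the
    saturated weight and whose psi declines steeply, mimicking surface-water
    oversaturation; the series then has n_points - 1 + n_oversaturated rows.
    """
    rng = np.random.default_rng(spec.seed)
    ws, wd = spec.saturated_weight, spec.dry_weight
    water = ws - wd
    # measurement schedule mirrors practice: points split between the turgid
    # region and the post-inflection tail (at least 5 there), with the tail
    # deep enough in psi for the osmotic line to have leverage
    rwc_min = max(0.4, spec.pi0 / (spec.tlp - max(0.5, 0.25 * abs(spec.tlp))))
    n_tail = max(5, int(round(0.55 * spec.n_points)))
    n_wet = spec.n_points - n_tail
    grid = np.concatenate(
        [
            np.linspace(1.0, spec.rwc_tlp, n_wet, endpoint=False),
            np.linspace(spec.rwc_tlp, rwc_min, n_tail),
        ]
    )
    psis = _pv_model_psi(grid, spec.pi0, spec.epsilon)
    masses = wd + grid * water

    if spec.n_oversaturated > 0:
        k = spec.n_oversaturated
        psi1 = psis[1]
        over_psis = psi1 * np.linspace(0.25, 0.75, k)
        over_masses = ws + water * np.linspace(0.02, 0.008, k)
        masses = np.concatenate([over_masses, masses[1:]])
        psis = np.concatenate([over_psis, psis[1:]])

    if spec.psi_noise_sd > 0:
        psis = np.minimum(psis + rng.normal(0.0, spec.psi_noise_sd, psis.size), 0.0)

    return PVDrydown(
        leaf_id=leaf_id,
        species=spec.species,
        fresh_masses=tuple(masses),
        psis=tuple(psis),
        dry_mass=wd,
        truth=PVTruth(
            pi0=spec.pi0,
            epsilon=spec.epsilon,
            tlp=spec.tlp,
            rwc_tlp=spec.rwc_tlp,
            saturated_weight=ws,
            n_oversaturated=spec.n_oversaturated,
        ),
    )


def _season_trend(spec: SeasonSimSpec, days: np.ndarray) -> np.ndarray:
    start, end = spec.day_range
    dry_end = spec.rewet_day if spec.rewet_day is not None else end
    trend = np.empty(days.size, dtype=float)
    drying = days <= dry_end
    trend[drying] = spec.psi_start + (spec.psi_min - spec.psi_start) * (
        (days[drying] - start) / (dry_end - start)
    )
    if np.any(~drying):
        trend[~drying] = spec.psi_min + (spec.psi_start - spec.psi_min) * (
            (days[~drying] - dry_end) / (end - dry_end)
        )
    return trend


def simulate_season(spec: SeasonSimSpec) -> SeasonalSeries:
    """Generate replicate psi (and optional gs) observations along a trend."""
    rng = np.random.default_rng(spec.seed)
    start, end = spec.day_range
    days = np.arange(start, end + 1, spec.step_days)
    trend = _season_trend(spec, days)

    gs_trend = None
    if spec.gs_start is not None:
        gs_trend = np.linspace(
            spec.gs_start, spec.gs_start * spec.gs_end_fraction, days.size
        )

    observations = []
    for i, day in enumerate(days):
        psis = np.full(spec.n_replicates, trend[i])
        if spec.replicate_sd > 0:
            psis = np.minimum(
                psis + rng.normal(0.0, spec.replicate_sd, spec.n_replicates), 0.0
            )
        gs = None
        if gs_trend is not None:
            gs_vals = np.full(spec.n_replicates, gs_trend[i])
            if spec.gs_sd > 0:
                gs_vals = np.maximum(
                    gs_vals + rng.normal(0.0, spec.gs_sd, spec.n_replicates), 0.0
                )
            gs = tuple(gs_vals)
        observations.append(
            DayObservation(day=int(day), psis=tuple(psis), gs=gs)
        )
    return SeasonalSeries(species=spec.species, observations=tuple(observations))


def simulate_conduits(spec: ConduitSimSpec, stem_id: str = "stem1") -> ConduitSet:
    """Draw a log-normal conduit-diameter population (um)."""
    rng = np.random.default_rng(spec.seed)
    diameters = rng.lognormal(spec.log_mean, spec.log_sd, spec.n_conduits)
    return ConduitSet(
        stem_id=stem_id,
        species=spec.species,
        diameters=tuple(diameters),
        sampled_area=spec.sampled_area,
    )
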