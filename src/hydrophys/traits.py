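"""Hydraulic and anatomical scalar traits.

Conduit diameters from lumen areas, the hydraulically weighted mean diameter
(sum D^5 / sum D^4 — a D^4-weighted mean, since flow scales with the fourth
power of diameter), vessel density, specific conductivity, the Huber value
(xylem:leaf area ratio, dimensionless, order 1e-5 for these species), and
hydraulic safety margins.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import ValidationError

__all__ = [
    "ConduitSet",
    "TraitRecord",
    "diameter_from_area",
    "area_from_diameter",
    "apply_cutoff",
    "hydraulic_mean_diameter",
    "vessel_density",
    "specific_conductivity",
    "huber_value",
    "safety_margin",
]

TRAIT_UNITS = {
    "tlp": "MPa",
    "epsilon": "MPa",
    "pi0": "MPa",
    "rwc_tlp": "%",
    "huber_value": "dimensionless",
    "specific_conductivity": "kg MPa^-1 s^-1 m^-1",
    "vessel_density": "vessels m^-2",
    "mean_diameter": "um",
    "hydraulic_mean_diameter": "um",
    "p50": "MPa",
    "safety_margin": "MPa",
    "native_plc": "%",
    "delta13c": "permil",
}


@dataclass(frozen=True)
class ConduitSet:
    """Conduit lumen diameters (um) measured over a sampled xylem area (m^2)."""

    stem_id: str
    species: str
    diameters: tuple[float, ...]
    sampled_area: float
    min_diameter_cutoff: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters, dtype=float)
        if d.size < 1:
            raise ValidationError(f"stem {self.stem_id}: no conduits")
        if np.any(d <= 0):
            raise ValidationError(f"stem {self.stem_id}: non-positive diameter")
        if not self.sampled_area > 0:
            raise ValidationError(f"stem {self.stem_id}: sampled_area must be > 0")

    def __len__(self) -> int:
        return len(self.diameters)


@dataclass(frozen=True)
class TraitRecord:
    species: str
    trait: str
    value: float
    units: str
    n: int
    sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.trait in TRAIT_UNITS and TRAIT_UNITS[self.trait] != self.units:
            raise ValidationError(
                f"trait {self.trait}: units {self.units!r} != "
                f"{TRAIT_UNITS[self.trait]!r}"
            )


def diameter_from_area(area):
    """Equivalent circle diameter (um) from a lumen area (um^2)."""
    area_arr = np.asarray(area, dtype=float)
    if np.any(area_arr <= 0):
        raise ValidationError("lumen area must be > 0")
    d = 2.0 * np.sqrt(area_arr / np.pi)
    return d if np.ndim(area) else float(d)


def area_from_diameter(diameter):
    """Circle area (um^2) from a diameter (um); inverse of diameter_from_area."""
    d = np.asarray(diameter, dtype=float)
    if np.any(d <= 0):
        raise ValidationError("diameter must be > 0")
    a = np.pi * (d / 2.0) ** 2
    return a if np.ndim(diameter) else float(a)


def apply_cutoff(conduits: ConduitSet, cutoff: Optional[float] = None) -> tuple[ConduitSet, int]:
    """Drop conduits narrower than the cutoff (um); returns (set, n_removed).

    The cutoff mirrors the exclusion of sub-10-um lumina in ring-porous
    material; it defaults to the set's own ``min_diameter_cutoff``.
    """
    cut = conduits.min_diameter_cutoff if cutoff is None else cutoff
    if cut < 0:
        raise ValidationError("cutoff must be >= 0")
    d = np.asarray(conduits.diameters, dtype=float)
    keep = d >= cut
    n_removed = int(np.count_nonzero(~keep))
    if n_removed == 0:
        return conduits, 0
    if not np.any(keep):
        raise ValidationError(
            f"stem {conduits.stem_id}: cutoff {cut} um removes every conduit"
        )
    return replace(conduits, diameters=tuple(d[keep])), n_removed


def hydraulic_mean_diameter(diameters) -> float:
    """Hydraulically weighted mean diameter: sum(D^5) / sum(D^4)."""
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise ValidationError("empty diameter list")
    if np.any(d <= 0):
        raise ValidationError("diameters must be > 0")
    return float(np.sum(d**5) / np.sum(d**4))


def vessel_density(n: int, sampled_area: float) -> float:
    """Conduits per square metre of sampled xylem."""
    if not sampled_area > 0:
        raise ValidationError("sampled_area must be > 0")
    if n < 0:
        raise ValidationError("count must be >= 0")
    return n / sampled_area


def specific_conductivity(kh: float, xylem_area: float) -> float:
    """Ks (kg MPa^-1 s^-1 m^-1): conductivity per xylem cross-section area."""
    if not xylem_area > 0:
        raise ValidationError("xylem_area must be > 0")
    return kh / xylem_area


def huber_value(xylem_area: float, leaf_area: float) -> float:
    """Xylem cross-sectional area per unit distal leaf area (both m^2)."""
    if not leaf_area > 0:
        raise ValidationError("leaf_area must be > 0")
    if xylem_area < 0:
        raise ValidationError("xylem_area must be >= 0")
    return xylem_area / leaf_area


def safety_margin(psi_min: float, p50: float) -> float:
    """Hydraulic safety margin: seasonal minimum water potential minus P50.

    Positive: the stem operated above its 50%-loss threshold; negative: the
    seasonal minimum exceeded P50 (both arguments in MPa, <= 0).
    """
    if psi_min > 0 or p50 > 0:
        raise ValidationError("psi_min and p50 must be <= 0 MPa")
    return psi_min - p50
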