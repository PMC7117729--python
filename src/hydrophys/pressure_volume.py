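"""Leaf pressure-volume curve analysis.

A dry-down series of (fresh mass, water potential) pairs plus a dry mass is
turned into the classic pressure-volume parameters: saturated mass, osmotic
potential at full turgor (the reciprocal of the osmotic line's intercept on
the (relative water deficit, 1/psi) plane), turgor loss point, relative water
content at turgor loss, and the modulus of elasticity.

The osmotic line is found by growing a window from the three driest points
toward wetter ones while the R^2 of the linear fit keeps increasing. The
wet-side boundary of that window plays the role of the curve's inflection
point: points before it form the "pre-inflection" region used for the
saturated-weight extrapolation and for oversaturation trimming. Because R^2
is invariant to affine maps of the abscissa and relative water deficit is
affine in fresh mass, the window can be located before the saturated weight
is known.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "PVDrydown",
    "PVParams",
    "OsmoticLine",
    "relative_water_content",
    "trim_oversaturated",
    "saturated_weight",
    "fit_osmotic_line",
    "max_osmotic_potential",
    "turgor_loss_point",
    "modulus_of_elasticity",
    "analyze_pv_curve",
]

MIN_POINTS = 8
MIN_AFTER_TRIM = 6
MAX_TRIM_FRACTION = 0.30
#: minimum number of points that must remain on the wet side of the window
MIN_PRE_INFLECTION = 3
#: R^2 differences below this are ties (machine-precision collinear data)
R2_TOL = 1e-12
#: transient R^2 dips tolerated while growing the window (measurement noise
#: produces dips up to ~0.08); the crash when the window crosses the
#: turgor-loss bend is far larger (>~0.2), which ends the search
R2_DIP_TOL = 0.15


@dataclass(frozen=True)
class PVTruth:
    """Ground truth attached to simulated dry-downs (parameter recovery)."""

    pi0: float
    epsilon: float
    tlp: float
    rwc_tlp: float
    saturated_weight: float
    n_oversaturated: int = 0


@dataclass(frozen=True)
class PVDrydown:
    """One leaf's dry-down: fresh masses (g, strictly decreasing), water
    potentials (MPa, <= 0) and the oven-dry mass (g)."""

    leaf_id: str
    species: str
    fresh_masses: tuple[float, ...]
    psis: tuple[float, ...]
    dry_mass: float
    truth: Optional[PVTruth] = None

    def __post_init__(self) -> None:
        m = np.asarray(self.fresh_masses, dtype=float)
        p = np.asarray(self.psis, dtype=float)
        if m.size != p.size:
            raise ValidationError(
                f"leaf {self.leaf_id}: fresh_masses and psis differ in length"
            )
        if m.size < MIN_POINTS:
            raise ValidationError(
                f"leaf {self.leaf_id}: need >= {MIN_POINTS} points, got {m.size}"
            )
        if np.any(m <= self.dry_mass):
            raise ValidationError(
                f"leaf {self.leaf_id}: fresh masses must exceed dry mass"
            )
        if np.any(np.diff(m) >= 0):
            raise ValidationError(
                f"leaf {self.leaf_id}: fresh masses must be strictly decreasing"
            )
        if np.any(p > 1e-12):
            raise ValidationError(f"leaf {self.leaf_id}: psis must be <= 0 MPa")

    def __len__(self) -> int:
        return len(self.fresh_masses)


@dataclass(frozen=True)
class OsmoticLine:
    """OLS line 1/psi = intercept + slope * RWD over the osmotic window."""

    slope: float
    intercept: float
    n_points: int
    r_squared: float
    window_start: int  # index of the wet-side boundary in the trimmed curve


@dataclass(frozen=True)
class PVParams:
    """Derived pressure-volume parameters for one leaf."""

    leaf_id: str
    species: str
    saturated_mass: float
    pi0: float
    tlp: float
    rwc_tlp: float
    epsilon: float
    osmotic_slope: float
    osmotic_intercept: float
    n_points_osmotic: int
    n_trimmed: int

    def __post_init__(self) -> None:
        if not (self.tlp <= self.pi0 < 0):
            raise ValidationError("expected tlp <= pi0 < 0")
        if not 0 < self.rwc_tlp < 1:
            raise ValidationError("rwc_tlp must lie in (0, 1)")
        if not self.epsilon > 0:
            raise ValidationError("epsilon must be > 0")


def relative_water_content(wf: float, wd: float, ws: float):
    """RWC = (wf - wd) / (ws - wd); values > 1 flag oversaturation."""
    if not ws > wd:
        raise ValidationError(f"saturated mass ws={ws} must exceed dry mass wd={wd}")
    wf_arr = np.asarray(wf, dtype=float)
    if np.any(wf_arr < wd):
        raise ValidationError("fresh mass below dry mass")
    rwc = (wf_arr - wd) / (ws - wd)
    return rwc if np.ndim(wf) else float(rwc)


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    res = stats.linregress(x, y)
    return float(res.rvalue**2)


def _window_start(masses: np.ndarray, psis: np.ndarray) -> int:
    """Wet-side boundary index of the osmotic window (greedy growth).

    Starts from the three driest points and adds wetter points while R^2 of
    the (abscissa, 1/psi) line does not decrease (1e-12 tolerance). Growth
    stops before points with psi ~ 0 and always leaves MIN_PRE_INFLECTION
    points on the wet side. The abscissa is fresh mass; by affine invariance
    of R^2 the choice equals the one made on the RWD plane.
    """
    n = masses.size
    if n < MIN_PRE_INFLECTION + 3:
        raise ValidationError("too few points to locate the osmotic window")
    usable = psis < -1e-9  # 1/psi undefined at full saturation
    if not np.all(usable[-3:]):
        raise ValidationError("the three driest points must have psi < 0")
    inv_psi = np.where(usable, 1.0 / np.where(usable, psis, -1.0), np.nan)

    start = n - 3
    prev_r2 = _r_squared(masses[start:], inv_psi[start:])
    while start - 1 >= MIN_PRE_INFLECTION and usable[start - 1]:
        r2 = _r_squared(masses[start - 1 :], inv_psi[start - 1 :])
        # stop at the crash where the window crosses the turgor-loss bend;
        # R^2 of sub-5-point windows is chance-dominated, so the rule arms
        # only once 5 points are in hand
        if n - (start - 1) >= 5 and r2 < prev_r2 - R2_DIP_TOL:
            break
        start -= 1
        prev_r2 = r2

    # boundary refinement: turgid points can slip past the crash rule when
    # the bend is gentle (small elasticity, or a point lands just above the
    # turgor-loss point); shrink while the wettest window point shows
    # clearly positive turgor against the line fitted without it. The noise
    # scale comes from the 4 driest points against their own line, so it is
    # unaffected by contamination of the window fit.
    local_fit = stats.linregress(masses[-4:], inv_psi[-4:])
    local_turgor = psis[-4:] - 1.0 / (local_fit.intercept + local_fit.slope * masses[-4:])
    noise_sd = float(np.std(local_turgor, ddof=2))
    threshold = max(0.02, 3.0 * noise_sd)
    while n - start > 3:
        rest = slice(start + 1, None)
        fit = stats.linregress(masses[rest], inv_psi[rest])
        pred_inv = fit.intercept + fit.slope * masses[start]
        turgor_boundary = psis[start] - 1.0 / pred_inv
        if turgor_boundary > threshold:
            start += 1
        else:
            break
    return start


def trim_oversaturated(curve: PVDrydown) -> tuple[PVDrydown, int]:
    """Remove artificial oversaturated leading points.

    A leading prefix is removed when every point in it is off the retained
    pre-inflection mass~psi line (mass residual above 2x the window's largest
    residual plus 0.5% of leaf water mass) and its removal raises that line's
    R^2. At most 30% of points are removed; a removal that would leave fewer
    than MIN_AFTER_TRIM points raises instead. Idempotent: trimming twice
    equals trimming once.
    """
    masses = np.asarray(curve.fresh_masses, dtype=float)
    psis = np.asarray(curve.psis, dtype=float)
    n = masses.size
    max_remove = int(np.floor(MAX_TRIM_FRACTION * n))
    water = float(masses.max() - curve.dry_mass)

    def prefix_valid(k: int) -> bool:
        kept_m, kept_p = masses[k:], psis[k:]
        ws_idx = _window_start(kept_m, kept_p)
        if ws_idx < MIN_PRE_INFLECTION:
            return False
        pre_m, pre_p = kept_m[:ws_idx], kept_p[:ws_idx]
        fit = stats.linregress(pre_p, pre_m)
        resid_win = pre_m - (fit.intercept + fit.slope * pre_p)
        threshold = 2.0 * float(np.max(np.abs(resid_win))) + 0.005 * water
        resid_prefix = masses[:k] - (fit.intercept + fit.slope * psis[:k])
        if not np.all(resid_prefix > threshold):
            return False
        # removal must raise the pre-inflection R^2
        r2_without = _r_squared(pre_p, pre_m)
        r2_with = _r_squared(
            np.concatenate([psis[:k], pre_p]), np.concatenate([masses[:k], pre_m])
        )
        return r2_without > r2_with

    best_k = 0
    for k in range(1, max_remove + 1):
        if n - k < MIN_AFTER_TRIM:
            if prefix_valid(k):
                raise ValidationError(
                    f"leaf {curve.leaf_id}: trimming {k} oversaturated points "
                    f"would leave fewer than {MIN_AFTER_TRIM}"
                )
            break
        if prefix_valid(k):
            best_k = k
    if best_k == 0:
        return curve, 0
    trimmed = replace(
        curve,
        fresh_masses=tuple(masses[best_k:]),
        psis=tuple(psis[best_k:]),
    )
    return trimmed, best_k


def saturated_weight(curve: PVDrydown) -> float:
    """Saturated leaf mass: the pre-inflection mass~psi line evaluated at 0.

    Fits fresh mass against water potential over the points on the wet side
    of the osmotic window and returns the predicted mass at psi = 0 MPa.
    Raises when fewer than 3 pre-inflection points are available.
    """
    masses = np.asarray(curve.fresh_masses, dtype=float)
    psis = np.asarray(curve.psis, dtype=float)
    ws_idx = _window_start(masses, psis)
    if ws_idx < 3:
        raise ValidationError(
            f"leaf {curve.leaf_id}: fewer than 3 points above the inflection"
        )
    fit = stats.linregress(psis[:ws_idx], masses[:ws_idx])
    ws = float(fit.intercept)
    if ws <= curve.dry_mass:
        raise ValidationError(
            f"leaf {curve.leaf_id}: extrapolated saturated mass {ws:.4g} "
            "does not exceed dry mass"
        )
    return ws


def fit_osmotic_line(curve: PVDrydown, ws: float) -> OsmoticLine:
    """Fit the osmotic line on the (RWD, 1/psi) plane.

    Starts from the last three (driest) points and grows the window toward
    the inflection while the goodness of fit increases; returns slope,
    intercept, window size and R^2.
    """
    masses = np.asarray(curve.fresh_masses, dtype=float)
    psis = np.asarray(curve.psis, dtype=float)
    if masses.size < 3 or np.any(psis[-3:] >= 0):
        raise ValidationError(f"leaf {curve.leaf_id}: need 3 valid tail points")
    start = _window_start(masses, psis)
    rwc = relative_water_content(masses, curve.dry_mass, ws)
    rwd = 1.0 - rwc
    fit = stats.linregress(rwd[start:], 1.0 / psis[start:])
    return OsmoticLine(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_points=int(masses.size - start),
        r_squared=float(fit.rvalue**2),
        window_start=int(start),
    )


def max_osmotic_potential(line: OsmoticLine) -> float:
    """Osmotic potential at full turgor: 1 / intercept (MPa, negative)."""
    if line.intercept >= 0:
        raise ValidationError(
            f"osmotic line intercept {line.intercept:.4g} is non-negative; "
            "a physical osmotic potential must be < 0"
        )
    return 1.0 / line.intercept


def _osmotic_psi(line: OsmoticLine, rwd: np.ndarray) -> np.ndarray:
    return 1.0 / (line.intercept + line.slope * rwd)


def turgor_loss_point(
    curve: PVDrydown, ws: float, line: OsmoticLine
) -> tuple[float, float]:
    """Turgor loss point and RWC at turgor loss.

    Turgor pressure is psi minus the osmotic potential predicted by the
    fitted line; the TLP is where it first reaches zero moving from wet to
    dry, located by linear interpolation between the bracketing points.
    """
    masses = np.asarray(curve.fresh_masses, dtype=float)
    psis = np.asarray(curve.psis, dtype=float)
    rwc = relative_water_content(masses, curve.dry_mass, ws)
    turgor = psis - _osmotic_psi(line, 1.0 - rwc)
    # window points lie on the osmotic line, so their turgor is zero up to
    # rounding; a tiny tolerance keeps the crossing at the first true zero
    tol = 1e-9 * max(1.0, float(np.max(np.abs(psis))))
    crossing = np.flatnonzero((turgor[:-1] > tol) & (turgor[1:] <= tol))
    if crossing.size == 0:
        raise ValidationError(
            f"leaf {curve.leaf_id}: turgor pressure never crosses zero"
        )
    i = int(crossing[0])
    # below the turgor-loss point computed turgor is ~0 (those points define
    # the osmotic line), so plain bracket interpolation is dragged dry-ward;
    # regressing turgor on RWC over the turgid prefix and intersecting zero
    # is exact on clean data. The crossing stays clamped inside the bracket.
    turgid = np.flatnonzero(turgor[: i + 1] > tol)
    if turgid.size >= 2:
        reg = stats.linregress(rwc[turgid], turgor[turgid])
        rwc_tlp = float(np.clip(-reg.intercept / reg.slope, rwc[i + 1], rwc[i]))
    else:
        frac = turgor[i] / (turgor[i] - turgor[i + 1])
        rwc_tlp = float(rwc[i] + frac * (rwc[i + 1] - rwc[i]))
    # at zero turgor the water potential equals the osmotic potential, so
    # evaluate the fitted line there rather than interpolating noisy psi
    tlp = float(_osmotic_psi(line, np.array([1.0 - rwc_tlp]))[0])
    return tlp, rwc_tlp


def modulus_of_elasticity(
    curve: PVDrydown, ws: float, line: OsmoticLine, rwc_tlp: float
) -> float:
    """Bulk modulus of elasticity: slope of turgor pressure vs RWC (turgid
    region, RWC > rwc_tlp), in MPa per unit relative water content."""
    masses = np.asarray(curve.fresh_masses, dtype=float)
    psis = np.asarray(curve.psis, dtype=float)
    rwc = relative_water_content(masses, curve.dry_mass, ws)
    turgid = rwc > rwc_tlp
    if np.count_nonzero(turgid) < 3:
        raise ValidationError(
            f"leaf {curve.leaf_id}: fewer than 3 points in the turgid region"
        )
    turgor = psis[turgid] - _osmotic_psi(line, 1.0 - rwc[turgid])
    fit = stats.linregress(rwc[turgid], turgor)
    eps = float(fit.slope)
    if eps <= 0:
        raise ValidationError(
            f"leaf {curve.leaf_id}: non-positive elasticity slope {eps:.4g}"
        )
    return eps


def analyze_pv_curve(curve: PVDrydown) -> PVParams:
    """Run the full pipeline on one leaf: trim, Ws, osmotic line, pi0, TLP,
    RWC_TLP and epsilon."""
    trimmed, n_trimmed = trim_oversaturated(curve)
    ws = saturated_weight(trimmed)
    line = fit_osmotic_line(trimmed, ws)
    pi0 = max_osmotic_potential(line)
    tlp, rwc_tlp = turgor_loss_point(trimmed, ws, line)
    eps = modulus_of_elasticity(trimmed, ws, line, rwc_tlp)
    return PVParams(
        leaf_id=curve.leaf_id,
        species=curve.species,
        saturated_mass=ws,
        pi0=pi0,
        tlp=min(tlp, pi0),  # numerical guard: tlp <= pi0 by definition
        rwc_tlp=rwc_tlp,
        epsilon=eps,
        osmotic_slope=line.slope,
        osmotic_intercept=line.intercept,
        n_points_osmotic=line.n_points,
        n_trimmed=n_trimmed,
    )
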