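"""Xylem vulnerability curves.

Percent loss of hydraulic conductivity (PLC) from paired conductivity
measurements, two-parameter logistic curve fitting per stem or pooled, and
derived pressure thresholds (P12, P50, P88). Xylem pressures are stored as
negative MPa throughout; conductivities in kg MPa^-1 s^-1 m^-1.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import ValidationError

__all__ = [
    "ConductivitySeries",
    "VulnerabilityFit",
    "NativePLCRecord",
    "logistic_plc",
    "percent_loss_conductivity",
    "fit_vulnerability_curve",
    "pressure_at_plc",
    "plc_at_pressure",
    "native_plc",
]

log = logging.getLogger(__name__)

#: relative headroom tolerated for conductivity > kmax (measurement noise)
KMAX_TOLERANCE = 0.01


def logistic_plc(psi, p50: float, slope_a: float):
    """Two-parameter logistic PLC response, 100 / (1 + exp(a * (psi - p50))).

    ``psi`` may be a scalar or array of xylem pressures (MPa, <= 0).
    Monotone non-increasing in ``psi`` for ``slope_a > 0``: more negative
    pressure means more embolism.
    """
    return 100.0 / (1.0 + np.exp(slope_a * (np.asarray(psi, dtype=float) - p50)))


@dataclass(frozen=True)
class ConductivitySeries:
    """Per-stem conductivity measurements along a tension ladder.

    ``tensions`` starts at 0 MPa (the flushed, maximum-conductivity
    measurement) and decreases strictly; ``kmax`` is the conductivity at
    zero tension.
    """

    stem_id: str
    species: str
    tensions: tuple[float, ...]
    conductivities: tuple[float, ...]
    kmax: float
    segment_length: float = 0.142

    def __post_init__(self) -> None:
        t = np.asarray(self.tensions, dtype=float)
        k = np.asarray(self.conductivities, dtype=float)
        if t.size != k.size:
            raise ValidationError(
                f"stem {self.stem_id}: tensions and conductivities differ in length"
            )
        if t.size < 2:
            raise ValidationError(f"stem {self.stem_id}: need at least 2 tensions")
        if t[0] != 0.0:
            raise ValidationError(
                f"stem {self.stem_id}: tensions must start at 0 MPa, got {t[0]}"
            )
        if np.any(np.diff(t) >= 0):
            raise ValidationError(
                f"stem {self.stem_id}: tensions must be strictly decreasing"
            )
        if not self.kmax > 0:
            raise ValidationError(f"stem {self.stem_id}: kmax must be > 0")
        if np.any(k < 0):
            raise ValidationError(f"stem {self.stem_id}: negative conductivity")
        if np.any(k > self.kmax * (1.0 + KMAX_TOLERANCE)):
            raise ValidationError(
                f"stem {self.stem_id}: conductivity exceeds kmax beyond tolerance"
            )

    @property
    def plc(self) -> np.ndarray:
        """PLC at each tension, computed from the stored kmax."""
        return percent_loss_conductivity(
            np.asarray(self.conductivities, dtype=float), self.kmax
        )


@dataclass(frozen=True)
class VulnerabilityFit:
    """Fitted logistic vulnerability curve and derived thresholds.

    ``p50``/``slope_a`` are the headline parameters (mean over stems in
    per-stem mode, joint estimates in pooled mode); p12/p88 derive from them.
    """

    p50: float
    slope_a: float
    p12: float
    p88: float
    species: str = ""
    mode: str = "per_stem"
    per_stem_p50s: tuple[float, ...] = field(default_factory=tuple)
    per_stem_slopes: tuple[float, ...] = field(default_factory=tuple)
    p50_sd: float = float("nan")
    rss: float = float("nan")
    n_points: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.converged:
            if not self.slope_a > 0:
                raise ValidationError("slope_a must be > 0")
            if not (self.p88 < self.p50 < 0):
                raise ValidationError("expected p88 < p50 < 0")
            # a shallow curve can put the 12% threshold above zero pressure,
            # in which case p12 is reported as NaN (not reliably computable)
            if not (math.isnan(self.p12) or self.p50 < self.p12):
                raise ValidationError("expected p50 < p12")


@dataclass(frozen=True)
class NativePLCRecord:
    """Native (field) PLC of one stem: Kn vs conductivity after flushing."""

    stem_id: str
    psi_at_harvest: float
    kn: float
    kmax_flushed: float

    @property
    def plc(self) -> float:
        return float(native_plc(self.kn, self.kmax_flushed))


def percent_loss_conductivity(kx, kmax):
    """Percent loss of conductivity, (1 - kx/kmax) * 100.

    Clamped to [0, 100]; values outside (kx > kmax from measurement noise,
    or kx < 0) trigger a logged warning, not an error. ``kx`` may be an
    array. Raises :class:`ValidationError` for ``kmax <= 0``.
    """
    if not kmax > 0:
        raise ValidationError(f"kmax must be > 0, got {kmax}")
    kx_arr = np.asarray(kx, dtype=float)
    if np.any(kx_arr < 0):
        raise ValidationError("conductivity kx must be >= 0")
    plc = (1.0 - kx_arr / kmax) * 100.0
    if np.any(plc < 0) or np.any(plc > 100):
        log.warning("PLC outside [0, 100] clamped (kx > kmax or kx < 0)")
        plc = np.clip(plc, 0.0, 100.0)
    return plc if np.ndim(kx) else float(plc)


def native_plc(kn, kmax_flushed):
    """PLC of a field-collected stem: native conductivity vs after flushing."""
    return percent_loss_conductivity(kn, kmax_flushed)


def _fit_logistic(psi: np.ndarray, plc: np.ndarray) -> tuple[float, float, float, bool]:
    """Least-squares logistic fit; returns (p50, slope_a, rss, converged)."""
    # data-driven start: tension nearest 50% observed PLC, unit slope
    p50_init = float(psi[np.argmin(np.abs(plc - 50.0))])
    if p50_init >= 0.0:
        p50_init = float(np.min(psi)) / 2.0
    try:
        popt, _ = curve_fit(
            logistic_plc,
            psi,
            plc,
            p0=(p50_init, 1.0),
            bounds=((-np.inf, 1e-9), (0.0, np.inf)),
            maxfev=10000,
        )
    except RuntimeError:  # pragma: no cover - exercised via flagged result
        return float("nan"), float("nan"), float("nan"), False
    resid = plc - logistic_plc(psi, *popt)
    return float(popt[0]), float(popt[1]), float(np.sum(resid**2)), True


def _p12(p50: float, slope_a: float) -> float:
    """12%-loss pressure, or NaN when the logistic puts it above zero."""
    p12 = p50 + math.log(88.0 / 12.0) / slope_a
    return p12 if p12 < 0 else float("nan")


def _stem_points(series: ConductivitySeries) -> tuple[np.ndarray, np.ndarray]:
    """Fit points for one stem: (psi, plc), excluding the zero-tension anchor.

    The zero-tension measurement defines kmax, so its PLC is identically 0
    by construction rather than a sigmoid observation; it is not fitted.
    """
    psi = np.asarray(series.tensions, dtype=float)
    plc = series.plc
    keep = psi < 0
    return psi[keep], plc[keep]


def fit_vulnerability_curve(
    series: list[ConductivitySeries] | ConductivitySeries,
    mode: str = "per_stem",
) -> VulnerabilityFit:
    """Fit logistic vulnerability curve(s) to one or more stems.

    ``mode="per_stem"`` fits each stem separately and reports the mean +/- SD
    of the per-stem P50s (the headline p50/slope are those means);
    ``mode="pooled"`` fits all points jointly with equal point weights.

    Raises :class:`ValidationError` when a stem has fewer than 3 distinct
    non-zero tensions, or (per-stem mode) when every observed PLC is below
    20% so the midpoint cannot be located. Non-convergence is returned as a
    flagged result (``converged=False``), never silently.
    """
    if isinstance(series, ConductivitySeries):
        series = [series]
    if not series:
        raise ValidationError("no conductivity series supplied")
    if mode not in ("per_stem", "pooled"):
        raise ValidationError(f"mode must be per_stem or pooled, got {mode!r}")
    species = series[0].species

    for s in series:
        psi, plc = _stem_points(s)
        if np.unique(psi).size < 3:
            raise ValidationError(
                f"stem {s.stem_id}: need >= 3 distinct non-zero tensions"
            )
        if mode == "per_stem" and np.max(plc) < 20.0:
            raise ValidationError(
                f"stem {s.stem_id}: all PLC below 20%; the curve midpoint is "
                "unconstrained, refusing a per-stem P50 (pool stems or extend "
                "the tension ladder)"
            )

    if mode == "pooled":
        psi = np.concatenate([_stem_points(s)[0] for s in series])
        plc = np.concatenate([_stem_points(s)[1] for s in series])
        p50, a, rss, ok = _fit_logistic(psi, plc)
        if not ok:
            return _failed_fit(species, "pooled", psi.size)
        return VulnerabilityFit(
            p50=p50,
            slope_a=a,
            p12=_p12(p50, a),
            p88=p50 + math.log(12.0 / 88.0) / a,
            species=species,
            mode="pooled",
            rss=rss,
            n_points=int(psi.size),
        )

    p50s, slopes, rsses = [], [], []
    n_points = 0
    all_ok = True
    for s in series:
        psi, plc = _stem_points(s)
        p50, a, rss, ok = _fit_logistic(psi, plc)
        all_ok &= ok
        p50s.append(p50)
        slopes.append(a)
        rsses.append(rss)
        n_points += psi.size
    if not all_ok:
        return _failed_fit(species, "per_stem", n_points)
    p50_mean = float(np.mean(p50s))
    a_mean = float(np.mean(slopes))
    return VulnerabilityFit(
        p50=p50_mean,
        slope_a=a_mean,
        p12=_p12(p50_mean, a_mean),
        p88=p50_mean + math.log(12.0 / 88.0) / a_mean,
        species=species,
        mode="per_stem",
        per_stem_p50s=tuple(p50s),
        per_stem_slopes=tuple(slopes),
        p50_sd=float(np.std(p50s, ddof=1)) if len(p50s) > 1 else float("nan"),
        rss=float(np.sum(rsses)),
        n_points=n_points,
    )


def _failed_fit(species: str, mode: str, n_points: int) -> VulnerabilityFit:
    warnings.warn(f"vulnerability fit did not converge ({species}, {mode})")
    nan = float("nan")
    return VulnerabilityFit(
        p50=nan, slope_a=nan, p12=nan, p88=nan, species=species,
        mode=mode, n_points=n_points, converged=False,
    )


def pressure_at_plc(fit: VulnerabilityFit, x: float) -> float:
    """Xylem pressure (MPa) at which the fitted curve reaches ``x`` % PLC.

    Closed form P50 + ln((100 - x)/x) / slope_a; x must lie in (0, 100).
    """
    if not 0.0 < x < 100.0:
        raise ValidationError(f"PLC level must be in (0, 100), got {x}")
    return fit.p50 + math.log((100.0 - x) / x) / fit.slope_a


def plc_at_pressure(fit: VulnerabilityFit, psi) -> float:
    """Evaluate the fitted logistic at xylem pressure ``psi`` (MPa, <= 0)."""
    psi_arr = np.asarray(psi, dtype=float)
    if np.any(psi_arr > 0):
        raise ValidationError("xylem pressure must be <= 0 MPa")
    out = logistic_plc(psi_arr, fit.p50, fit.slope_a)
    return out if np.ndim(psi) else float(out)
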