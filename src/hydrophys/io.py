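"""CSV schemas and (de)serialisation.

Long format throughout: one observation per row, units declared in column
name suffixes (_mpa, _g, _um, _m2, _mmol). Water potentials and xylem
tensions are stored as negative MPa; readers reject positive values unless
``tension_magnitudes=True``, in which case positive magnitudes are negated.
Dates are day-of-year integers.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .pressure_volume import PVDrydown, PVParams
from .seasonal import DayObservation, SeasonalSeries
from .traits import ConduitSet, TraitRecord, diameter_from_area
from .vulnerability import ConductivitySeries, VulnerabilityFit

__all__ = [
    "read_conductivity_csv",
    "write_conductivity_csv",
    "read_pv_csv",
    "write_pv_csv",
    "read_season_csv",
    "write_season_csv",
    "read_conduit_csv",
    "write_conduit_csv",
    "write_fit_json",
    "read_fit_json",
    "pv_params_frame",
    "trait_frame",
    "trajectory_frame",
    "comparison_frame",
]

VC_COLUMNS = ("stem_id", "species", "tension_mpa", "conductivity")
PV_COLUMNS = ("leaf_id", "species", "fresh_mass_g", "psi_mpa", "dry_mass_g")
SEASON_COLUMNS = ("species", "day", "psi_mpa")  # gs_mmol optional
CONDUIT_COLUMNS = ("stem_id", "species", "sampled_area_m2")  # + diameter or area

FLOAT_FORMAT = "%.10g"


def _read_table(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing column(s) {', '.join(missing)}")
    return df


def _check_numeric(df: pd.DataFrame, path, columns) -> None:
    for col in columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad) > 0:
            # +2: 1-based rows plus the header line
            raise ValidationError(
                f"{Path(path).name}: non-numeric value in column {col!r} "
                f"at row {int(bad[0]) + 2}"
            )
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0]) + 2
            raise ValidationError(
                f"{Path(path).name}: empty cell in column {col!r} at row {row}"
            )
        df[col] = vals


def _apply_sign_convention(
    df: pd.DataFrame, path, column: str, tension_magnitudes: bool
) -> None:
    if tension_magnitudes:
        df[column] = -df[column].abs()
        return
    positive = df.index[df[column] > 0]
    if len(positive) > 0:
        raise ValidationError(
            f"{Path(path).name}: positive value in column {column!r} at row "
            f"{int(positive[0]) + 2}; pass tension_magnitudes "
            "(--tension-magnitudes) if values are magnitudes"
        )


def read_conductivity_csv(
    path, tension_magnitudes: bool = False
) -> list[ConductivitySeries]:
    """Read per-stem conductivity ladders.

    kmax is taken from each stem's zero-tension row, which must be present.
    """
    df = _read_table(path, VC_COLUMNS)
    _check_numeric(df, path, ("tension_mpa", "conductivity"))
    _apply_sign_convention(df, path, "tension_mpa", tension_magnitudes)
    series = []
    for (stem_id, species), grp in df.groupby(["stem_id", "species"], sort=False):
        grp = grp.sort_values("tension_mpa", ascending=False)
        tensions = grp["tension_mpa"].to_numpy()
        k = grp["conductivity"].to_numpy()
        if tensions[0] != 0.0:
            raise ValidationError(
                f"stem {stem_id}: no zero-tension (kmax) measurement"
            )
        series.append(
            ConductivitySeries(
                stem_id=str(stem_id),
                species=str(species),
                tensions=tuple(tensions),
                conductivities=tuple(k),
                kmax=float(k[0]),
            )
        )
    return series


def write_conductivity_csv(series: list[ConductivitySeries], path) -> None:
    rows = [
        {
            "stem_id": s.stem_id,
            "species": s.species,
            "tension_mpa": t,
            "conductivity": k,
        }
        for s in series
        for t, k in zip(s.tensions, s.conductivities)
    ]
    pd.DataFrame(rows, columns=list(VC_COLUMNS)).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_pv_csv(path, tension_magnitudes: bool = False) -> list[PVDrydown]:
    """Read leaf dry-downs; dry_mass_g is repeated on every row of a leaf."""
    df = _read_table(path, PV_COLUMNS)
    _check_numeric(df, path, ("fresh_mass_g", "psi_mpa", "dry_mass_g"))
    _apply_sign_convention(df, path, "psi_mpa", tension_magnitudes)
    curves = []
    for (leaf_id, species), grp in df.groupby(["leaf_id", "species"], sort=False):
        dry = grp["dry_mass_g"].unique()
        if dry.size != 1:
            raise ValidationError(f"leaf {leaf_id}: inconsistent dry_mass_g")
        curves.append(
            PVDrydown(
                leaf_id=str(leaf_id),
                species=str(species),
                fresh_masses=tuple(grp["fresh_mass_g"]),
                psis=tuple(grp["psi_mpa"]),
                dry_mass=float(dry[0]),
            )
        )
    return curves


def write_pv_csv(curves: list[PVDrydown], path) -> None:
    rows = [
        {
            "leaf_id": c.leaf_id,
            "species": c.species,
            "fresh_mass_g": m,
            "psi_mpa": p,
            "dry_mass_g": c.dry_mass,
        }
        for c in curves
        for m, p in zip(c.fresh_masses, c.psis)
    ]
    pd.DataFrame(rows, columns=list(PV_COLUMNS)).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_season_csv(path, tension_magnitudes: bool = False) -> list[SeasonalSeries]:
    """Read dated replicate observations, one series per species.

    The optional ``gs_mmol`` column may be absent or hold blanks; a day's gs
    replicates are the non-blank values measured that day.
    """
    df = _read_table(path, SEASON_COLUMNS)
    _check_numeric(df, path, ("day", "psi_mpa"))
    _apply_sign_convention(df, path, "psi_mpa", tension_magnitudes)
    has_gs = "gs_mmol" in df.columns
    out = []
    for species, sgrp in df.groupby("species", sort=False):
        observations = []
        for day, grp in sgrp.groupby("day", sort=True):
            gs = None
            if has_gs:
                gs_vals = pd.to_numeric(grp["gs_mmol"], errors="coerce").dropna()
                gs = tuple(gs_vals) if len(gs_vals) else None
            observations.append(
                DayObservation(
                    day=int(day), psis=tuple(grp["psi_mpa"]), gs=gs
                )
            )
        out.append(SeasonalSeries(species=str(species), observations=tuple(observations)))
    return out


def write_season_csv(series: list[SeasonalSeries], path) -> None:
    rows = []
    for s in series:
        for obs in s.observations:
            gs = obs.gs if obs.gs is not None else [np.nan] * len(obs.psis)
            for i, psi in enumerate(obs.psis):
                rows.append(
                    {
                        "species": s.species,
                        "day": obs.day,
                        "psi_mpa": psi,
                        "gs_mmol": gs[i] if i < len(gs) else np.nan,
                    }
                )
    pd.DataFrame(rows, columns=list(SEASON_COLUMNS) + ["gs_mmol"]).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_conduit_csv(path) -> list[ConduitSet]:
    """Read conduit measurements: diameter_um or lumen_area_um2 per row."""
    df = _read_table(path, CONDUIT_COLUMNS)
    if "diameter_um" in df.columns:
        _check_numeric(df, path, ("diameter_um", "sampled_area_m2"))
        diam_col = "diameter_um"
    elif "lumen_area_um2" in df.columns:
        _check_numeric(df, path, ("lumen_area_um2", "sampled_area_m2"))
        df["diameter_um"] = diameter_from_area(df["lumen_area_um2"].to_numpy())
        diam_col = "diameter_um"
    else:
        raise ValidationError(
            f"{Path(path).name}: need a diameter_um or lumen_area_um2 column"
        )
    sets = []
    for (stem_id, species), grp in df.groupby(["stem_id", "species"], sort=False):
        area = grp["sampled_area_m2"].unique()
        if area.size != 1:
            raise ValidationError(f"stem {stem_id}: inconsistent sampled_area_m2")
        sets.append(
            ConduitSet(
                stem_id=str(stem_id),
                species=str(species),
                diameters=tuple(grp[diam_col]),
                sampled_area=float(area[0]),
            )
        )
    return sets


def write_conduit_csv(sets: list[ConduitSet], path) -> None:
    rows = [
        {
            "stem_id": c.stem_id,
            "species": c.species,
            "diameter_um": d,
            "sampled_area_m2": c.sampled_area,
        }
        for c in sets
        for d in c.diameters
    ]
    pd.DataFrame(
        rows, columns=["stem_id", "species", "diameter_um", "sampled_area_m2"]
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_fit_json(fit: VulnerabilityFit, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(fit), fh, indent=2, sort_keys=True)


def read_fit_json(path) -> VulnerabilityFit:
    with open(path) as fh:
        payload = json.load(fh)
    payload["per_stem_p50s"] = tuple(payload.get("per_stem_p50s", ()))
    payload["per_stem_slopes"] = tuple(payload.get("per_stem_slopes", ()))
    return VulnerabilityFit(**payload)


def pv_params_frame(params: list[PVParams]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(p) for p in params])
    return df.rename(
        columns={
            "saturated_mass": "saturated_mass_g",
            "pi0": "pi0_mpa",
            "tlp": "tlp_mpa",
            "epsilon": "epsilon_mpa",
        }
    )


def trajectory_frame(traj) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "day": traj.days,
            "species": traj.species,
            "plc_mean_pct": traj.plc_mean,
            "plc_min_pct": traj.plc_min,
            "plc_max_pct": traj.plc_max,
            "psi_mean_mpa": traj.psi_mean,
            "psi_sd_mpa": traj.psi_sd,
            "psi_min_mpa": traj.psi_min,
            "psi_max_mpa": traj.psi_max,
        }
    )


def comparison_frame(results) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in results])


def trait_frame(records: list[TraitRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])
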