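# hydrophys

A plant drought-physiology toolkit covering the lab-to-season analysis chain
for woody species:

- **Vulnerability curves** — percent loss of hydraulic conductivity (PLC)
  from paired conductivity measurements, two-parameter logistic fits per
  stem or pooled, derived P12/P50/P88 thresholds, and native PLC.
- **Pressure–volume analysis** — oversaturation trimming, saturated-weight
  extrapolation, osmotic-line fitting on the (relative water deficit, 1/Ψ)
  plane, osmotic potential at full turgor, turgor loss point, RWC at turgor
  loss, and the modulus of elasticity.
- **Seasonal embolism projection** — accumulated PLC through a season under
  a no-refilling rule (instantaneous PLC from the fitted curve at each day's
  mean/min/max water potential, accumulated as a running maximum), plus
  stomatal-conductance retention summaries.
- **Hydraulic/anatomical traits** — conduit diameters from lumen areas,
  hydraulically weighted mean diameter (ΣD⁵/ΣD⁴), vessel density, specific
  conductivity, Huber value, and hydraulic safety margins (Ψmin − P50).
- **Group comparison** — Shapiro–Wilk-gated Welch's t / Wilcoxon rank-sum
  workflow with a variance-ratio F test reported alongside.
- **Synthetic data** — seeded generators for all four input kinds with
  closed-form ground truth, so every estimator is testable by parameter
  recovery.

Sign convention: xylem pressures and water potentials are negative MPa
everywhere; CSV readers accept positive "tension magnitudes" only behind an
explicit flag.

## CLI

```bash
# generate synthetic inputs (CSV + ground-truth sidecar)
hydrophys simulate --kind vc --seed 1 --outdir data/

# fit vulnerability curves; save the fit for the seasonal projection
hydrophys vcfit data/vc_data.csv --mode per_stem --fit-json fit.json

# pressure-volume parameters, one row per leaf
hydrophys pvcurve data/pv_data.csv --out pv_params.csv

# accumulated-PLC trajectory under the no-refilling rule
hydrophys season data/season_data.csv --fit fit.json --out trajectory.csv

# anatomical traits (optional small-conduit cutoff for ring-porous material)
hydrophys traits data/conduit_data.csv --cutoff-um 10

# two-group comparison from a long-format CSV (group,value)
hydrophys compare groups.csv --alpha 0.05

# chain everything from a YAML config
hydrophys run --config config.yaml --outdir out/
```

Exit codes: 0 success, 2 validation error, 3 convergence failure.

Input schemas (long format, units in column names):

| kind | columns |
| --- | --- |
| conductivity | `stem_id, species, tension_mpa, conductivity` (zero-tension row = Kmax) |
| pressure–volume | `leaf_id, species, fresh_mass_g, psi_mpa, dry_mass_g` |
| seasonal | `species, day, psi_mpa[, gs_mmol]` |
| conduits | `stem_id, species, diameter_um` or `lumen_area_um2`, `sampled_area_m2` |

## Notes

- The logistic PLC(Ψ) = 100/(1 + exp(a(Ψ − P50))) is the only curve family
  in v1; the midpoint parameter is P50 directly.
- The fitted P12 is reported as NaN when a shallow curve places the 12 %
  threshold above zero pressure (it is then not reliably computable).
- Huber values are dimensionless and of order 1e-5 for evergreen trees.
- Plots (`--plot` flags) are diagnostics only and never feed any computed
  result.
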