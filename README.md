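# dibkit

Analysis toolkit for three model-membrane assays, with matched synthetic-data
generators so the whole pipeline is testable without instrument data:

1. **Droplet-interface-bilayer (DIB) water permeability** — two adhered
   aqueous microdroplets in oil exchange water across the bilayer at their
   contact disc when an osmotic gradient exists. From time series of droplet
   radii and contact radius (or rendered image stacks), `dibkit` infers the
   osmotic water permeability coefficient P_f (μm/s) by initial-rate or full
   ODE least-squares fitting, and aggregates replicates to mean ± SEM.
2. **DSC endotherm analysis** — converts heat-flow thermograms (mW) to molar
   excess heat capacity, subtracts a linear two-window baseline, and reports
   the transition temperature T_m (apex), enthalpy ΔH (peak area), width at
   half height ΔT_1/2, and condition-vs-control comparisons (ΔT_m, ΔH/ΔH°).
3. **Raman C–H packing-order ratios** — baseline-corrects spectra
   (asymmetric-least-squares with band-masked polynomial refinement),
   normalizes at the 2848 cm⁻¹ band, and computes the peak-height ratios
   I2930/I2848 and I2930/I2890 with replicate statistics.

## Layout

| module | contents |
| --- | --- |
| `dibkit.droplet_geometry` | truncated-sphere volumes, contact geometry, circle fitting on image frames, trajectory tracking |
| `dibkit.permeability` | osmotic flux law, P_f estimators (`initial_rate`, `ode_fit`), replicate aggregation, percent change |
| `dibkit.dsc` | heat-flow calibration, baseline subtraction, transition metrics, control comparison |
| `dibkit.raman` | baseline correction, normalization, band intensities, packing ratios, ratio summaries |
| `dibkit.synthetic_data` | seeded generators for trajectories, rendered droplet images, thermograms, and spectra, plus the C–H band amplitude calibration helper |
| `dibkit.report` | YAML-driven study orchestration (`run_study`) with deterministic per-condition seeding and a checksummed manifest |
| `dibkit.io` | CSV/JSON/TIFF readers and writers |
| `dibkit.cli` | `dibkit` command-line entry point |

## CLI

```bash
# generate synthetic data
dibkit simulate dib   --config dib.yaml   --seed 1 --out traj.csv
dibkit simulate dsc   --config dsc.yaml   --seed 1 --out thermogram.csv
dibkit simulate raman --config raman.yaml --seed 1 --out spectrum.csv

# analyze
dibkit estimate-pf  --traj traj.csv --conditions cond.yaml --method ode_fit
dibkit summarize-pf --glob 'traj_*.csv' --conditions cond.yaml --out summary.csv
dibkit analyze-dsc  --in thermogram.csv --pre -38:-30 --post -6:-1 --out metrics.json
dibkit analyze-raman --in spectrum.csv --out ratios.csv

# full study (conditions × assays, report tables + manifest)
dibkit run --config study.yaml
```

`cond.yaml` holds the osmotic conditions (`osmolality_1`, `osmolality_2` in
osmol/L, optional `v_w` in cm³/mol). Generator configs mirror the
`DIBSimConfig` / `DSCSimConfig` / `RamanSimConfig` dataclass fields.

### File formats

* Trajectory CSV: `time_s, R1_um, R2_um, rc_um` (header mandatory).
* Thermogram CSV: `temp_C, heatflow_mW` + JSON sidecar with
  `scan_rate_C_per_min` and `sample_moles`. Heating scans, endotherm-up.
* Spectrum CSV: `wavenumber_cm1, intensity`.
* Image stacks: multi-page TIFF (or a directory of PNGs) + JSON sidecar with
  pixel size, timestamps and generator ground truth.

## Conventions

* Osmolality measured in mOsm/kg is converted to osmol/L with an explicit
  density convention (default 1 kg/L); `mosm_per_kg_to_osmol_per_l` makes the
  conversion visible.
* The flux law is `dV1/dt = -P_f · v_w · π·rc² · (c2 - c1)` with per-droplet
  solute amounts conserved; droplet shrinkage geometry is selectable:
  `constant_contact_radius` (default) or `constant_contact_angle`.
* Measurement noise is additive Gaussian on the sphere radii.
* Raman band intensity is peak height (local maximum within ±10 cm⁻¹ of the
  nominal centre), not integrated area.

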