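# dermvbe

Mechanistic dermal absorption modelling and virtual bioequivalence (VBE)
trial simulation for topical drug products, worked end to end on a 0.25%
desoximetasone spray.

The pipeline covers:

* **formulation** — quantitative composition (Q2) and quality attributes
  (Q3): primary/tertiary composition, volume-weighted mixture density,
  continuous-phase fractions, Stokes–Einstein vehicle diffusivity, and
  zero-order evaporation ("metamorphosis") of the volatile fraction.
* **skin** — a 1-D multilayer permeation model: vehicle film, N
  stratum-corneum layers with parallel lipid/transcellular pathways, viable
  epidermis and dermis, terminating in a Franz-cell receptor sink (IVPT) or
  perfusion-limited dermal uptake into a two-compartment systemic model
  (in vivo). Linear, mass-conservative, integrated by piecewise matrix
  exponentials with a stiff-ODE cross-check.
* **ivpt** — Franz-cell study simulation with tape-strip accounting, and a
  reproducible two-stage calibration of the two free transport parameters
  (SC-lipid:vehicle partition coefficient and corneocyte permeability) to
  cumulative receptor profiles and end-of-study local amounts.
* **systemic** — in vitro–in vivo extrapolation with dermal blood flow,
  vasoconstriction scaling (flow ∝ capillary radius² × perfused fraction),
  multi-application dosing schedules and wipe-off events.
* **trials** — lognormal virtual populations, NCA (Cmax, AUC_last, AUC_inf,
  λz), parallel-design BE statistics (90% CI vs 80–125%), power analysis,
  formulation safe-space sweeps and physiology × dose scenario matrices.
* **synthdata** — synthetic replicate-level "observed" IVPT datasets
  (monotone cumulative curves, lognormal noise, optional outlier replicate)
  and the full YAML fixture suite, so everything runs offline.

## CLI

```sh
dermvbe formulation report --out composition.csv
dermvbe synth fixtures --outdir fixtures/
dermvbe synth ivpt --seed 1 --outdir observed/
dermvbe ivpt run --out receptor.csv
dermvbe ivpt calibrate --receptor observed/ivpt_receptor.csv \
    --local observed/ivpt_local.csv --drop-replicate 2 --mask-times 4
dermvbe vbe run --seed 1 --n-per-arm 40 --out trial.csv
dermvbe vbe power --seed 1 --n-grid 10,20,40 --out power.csv
dermvbe vbe safespace --seed 1 --parameter solubility \
    --values 0.1,0.3,0.5,0.7,1.0 --out safespace.csv
dermvbe vbe matrix --seed 1 --bounds "solubility:0.4:0.7" --out matrix.csv
```

Options default to the packaged desoximetasone spray example; pass
`--formulation/--physiology/--compound/--dosing` YAML files (in the dialect
written by `dermvbe synth fixtures`) to override.

## Conventions

Amounts mg, volumes ml, lengths µm in configs (cm internally), time h,
permeabilities cm/h, concentrations mg/ml; compositions stored as fractions,
reported as percent.
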