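# vigsa — global sensitivity analysis of vegetation indices

Vegetation indices (NDVI, GNDVI, water and LAI indices, …) are designed to
track one vegetation property — leaf chlorophyll content, leaf water
content, or leaf area index — but every index also responds to the other
leaf and canopy variables that shape a reflectance spectrum.  `vigsa`
quantifies that robustness: it runs variance-based global sensitivity
analysis over coupled leaf–canopy radiative-transfer simulations and
reports, per index and per model variable, the fraction of the index's
variability each variable drives.

For a model `y = f(x1 … xk)` with inputs rescaled to the unit hypercube,
the first-order and total-effect Sobol' indices

    Si  = V[E(y | xi)] / V(y)
    STi = E[V(y | x~i)] / V(y)

are estimated simultaneously with the radial (Saltelli) scheme: two
independent N×k Sobol'-sequence matrices **P**, **Q** and k hybrid
matrices `PQ(i)` (P with column i from Q), for exactly `N(k+2)` model
runs.  Spectra are simulated once per design row and reused for every
index and for per-wavelength analysis.

The package ships:

- **sampling / estimators** — quasi-random radial designs, the Si/STi
  Monte Carlo estimators with degenerate-output and invalid-row handling,
  convergence scanning, and analytic benchmarks (Ishigami, g-function,
  linear forms) with closed-form indices plus an independent double-loop
  oracle for cross-checking;
- **radiative transfer** — a PROSPECT-4-style plate model for leaf
  optics, a 4SAIL turbid-medium canopy for homogeneous scenes (1-nm grid,
  2101 bands) and an INFORM-style geometric-optical forest scene (5-nm
  grid, 421 bands), with default variable bounds for an 8-variable
  homogeneous and a 12-variable forest configuration.  The bundled
  spectral coefficient table is *synthetic* (analytically generated from
  the known absorption physics — see `docs/methods.md`); real coefficient
  tables and soil spectra can be loaded from plain-text files;
- **sensors** — band settings and Gaussian/boxcar/tabulated spectral
  response convolution for Landsat 8, MODIS, Sentinel-2, Sentinel-3
  (OLCI+SLSTR) and a 230-band EnMAP layout, with per-sensor
  role-to-band maps;
- **index registry** — a parser/evaluator for index expressions over band
  roles and explicit `rho(λ)` terms, and ~35 published chlorophyll-,
  water- and LAI-sensitive indices with their sensor applicability.

## Worked example

Which variables drive NDVI in a homogeneous crop canopy versus a forest?

```python
from vigsa import RunConfig, run_vi_gsa

for model in ("PROSAIL", "PROINFORM"):
    config = RunConfig(model=model, N=500, vi_list=["NDVI"])
    r = run_vi_gsa(config).results["NDVI"]
    shares = dict(zip(r.variable_names, 100 * r.sti_shares()))
    ...
```

prints (see `examples/forest_vs_crop_ndvi.py`):

```
PROSAIL: NDVI variability shares (%), 5000 runs
         LAI  43.9
         Cab  30.1
         LAD  17.1
  soil_coeff   4.1
         SZA   3.3
          Cm   1.2

PROINFORM: NDVI variability shares (%), 7000 runs
         Cab  44.8
        LAIu  25.6
          CD  12.3
          SD   6.7
  soil_coeff   3.3
        LAIs   2.2
          Cm   2.1
         LAD   1.5
         SZA   1.0
```

In the crop scene NDVI is split between canopy density (LAI) and
chlorophyll; in the forest scene the structural variables — understory
LAI, crown diameter, stem density — absorb what LAI carried, tree height
does nothing at nadir, and chlorophyll remains the single largest driver.
Each number is that variable's share of the index's total-effect
variability; the runs used 500 samples per variable (the standard study
size is 2000).

Other entry points: `run_spectral_gsa` (per-wavelength STi over the full
400–2500 nm range), `convergence` (STi trajectories vs sample size),
`convolve_to_sensor` / `builtin_registry` / `evaluate_vi` for working with
sensors and indices directly, and one short script per capability under
`examples/`.

A thin CLI wraps the same workflow:

```
vigsa run --config cfg.yaml
vigsa spectral --config cfg.yaml
vigsa convergence --config cfg.yaml --n-grid 250,500,1000,2000
vigsa list-indices --sensor Sentinel2
vigsa list-sensors
```

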