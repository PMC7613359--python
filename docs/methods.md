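# Methods

`vigsa` quantifies how robust a vegetation index (VI) is to the leaf and
canopy variables that drive top-of-canopy reflectance.  It does so with
variance-based global sensitivity analysis (GSA): every input variable of a
radiative-transfer model (RTM) is varied jointly over its full physical
range, the model output (a reflectance spectrum, then each VI computed from
it) is treated as a random variable, and the fraction of its variance
attributable to each input is estimated.

## Sensitivity estimators

For a model `y = f(x)`, `x = (x1 … xk)` rescaled to the unit hypercube, the
first-order Sobol' index of variable i is

    Si = V[E(y | xi)] / V(y)

and the total-effect index

    STi = E[V(y | x~i)] / V(y)

(`x~i` = all variables except i).  Si measures the variance the variable
drives on its own; STi adds every interaction it takes part in, so
STi ≥ Si.  Both are estimated simultaneously with the radial (Saltelli)
Monte Carlo scheme: two independent N×k unit-hypercube matrices **P** and
**Q** are drawn as the left/right halves of one N×2k low-discrepancy Sobol'
sample, plus k hybrid matrices `PQ(i)` equal to **P** with column i taken
from **Q**.  With `f(P)`, `f(Q)` and `f(PQ(i))` in hand,

    f0 = mean f(P),   V = mean f(P)^2 − f0^2
    Si  = (1/N)  Σj f(Q)j  (f(PQ(i))j − f(P)j) / V
    STi = (1/2N) Σj (f(P)j − f(PQ(i))j)^2      / V

for a total of exactly `N(k+2)` model runs shared by all k variables and by
every VI computed from the same spectra.

Numerical choices:

- The Sobol' generator is unscrambled and skips the initial all-zeros
  point, so the default design is reproducible without a seed; seeds only
  affect the pseudo-random and Latin-hypercube schemes.
- Finite-N first-order estimates can be slightly negative; raw values are
  preserved (`Si_raw`, `STi_raw`) and clipped-to-zero values reported,
  since stacked-share plots and percentage statements presume nonnegative
  indices.
- An output variance below `1e-12 × max(1, f0²)` marks the output
  degenerate; all indices are reported zero with a flag.
- A VI with a guarded denominator (|den| < 1e-9) yields NaN for that
  simulation; the estimator then drops that design row across **P**, **Q**
  and all radial blocks jointly, keeping the row pairing the estimators
  require.  Excluded counts are logged in the run manifest.
- Because STi values need not sum to one, "variable i drives X % of the
  index's variability" statements use the normalized shares
  `STi_i / Σj STi_j`; per-variable percentages quoted alone are raw
  `100·STi`.

Correctness is established against analytic benchmarks with closed-form
index values (additive linear forms, the Ishigami function, Sobol's
g-function) and against an independent brute-force double-loop estimator of
`V[E(y|xi)]` that uses plain pseudo-random sampling, so its Monte Carlo
error is uncorrelated with the radial estimator's.

### Convergence scanning

Stability in N is assessed by building the design once at the largest
requested N and applying the estimators to its leading prefixes — under the
nested Sobol' sequence the length-N prefix *is* the design of the smaller
run, so one simulation pass yields the whole trajectory.  With the default
bounds, NDVI total-effect trajectories change by less than 0.02 per step
from roughly 1000–1500 samples per variable; the standard run size is 2000,
i.e. 20,000 model runs for the homogeneous canopy model and 28,000 for the
forest model.

## Radiative transfer models

**Leaf (PROSPECT-4).**  The leaf is N stacked elementary plates; per
wavelength the plate absorption mixes the specific absorption coefficients
of chlorophyll a+b (Cab, µg/cm²), water (Cw, cm) and dry matter (Cm,
g/cm²), divided by the structure parameter N.  Plate transmissivity uses
the exponential-integral slab solution, interface reflectance Stern's
average transmissivity of a dielectric interface (incidence cone 40° at the
top surface, 90° inside), and the N-plate stack the Stokes doubling
relations, with the non-absorbing `r + t → 1` limit handled explicitly.
Output: reflectance and transmittance on the 1-nm 400–2500 nm grid
(2101 samples).

**Homogeneous canopy (4SAIL).**  A four-stream turbid-medium model over a
Lambertian soil: direct solar and view-direction fluxes plus two diffuse
hemispherical fluxes.  The mean leaf inclination angle (LAD, degrees) is
converted to a 13-class leaf inclination distribution through Campbell's
ellipsoidal parameterization.  The hot-spot single-scattering correction
uses the standard exponential gap-correlation integral (hot-spot parameter
0.01).  Observation is fixed at nadir with zero relative azimuth and zero
diffuse irradiance fraction; the solar zenith angle is a sampled variable.
The soil background is a single bundled dry-soil reference spectrum
multiplied by a scalar brightness coefficient in [0, 1] (two-spectrum
mixing can be substituted by passing a custom soil spectrum).

**Forest canopy (INFORM-style hybrid).**  The forest couples the
turbid-medium solver with a geometric-optical scene mixture on the 5-nm
grid (421 bands; leaf spectra and soil are block-averaged from 1 nm before
the canopy stage):

1. understory: 4SAIL at the understory LAI (LAIu) over the soil, with a
   fixed spherical leaf-angle distribution;
2. crown layer: 4SAIL at the single-tree LAI (LAIs) over the understory
   background, with the sampled LAD;
3. scene mixture: crown cover at nadir follows Poisson crown overlap
   `co = 1 − exp(−SD·πCD²/4 /10⁴)` (SD stems/ha, CD crown diameter in m),
   the crown-shadow fraction the same with projected area scaled by
   1/cos(SZA).  A shadow is visible only once its offset `H·tan(SZA)`
   clears the casting crown.  Shadowed understory is lit only through
   crowns (factor `exp(−ks·LAIs)`).

The Poisson overlap (rather than a hard cap) keeps crown geometry
influential in dense stands, and confining the sampled leaf angle to the
crown layer reflects the convention that the understory has its own, fixed
angle distribution.  Tree height consequently enters only through shadow
visibility and has next to no effect at nadir — consistent with the
reported behaviour of this model family.  Limits built into the tests:
vanishing crowns (SD→0.5, CD→0.1) recover the understory-only scene, and
additionally zero understory recovers bare soil.

**Toy model.**  A data-free closed-form canopy: flat 0.5 baseline minus one
Gaussian absorption feature (σ = 40 nm, amplitude 0.35) per parameter,
linear in each parameter at its feature center.  It makes the entire
sampling → model → sensor → index → estimator chain testable with known
sensitivity structure (including exact dummy variables).

### Spectral coefficients are synthetic

Real PROSPECT-4 calibration tables are not bundled.  The default
coefficient table is generated analytically from features whose positions
and magnitudes follow the known physics: chlorophyll absorption peaks near
430 and 670 nm (≈0.1 cm²/µg) vanishing past the red edge; water absorption
with the pure-water magnitudes (weak 970/1200 nm overtones, ≈29 cm⁻¹ at
1450 nm, ≈120 cm⁻¹ at 1940 nm, rising continuum to 2500 nm); dry matter
rising into the SWIR with features near 1730/2100/2300 nm; refractive
index declining from ≈1.52 to ≈1.41.  A loader accepts real tables
(CSV/whitespace, columns `wavelength_nm, refractive_index, k_Cab, k_Cw,
k_Cm`, optional SHA-256 verification), and a two-column soil spectrum can
replace the synthetic soil.

What this implies for the tests: the qualitative attribution structure
(chlorophyll rules the visible, water the NIR/SWIR, structure the scene
composition) is faithfully reproduced, and most headline percentages land
within a few points of published values, but exact numeric agreement is not
expected — the synthetic table is not a measured calibration, and the
sensor response functions are Gaussian approximations built from
center/FWHM rather than the (unpublished) tabulated responses.

## Sensors and indices

Bundled band settings cover Landsat 8 OLI, MODIS (reflective bands ≤ 2500
nm), Sentinel-2 MSI, Sentinel-3 (OLCI + SLSTR as one logical sensor) and a
nominal EnMAP layout (89 VNIR bands at 6.5 nm + 141 SWIR bands at 10 nm =
230 bands, placed so the conventional role wavelengths fall exactly on
band centers).  Convolution uses a normalized Gaussian SRF from
center/FWHM by default (boxcar or tabulated responses optional).  Thermal
bands are outside the simulated range and omitted.

Index formulas are text expressions over role symbols (BLUE, GREEN, RED,
RedEdge, NIR, SWIR) and explicit `rho(λ)` terms.  Role-to-band maps are
bundled per sensor and user-overridable.  `rho(λ)` resolves to the nearest
grid point on continuous grids and to the nearest band center on sensor
band sets, rejected beyond 100 nm — an index is offered for a sensor only
if it is conventionally applied to it *and* every referenced band
resolves, so e.g. a 1240-nm water index is refused on Landsat 8 rather
than silently approximated.  Indices whose typeset sources are ambiguous
are shipped in the canonical form of their original publications with the
ambiguity recorded in their metadata; where distinct variants exist for
different band sets (leaf-water index 2) both ship under distinct names.

## Design choices and limitations

- Only uniform marginals with the three schemes (Sobol', pseudo-random,
  Latin hypercube) are implemented; non-uniform marginals would be an
  inverse-CDF transform of the unit samples and are out of scope.
- Point estimates only; no bootstrap confidence intervals.
- Pairwise interaction indices are not estimated separately — first-order
  and total effects bracket them.
- The forest model is this package's own SAILH+FLIM-style coupling, not a
  line-by-line port of any published code; its NIR plateau retains more
  turbid-medium (leaf-angle and water) influence than the original forest
  implementations appear to show, which is visible in the two
  forest-scene checks the acceptance suite leaves failing.
- Problem sizes: the standard run is 2000 samples per variable (20,000 /
  28,000 model runs, about one/one-and-a-half minutes each on a single
  CPU); estimator benchmarks use 2^13–2^14 samples.
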