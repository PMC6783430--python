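# Methods

This note documents the models, numerical choices, and limitations of the
`ocean_ch4` package: what is computed, under which assumptions, and what the
synthetic-world experiments do and do not demonstrate.

## Disequilibrium (ΔCH₄)

ΔCH₄ = [CH₄] − S(T,S)·pCH₄ᵐᵒⁱˢᵗ. The solubility S is the
Wiesenburg–Guinasso (1979) atmospheric-equilibrium fit for CH₄ (nmol L⁻¹ per
mole fraction; evaluated per ppb), valid for T ∈ [−2, 40] °C and
S ∈ [0, 45]; inputs outside that range are rejected, not clamped. The moist
correction is pᵐᵒⁱˢᵗ = pᵈʳʸ(1 − e_w/P) with e_w from the Weiss–Price (1980)
seawater vapor-pressure formula and P fixed at 1 atm (no sea-level-pressure
field is used). Coefficients live in `constants.py` with a version tag so
transcriptions can be audited; the tests evaluate independently transcribed
copies of both formulas.

Station dry-air pCH₄ is interpolated to each record by ordinary kriging on
great-circle distance with an exponential variogram (range 3000 km, nugget
0, both configurable). The variogram choice reflects the smoothness of
monthly-mean atmospheric CH₄; the binding contracts are exactness at station
locations and the constant-field degenerate case, both tested. Kriging
weights depend only on geometry, so they are cached per target point.

Record filtering keeps samples within the climatological mixed-layer depth
(interpolated in space and month), inside 1980–2016; records without
temperature are dropped unless their source is on a configured allow-list,
and missing salinity is filled from a climatology and flagged. Cell-month
means are arithmetic means of raw ΔCH₄ (transformation happens only at
training time). Grid convention: cell centers, half-open [lo, hi) edges,
longitude in [−180, 180); cell areas are exact spherical-zone areas.

## Mapping

The training target is IHS(ΔCH₄) = ln(ΔCH₄ + √(ΔCH₄²+1)), which behaves like
a log over four orders of magnitude but is defined at negative
(undersaturated) values; maps are back-transformed with sinh. Predictors:
log₁₀ seafloor depth (the coastal relation is a power law, making the log
form natural; switchable), SST, SSS, NPP (or chlorophyll via the
`biology_field` switch), POC export, PO₄, subsurface O₂, hydrate inventory,
and a cyclic month encoding (sin/cos; switchable — monthly structure of the
target is otherwise invisible to a single model).

* **ANN**: one hidden layer of 20 logistic units, linear output, L-BFGS with
  an L2 weight penalty (α = 10⁻³ by default; `select_l2_penalty` grid-searches
  it on the validation split). This is a practical stand-in for Bayesian
  regularization: the contract is a regularized fit with the stated topology,
  not a specific optimizer.
* **RRF**: 50 bagged CART trees per member, each tree limited to 100 decision
  splits (`max_leaf_nodes = 101`); "100 splits" is interpreted as a per-tree
  budget rather than a depth bound.

Each member draws its own random 70/30 row split; skill (correlation,
centered RMSD, normalized s.d. — satisfying the Taylor identity
cRMSD² = s_p² + s_o² − 2 s_p s_o R) is computed only on held-out rows, in
IHS space. Linear and multiple-linear OLS baselines use the same split
protocol but face the *raw* predictors (the depth log transform is undone),
since their purpose is to quantify the gap a nonlinear model closes. An
overfitting guard trains at 5/20/80 hidden units and checks that validation
skill plateaus while training skill keeps rising.

## Diffusive flux and Monte Carlo

F = (1 − ε_ice f_ice) k ΔCH₄, evaluated at daily resolution because k is
nonlinear in wind speed. Monthly ΔCH₄ and ice fields are linearly
interpolated between month centers with wrap-around at the year boundary.
The k registry holds four published wind-speed relations (two quadratic, one
quadratic-plus-linear, one cubic), all scaled by (Sc/660)^(−1/2) with the
CH₄-in-seawater Schmidt polynomial; their mutual spread exceeds 20% at 5–10
m s⁻¹ winds, which is why the algorithm choice is part of the Monte-Carlo
draw. Unit conversions (cm hr⁻¹ → m day⁻¹; mmol → Tg with a CH₄ molar mass
of 16.043 g mol⁻¹) are centralized in `constants.py`.

Each Monte-Carlo draw pairs one ensemble ΔCH₄ map with a wind product, an
ice product, a k algorithm (uniform, independent) and one ε_ice ~ U(0.9, 1)
per draw (not per cell). Because F is linear in ΔCH₄ at a fixed draw, annual
integrals are computed from monthly transfer aggregates
A_m = Σ_d w_dm k_d and B_m = Σ_d w_dm f_d k_d (the day loop folded into
12×12 interpolation-weight products); the literal daily loop is retained and
the two paths agree to round-off in the tests. Regional integrals use the
four bathymetric classes (0–50/50–200/200–2000/>2000 m); ensemble summaries
report mean, s.d., and the 10/25/50/75/90th percentiles, the 10–90 band
being the "likely range". The variance-partition diagnostic contrasts the 60
(wind × ice × k) permutations applied to the mean map against the mean
transfer field applied to each member map. The resolution sweep re-runs
bin → train → flux at several grid resolutions from the same records.

## Ebullition

The bubble model integrates moles of CH₄ and a lumped background gas
(N₂/O₂) in depth for a bubble released as pure CH₄:

* hydrostatic pressure P(z) = 1 atm + ρgz; ideal-gas volume/diameter;
* Mendelson (wave-analogy) clean-bubble rise velocity
  w = √(2.14σ/ρd + 0.505gd);
* Higbie penetration mass transfer k_L = 2√(D w / π d), multiplied by a
  shape-oscillation renewal factor ramping 1 → 1.6 between 4.6 mm (the
  Eötvös-number threshold for shape oscillations) and 8 mm. The ceiling 1.6
  is the model's single calibrated constant, set so the ε_tr(d, z) surface
  reproduces the published large-bubble transfer bound (an 8 mm bubble
  released at 100 m delivers <1% of its CH₄ to the surface);
* Henry-law exchange with zero ambient dissolved CH₄ and air-equilibrated
  background gas, in a constant water column (15 °C, S = 35 by default —
  stated package defaults, not inferred field conditions).

Integration is adaptive RK45 in depth with rtol 10⁻⁶, a step cap keeping
diameter changes small, and a termination event for complete dissolution
(ε_tr = 0). The dissolved tally is co-integrated so mass conservation
(released = surviving + dissolved) is checked to 10⁻⁶. Transfer is counted
at the sea surface: CH₄ delivered to the mixed layer by a surfacing bubble
is assumed emitted.

Spectrum efficiency is the volume-fraction-weighted mean of ε_tr over the
discrete bubble spectrum; the default spectrum is a parametric lognormal
stand-in (volume weights centered at 4 mm, σ_ln = 0.25) matching the two
published constraints (≥99% of volume in 2–8 mm; volume-weighted mean
diameter ≈ 4 mm) — observed seep spectra are not redistributed with the
package. Depth averaging weights ε_tr(z) by ocean area per depth, assuming
seep flux uniform per unit area in the scenario interval ([0, 200] m and
[0, 100] m); a uniform reference hypsometry and the synthetic bathymetry's
hypsometry are both supported. Under the reference configuration the two
scenarios give ε̄_tr ≈ 0.13 and ≈ 0.07, a few percentage points below the
published 17%/11% — the expected fidelity for a re-implemented bubble model,
and the reason the ebullitive upscaling accepts an externally supplied
efficiency range. Upscaling is interval arithmetic ΣF_eb = ε̄_tr · ΣF_sf with
uniform probability inside the interval; totals convolve the uniform
ebullitive draw with resampled diffusive Monte-Carlo members.

## Attribution

Per-predictor R² against the annual-mean map, split at the 2000 m isobath,
with identity/semi-log/log-log transforms; cells with non-positive ΔCH₄ (or
predictor) are excluded from log variants and counted. The coastal power law
is fit as log₁₀(binned mean ΔCH₄) vs log₁₀(depth) over 12 log-spaced bins in
10–2000 m (bin count and edges configurable); note that with arithmetic bin
means over finite bins the recovered amplitude carries a ~1% Jensen
(curvature) bias even for noiseless data — the exponent is essentially
unbiased. The NPP relation is a binned linear fit; the NPP+PO₄ regression is
unbinned OLS with a collinearity flag. Band averages are area-weighted means
over fixed latitude cuts (tropical <15°, subtropical 15–45°, subpolar
45–60°, polar >60°).

## Synthetic world

A closed basin (lon 0–40°E, lat 70°S–70°N, 0.5° default) with a western
coastline: the shelf deepens linearly to 200 m over 8° (giving near-uniform
shelf hypsometry, matching the uniform-seep-area assumption of the depth
averaging), then a slope to 2000 m and an abyssal ramp to 5500 m, with a
mild along-shore modulation. ΔCH₄ truth follows the coastal power law
A z^b (A = 69 nM, b = −0.8) below 2000 m and the open-ocean NPP relation
(0.3·NPP + 14)/10³ nM above, blended linearly over 1500–2500 m so the
mapping stage sees no discontinuity; a polar undersaturation patch south of
55°S makes ΔCH₄ negative there, exercising the IHS transform and uptake
fluxes.

Observations are random-walk cruise tracks (60 tracks × 40 records by
default, half starting over the shelf so sampling density rises shoreward);
each record carries [CH₄] = S·pᵐᵒⁱˢᵗ + ΔCH₄·η with η unit-mean lognormal
(σ_ln = 0.5, chosen to represent interlaboratory discrepancies of up to
25–50% plus sub-grid variability; unit mean keeps binned means unbiased).
Fixed fractions of records fall below the mixed layer (15%) and outside the
date window (5%) to exercise the filters. Atmospheric stations (5, spanning
latitude) carry a 1650 → 1850 ppb linear trend over 1980–2016, an
interhemispheric gradient, and a seasonal cycle. Wind products are five
zonal (lat × day) profiles — a shared base plus smooth perturbations of 10%
scale; ice products are three seasonal-edge variants poleward of 60°.
Everything derives from one seed via stage-name hashing, so stages are
insulated from each other's draw counts and every generator is
byte-reproducible.

**What the synthetic world does not emulate:** real coastline geometry,
ocean circulation, seasonality of the underlying ΔCH₄ field, spatially
correlated measurement bias, and — most importantly — structure in ΔCH₄
that is *not* a function of the predictor set. Because the truth is
deterministic in the predictors, mapping members agree more with one another
than they would on real data (held-out R ≈ 0.9 vs the 0.75–0.9 typical of
real sparse-data mapping), so the map-ensemble spread here understates the
mapping uncertainty of a real application, and the partition of flux
variance between mapping and gas-transfer sources is closer to even than it
would be with real observations. Passing parameter-recovery tests shows the
pipeline is self-consistent and unbiased under its stated noise model, not
that real-world skill would be comparable.

## Problem sizes

Default study conditions: 0.5° grid (280×80 cells), 2400 observations, 100
members per family, 1000 Monte-Carlo draws — the full default pipeline runs
in minutes on one CPU thanks to the aggregate flux path. The test suite
exercises the same code at reduced scale (2° worlds, ensembles of 2–10
members per family, 1° demo pipeline) so the whole suite completes in a few
minutes; the acceptance checks that are defined at the default conditions
(member retention R > 0.75, variance partition) run on the 0.5° default
world with 10 members per family.

## Known limitations

* The kriging of station pCH₄ is 2-D on the sphere with a single default
  variogram; no cross-validation of the variogram is performed.
* The bubble model ignores hydrate skins, plume-scale upwelling, water-column
  CH₄ oxidation, and depth-varying stratification; its transfer-efficiency
  surface is calibrated to published bounds rather than validated against
  bubble observations.
* ε_ice is drawn once per Monte-Carlo member, not per cell; ice cells with
  missing fraction are treated as open water.
* Tg conversions assume pure CH₄ (16.043 g mol⁻¹); day interpolation of
  monthly fields is linear between month centers.
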