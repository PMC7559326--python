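# Methods

## Scope and model

`surfilm` treats one physical situation: a protein monolayer deposited
on silica, then exposed to a non-ionic ethoxylated surfactant, probed
in parallel on a flat SPR sensor and on colloidal beads by DLS and
electrophoresis. The package's job is the *common currency*
conversion — everything else (transfer-matrix optics, cumulant
analysis, isotherm fitting, Smoluchowski ζ) is standard machinery
implemented so the conversion chain is complete and testable.

The film is assumed incompressible, homogeneous, and identically
hydrated on the flat and curved surfaces (six waters per EO group,
taken concentration-independent). The curvature correction
`V/A = d(1 + H_c d + K_c d²/3)` is exact for spherical shells —
verified in the test suite against `((R+d)³−R³)/(3R²)` over a (d, R)
lattice at 1e−9 relative — and curvatures are evaluated at the inner
(bead) surface.

## SPR branch

* **Stack defaults.** BK7 prism n = 1.52; 50 nm gold with literature
  complex index 0.14+3.7i (670 nm) / 0.17+4.9i (785 nm); 10 nm silica
  n = 1.46; buffer n₀ = 1.334. All configurable; every report echoes
  the constants table it used.
* **Adlayer index fixed** (1.52 protein, 1.45 surfactant): thickness
  and index are degenerate in a single-wavelength fit, so only *d* is
  free, bounded to [0, 100] nm. A 201-point coarse grid brackets the
  optimum before bounded scalar refinement (xatol 1e−7 nm); a misfit
  that decreases monotonically into the bound raises a convergence
  error with diagnostics instead of returning the edge.
* **Angle features.** TIR = maximum of dR/dθ with 3-point parabolic
  refinement; resonance minimum = 3-point parabola around the grid
  argmin; boundary minima return the edge value with a warning.
  Synthesis grid 50–77.5° at 0.01°, matching the acquisition range of
  the instrument class.
* **Plateau detection.** Per injection, candidate windows (default
  60 s) are scanned backwards from the end of the buffer phase; the
  first with |linear slope| < 1e−4 °/s wins. No stated criterion exists
  for this in the source workflow, so both parameters are explicit and
  configurable; never-stable segments are returned flagged, not
  dropped.
* **Units.** Thickness nm, coverage ng/cm², optics concentration
  g/cm³; the ng/cm² conversion in the De Feijter step is
  Γ = 100·D₀[nm]/(dn/dC)[cm³/g].

## DLS branch

* q is computed from a 173° backscatter geometry, λ = 633 nm,
  n = 1.33 (typical of the instrument class; configurable). Water at
  25 °C: η = 0.89 mPa·s, T = 298.15 K.
* **Cumulant fit**: weighted quadratic polynomial in lag on
  ln(g₂−1), using only the leading contiguous decay above 5% of the
  initial amplitude — points beyond the first floor crossing are
  noise-dominated and would otherwise destabilise the µ₂ term.
* **Inversion**: non-negative least squares on a 64-point log-spaced
  1–5000 nm exponential dictionary with Tikhonov damping; α defaults
  to an L-curve curvature maximum over 1e−6…1. Off-grid true sizes are
  representable only to half a grid cell; recovery tests therefore
  ask for mode indices within one cell of the nearest grid point.
* Intensity weighting of synthetic multimodal populations is taken as
  given (fractions of scattered intensity); the Rayleigh r⁶
  number→intensity conversion is *not* applied to micron-scale
  aggregates, where it would be a poor approximation — the
  aggregation-size profile is declared phenomenological (a log-normal
  bell peaking at the half-saturation concentration and relaxing to
  the coated-bead size) and carries no mechanistic claim about
  bridging flocculation.

## Isotherm fitting

Linear response space, optional 1/σ² weights, five seeded starts with
K-type parameters initialised on a log grid spanning the data range
(affinities span decades), `scipy.optimize.least_squares` with tight
tolerances. Standard errors come from the jacobian at the optimum
scaled by RSS/dof; **confidence intervals use Student-t quantiles**
with the fit's residual dof — with ~10-point series the normal
quantile visibly undercovers. With multiplicative noise, weights
σ ∝ y are the statistically matched choice and are what the
Monte-Carlo recovery tests use. Model choice is reported via AIC; both
Sips and BET fits are recorded rather than one being silently
preferred. The Sips heterogeneity index is capped at 1 (a heterogeneous
surface broadens the isotherm); an explicit flag lifts the cap for
Hill-type cooperative use. The BET form diverges at K_ml·c = 1 and
inputs at or beyond the divergence raise a domain error.

## Synthetic scenario (what it emulates, what it does not)

Defaults: 30 nm beads + 7 nm protein monolayer → 44 nm coated
diameter, curvature radius R = 20 nm; protein adsorption Sips with
n = 0.7, half-saturation 12 µM, saturation 450 ng/cm²; surfactant
multilayer BET with q₁ = 12 nm, K_L = 100 L/mol, K_ml = 3.55 L/mol —
chosen once so the dry coverage at 2 wt% is in the 460 ng/cm² class and
the planar-equivalent film at 9 wt% is ~32 nm; dn/dC 0.186 cm³/g
(protein) and 0.131 cm³/g (ethoxylate); mobilities −2.43 and
−0.84 µm·cm/(V·s). Noise models: multiplicative Gaussian on
reflectivity, additive Gaussian (2e−3 default) on g₂−1, exponential
association/rinse transients (τ = 20 s) on sensograms. Fixed seed ⇒
byte-identical files.

The generator produces monodisperse coated beads, perfectly stable
plateaus, no drift unless asked, no multiple scattering, no vendor
smoothing. Passing recovery tests therefore demonstrates correctness
of the analysis chain, not robustness to every instrumental artefact;
mean sizes from real instruments pass through proprietary analysis the
package does not attempt to reproduce.

## Problem sizes

The default test and acceptance runs use 10-point isotherms, 200-lag
ACFs, 200-replicate Monte-Carlo recovery at 5% noise, 50-replicate
thickness-fit noise studies on a 0.05° angle grid, and the full
synthetic scenario (12 scans, 12 traces). These sizes make every
statistical check stable at three-significant-figure level while a
full run of suite plus acceptance script completes in about a minute.

## Known limitations

* Single-wavelength SPR: d and n cannot be separated; dual-wavelength
  decomposition is out of scope.
* Smoluchowski only (κa ≫ 1); no Henry/Ohshima correction, no soft-layer
  electrokinetics.
* Intensity-basis size distributions only; no Mie or multiple-scattering
  corrections.
* The two-site fast-exchange bound-fraction operations assume a single
  exchange-averaged diffusion coefficient; they exist to show when a
  bound fraction is *undetectable* at a given precision, not to fit
  exchange kinetics.
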