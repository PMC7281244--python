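# Methods

This note records the models implemented in fibrilkit, the conventions and
defaults they use, the numerical choices behind them, and what the synthetic
data do and do not emulate.  Units are fixed package-wide: lengths in Å,
momentum transfer Q in Å⁻¹, absolute intensities (differential scattering
cross sections dΣ/dΩ) in cm⁻¹, CD signals in millidegrees, times in minutes.

## SAXS forward models

Every species carries one `scale` parameter, the forward intensity in cm⁻¹,
into which number density, contrast squared and particle volume squared are
absorbed; the species contribution is `scale · P(Q)` with P(0) = 1.  The
mixture intensity is the plain sum of species contributions plus a flat
background — the dilute-solution limit, with no structure-factor or
interparticle-interference terms.

**Sphere.** P(Q) = [3(sin x − x cos x)/x³]², x = QR.  Mostly an analytic
oracle: its radius of gyration √(3/5)·R and first zero at x ≈ 4.4934 anchor
the Guinier tests.  A Taylor series replaces the closed form for x < 10⁻²,
where the subtraction sin x − x cos x loses precision.

**Cylinder.** Orientation average P(Q) = ∫₀¹ |F(Q,u)|² du over u = cos α,
with F the product of the cross-section factor 2J₁(QR sin α)/(QR sin α) and
the length factor sinc(QL cos α/2).  The integral uses Gauss–Legendre
quadrature starting at 64 points and doubling until the pointwise relative
change is below 10⁻⁴ (cap 1024).  Radius polydispersity is a truncated
Gaussian (relative σ = `polydispersity`, truncated at R > 0; Schulz
available via `distribution="schulz"`) integrated on a 25-point trapezoid
grid over ±3σ, each radius weighted by its volume squared (larger particles
scatter their physical share) and the result renormalized so that I(0) =
scale.  A brute-force double-trapezoid oracle at ~100× resolution agrees
with the implementation to better than 0.1% for both distributions.  Inside
iterative fitting a fixed 96-point orientation rule with a 17-point radius
grid is used instead (`fast=True`), accurate to < 0.1% wherever the
intensity exceeds 10⁻⁴ of its forward value — noise floors in fitted data
sit far above that.

**Worm-like chain.** The chain factor interpolates between the Debye coil
function evaluated with the Benoit–Doty Rg of the Kratky–Porod chain,
Rg² = (Lb/6)[1 − 3/(2n) + 3/(2n²) − (3/(4n³))(1 − e^(−2n))], n = L/b,
and the rod asymptote π/(QL) + 2/(3Q²Lb) (infinitely thin rod with the
first flexibility correction), blended by the smooth switch
w(x) = [1 + tanh((x − 1.523)/0.1477)]/2 in x = Q·Rg.  This is the
parametrized coil/rod crossover family of Pedersen–Schurtenberger type,
deliberately **without** excluded-volume corrections: the chains modelled
here are dense protein aggregates, not swollen synthetic polymers, and the
simpler variant has one fewer modelling assumption.  A circular
cross-section factor [2J₁(QR_cs)/(QR_cs)]² multiplies the chain factor.
`cross_radius` is the **geometric** cross-section radius; the corresponding
cross-section radius of gyration is R_cs/√2 and is exposed as
`cross_radius_of_gyration` so either convention can be read off.
`aggregation_number` (monomers per chain) is carried as reported metadata
and does not enter the form factor — how it maps onto the forward intensity
depends on contrast assumptions the data cannot constrain.  Accuracy
contract: matches the Debye function within 5% for L ≫ b in the Q·b ≪ 1
regime, and the log-log slope reaches −1 at high Q.

**Atomic structures.** Debye double sum
P(Q) = Σᵢⱼ fᵢfⱼ sinc(Q rᵢⱼ)/(Σfᵢ)² with per-atom excess scattering lengths
f = occupancy · (Z_eff − ρ_w·V_disp), ρ_w = 0.334 e⁻/Å³.  Crystal
structures at typical resolution carry no hydrogens, so an average protein
hydrogen complement is merged into the heavy atoms (C +1.3 H, N +0.4,
O +0.1, S +0.1, with the corresponding displaced volumes); this affects the
overall contrast far more than the shape of P(Q) at small angle, which is
what the analyses use.  The hydration shell is represented by dummy
scatterers on the rolling-probe (solvent-accessible) surface: golden-spiral
candidate points at r_vdw + r_probe around each atom, buried points culled,
survivors thinned to ~one per `shell_spacing`² and displaced to mid-shell;
each dummy carries `shell_contrast` · (spacing² · thickness) electrons.
Defaults: probe 1.4 Å, shell thickness 3.0 Å, spacing 3.0 Å, contrast
+0.03 e⁻/Å³ — all overridable, since published analyses differ in these
choices.  The pair sum is exact up to 5·10⁵ pairs and switches to a
0.1 Å distance histogram beyond (relative error ≪ 0.1% for Q ≲ 0.5 Å⁻¹).

## Guinier analysis

Both Guinier laws are fitted as weighted linear regressions in log space
(ln I or ln QI versus Q²), weights (I/σ)² from propagated log-space errors,
unweighted when the curve carries no σ.  The valid window is found
iteratively: fit, evaluate Q·size at the window edge, truncate to
Q·R_g ≤ 1.3 (globular) or Q·R_c ≤ 1.0 (rod), repeat until stable; an
oscillating selection keeps the wider window, and a shrink below 5 points is
damped (halving) before the regime is declared absent.  The converged window
is then refined by trimming end points whose residuals exceed twice the
interior scatter (floor 10⁻⁴ log units) — the automated version of choosing
the straight Guinier segment by eye.  On data generated from the defining
equations the residuals vanish, nothing is trimmed, and the inversion is
exact to machine precision; on curves with systematic curvature (finite
cylinder length at low Q, form-factor curvature at high Q) the trim removes
the bias that a fixed Q·size window leaves (≈ +1.8% on a sphere, −3% on
long cylinders).  Failure to converge is itself the diagnostic output: a
fibrillated sample has no globular Guinier regime, and
`NoGuinierRegimeError` is that signal.

**Two-population rod decomposition.**  A single rod-like fit runs first;
where its residuals exceed both 3σ and a 5% systematic floor, a second
population is indicated.  Both rod-Guinier laws,
I = A/Q·exp(−Q²R_c²/2), are then fitted **jointly** by bounded multi-start
least squares (σ-weighted, or counting-statistics-shaped weights √(I·ΔQ)
when σ is absent) over the window below the thin population's Guinier
limit, iterated to self-consistency.  The classical sequential recipe —
fit the thick rods at low Q, subtract, fit the thin rods higher — fails
here by construction: below both Guinier limits every point mixes the two
slopes (the single fit of the 77/30 Å pair returns R_c ≈ 55), and near the
thick population's form-factor zero the local log-slope mimics an
arbitrarily large apparent radius, so the subtracted residual is dominated
by extrapolation error.  The joint fit recovers both radii of the
equal-forward-intensity 77/30 Å pair within 6%/1%.  Known limitation: for
monodisperse populations the Gaussian rod-Guinier law is misspecified
against the exact J₁² cylinder curve at a level far above counting noise,
and when the populations are unbalanced (forward-intensity ratios ≳ 4) or
their radii closer than ~2×, the global χ² minimum genuinely moves off the
true radii; in those configurations the method reports non-detection or
raises an ambiguity error rather than returning wrong values.  Smooth
polydisperse fibril data are kinder than the monodisperse worst case.

**Kratky classifier.** y = Q²I; label "bell" when the high-Q tail (top 25%
of the Q range) falls below half the global maximum (compact globule),
"plateau" when the tail stays within ±15% of its own mean (flexible chain),
"rising" otherwise; score = 1 − tail/maximum clipped to [0, 1].

## Mixture fitting

Free parameters are addressed by path (`species[0].radius`, `background`),
each with finite bounds containing its initial value.  The objective is
Σ[(I_obs − I_model)/σ]², minimized by bounded trust-region least squares;
multi-start draws the remaining starts from a seeded Latin-hypercube sample
of the bound box (default 8 starts; the recovery analyses use 2, which the
well-conditioned synthetic problems need at most).  Uncertainties come from
the inverse curvature (JᵀJ)⁻¹ scaled by the residual variance; the
residual-resampling bootstrap resamples **standardized** residuals
(rescaled to each point's σ) so the strongly Q-dependent counting-noise
scale survives the permutation — resampling raw residuals inflates the
spread several-fold.  Population "fractions" are shares of the total
forward intensity I(0), background excluded: mass or number fractions would
require contrast and volume assumptions the data do not determine, so the
intensity convention is used and stated wherever fractions are reported.
Model comparison ranks by total χ² + 2k (an Akaike-type penalty on the χ²
scale); failed fits stay in the report with infinite score.

## Congo-Red analysis

The β-structure proxy is A(538)/A(505), evaluated by linear interpolation
to the exact wavelengths (grids rarely contain them); it is dimensionless,
dilution-invariant, and reported raw.  Its validation decomposes the
spectrum into two Gaussian bands (centers initialized at 505/540 nm, widths
free) and compares the band **area** ratio with the band **peak-intensity**
ratio: for overlapping bands these are the quantities whose empirical
agreement licenses a simple ratio statistic, and they agree identically
when the bands have equal widths.  The raw interpolated ratio is reported
alongside but is not the equivalence partner: it mixes both bands at each
wavelength and tends to a positive constant as the bound fraction → 0,
where the area ratio tends to 0.  Kinetic traces average the ratio over
replicates per time point (s.e.m. recorded; at least nine replicates in the
emulated protocol) and demand equal replicate counts across time points.

## CD analysis

Baseline subtraction, then a natural smoothing spline (strength = the
spline penalty λ; 0 disables).  Minima are local minima of the smoothed
signal with negative value, shoulder-suppressed by a prominence threshold
of 5% of the deepest minimum.  Classification is purely band-shape-based
(no secondary-structure deconvolution, which the underlying experiments do
not support because curves are arbitrarily scaled): native-like iff minima
fall in both 204–212 nm and 218–226 nm (the α+β doublet), β-rich iff
otherwise exactly one minimum lies in 210–222 nm (the cross-β band),
indeterminate else.  The score is the depth of the shallowest classifying
minimum over the largest signal magnitude — scale-invariant, like the
label.

## Kinetics

Four-parameter logistic y = base + (plateau − base)/(1 + e^(−rate(t−t½))),
weighted by 1/s.e.m. when available; lag = max(0, t½ − 2/rate), the
tangent-at-midpoint convention standard in amyloid kinetics.  A fit is
flagged censored when the last observed point sits below 90% of the fitted
plateau or when no transition is detectable (amplitude below 5% of the data
scale) — lag and rate are then not interpretable, which prevents
meaningless estimates on blocked conditions.  Condition comparison reports
per-condition lag/rate/plateau with seeded residual-bootstrap spreads and
labels a condition "blocked" when it is censored while sitting below 20% of
the reference plateau.

## Synthetic data: what it emulates, what it does not

All generators are pure functions of (configuration, seed).

* **SAXS noise**: Gaussian with σ = noise·√(I·ΔQ) — the shape
  counting statistics imprint on azimuthally averaged detector images.  Real
  reduction artefacts (beamstop smearing, buffer-subtraction residuals,
  radiation damage) are not emulated, so passing recovery tests demonstrate
  estimator correctness under the stated noise model, not robustness to
  instrument systematics.
* **Fibrillation scenarios**: lag/rate/plateau per protein × trehalose ×
  NaCl combination live in a shipped YAML table
  (`fibrilkit/data/scenarios.yaml`), encoding the studied qualitative
  orderings — NaCl shortens the lag for both proteins; trehalose without
  salt blocks lysozyme fibrillation outright (plateau ≈ 0.02) and with salt
  only mildly slows elongation; trehalose extends the insulin lag from 80
  to ≈240 min and lowers its plateau by ≈10%, both effects erased by
  100 mM NaCl.  Keeping the table as data makes these encodings auditable
  and editable without touching code.
* **Kinetic traces** map the bound fraction to ratio units linearly,
  calibrated at the generator's own endpoints (fully-free and fully-bound
  spectra).  The real dye response is mildly convex in the bound fraction;
  emulating it would shift every generating lag by a known ≈15 min and turn
  each scenario table entry into a pair of numbers.  A linear response
  keeps the table parameters exactly the logistic parameters of the trace.
* **Congo-Red spectra**: two Gaussian bands (free 505 nm, bound 540 nm),
  equal 50 nm FWHM.  Equal widths keep the composite signal broad while
  making the band-area and peak-intensity ratios agree, the equivalence the
  ratio statistic rests on; the measured 538/505 ratio is strictly
  increasing in the bound fraction across the generator's whole range.
* **CD spectra**: linear combinations of canonical Gaussian basis bands —
  native α+β (positive 193 nm, minima 208/222 nm), cross-β (single 215 nm
  minimum), disordered coil (198 nm minimum).  Band σ of 4.5–5 nm keeps the
  native doublet resolved; real CD bands are broader and the doublet
  shallower, so the classifier's clean single switch along the
  native→β interpolation (observed at fraction ≈ 0.46) is a property of
  the basis, verified by test, not a claim about all real spectra.
* **Atomic stand-in**: `synthetic_globular_structure` is an explicitly
  synthetic globule — uniform heavy atoms with protein-like composition in
  a 24×14×14 Å ellipsoid at protein density — sized so the bare-coordinate
  Rg (≈14 Å) plus hydration shell reproduces the ≈16 Å Guinier radius of a
  lysozyme monomer.  It is used where an atomic model is needed and no
  experimental structure is available; it has no secondary structure and no
  real surface topology.
* **End-state fixtures**: the generating mixtures put dimensions the
  experiments determined (cylinder radii 40/38/60 Å with 30%
  polydispersity, worm-like cross radii 9.5/15.8/20 Å, population shares
  85/90/15/10%) together with quantities they left unconstrained and that
  the probed Q range cannot resolve — cylinder lengths (2000–4000 Å ≫ 1/Q),
  chain contour and Kuhn lengths — which are fixed at documented defaults in
  the manifest; only cross-sectional quantities are meaningful for the rods.

## Analysis problem sizes

The recovery analyses use 120-point curves on Q ∈ [0.008, 0.35] Å⁻¹ with
noise scale 0.01 and 50 seeded replicates per scenario, two optimizer starts
each; the rod-decomposition and Guinier analyses use 150–200-point curves.
These sizes put every recovered parameter's replicate spread well inside its
tolerance while keeping a full analysis run in minutes on one core.

## Known limitations

* The two-population decomposition degrades on unbalanced monodisperse
  mixtures (see above) — an information limit of cross-section Guinier
  analysis, not an implementation artefact.
* The worm-like chain crossover is a parametrization; in the crossover
  region Q·Rg ≈ 1.5 it is accurate only at the few-percent level, and no
  excluded-volume variant is provided.
* Absolute-scale calibration, 2D reduction, buffer subtraction and
  interparticle structure factors are out of scope; curves are assumed
  reduced, subtracted and dilute.
* CD analysis is band-shape classification only; it reports no secondary
  -structure percentages.
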