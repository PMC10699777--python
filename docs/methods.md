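# Methods

This note documents the models behind `n2opulse`, the defaults it ships,
what the synthetic generators do and do not emulate, and the numerical
choices that were genuinely open.

## Chamber fluxes

A closure is modelled as a well-mixed loop of volume V (chamber + sample
loop) over a collar of area A at temperature T and pressure P. The flux is
the OLS slope of the N₂O mole fraction against time over the retained
window, converted via the ideal gas law:

    F [ng N m⁻² s⁻¹] = (dC/dt) [ppb s⁻¹] · (P·V)/(R·T) · 28.014 / A

with 28.014 g N per mol N₂O (two N atoms). Conversion is exactly linear in
the slope and in V, and inverse in A.

* **Windowing.** Default deadband 30 s and fit span the remainder of a
  120 s closure (i.e. the last 90 s), both configurable. The deadband
  absorbs the mixing transient after closure.
* **Gating.** The two-sided t test on the OLS slope (identical to the test
  on the Pearson correlation for simple regression) gates fluxes with
  p > α (default 0.05) to zero; slope, R² and p are still reported. A
  perfectly flat trace is reported as slope 0, p 1, gated. On pure-noise
  closures the empirical gate size matches α (checked by simulation at
  10⁴ replicates).
* **Not modelled.** Dilution of the loop by make-up air during the short
  closure is neglected in the estimator (the generator can be extended to
  inject it to quantify the bias); nonlinear (diffusion-limited) chamber
  fits are out of scope.
* **Pulse summaries.** Peak = maximum gated flux in the window (ties break
  to the earliest closure); cumulative = trapezoid of flux against time in
  hours. Records with instrument dropouts are not interpolated; instead the
  summary reports sampling coverage and the largest gap. At 30-min sampling
  the trapezoid integrates the default pulse within 2% of dense quadrature.
* ***δ¹⁵N index.** The mean of the raw δ¹⁵N stream over the final 10 s of
  a closure. Because the loop starts full of ambient N₂O, this index is
  always pulled toward the ambient value and is reported as an arrival-time
  index, never as a source signature (the Keeling intercept serves that
  purpose).

## Isotopocules and calibration

Ratios convert to deltas as δ = (R_sam/R_std − 1)·10³ against
¹⁵N/¹⁴N(AIR) = 0.0036765 and ¹⁸O/¹⁶O(VSMOW) = 0.0020052 — standard scale
constants, shipped as package constants. SP = δ¹⁵Nα − δ¹⁵Nβ;
δ¹⁵N_bulk is the arithmetic mean of the site deltas (exact to first order
and consistent with the certified USGS values at printed precision; the
USGS 52 certified SP differs from its printed α−β by 0.01‰ — certified
values are taken as authoritative).

Laser-spectroscopic N₂O isotope analysers show concentration and CO₂
dependencies. The calibration model is deliberately explicit and linear:

    measured = b₀ + b₁·true + b₂/[N₂O] + b₃·[CO₂]

fitted per isotopocule channel by least squares on reference-gas runs
(≥2 standards × ≥3 N₂O levels × CO₂ levels), inverted for the true delta
when applied. The validity range is the calibrated concentration span;
corrections outside it extrapolate but flag the reading. The functional
form is a documented choice, swappable if an instrument needs curvature;
a rank-deficient design (e.g. a single CO₂ level) is rejected naming the
collapsed factor rather than silently dropping the term.

## Keeling plots

Two-source mixing (ambient background + soil source) makes the mixture
delta linear in 1/[N₂O]; the OLS intercept at 1/[N₂O] → 0 is the source
signature. Model I (OLS) regression is the default; with exactly two
distinct concentrations the line is exact and the intercept SE is reported
as missing. All concentrations equal is a degenerate design and an error.
Linear-in-delta mixing is an approximation — at tracer-level deltas
(thousands of ‰) the exact bookkeeping is done on the atom-fraction scale
(below), but the Keeling generator intentionally mixes linearly so that
the estimator's exactness property is testable.

## ¹⁵N tracer mass balance

Atom fraction x = R/(1+R) with R = R_AIR·(1+δ/10³). Two-pool balance:

    f_tracer = (x_mix − x_native)/(x_tracer − x_native)

with the native pool at natural abundance (x ≈ 0.0036630) and the tracer
at 2 at% (δ ≈ +4551‰) by default. Mixtures falling slightly outside
[native, tracer] from analytical noise are clipped to [0, 1] and flagged,
not raised. On the delta scale this arithmetic would be biased at such
enrichment, which is why the module converts first.

## Source partitioning

Endmember rectangles in (SP, δ¹⁵N_bulk, δ¹⁸O) space are *substrate
relative*; `build_endmembers` translates each axis by the measured
substrate signature it depends on (δ¹⁸O-H₂O for the water-derived O of
bacterial/fungal/nitrifier denitrification; δ¹⁵N of NO₃⁻, NO₂⁻ or NH₄⁺
for the N). Translation only — widths are conserved, SP is never shifted.
Defaults: δ¹⁸O-H₂O = −9‰, δ¹⁵N-NO₃⁻ = NO₂⁻ = 7.2‰ (a combined
nitrate+nitrite value), δ¹⁵N-NH₄⁺ = 0‰.

N₂O → N₂ reduction enriches the residual N₂O. Two system models:

* closed (Rayleigh distillation): δ = δ₀ + ε·ln f
* open (steady-state supply/partial consumption): δ = δ₀ − ε·(1 − f)

where f is the fraction of N₂O remaining and ε < 0. Both forms enrich the
residual in the same direction and are exactly invertible for f
(closed: f = exp(Δδ/ε); open: f = 1 + Δδ/ε, clipped to (0, 1] with a flag
when the measured shift points the wrong way). The open-system form is the
steady-state mass balance; a sign convention that depletes the residual for
ε < 0 would contradict the closed form and is not used.

**Attribution** (`classify_point`) explains an observation as an endmember
point displaced along the reduction trajectory: candidates are each box's
8 corners and centroid; for each, the residual (unweighted Euclidean in ‰
over the available axes; per-axis weights available via config) is
minimised over f on a 200-point log grid in [0.01, 1] and then refined
analytically — both system models displace along the fixed direction ε, so
the optimal f is an orthogonal projection onto that line, clipped to the
admissible interval. A reading on a trajectory therefore has residual
exactly 0, and the procedure is deterministic for a fixed grid. Missing
axes (e.g. SP-only data) are simply dropped from the distance.

**ε defaults.** Net isotope effects of N₂O reduction vary with conditions
and are not universal constants. The shipped defaults are
literature-compilation midpoints and ranges — ε_SP −5.0‰ [−8.2, −2.9],
ε15 −6.6‰ [−11.6, −1.8], ε18 −15.4‰ [−25.1, −5.1] — exposed as
configuration the user is expected to confirm or override, not asserted as
facts. Likewise the δ¹⁵N/δ¹⁸O extents of the endmember boxes (and the SP
ranges of nitrification and nitrifier denitrification) are approximate
compilation values; the SP ranges of bacterial denitrification
(−7.5 to 3.7‰), fungal denitrification (27.2 to 39.9‰) and
chemodenitrification (20.1 to 25.7‰) follow the commonly used published
compilation.

**Identifiability.** With literature-width boxes, f is not identifiable to
better than the box's extent along ε divided by |ε| — the familiar
fan of dashed reduction lines from a box's corners. The parameter-recovery
test therefore pins the generator's known starting point (zero-width box)
and shows the estimator chain recovers f within 0.1 under 2‰ noise on
the mean of 10 samples; prior-width uncertainty is quantified separately by
`partition_uncertainty`, a seeded Monte Carlo over uniform draws of
endmember points within boxes and ε within the configured ranges, whose
90% interval covers a known f in ≥85% of simulated replicates.

## qPCR

Cq = intercept + slope·log₁₀(copies); E = 10^(−1/slope) − 1 as a fraction
(E = 1 is perfect doubling, slope −3.3219 cycles/decade). A non-negative
slope is a curve failure (inhibited or failed run), not a fit to accept.
Unknowns use the mean Cq of technical replicates; copies per gram of soil
requires explicit extraction metadata (soil mass, elution and template
volumes, dilution) — there are no silent volume defaults. Quantities
outside the standards' dynamic range are computed (linear extrapolation)
but flagged. Detection: more than a configurable fraction (default
majority) of replicates amplifying below a cycle limit (default 40).
Reported efficiencies are not thresholded by the package; acceptance
criteria belong to the user's QC config.

## Synthetic generators: what a green test establishes

All generators draw every random number from the scenario seed
(`numpy.random.default_rng`), so runs are bit-reproducible.

* **Pulse** (`gen_chamber_series`): flux rises linearly to the peak
  (default 414 ng N m⁻² s⁻¹ at 30 min, a high-emission dryland wetting
  pulse) then decays exponentially (τ = 60 min, back near baseline within
  ~4 h); 2-min closures every 30 min over 5 h; iid Gaussian concentration
  noise (default 2 ppb). Flux is held at its closure-start value within a
  closure and the schedule includes the peak time, so noiseless peak
  recovery is exact. The shape is a named, swappable function; the
  generator does not emulate within-pulse autocorrelation, chamber
  dilution, or diffusion physics — green tests establish estimator
  correctness, not soil realism.
* **Mixtures** (`gen_isotopocule_samples`): per-process points uniform in
  the substrate-corrected boxes (or pinned), fraction-weighted linear
  mixing (SP treated as a conservative delta-like coordinate, matching the
  standard graphical treatment), Rayleigh displacement at f, iid Gaussian
  noise per axis; readings carry isotopocule ratios that exactly invert
  the delta conversion. Noise is Gaussian because instrument scatter is
  summarised only as a CV bound in practice.
* **Keeling** (`gen_keeling_series`): concentration-weighted linear delta
  mixing (error < 0.1‰ below ~3000‰ at these mixing ratios); exact
  atom-fraction mixing is provided separately (`mix_atom_fractions`) and
  used for tracer-level bookkeeping.
* **qPCR** (`gen_qpcr_plate`): Cq exactly log-linear with configurable
  efficiency, Gaussian Cq noise; no plate effects or inhibition curves.

## Degenerate inputs and tolerances

Zero time variance, all-equal Keeling concentrations, rank-deficient
calibration designs, < 3 dilution levels and non-negative qPCR slopes are
errors, not warnings. f = 0 is rejected wherever ln f appears. Exact
inversion properties are tested to 1e-9…1e-12; calibration closure to
1e-6‰; significance-gate size to three binomial standard errors at 10⁴
simulations.
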