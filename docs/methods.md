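# Methods

## Scope and model

The package quantifies how a secretory client protein (µs, the IgM heavy
chain) that stringently sequesters the HSP70 chaperone BiP drives ER
expansion and UPR signaling, and it formalizes ratiometric stress sensing
as an equilibrium competition. Three complexes interconvert by mass
action:

    T + B ⇌ TB   K_TB      sensor bound to BiP      (OFF)
    T + C ⇌ TC   K_TC      sensor bound to client   (ON)
    B + C ⇌ BC   K_BC      chaperone-client complex

with conservation T_tot = T + TB + TC, B_tot = B + TB + BC, C_tot = C +
TC + BC. Sensor activity is TC/T_tot; free sensor is treated as inactive
by default (`free_sensor_active` flips that, since the activity of the
unbound sensor is not settled). One generic sensor stands in for
IRE1α/PERK/ATF6α collectively; per-branch constants can be supplied but no
published values exist for this system.

**Parameters (all invented, documented as such):** K_TB = K_TC = 1 µM,
K_BC = 10 µM, T_tot = 1 µM, with totals in mM. They are chosen only so
that (i) the sensor is sub-stoichiometric and (ii) B_tot ≫ K_BC at the
mM-scale BiP concentrations the pipeline estimates. In that regime the
*switch position* is ratiometric: the client/BiP ratio at half-activation
sits at 1 to within 1% across at least a 3× change of absolute scale (the
test suite verifies 0.5 vs 1.5 mM BiP). Note that raw activity *below*
the switch is not scale-invariant — it falls off as ~K_BC/B_tot — so the
ratiometric claim is about where the sensor switches, which is what the
competition mechanism robustly encodes.

**Feedback variant.** dB_tot/dt = k_syn0 + k_upr·a(t) − k_deg·B_tot with
a(t) the equilibrium activity at the instantaneous totals and C_tot(t) a
logistic client onset (default 0→1.4 mM, half-time 12 h, Hill 2.5 — the
concentration course implied by 1.7×10⁸ copies entering a ~200 fl ER).
Defaults k_syn0 = 0.025 mM/h and k_deg = 0.05/h put basal BiP at 0.5 mM
with a ~20 h turnover; k_upr = 0.2 mM/h per unit activity is sized so the
chronic steady state ends with BiP again in excess of the client
(B_ss ≈ 1.5–1.6 mM > 1.4 mM) while the correction is slow enough that the
client transiently eclipses BiP, producing the acute transient maximum
followed by a strictly submaximal chronic plateau. With k_upr = 0 the
activity rises to its bound and never subsides — the no-UPR pathology.

**Numerics.** The equilibrium is solved by a damped fixed-point iteration
on the free (B, C) (damping halved when the update norm grows), polished
by a damped Newton step on the two conservation residuals with the
analytic Jacobian; residuals are driven to ≤1e-12 relative (acceptance
bound 1e-9), and non-convergence raises with diagnostics rather than
returning silently. An independent nested-bisection oracle in the test
suite agrees to ≤1e-6 relative on ≥100 random systems spanning totals and
constants in [1e-3, 10]. The feedback ODE is integrated with an adaptive
Runge-Kutta scheme (rtol 1e-6) that calls the equilibrium solver inside
the right-hand side.

## Absolute quantitation

Standard curves are ordinary least squares of signal on known mass with a
free intercept (blots carry background). The standard's purity (the mass
fraction of the lane that is the analyte: 0.7 for µs within whole IgM,
1.0 for recombinant BiP) enters as mass_ng = (signal − intercept)/slope ×
purity, and copies/cell = mass_ng·10⁻⁹/(MW·10³)·N_A/cells-per-lane.
Masses back-computed below the intercept clamp to zero with a warning —
faint lanes legitimately fall under the fitted background. Kinetics are
fitted with a four-parameter logistic on a log-time axis,
y = bottom + (top − bottom)·tʰ/(tʰ + t50ʰ), so t = 0 maps to the baseline
exactly and unobserved times can be interpolated from the fit.

Unweighted OLS on a dilution series with multiplicative noise gives the
top standard most of the slope leverage, so a single blot's absolute
scale carries a shared relative error with sd ≈ the densitometry CV.
Fold-changes within a blot cancel that error entirely; absolute estimates
average it out across independent blots. The tests are structured
accordingly (fold-changes at single-blot level, absolute recovery as an
across-blot mean).

The hybrid XBP1 RT-PCR band is a spliced/unspliced heteroduplex; its
intensity is split 50/50 between the two species before percent spliced
is computed (isolated in one function should a different correction be
preferred). BiP-vs-µs classification uses Welch's unequal-variance
two-tailed t-test with the asymmetric thresholds of the heat-map scale it
implements: BiP excess requires p ≤ 0.001, client excess p ≤ 0.05.

## Stereology and concentrations

Volume fraction = (area fraction)^{3/2}, applied to fractions in [0, 1]
(applying it to percent values would not fix 100%). This cuboid
approximation is the study's own; no unbiased stereology correction is
attempted. The cytoplasm volume defaults to 2×10³ fl (HeLa) and is
overridable. Segmentation thresholds default to Otsu on the masked
intensities with a fixed-threshold override; a contrast-free region
yields zero ER by convention. Two routes to the expanded-ER volume are
implemented: the direct 18% → 7.6% → ~153 fl route, and the ~3-fold
expansion of the resting volume (~219 fl); the adapted ~1.5 mM BiP
concentration arises from the second, which is the route the original
arithmetic follows, while the first gives ~2.2 mM — both are reported by
the workflow where relevant.

## Proteome composition

Intensities are treated as mass-proportional, so a compartment's mass
fraction is its share of summed intensity. "Most abundant" is the union
over days of the top-N (default 500) proteins per day, ties broken by
mean intensity then id. µs is carried as its own category next to ER
residents. The outlier statistic bins proteins by intensity rank (default
300 per bin, last bin absorbs the remainder) and computes an asymmetric
robust z from the bin median and the 15.87/84.13 percentile half-widths
of the log-ratios; two-sided p from the standard-normal tail, significant
at p < 0.05. The per-protein ANOVA over days first normalizes each
replicate column by its summed intensity and flags changes at p < 0.01,
with a Benjamini-Hochberg column attached for convenience.

## Synthetic data: what it does and does not emulate

The generator's defaults are the study conditions: µs logistic 0→1.7×10⁸
copies/cell (half-time 10 h, Hill 2.5); BiP 2×10⁷→2×10⁸ (half-time 24 h,
Hill 3 — the lag is a larger half-time, not a hard delay, so BiP roughly
doubles by 12 h and reaches ≈9.6× baseline at 64 h); ER area fractions
0.11 ± 0.02 resting and 0.18 ± 0.02 induced, truncated to (0, 1), n = 10
cells; proteome ER mass share 3/6/10/12% at days 0/1/3/7 with BiP pinned
to 15/25/30/35% of the ER(+µs) mass and µs at 1 ppm → 1% → 2% of total.
Densitometry and intensity noise is multiplicative lognormal with mean
exactly 1 (CV 0.15 for blots — a choice, the replicate CV is not
published — and 0.30 for intensities); per-blot detection slope is drawn
lognormally (σ = 0.2) around 100 signal/ng with a background of 50.
The synthetic proteome holds 1000 proteins with within-compartment
Zipf(1.1) abundance, enough that top-500 selection is non-degenerate and
covers ~95% of total intensity; compartment-day blocks are rescaled so
the programmed fractions are hit exactly. Micrographs are thresholded
Gaussian random fields: dark blobs at the target fraction of the
cytoplasm disk on a brighter noisy background.

Not emulated: MS spectra, SILAC channel structure, blot image rendering,
saturation/nonlinearity of densitometry, spatial ER morphology beyond
area fraction, and biological between-day correlation of proteome noise.
Passing tests therefore demonstrate that the *accounting and inference
chain* is correct against a known truth, not that real blots or LFQ
tables satisfy the generator's error model.

## Problem sizes and determinism

Defaults are sized for interactive use: 10 time points × 5 replicates per
blot, 10 cells per EM condition, 1000 proteins, 128-point model grids,
20-seed recovery experiments; the full default report completes in a few
seconds. A single seed is expanded into independent per-module streams
(SeedSequence spawn keys), so adding a stage never perturbs another
stage's draws and identical (seed, parameters) give byte-identical
outputs.

## Known limitations

- Dissociation constants, sensor copy numbers and feedback rates are free
  parameters; conclusions from the model are property-level (monotonicity,
  switch position, acute→chronic shape), not fits.
- ATF6α p90 depletion/resynthesis, branch-specific kinetics, IRE1α
  clustering and BiP AMPylation are out of scope; chronic submaximal
  output in real cells may also reflect adaptation layers the
  BiP-feedback route does not capture.
- The equilibrium model assumes binding is fast relative to synthesis and
  degradation, and ignores compartment-volume growth in the feedback
  variant (concentrations, not amounts, are integrated).
- The ~600-protein union size of the top-500 selection depends on rank
  churn across days; the generator's churn comes from its intensity CV
  and is tuned for plausibility, not derived.
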