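# Methods

## Problem and model

An evacuated citrate blood-collection tube is dosed at production with
an anticoagulant amount

    n_ac = c_ac_nom * V_ac_nom        [μmol] = [mmol/L] * [mL]

and sealed under vacuum so that venepuncture draws a nominal specimen
volume `V_draw_nom`. Coagulation tests assume the 9:1 specimen-to-
anticoagulant proportion these nominals imply. Two things can drift:
the dosed amount can be biased, and the liquid volume `V_ac` shrinks
on the shelf by water evaporation (the amount `n_ac` does not). On a
purified-water model both are recoverable from two complementary
determinations:

* **Composite extraction.** The citrate of `N` tubes is washed
  quantitatively into one volumetric flask (`V_f`); the flask
  concentration `c_comp` gives the amount per tube
  `n_ac = c_comp * V_f / N`.
* **Per-tube fill.** Water is added to one tube in exactly
  `V_draw_nom`; the measured concentration `c` closes the mass balance
  `n_ac = c * (V_draw_nom + V_ac)`, so
  `V_ac = (n_ac - V_draw_nom * c) / c`.

Projecting the determined amount onto the nominal total volume,
`c_Vtot = n_ac / (V_draw_nom + V_ac_nom)`, expresses what a compliant
tube would deliver and is compared (as relative bias, %) with the
declared concentration at draw. Compliance uses a symmetric 10 %
tolerance, boundary inclusive: the campaign data treat biases of
8–9 % as acceptable and never adjudicate the exact boundary, so
`|bias| = 10 %` passes. A negative computed `V_ac` (possible when
measurement noise exceeds a near-zero residual volume) is reported
with a warning flag, not clamped, so it remains usable in uncertainty
analysis.

All concentrations are amount concentrations in mmol/L and volumes in
mL; since mmol/L ≡ μmol/mL, amounts come out in μmol with no
conversion factor.

## Calibration and uncertainty

Citrate in HCl medium absorbs at 210 nm linearly over the working
range; the default six working levels are 0.25, 0.5, 1, 2, 3 and
4 mmol/L (configurable). The line `y = a·x + b` is fitted by
unweighted ordinary least squares; the residual standard deviation
`s_yx` uses n − 2 degrees of freedom, `s_a = s_yx/√Sxx` and
`s_b = s_yx·√(Σx²/(n·Sxx))`.

A concentration `x0 = (y0 − b)/a` read off the line carries the
standard uncertainty of interpolation

    s_x0 = (s_yx / a) · sqrt(1/m + 1/n + (y0 − ȳ)² / (a²·Sxx))

with `m` replicate readings of the unknown (default 1). `s_x0` is
minimized at the calibration centroid and symmetric about it. The
relative interpolation uncertainty is combined in quadrature with the
0.0087 relative standard uncertainty of the procedural 10-fold
dilution (1-mL class-A pipette into a 10-mL class-A flask); other
procedural contributions are treated as negligible. A non-positive
interpolated concentration is flagged non-quantifiable instead of
raising, so batch quantification continues.

The standard-additions estimator (for suspected matrix effects) fits
the same OLS line through (added concentration, absorbance) pairs
including the zero addition and reports the magnitude of the x-axis
intercept, `b/a`; a non-positive slope is a degenerate design.

Rounding happens only at presentation (report rendering uses decimal
round-half-up at the table's printed digits); all internal arithmetic
is full precision, and reports always carry the full-precision value
next to the rounded one.

## Water-loss testing

Tube masses weighed repeatedly (10 tubes per date, six dates over
about four months in the bundled campaign) are tested with a one-way
ANOVA with date as the factor, computed directly from per-date
summaries (count, sum, mean, unbiased variance) — algebraically
identical to the raw-data ANOVA. When F exceeds its critical value,
date means are separated with Fisher's least significant difference

    LSD = t_{1−α/2, h(n−1)} · s · sqrt(2/n),   s = sqrt(MS_within)

(two-sided t, df = h(n−1); at h = 6, n = 10, α = 0.05 the quantile is
2.00488, which reproduces the campaign's 0.01916 g and 0.02038 g).
LSD is defined only for balanced designs; unbalanced input yields an
ANOVA without an LSD. No multiplicity correction is applied beyond
the protected-by-F use of unprotected LSD, matching standard practice
for this design. The pairwise rule |Δmean| > LSD is rendered as a
compact-letter display: letters label the maximal runs of the means
sorted in descending order, and a group in overlapping runs carries
several letters. The published asterisk-table layout is one rendering
of the same partition; the |Δmean| > LSD rule is the unambiguous
definition.

Draw volumes are checked against `nominal · (1 ± 10 %)`, boundary
inclusive. The physical pressure/temperature correction of draw
volumes is out of scope (it is not applicable to citrate tubes, where
the liquid volume and water vapour pressure confound the vacuum
model).

## Synthetic campaign generator

The simulator produces what the laboratory observes — tube masses,
absorbances, composite and per-tube concentrations — from known
ground truth:

* amount per tube: `n = c_nom·V_ac_nom·(1 + bias)·(1 + ε)`,
  `ε ~ N(0, fill_cv)`; defaults bias = 0.05 (the campaign observed
  3–23 %), fill_cv = 0.01 (about the dosing precision a producer
  holds);
* liquid volume: same relative fill scatter, then linear evaporation
  `V(t) = max(0, V0 − rate·t)`; default rate 1e-4 mL/day (a slow,
  tight tube; the leaky campaign type B corresponds to ≈9e-4 mL/day,
  the 0.117 g mean drop over 132 days). Evaporation is modelled
  linear because the observed mean-mass drift over the four-month
  window is close to linear; concentration-dependent vapour-pressure
  suppression is not modelled;
* weighing: tare (arbitrary constant 6.25 g — only differences enter
  the ANOVA) + liquid mass at water density 1 g/mL + N(0, 0.022 g),
  the within-date scatter the campaign weighings show;
* spectrometry: `A = a·(c/dilution) + b + N(0, 0.001)` absorbance
  noise, a realistic photometric repeatability.

All randomness flows from one integer seed through
`numpy.random.default_rng`; equal seeds give byte-identical output.
Gaussian noise everywhere: replicate dispersions in the campaign
tables are small and symmetric. The generator does not emulate
spectral shapes, interferents/additives, internal pressure physics,
or non-linear detector response — so passing recovery tests shows the
arithmetic chain and its statistical calibration are right, not that
real spectra are free of matrix effects (the campaign's C_1.8 type
shows such irregularities).

The composite procedure constant is a 50-mL flask with 5 tubes (this
lands the campaign's flask concentrations inside the working range and
matches the reported amount scale); the noisy-recovery property uses
10 tubes per composite.

## Numerical and design choices

* OLS is delegated to `scipy.stats.linregress`; the dispersion
  statistics are recomputed from the stated closed forms. t and F
  quantiles come from `scipy.stats` (good far beyond the 5 digits the
  LSD needs).
* Degenerate inputs: < 3 calibration points and empty uncertainty
  lists are validation errors; identical calibration levels, zero
  slope and zero per-tube concentration are degeneracy errors (CLI
  exit codes 2 and 3 respectively). A no-variation ANOVA (all group
  variances and means equal) returns F = 0 with a degenerate flag.
* The bundled campaign tables carry values at their reported
  precision. Recomputing derived columns from those rounded inputs
  reproduces them within half a unit in the last printed digit once
  the half-unit rounding of the inputs themselves is propagated to
  first order; the reported intermediates were carried unrounded. Two
  residual-volume cells (B_1.8_31.7. at 0.018 mL and C_1.8_31.3. at
  0.008 mL) are hypersensitive to that rounding — the recomputed
  value can differ by ~15 % of a volume that is itself the small
  difference of two rounded numbers — and are excluded from numeric
  comparison. The campaign's reported within-day RSD of 0.18 % is
  likewise not recoverable from its printed replicate concentrations
  (which give 0.30 %); the package reproduces the mean and sd
  (1.4150 ± 0.0043 mmol/L) and does not assert the RSD figure.
* Statistical self-checks run at desk scale: the null calibration of
  the ANOVA uses 5000 simulated datasets (type-I error 0.05 ± 0.01),
  the null/power checks of the mass-series generator 400 and 200
  seeds, and the noisy amount-recovery property 200 replicates per
  amount magnitude — sizes chosen to keep binomial uncertainty well
  inside the asserted margins.

## Known limitations

* The purified-water model ignores blood-matrix effects entirely; the
  package evaluates tubes, not specimens.
* Predicting the anticoagulant concentration for an actual venepuncture
  (substituting a measured draw volume for the nominal one) is left to
  the caller — the arithmetic is `conc_at_nominal_total` with a
  different denominator.
* Contaminant re-expression (e.g. K⁺/Mg²⁺ content at nominal total
  volume) reuses the same projection arithmetic; no dedicated API.
* LSD on unbalanced designs, weighted calibration fits, and
  exponential evaporation are not implemented (the last is noted as a
  config extension point but the linear model covers the studied
  window).
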