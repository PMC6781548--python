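# Methods

## Model

The package models the chemistry of an active saxagliptin film coat as
a deterministic mass-action network over nine molar-equivalent
concentrations (mol per kg of film coat): reactive PEG monomer units,
their oxidation products GA, A, F and FA, and the drug family SAXA,
SCA, ESCA, SFA. Working in molar equivalents rather than mass units
makes the two conservation laws exact — every reaction converts one
PEG-derived unit into another (formylation moves an FA unit into SFA)
and every drug-side reaction preserves the saxagliptin skeleton —
whereas mass units would not (F → FA gains an oxygen).

Assumptions worth stating explicitly:

* Oxygen is in large excess and folded into the apparent constants
  k′; PEG oxidation steps are first-order in reactive PEG.
* FA forms exclusively through formaldehyde oxidation; hydrolysis of
  PEG-formyl esters is deliberately not modeled (it would add species
  without adding identifiable structure at stability-study scale).
* Cyclization and epimerization are specific-base catalysed (rate ∝
  c_OH⁻), formylation specific-acid catalysed (rate ∝ c_H⁺·c_FA).
* All of the drug is reactive (x_SAXA = 1; regressing it frees nothing
  — measured drug loss shows no plateau), while only the fraction
  x_PEG = k_H′(T)·a_w·φ(PEG:polymer) of PEG is: surface water supplies
  the reaction medium (Henry-type proportionality with water activity)
  and only out-of-phase, melt-mobile PEG degrades. φ is a
  piecewise-linear interpolant through published DSC anchor points
  (10% w/w → 0, 20% → 5%, 30% → 22%), extrapolated linearly above the
  last anchor and clipped to [0, 1]. The humidity and phase effects are
  composed multiplicatively — the simplest factorization consistent
  with both being described independently; a `phase_corrected` switch
  disables the lookup.
* Micro-environmental pH either is supplied as a measurement or, in
  dynamic mode, follows the linear closure pH = β₀ + β₁·w_FA with
  β₀ = 5.6703 and β₁ = −570.45 per unit FA mass fraction. The slope
  only has this magnitude if w_FA is a mass fraction (kg/kg): a few
  hundred ppm of FA then lowers pH by 0.1–0.2, matching the measured
  5.43–5.63 range; any other unit choice for the closure argument is
  inconsistent with that range. The closure is clipped below at pH 1.0
  (configurable) and above at β₀, since FA can only acidify.
* The water ionization constant defaults to Kw = 1e-14 at all
  temperatures; a per-temperature override table is accepted. The pH
  dynamics are dominated by the FA closure, so the refinement is rarely
  material.
* Net formylation debits FA stoichiometrically (`consume_fa`, default
  on); without it the PEG-family conservation law would not hold. The
  reverse constant k8′ defaults to zero (irreversible base model); the
  reversible variant reduces exactly to the base law at k8′ = 0.

## Parameterization and defaults

Rate constants are stored as (k_ref, E_a) pairs — the value at the
313.15 K reference temperature plus an activation energy in kJ/mol —
rather than (A, E_a). The two forms are algebraically equivalent, but
the reference-value form decorrelates the pair during regression: data
at the reference temperature constrain k_ref alone.

Two activation energies are anchored to regression values for this
system: 88.54 kJ/mol for the OH⁻-catalysed cyclization (k5) and
151.6 kJ/mol for the H⁺-catalysed formylation (k7). All other defaults
are package calibration values (not literature constants), chosen once
so that desk-scale simulations of the default study design reproduce
the qualitative record:

| parameter | default (k_ref at 40 °C, E_a) | rationale |
|---|---|---|
| k1 (PEG→GA) | 0.02 /d, 90 | minor acid branch |
| k2 (PEG→A)  | 0.01 /d, 85 | minor aldehyde branch |
| k3 (PEG→F)  | 0.04 /d, 95 | dominant branch feeding FA; PEG oxidation ~done in 50 d |
| k4 (F→FA)   | 0.15 /d, 100 | F peaks within the first two weeks then drains into FA |
| k5 (SAXA→SCA) | 6e4 /(mol/L)/d, 88.54 | ~5% cyclization over 200 d at pH 5.66 |
| k6 (SCA→ESCA) | 2e6 /(mol/L)/d, 20 | ESCA rivals SCA at 40–50 °C; epimerization nearly thermally insensitive, so SCA dominates at 30 °C |
| k7 (formylation) | 1e3 /(mol/L)/(mol/kg)/d, 151.6 | SFA from ~0.1% (dry, low PEG) to a few % (humid, high PEG) |
| k8 (reverse) | 0 | irreversible base model |
| k_H′ | 0.025 per unit a_w, 0 | FA stays at a few hundred ppm and pH above ~5.2 across the design |

The film-coat basis fixes the drug load at 20% w/w; PEG scales with
the PEG:SAXA ratio and HPMC makes up the balance, so the design ratios
0.8–1.4 map to PEG:polymer fractions 0.20–0.35, straddling the phase
lookup's steep region.

## Numerics

* Integration: classical fixed-step RK4. The "tolerance" is defined as
  a step-halving convergence criterion — the maximum step starts at the
  smallest reporting interval (or a quarter of the span, whichever is
  smaller) and is halved until no reported concentration changes by
  more than the tolerance (default 1e-5 mol/kg) between successive
  refinements, with at most 20 halvings. This is a reproducible,
  scheme-independent reading of a fixed-step solver tolerance; it is
  interpreted as an absolute change because the tracked species span
  five orders of magnitude and a relative rule would be dominated by
  trace species at round-off.
* Admissibility: after each accepted step, components within −1e-9 of
  zero are floored at zero (round-off guard); larger negative or
  non-finite excursions reject the step size.
* Closed-form verification (exponential decay, serial-reaction
  Bateman solutions) is run at a tightened tolerance of 1e-8, where the
  integrator matches the analytic forms to better than 1e-6 relative;
  at the default 1e-5 the agreement is ~4e-6, i.e. tolerance-limited,
  not scheme-limited.
* Regression: Levenberg–Marquardt (lmfit/MINPACK) on log-transformed
  parameters (all are positive), bounded to ±6 decades around the
  start, relative step/SSE convergence thresholds 1e-10, forward-
  difference Jacobian with a 1e-3 relative log-step so the numerical
  derivative rides above integration-level noise. Trial points whose
  integration fails return a large finite penalty so the optimizer
  retreats instead of aborting.
* Residuals: per-species range weighting (each residual divided by the
  maximum observed value of that species across all datasets), so ppm-
  scale impurities and the drug assay contribute comparably. Censored
  observations enter one-sidedly as max(0, simulated − LOQ)/w: a
  prediction below the quantitation limit is exactly consistent with a
  below-LOQ report.
* Staged fit: stage 1 regresses the apparent constants and the
  humidity proportionality on the 40 °C / a_w 0.10 block (at a single
  condition k_H′ is precisely the reactive fraction x_PEG, which the
  base-condition model build regresses); stage 2 refits k_H′ on the
  other humidities at 40 °C; stage 3 fits the activation energies
  across temperatures. Designs with a single temperature and free
  activation energies are flagged non-identifiable up front. On
  noiseless data the staged and direct joint fits agree to well below
  0.1% per parameter.

## Synthetic data

The generator emulates a film-coated-tablet stability program: a full
factorial of four compositions (PEG:SAXA 0.8/1.0/1.2/1.4), three
temperatures (30/40/50 °C — the model-building range; harsher stress
temperatures are excluded by default) and three water activities
(0.10/0.30/0.50), sampled at 0/7/14/30/60/108/180 days (a
reconstruction of a protocol sampling from day 7 to day 108, extended
to the 180-day simulation horizon; at least four time points per
condition are enforced). Observation noise is multiplicative Gaussian
(σ = 0.05 by default — UHPLC error is roughly proportional), truncated
at zero; per-species quantitation limits (10 ppm for the small organic
impurities, 50 ppm for drug-related products) censor low values, which
are stored at the LOQ with a flag. A time-zero sample with all
degradation products at zero is always included. The generator does
not emulate analytical drift, tablet-to-tablet variability or assay
artefacts, so passing recovery tests demonstrate identifiability under
the stated noise model, not robustness to real-assay pathologies.

One deliberate divergence from the measured record: in the forward
model FA and SFA are positively correlated across the design (both
grow with PEG content), whereas the measured study reports a strongly
negative FA–SFA correlation; the generator makes no attempt to
reproduce that sign, and the statistical checks assert only the
mechanistically forced pH–FA anticorrelation.

## DoE statistics

The MLR module mid-range-centers and half-range-scales each continuous
factor over its design span (so every coefficient is the response
change from design center to factor extreme — a documented, open
convention; commercial DoE packages use proprietary variants, so
numeric coefficient equality with any particular tool is not claimed,
only sign and ordering behaviour), codes composition sum-to-zero and
reports it expanded to one coefficient per level, fits main effects
only by OLS, and computes Q² from leave-one-out PRESS via the hat
matrix. Constant responses return zero coefficients with R² = Q² = 0
and a warning; rank-deficient designs raise an error naming the
aliased columns. Correlation matrices are plain Pearson; zero-variance
responses are reported as undefined (NaN), never coerced to 0.

## Problem sizes

The default full-design study is 36 conditions × 7 time points × 8
observed species (2016 observations). The staged refit of that design
from ×1.5-perturbed starts — the heaviest routine computation — runs in
roughly 15 s on one CPU; the whole test suite, including a ten-replicate
noisy recovery study on a reduced design, completes in about a minute.

## Known limitations

* The pH closure is calibrated at one condition family; extrapolating
  it far outside a few hundred ppm FA leans on the clip floor.
* k_H′ is shared across temperatures by default (its own temperature
  dependence is accepted via an activation energy but defaults to 0).
* No formal confidence intervals or profile likelihoods are computed;
  the covariance proxy is the LM step history and SSE record.
* The reversible-formylation constant k8′ is only identifiable from
  data showing an SFA plateau; with the default design it is left off.
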