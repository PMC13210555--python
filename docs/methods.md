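# Methods

This note records the models, numerical choices, and design decisions behind
depotkit, and what the synthetic-data studies do and do not demonstrate.

## Disposition model and unit impulse response

IV bolus concentrations are described by a macro-parameterized sum of
exponentials `C(t) = Σᵢ Aᵢ e^(−λᵢ t)` (1–3 terms, exponents strictly
decreasing), the standard mammillary-model parameterization when only the
plasma curve matters. Fitting is **naive-pooled**: all subjects' samples enter
one log-scale least-squares objective, `ln C(t) = ln Σ Aᵢe^(−λᵢt) + ε`, with ε
additive on natural-log concentrations. The downstream consumer of the fit is
the mean unit impulse response — a fixed-effects quantity — so pooled fitting
is sufficient; between-subject uncertainty is supplied by a subject-level
bootstrap (the resampling unit is the subject, so a rabbit's sparse samples
move together; percentile 95% CIs; refits that fail are counted and skipped,
with >20% failures an error). This is a deliberate simplification relative to
full nonlinear mixed-effects estimation, which pooled sparse designs cannot
support reliably.

Numerics: parameters are fit as logs to enforce positivity; initials come from
log-linear curve stripping (peel the terminal phase, subtract, repeat) plus
seeded jitters (10 starts by default); Levenberg–Marquardt with tolerances
1e−14. Exponential sums are ill-conditioned, hence the multi-start. CV% is the
delta-method standard error of the log-parameter (≈ relative SE). AIC is
`n·ln(SSR/n) + 2k` with `k = 2·n_exp + 1` (residual SD counted); `SSR/n` is
floored at 1e−20 so that models fitting noise-free data "perfectly" compare by
parameter count instead of floating-point noise. Model selection takes the
lowest AIC, ties to fewer exponentials.

**Identifiability floor.** A fitted exponent whose half-life exceeds five times
the sampled span is indistinguishable from a constant baseline, which lies
outside the disposition family (a bolus concentration must decay). Multi-start
solutions that collapse this way are discarded; if every start collapses the
model is refit with the floor as an explicit bound, and the near-boundary
estimate is visible through its CV%. This matters for analytes whose terminal
phase skirts the assay LLOQ (bictegravir here): the LLOQ/2-imputed tail is
flat, and an unconstrained pooled fit can otherwise absorb it into a
non-decaying phase, which then wrecks the year-long deconvolution.

The UIR is the fitted model with coefficients divided by the IV dose,
`cᵢ = Aᵢ/D` in (ng/mL)/ng.

## Deconvolution

The input rate is piecewise constant on a uniform grid: a node at 24 h (day 1)
then 72-h segments to the end of follow-up, the study's reporting grid. For a
segment `[s, e)` at rate `r`, the concentration contribution at `t ≥ s` is
analytic:

```
r · Σᵢ (cᵢ/λᵢ) · (e^(−λᵢ·max(0, t−e)) − e^(−λᵢ·(t−s)))
```

so the forward map is an exact matrix `A` with no quadrature error, and
cumulative absorbed mass is the exact integral of the recovered step function.
The inverse problem is

```
min ‖C_obs − A·r‖² + λ‖D₂ r‖²   subject to r ≥ 0
```

solved by non-negative least squares on the stacked system (`D₂` is the second
difference). The objective lives on the linear concentration scale because the
model is linear in the unknown rates. λ defaults to 0 when observations are at
least as numerous as grid segments (dense sampling); with sparser sampling an
unregularized solve is refused and λ is chosen by generalized cross-validation
over a log-spaced ridge path, using the unconstrained ridge trace for the
effective degrees of freedom. The commercial toolkit used in the source study
implements a different (dispersion-function) deconvolution; this formulation is
transparent and testable, and exact numeric agreement with that toolkit is not
claimed.

Fraction input divides cumulative mass by the drug mass loaded in the implant
(not dose absorbed at infinity), which makes the percent-remaining arithmetic
`100·(loaded − cumulative)/loaded` exact; a cumulative estimate exceeding the
load (an estimation artifact) yields a warning, not an error. Snapshot
summaries take node-wise medians/IQRs across the subjects still observed at
each node; burst is the node of maximal median rate; month `m` maps to the node
nearest `30.4·m` days (the source study does not state its convention). Rates
are reported in µg/day (= ng/h × 24/1000) and masses in mg only at reporting
boundaries; all internal math is ng and hours.

## Noncompartmental analysis

λz is the negated slope of ln C over a terminal window. Auto-selection scans
contiguous suffixes after (and excluding) Cmax, minimum three points, and keeps
the best adjusted r² — the convention of common NCA software, since the source
study does not state its point-selection rule. Slopes within 1e−12 of zero are
flagged as "no terminal phase" rather than inverted into absurd half-lives.
For the sparse IV arm the NCA substrate is the per-timepoint group mean
profile; for the implant arm the median of per-subject λz is reported. AUC uses
linear-up/log-down by default (log trapezoid exact for exponential decline).
Flip-flop is declared when λz(SQ)/λz(IV) < 1; for these implants the ratio is
of order 10⁻³.

## Dissolution and IVIVC regressions

Six cumulative-release models: `F = b + mt` (zero order), `ln(1−F) = b + mt`
(first order, residuals minimized on the log of the fraction remaining,
normalized to 1), `F = b + m√t` (Higuchi), Weibull
`F = Fmax(1 − e^(−(t−Tlag)^b/A))` with Tlag fixed at 0 (implants release from
insertion; a free lag is not identifiable from twice-weekly sampling), a
two-branch Weibull mixture, and Makoid–Banakar
`F = Fmax·(t/Tmax)^n·e^(n(1−t/Tmax))`. The published study defers the
nonlinear forms to a commercial user guide; the canonical published forms
above are this package's normative definitions. Nonlinear fits run multi-start
Levenberg–Marquardt on transformed parameters (log time-scale `t63 = A^(1/b)`,
log shapes, logistic mixing fraction), which removes the extreme scale
disparity of raw `A` values. r² is computed on the fitted scale (log scale for
first order); ranking uses the same floored AIC as above, so on noise-free
data the generating model beats its super-models by parameter count.

IVIVC pairs the mean fraction dissolved with the mean (over subjects) fraction
absorbed at the in vitro sampling times, interpolating the absorption step
integral (exact, since cumulative input is piecewise linear). Five candidate
regressions of `f_abs` on `f_diss`: linear, three-parameter exponential rise
to maximum `y0 + a(1−e^(−bx))`, four-parameter sigmoid
`y0 + a/(1+e^(−(x−x0)/b))`, power `a·x^b`, and a five-parameter asymmetric
sigmoid. The exact source-tool parameterizations being unavailable, these are
the common curve-fitting conventions for those model names. 95% prediction
bands use the t quantile × `s·√(1+leverage)` with delta-method leverage
`J(JᵀJ)⁻¹Jᵀ`. No heteroscedastic weighting is applied.

Minimum sink volume is `multiplier·rate·interval/solubility`, the check that
drug released over the longest transfer interval stays below solubility in the
medium.

## Dose translation

The implant is treated as a continuous constant-rate infusion: `Css = k₀/Cl`.
Pediatric clearance comes from published pediatric exposure when available
(`Cl = Dose·F/AUC₂₄`, mg → µg, result mL/h) or from adult apparent clearance
scaled by `(W_ped/W_adult)^0.75` with defaults 15 kg (CDC growth-chart weight
for the 2–5-year target population) and 70 kg. The package computes at full
precision; published concentration tables that carried a *rounded* clearance
through the arithmetic are reproduced via an explicit clearance override, and
display rounding is half-up at a per-analyte precision (2 decimals for
islatravir, 1 for the others, matching how such tables print).

## Synthetic studies: what they emulate and what they don't

The generator reproduces the study designs: IV — 8 timepoints over 30 h (0.5,
1, 3, 6, 12, 18, 24, 30), 16 subjects × 2 samples, balanced so each timepoint
carries 4 observations (seeded permutations of the slot list until every
subject's pair is distinct); SQ — sampling days 1, 7, 14 then every 14 days to
day 364, with a truncated-arm override; in vitro — 3.5-day total-replacement
intervals. IV truth uses the study's biexponential estimates per analyte with
independent log-normal between-subject variability on each macro-parameter
(SD 0.3) and log-additive residual error (SD 0.2) — both package choices, as
the study reports no error magnitudes — with LLOQ censoring at 1.0 (BIC) and
0.1 ng/mL (ISL/FTC). Per-kg IV doses are converted with a default 3.0 kg
rabbit weight (typical adult New Zealand White; the study does not report
weights).

Depot inputs are fixed Weibull shapes chosen once to mirror each implant's
qualitative behavior: bictegravir a single Weibull (b = 0.85, time-scale
2500 h^b, 35% of the 165 mg load eventually delivered) whose rate declines
from insertion (burst at day 1); islatravir and emtricitabine double-Weibull
mixtures (25–30% fast branch peaking near day 7 atop a slow first-order branch
with ~140-day time constant) delivering ~55% of 62 mg and ~68% of 100 mg over
the year. Implant concentrations are the exact step-convolution of the UIR
with a mass-preserving fine-grid projection of the input, times log-normal
residual noise, with a per-subject log-normal scale on the input rate (capped
so cumulative input never exceeds the load).

What passing tests show: the estimation machinery is correct (round-trip
inversion, parameter recovery, model selection, translation arithmetic) under
the stated designs and error structure. What they do not show: robustness to
model misspecification absent from the generator — correlated random effects,
non-log-normal error, assay drift, implant-to-implant loading variability,
in vivo/in vitro medium differences — nor agreement with the commercial
deconvolution toolkit's internals. Under between-subject variability the
pooled IV fit can still be biased for a minor phase (the reason the original
analysis used mixed-effects models where the data allowed); the recovery
simulations therefore characterize the residual-error-only case the pooled
model actually assumes.

## Problem sizes

Defaults used by the test suite and acceptance script: 100 replicates for the
sparse-design recovery study (two noise levels), 52-point dissolution
profiles, 18-point IVIVC pairs, 124-segment deconvolution grids (day 1 to day
372 at 72 h), and 10–250 bootstrap resamples depending on context. These sizes
were chosen so a full run completes in minutes on a single CPU while leaving
the Monte Carlo conclusions stable across seeds.

## Known limitations

* Single-dose studies only: no multi-dose superposition, no irregular
  infusion records.
* No mixed-effects engine, covariate models, or micro-rate-constant output.
* No Wagner–Nelson / Loo–Riegelman mass-balance alternatives; deconvolution
  assumes linear, time-invariant disposition.
* No formal regulatory IVIVC validation (internal/external predictability of
  Cmax/AUC); the IVIVC here is descriptive.
* No PBPK or maturation-function pediatric scaling; allometry only.
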