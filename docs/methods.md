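# Methods

This note documents the statistical procedures, the tunable parameters and
their defaults, the synthetic-data model, and the design choices made where
the design was genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Endpoints and exposure

Growth is scored as the specific growth rate over the full exposure,
SGR = (ln Xj − ln Xi)/(tj − ti) in day⁻¹, from cell densities at 0 h and
72 h; negative rates (decline) are valid. The photosynthesis endpoint is
the light-adapted effective quantum yield ΔF/Fm′ = (Fm′ − F)/Fm′ at 24 h;
dark-adapted Fv/Fm and rapid light curves are out of scope. Inhibition is
100·(X_control − X_treatment)/X_control with the **arithmetic mean of
seawater-control replicates** as baseline; the solvent control is stored
separately and pooled into the baseline only on request
(`pool_solvent_control`), since solvent carriers at < 0.01% v/v typically
show no growth effect. Per-replicate control inhibitions are kept (mean
zero by construction) so fits see control variance. Inhibition below zero
(stimulation) is preserved, never clipped.

Exposure per treatment is the time-weighted average concentration, the
geometric mean √(c_start·c_end) of measured start and end concentrations —
the exact time average of a first-order dissipation trajectory. Missing or
non-positive measurements fall back to half the limit of quantitation when
an LOQ is configured, otherwise to the nominal concentration; either
fallback is flagged in the `conc_source` column. TWA is computed per
treatment (not per assay batch). Concentrations are µg/L internally; input
units are declared at read time (`ug/L`, `mg/L`, `ng/L`).

## Assay validity

A test is flagged valid when (i) mean control SGR ≥ 0.92 day⁻¹, (ii)
control SGR CV ≤ 10% (sample sd, n−1), and (iii) the signed pH increase
t72 − t0 is ≤ 1 unit in every treatment (decreases never fail). The
reference-toxicant inhibition (diuron-like, 4 µg/L) is reported as a
between-assay consistency indicator, not a hard gate — it gates
interpretation, not computation. QC failure warns and flags the run
summary but does not abort: the analyst decides what an invalid assay is
worth. QC never alters endpoint values.

## Four-parameter logistic ECx

The mean model in log₁₀ concentration is
y = bottom + (top − bottom)/(1 + 10^((log EC50 − log c)·hill)). Controls
(concentration zero) are not placed on the log axis; they only define the
0% baseline. Replicate-level inhibition is fitted by bounded least squares
(trust-region reflective) from 8 deterministic starts (midpoint spread over
the tested range × slopes 0.7 and 2), keeping the lowest SSE. Bounds:
bottom ∈ [−30, 40]%, top ∈ [40, 120]%, hill ∈ (0, 10], log EC50 within the
tested range ± 1 decade. R² = 1 − SSE/SST on the replicate data.
Duplicate concentrations after TWA are treated as distinct design points
with shared concentration.

ECx is the closed-form inverse of the fitted curve on the **absolute
inhibition scale** (x% of the control response), matching the reading of
EC50 as "inhibits by 50%"; the relative-to-asymptote convention is not
used. The inversion censors ("> max tested") when the level lies outside
the fitted asymptotes or the solution exceeds the highest tested
concentration; solutions below the lowest tested concentration are
reported uncensored, because a "greater-than" bound would be directionally
wrong there.

Confidence intervals are a 95% percentile bootstrap (default 2000
resamples), resampling replicates with replacement within each
concentration and refitting warm-started at the full-data solution.
Resampled deviations from each group mean are rescaled by √(n/(n−1)):
within-group resampling deflates variance by (n−1)/n, and at n = 5 the
uncorrected interval measurably undercovers (≈88% empirical coverage over
600 simulations versus ≈92% with the correction — the residual gap from
95% is the usual percentile-bootstrap optimism for a nonlinear functional
at this sample size). Resamples that fail to fit or censor are dropped; if
they exceed 20% the interval carries a `wide_warning`. Bootstrap intervals
were chosen over asymptotic standard errors because they remain usable at
n = 5 per concentration and are fully specified.

## Nonresponse path

Herbicides without a concentration response (e.g. an ACCase inhibitor
against a diatom carrying only the insensitive plastidial enzyme form) are
detected by a one-way fixed-effects ANOVA on raw endpoint values across
control + test treatments (the reference treatment, a different chemical,
is excluded). An assay is *nonresponsive* iff the ANOVA is non-significant
(p ≥ 0.05) **and** mean inhibition at the top concentration is < 10%.
Nonresponsive assays skip the 4PL and NEC fits and report every threshold
as "> max tested concentration" and ReP as "NA". Degenerate inputs (zero
within-group variance everywhere) short-circuit with F = 0, p = 1 when all
means agree and F = ∞, p = 0 otherwise, with an exact-separation note.

## Bayesian NEC threshold model

The proportional response y = 1 − inhibition/100 per replicate is modelled
against x = ln(concentration) as a broken stick,
E[y|x] = α·exp(−β(x − γ)·I(x − γ)) − Δ, with gaussian error σ. Below the
threshold γ the mean is constant at α − Δ; exp(γ) is the NEC in µg/L.
Natural log was chosen for x; the NEC is reported after exponentiation.
Controls cannot sit at ln 0 and are placed one decade below the lowest
test concentration by default (`control_decades` ∈ {0.5, 1, 2} to probe
sensitivity); the placement is recorded in the output. The NEC is fitted
on the growth endpoint, whose thresholds feed guideline derivation.

Priors (weakly informative, all overridable):
γ ~ Uniform(min x − 0.5, max x); α ~ Normal(control-y mean, 10 × control-y
sd) truncated positive; β ~ Gamma(10⁻⁴, 10⁻⁴); Δ ~ Normal(0, 1);
σ ~ half-Cauchy(1). Δ is left free rather than pinned at 0 — with
proportional data and top ≈ 1 it is weakly identified, which the tight
prior handles.

Sampling uses the emcee affine-invariant ensemble (16 walkers, 6000 steps,
3000 burn-in by default, ≈48k kept draws) with a differential-evolution
move mixture (80% DEMove, 20% DESnookerMove), which mixes far better than
the stretch move when a walker lands in a minor mode of this ridged
posterior. Walkers are folded into 4 pseudo-chains for split-R̂ and ESS;
any R̂ > 1.05 or ESS < 400 raises a warning and flags the fit, never
silently passes. Runs are deterministic given the seed. The NEC summary is
the posterior median of exp(γ) with the central 95% credible interval
(reported in the "95% confidence interval" slot of the output tables).

Known limitation: when the true threshold coincides *exactly* with a
tested concentration, the posterior for γ spreads into the empty design
gap above the knot and the 95% interval covers the truth in only ≈80% of
simulations — a boundary pathology shared by change-point models
generally. Calibration studies therefore place the truth strictly between
tested concentrations (the generic configuration; with continuous
dissipation and TWA exposure an exact coincidence has probability zero),
where coverage is ≈90–93%.

## Synthetic bioassays

The generator emulates a 72-h static test: control + optional reference
(4 µg/L, fixed inhibitions ≈22% SGR / ≈42% yield) + a geometric
concentration series (default 7 levels spanning two decades around the
truth EC50), n = 5 replicates started at 3×10³ cells/mL. Defaults encode
the observed study conditions: control SGR 1.55 day⁻¹ (the middle of the
1.41–1.68 range seen across valid assays), control yield 0.46, 4% CV
lognormal counting noise on densities (multiplicative — counts are
positive and CV-scaled), 0.01 additive gaussian noise on yield
(near-symmetric around 0.45), 5% CV lognormal analytical noise on measured
concentrations (typical LC–MS/MS precision), 80% of nominal remaining at
72 h. The yield endpoint uses the growth truth curve with its EC50 divided
by a sensitivity factor (default 3). Effects are evaluated at the TWA of
the *simulated measured* concentrations, so a noiseless generator
round-trips exactly through the analysis (veriﬁed to ≤ 1e−10).

What the generator does **not** emulate: hormesis (a negative-inhibition
truth option exists only to exercise the no-clipping contract), replicate
correlation within incubator positions, fluorescence kinetics or
event-level cytometry, pH-driven growth feedback, and non-first-order
dissipation. Passing recovery tests therefore demonstrates correctness of
the estimators under the assumed noise structure, not robustness to every
laboratory artefact.

## Calibration-study conditions

Simulation studies (test suite and `scripts/acceptance.py`) use problem
sizes chosen to estimate each property with useful precision at interactive
runtimes: 4PL recovery over 50 assays with replicate inhibition sd 5%,
hill 1.5 and 7 concentrations spanning 2.5 decades (published EC50/EC10
ratios imply slopes ≈1.1–1.5, and the curves bracket ≈1–99% inhibition, so
this is the realistic steep-curve regime); bootstrap calibration over 200
assays at 200 resamples; NEC calibration over 100 datasets at reduced
chains (2500 steps, 1250 burn-in), where the flagged-if-unconverged
diagnostics still hold. ECx inversion is verified against the analytic
Hill inverse on 100 random parameter sets to ≤ 1e−9.

## Numerical conventions

Internal values are full precision; rounding to 3 significant figures (and
"> max"/"NA" rendering) happens only at serialization. JSON output is
sorted-key and reruns are byte-identical for identical (input, config,
seed). All randomness flows from explicit integer seeds through
`numpy.random.Generator` / `RandomState`; the sampler, bootstrap and
generator never touch global RNG state.
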