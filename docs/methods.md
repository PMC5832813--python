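# Methods

## The model chain

The package treats biota-mediated sediment resuspension as an energetic
process: whatever the mechanical mode of sediment reworking (deep funnel
feeding, siphonal disturbance, surface crawling), its intensity is assumed
proportional to the energy the population spends, summarised by its areal
metabolic rate. Four stages connect a field-style size measurement to a
temperature-projected resuspension estimate.

**1. Size to mass.** Body mass M (mg ash-free dry weight) comes from a
per-species power law M = p·size^q. The coefficients are laboratory
calibrations that differ between species and sites; they are configuration
(TOML), not constants. The packaged defaults are power laws calibrated to the
size/mass pairs of the packaged dataset and should be replaced for new data.
Shell length (mm) is the size currency for bivalves, wet weight (mg) for the
lugworm.

**2. Mass to individual metabolic rate.** Two forms are provided. The pure
allometric law I = a·M^b (default b = 0.75, the canonical metabolic-scaling
exponent; a is a free normalization) is the default and the form used by the
temperature projection. A ln-linear empirical form accepts an arbitrary
coefficient table over ln M, 1/T and 0/1 trait indicators — the shape of
published respiration regressions for aquatic macroinvertebrates — and
converts its J/day prediction to mW by the exact factor 1000/86400. No
third-party regression coefficients are reproduced in the package; the
packaged dataset carries its precomputed I values, so downstream stages never
depend on any particular respiration model. Tissue energy density defaults to
21.5 J per mg AFDW.

**3. Population scaling and regression.** I_TOT = N·I, with density N an
exact design variable (its CI is zero, so the I_TOT half-width is N times the
I half-width — the pattern the packaged table follows). The central fit is
OLS of R_TOT on I_TOT; functional-group variants (separate intercepts, or
intercepts and slopes, for deep / intermediate burrowing bivalve / shallow
groups, treatment-coded against the deep group) are compared by bidirectional
stepwise selection. R_BIO = (R_TOT − R_CONTROL)/I_TOT is analysed against
density and body mass with the same machinery; with no covariate signal the
selected intercept-only model estimates the mean g-per-mW effect.

**4. Temperature projection.** R(T) = c + d·I_TOT·exp(−E/k(1/T − 1/T_ref)).
Only the biotic term scales; the abiotic baseline c is temperature-invariant
by assumption, so a cooling scenario is bounded below by c. E defaults to
0.65 eV, the standard mean activation energy of heterotrophic metabolism; it
is an explicit, visible scenario parameter because projected percentages are
sensitive to it. Interfaces take °C and convert to kelvin internally
(+273.15); k = 8.617×10⁻⁵ eV K⁻¹.

## Statistical conventions

- **CI semantics.** “±95% CI” columns are symmetric half-widths, treated as
  1.96σ of independent Gaussian errors. Propagation is first-order
  (delta method) by default: ci_out = √Σ(∂f/∂xᵢ·ciᵢ)². A seeded Monte Carlo
  propagator (inputs drawn at σ = ci/1.96, output mean ± 1.96·sample σ) is
  the audit; the two agree within 5% for smooth maps with relative CIs below
  ~20%, which is the regime of these data. Whether any given published table
  used the analytic or simulated route is generally unknowable; providing
  both brackets the answer.
- **AIC.** AIC = −2 logLik + 2(p+1) under the Gaussian likelihood, counting
  the residual variance as a parameter. This is the convention of R's
  `AIC`/`stepAIC` (statsmodels' OLS AIC is exactly 2 lower) and is required
  for comparability with published model-comparison tables.
- **Stepwise scope.** Bidirectional: from the full model, the best single
  term drop or (hierarchy-respecting) add is taken while it lowers AIC.
  Interactions are dropped before their main effects; the categorical enters
  and leaves as one block. The candidate space is the tiny hierarchical
  lattice of the full spec, so tests verify the selection against exhaustive
  enumeration.
- **Inference.** 95% CIs and p-values use the t distribution with n−p df
  (visible in the third decimal at n = 32 relative to normal quantiles).
  Significance is reported at 0.05 and 0.1; no multiple-testing correction
  (none is appropriate for a three-model comparison read as one selection).
- **Correlation diagnostics.** Both Pearson and Spearman (average ranks,
  large-sample p) are computed. On the packaged table they differ noticeably
  (Pearson 0.83/0.37, Spearman 0.76/0.56 for I_TOT/density vs R_TOT): the
  relationship is linear with two extreme design points that compress the
  ranks. Reporting both avoids over-reading either.
- **Leverage sensitivity.** The simple fit is refit after removing the k
  treatments with the largest I_TOT (k = 2 by default — the two deliberately
  extreme design points). Rows tied at the k-th largest value are all
  removed and the effective count reported.
- **Degenerate inputs.** A zero-variance response defines R² = 0 (nothing to
  explain); a perfect fit yields infinite log-likelihood, reported as-is;
  rank-deficient designs raise an error naming the collinear terms rather
  than silently pseudo-inverting.

## The packaged dataset

The 32-treatment flume table (`sedimet/datasets/flume_treatments.csv`) is the
dataset of record: six species in three functional groups, 1–4 size classes
each, densities 13–382 ind. m⁻², observed equilibrium resuspension after 48 h
of bioturbation at 0.18 Pa bed shear stress, all quantities with 95%
half-widths. The mean defaunated-control resuspension is 32.25 g m⁻²
(±1.73), used as the global R_CONTROL default; a per-flume control mode
exists for datasets that record internal controls per run.

Two transcription caveats are embedded deliberately rather than repaired.
First, the printed individual-rate column is internally inconsistent with
I_TOT/N for the shallow-group treatments (and marginally for two high-density
bivalve rows); the stored I_TOT is authoritative, and table assembly flags
the inconsistent rows with warnings instead of altering them. Second, the
smallest lugworm size class is recorded as 160 ± 8 mg wet weight, the reading
under which all three lugworm size/mass pairs fall on a single power law and
the AFDW/wet-weight ratio is biologically plausible (~10–12%).

## Synthetic-data generator

`GeneratorConfig`/`generate_table` emulate the experiment's design: the same
32 (species, size class, density) treatments with their real I_TOT values —
so simulation studies inherit the true leverage structure, including the two
extreme metabolism treatments — and two replicate runs per treatment,

    R_r = c + offset(group) + d·I_TOT + ε_treatment + ε_replicate,

with Gaussian, homoscedastic treatment-level noise (matching the unweighted
OLS analysis; a heteroscedastic option exists for robustness studies only).
R_TOT is the replicate mean and its CI the normal interval from the replicate
spread. Defaults: c = 35 g m⁻², d = 0.36 g mW⁻¹ (the fitted values, rounded),
σ = 15 g m⁻² — which puts the simple fit's R² near the observed 0.68 on this
design — and replicate σ = 5 g m⁻², a free choice (the source experiment
reports no replicate-level spread) set to reproduce the magnitude of the
observed replicate CIs. Generated R_TOT is not truncated at zero: the
observed range never approaches zero and truncation would bias recovery
experiments.

The generator does **not** emulate: the time course of erosion towards
equilibrium, density saturation from overlapping zones of influence at
extreme densities, any dependence of noise on treatment identity, or
behavioural responses to temperature and sediment properties. Passing
recovery tests therefore demonstrate the estimation machinery is correct
under the stated model, not that the linear-in-metabolism model itself is
adequate for new field conditions.

`recovery_experiment` refits each of many seeded replicates and reports bias,
RMSE and 95% CI coverage for (c, d), optionally the stepwise selection
frequency per model. Coverage claims are flagged unreliable below 100
replicates. At the default configuration, coverage sits in the nominal
91–99% band over 500 replicates and the no-offset truth selects the simple
model in the majority of runs.

## Problem sizes

The whole default validation suite runs at desk scale: the real dataset has
32 rows; simulation-based tests use 60–500 replicates of that design, sizes
chosen so each law-of-large-numbers or coverage statement is stable to well
within its asserted tolerance.

## Known limitations

- The activation energy behind the temperature scenarios is an assumed
  canonical value, not an estimate from these data; scenario outputs expose
  it as a parameter for exactly that reason.
- The analysis operates on treatment means of two replicates, as the source
  design does; no replicate-level mixed modelling is attempted.
- Density saturation, inter-species interactions, biofilm disruption and
  bed-shear physics are outside the model: extrapolation beyond the
  experimental density and size ranges compounds the linearity assumption.
- The per-species size→mass placeholder rules are single- or two-point
  calibrations; they reproduce the packaged masses but carry no uncertainty
  of their own.
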