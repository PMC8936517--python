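# Methods

This note records the models, conventions and numerical choices behind
`drugscreen`, and what the simulation-based tests do and do not
demonstrate.

## Assay model and normalization

A well's luminescence signal is treated as proportional to the number of
viable cells. Negative controls (vehicle) define 100% viability, positive
controls (full kill) define 0%:

    viability% = 100 · (signal − μ_pos) / (μ_neg − μ_pos)

Control summaries use the mean and sample SD — the standard Z′-factor
estimators — rather than robust alternatives; the Z′ usability floor
defaults to 0.4 (configurable), a deliberately permissive screening gate:
plates below it are reported and excluded rather than silently dropped,
and `--force` re-admits them. Viability is **not** clamped before curve
fitting (overshoot above 100% or below 0% carries information about the
noise and the asymptotes); the inhibition fraction used for Bliss scoring
is clamped to [0, 1] because the independence model needs probabilities.

## Outlier screen

Manual curation of screening plates is replaced by a two-stage automated
rule operating on normalized viabilities:

1. **Replicate rule.** Within wells sharing an identical treatment,
   a well is flagged when it sits further from the group median than
   `max(3 × 1.4826 × MAD, 15 points)`. Pairs are never adjudicated by
   this rule.
2. **Residual rule.** Within each titration (one concentration axis
   varying over ≥ 4 levels), a preliminary curve is fitted to all wells.
   Because assay noise is multiplicative, the per-point residual scale is
   `max(σ_rel · predicted viability, 0.5 points)`, with σ_rel estimated
   from replicate agreement pooled across the table (median over groups;
   robust to contaminated groups) and from fit residuals only when no
   replicates exist. Replicated wells are adjudicated within their
   replicate group — a pair whose spread exceeds 6 pair-noise SDs
   contains an outlier, and the member farther from the fit is flagged —
   while the plain 3σ curve-residual test applies to singleton wells
   only. Curve residuals of replicated wells are deliberately not used
   directly: with 6-point/4-parameter fits they carry systematic
   lack-of-fit shared by both replicates, which a per-well test would
   misread as outliers.

Flagged wells are excluded from downstream fits but remain in every
output table. On simulated plates (5% CV, 2% outlier rate, 3× outlier
scale) the screen reaches ≥ 0.8 sensitivity at ≤ 0.2% false flags; an
outlier sitting on the lower asymptote (true viability below roughly half
a point) is undetectable in principle and bounds the sensitivity.

## Curve fitting

The four-parameter log-logistic model is fitted by bounded nonlinear
least squares (`scipy.optimize.least_squares`, trust-region reflective)
with a three-point multi-start over the midpoint (minimum, geometric
middle and maximum of the tested range; slope started at 1, asymptotes at
the observed extremes). Bounds keep the asymptotes identifiable on
6-point data: bottom ∈ [−20, 50], top ∈ [50, 150], slope ∈ [0.1, 10],
midpoint within the tested range ± 2 decades. "Convergence failure" is
operational: a hard solver failure, non-finite parameters, or a midpoint
pinned at its bound while fitting worse than the constant model. On
failure the ordinary logistic model is refitted on the log₁₀ axis; if
that also fails, a constant curve flagged non-converged is returned. A
solver stop on the evaluation budget still yields a usable solution and
is not treated as failure. Flat data (zero range) short-circuits to a
degenerate constant curve.

Short rows of the 4×4 triple design are fitted with relaxed asymptote
bounds (bottom ∈ [−20, 30], top ∈ [30, 150]) because the fixed drugs
depress the zero-dose viability below the single-agent top bound; the
bound overlap at a single point preserves top ≥ bottom.

IC values solve `I(x) = level` by bracketed root finding on the log axis,
restricted to the tested range ± 1 decade: beyond that span the curve is
considered not to reach the level, so wild extrapolations are never
reported as concentrations. If the level is already exceeded at the low
edge of the span, the edge is returned. Cohort-level IC20s (the priming
concentrations for combination designs) are geometric means over samples,
excluding — and counting — samples whose curves never reach 20%.

## Drug sensitivity score

DSS integrates the clamped inhibition curve above the activity threshold
*t* (default 10% inhibition) on the log₁₀-concentration axis, normalized
by `(100 − t)·(x_max − x_min)` so that 100 means complete kill across the
whole range. There is no logarithm-of-upper-limit divisor. Integration
uses a fixed 1024-point trapezoid grid (branch-agnostic between the two
fitted model families), with the threshold crossing refined by bisection;
agreement with a 10⁵-point quadrature oracle is within 10⁻³ DSS units,
enforced by test. Clamping inhibition to [0, 100] inside the integral
prevents growth stimulation (negative inhibition) from producing negative
area, keeping DSS in [0, 100]. Band edges are low [0, 10], intermediate
(10, 40], high (40, 100].

For primed doubles, one DSS is computed for the combination curve and one
for the partner's single-agent curve over the *identical* partner
concentration range; their difference is the combination benefit. For
triples, each of the four rows (first drug fixed, second titrated) is
fitted and scored over the titrated range, and the four scores are
averaged; the row orientation is a declared convention, with column-wise
averaging available behind a flag.

## Synergy

Bliss independence `E = fA + fB − fA·fB` on clamped inhibition fractions
is the only reference model. Cell scores are `100·(f_obs − E)` in
percentage points; the matrix summary reports the mean over non-zero dose
pairs and the synergy sum (mean × number of cells, 16 for the 4×4
design). Classification is strictly `score > 0`, with no noise band.

Triple designs are scored by **conditional two-way Bliss**: the fixed
background drug is common to every cell, so its effect is absorbed into
the baseline by renormalizing all viabilities to the background-alone
wells before computing inhibition fractions. Three-way attribution is
unidentifiable from a design in which the third drug never varies; an
exploratory three-way mode (`1 − (1−fA)(1−fB)(1−fC)`) exists behind a
flag for sensitivity analysis. Monotherapy anchors come from zero-dose
arm wells when present and from single-agent fitted curves otherwise;
the source is recorded.

## Synthetic plates

The simulator inverts the analysis models so every stage has a recovery
test surface. True responses follow the same log-logistic family the
analysis fits; combinations compose survival multiplicatively with an
optional uniform Bliss excess `delta` subtracted when both paired drugs
are dosed (clamped to [0, 1]); the background drug of the triple design
always composes multiplicatively, with synergy injected only on the
varying pair. Noise is multiplicative lognormal on the raw signal (mean
1, configurable CV) — luminescence scales with cell number and signals
stay non-negative — with an optional rate of gross outlier wells
(signal × 3 by default) whose ground-truth labels score the outlier
screen. Controls default to 16 + 16 wells per plate, enough for a stable
Z′; replicates default to 2 per treated condition. Cohort plates default
to one well per condition so a 30-drug × 6-concentration panel fits a
single 384-well plate alongside its controls.

The positive-control background signal defaults to zero so the
ground-truth viability scale and the control-normalized scale coincide;
a non-zero `pos_ctrl_fraction` is available to study that normalization
bias explicitly. Per-sample heterogeneity multiplies drug-level IC50s by
a lognormal factor (log-SD 0.5 by default, a realistic spread for ex vivo
cohorts); two-group mode multiplies the resistant half's IC50s by a fold
shift on a subset of drugs and records the labels.

Deliberately not modeled: spatial plate effects (edge evaporation,
drift), growth kinetics, batch effects between plates, and correlated
noise. Passing recovery tests therefore shows the analysis is correct
under the stated noise model, not that it is robust to artifacts the
simulator does not produce.

When validating recovery of an injected interaction, study conditions are
chosen so the effect is identifiable: dose grids and potencies that keep
combined survival away from the [0, 1] clamp, where part of the injected
excess would be truncated by construction.

## Cohort analysis

Clustering uses `scipy.cluster.hierarchy.linkage(method="ward")` on
Euclidean distances — the Ward.D2-style criterion, pinned for
reproducibility. DSS values are clustered unscaled by default (they share
the 0–100 scale); per-treatment z-scoring is behind a flag. Missing cells
are imputed with the treatment-wise median before clustering and the
imputation count is reported. Dendrograms export as Newick with branch
lengths derived from merge heights. The number of clusters is a user
parameter (`k`); the package takes no position on the "right" cut.

Two-group comparisons use the Mann–Whitney U test: the exact distribution
for combined n ≤ 12 (scipy's exact method without ties; a direct
enumeration over all group assignments when ties are present), and the
tie-corrected normal approximation with continuity correction otherwise.

## Pipeline and reproducibility

The pipeline classifies treatment groups structurally: one drug titrated
= single agent; two drugs with one fixed = primed double; three drugs
with two varying = triple matrix, whose two-drug arms are consumed as
monotherapy anchors rather than re-analyzed as doubles. All iteration is
sorted, every random stream derives from the single run seed, and floats
are written with fixed formatting, so identical inputs give byte-identical
output tables. Configuration comes from defaults, an optional YAML file
and flags (flags win); the effective configuration is echoed into the run
directory and its hash logged.

Problem sizes in tests and the acceptance script (6-drug panels, 200
plates for the outlier screen, 100 seeds for synergy recovery, 20 seeds
for cluster recovery, a 44-sample × 30-drug cohort for the end-to-end
run) were chosen to give stable estimates at interactive runtimes.

## Known limitations

- The logistic fallback's midpoint lives on the log₁₀ axis; `midpoint_nM`
  converts, but slope values are not comparable between the two families.
- Four-point row fits of the triple design are weakly identified; bounds
  and the constant-model fallback keep them stable, but per-row
  parameters should not be over-interpreted — only the integrated DSS is
  reported.
- Conditional Bliss requires measurable background-alone viability; a
  background drug that kills everything leaves the triple synergy
  undefined (reported in the log, not guessed).
- The Mann–Whitney exact branch enumerates all assignments only for
  combined n ≤ 12; beyond that the normal approximation is used even
  when ties make it conservative.
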