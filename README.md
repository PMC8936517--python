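# drugscreen

Analysis toolkit for ex vivo drug-sensitivity screening of patient-derived
cells (e.g. CD138⁺ multiple-myeloma cells) in 384-well viability assays.
It covers the full path from raw luminescence plates to cohort-level
results: plate quality control and control-based normalization,
concentration–response curve fitting, drug sensitivity scoring, Bliss
synergy analysis for drug combinations, and hierarchical clustering of
drug-response profiles across a patient cohort. A built-in simulator
generates plates with known ground truth, so every stage of the analysis
can be validated by parameter recovery.

It is aimed at groups running functional precision-oncology screens who
want a reproducible, scriptable alternative to spreadsheet pipelines and
point-and-click web tools.

## The quantities it computes

**Plate QC.** Each plate carries DMSO vehicle wells (negative controls,
100% viability) and benzethonium-chloride wells (positive controls, full
kill). Control separation is summarized by the Z′-factor

    Z' = 1 − 3(σ₊ + σ₋) / |μ₊ − μ₋|

and viability is normalized as `V = 100·(signal − μ₊)/(μ₋ − μ₊)`. An
automated two-stage outlier screen (replicate consistency on the
multiplicative noise scale, plus curve-fit residuals) replaces manual
curation; flagged wells are excluded from fits but never deleted.

**Curve fitting.** Each titration is fitted with the four-parameter
log-logistic model

    V(x) = c + (d − c) / (1 + exp(b·(ln x − ln e)))

(slope *b*, bottom *c*, top *d*, midpoint *e*), with an ordinary logistic
fallback on the log₁₀ axis when the log-logistic fit fails to converge.
IC20/IC50 are read off the fitted curve, never extrapolated more than one
decade beyond the tested range.

**Drug sensitivity score (DSS).** A type-1 area metric with activity
threshold *t* = 10% inhibition, integrated on the log₁₀-concentration
axis over the tested range and normalized to [0, 100] (no
logarithm-of-upper-limit divisor):

    DSS = 100 · ∫ₓₜ^xmax (Î(x) − t) dx / ((100 − t)(x_max − x_min))

with Î the inhibition curve clamped to [0, 100] and x_t its first
threshold crossing. Scores fall into efficacy bands: low [0, 10],
intermediate (10, 40], high (40, 100].

**Combinations.** Doubles follow the IC20-priming design (potent drug
fixed at its cohort IC20, partner titrated 0.1–1000 nM): the combination
DSS is compared with the partner's single-agent DSS over the identical
range, and Bliss synergy `100·(f_obs − (fA + fB − fA·fB))` is scored per
concentration. Triples use a 4×4 dose matrix (0.1–100 nM) over a third
drug fixed at its IC20; the matrix DSS is the mean of per-row curve
scores, and synergy is summed over the 16 cells with the background drug
absorbed into the baseline (conditional two-way Bliss). A combination is
called synergistic when its mean score exceeds 0.

**Cohort analysis.** Per-sample DSS vectors are assembled into a samples
× treatments matrix, clustered with Euclidean distance and Ward linkage
(dendrograms exportable as Newick), and two-group comparisons use the
Mann–Whitney U test (exact for small samples, tie-corrected normal
approximation otherwise).

## Worked example

`examples/single_agent_dss.py` simulates one plate (five drugs, 6-point
titrations 0.1–10 000 nM, 5% multiplicative noise), runs QC,
normalization, outlier screening, curve fitting and scoring:

```
plate P1: Z' = 0.871 (usable: True)
drug            IC50 fit IC50 true    DSS  band
bortezomib          10.6      10.0   56.5  high
carfilzomib          2.9       3.0   67.5  high
dexamethasone       47.4      50.0   43.2  high
melflufen          288.2     300.0   27.9  intermediate
venetoclax        4863.8    5000.0    6.9  low
```

Fitted IC50s track the simulator's ground truth, and DSS ranks the drugs
by how much of the tested range shows activity — venetoclax (IC50 at the
edge of the range) scores in the low-efficacy band despite eventually
reaching 50% inhibition. `examples/combination_synergy.py` and
`examples/cohort_clustering.py` walk through the combination designs and
the cohort clustering the same way.

The same pipeline is available from the shell:

```bash
drugscreen simulate --design cohort --samples 4 --seed 7 --out sim/
drugscreen run sim/plates.csv --out results/
```

which writes `qc_report.csv`, `normalized_wells.csv`, `curves.csv`,
`dss_single.csv`, `dss_combo.csv`, `synergy.csv`,
`synergy_landscape.csv`, `cohort_matrix.csv` and a Newick dendrogram
under `results/`. Identical inputs and seed give byte-identical outputs.

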