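"""Single-agent screening walkthrough: simulate one 384-well plate, run QC,
normalize to controls, fit log-logistic curves, and score drug sensitivity.

The printed table shows, per drug, the fitted IC50 against its true value
and the drug sensitivity score (DSS) with its efficacy band — DSS near 0
means the drug never clears the 10% activity threshold over the tested
range, DSS near 100 means complete kill across all six concentrations.
"""

import drugscreen as ds

panel = [ds.GroundTruthProfile("bortezomib", ic50=10.0),
         ds.GroundTruthProfile("carfilzomib", ic50=3.0),
         ds.GroundTruthProfile("dexamethasone", ic50=50.0),
         ds.GroundTruthProfile("melflufen", ic50=300.0),
         ds.GroundTruthProfile("venetoclax", ic50=5000.0)]

plate, truth = ds.simulate_single_agent(
    panel, noise=ds.NoiseModel(cv=0.05, seed=1))

report = ds.zprime(plate)
print(f"plate {report.plate_id}: Z' = {report.zprime:.3f} "
      f"(usable: {report.usable})")

norm = ds.flag_outliers(ds.normalize(plate, report))
treated = norm[norm["role"] == "treated"]

print(f"{'drug':<14} {'IC50 fit':>9} {'IC50 true':>9} {'DSS':>6}  band")
for drug, grp in treated.groupby("drug1"):
    curve = ds.fit_curve(grp["conc1_nM"], grp["viability_pct"],
                         flags=grp["outlier"])
    score = ds.dss(curve)
    ic50 = ds.ic_value(curve, 50.0)
    true = truth.profiles[drug].ic50
    ic50_txt = f"{ic50:9.1f}" if ic50 is not None else "  >range "
    print(f"{drug:<14} {ic50_txt} {true:9.1f} {score:6.1f}  "
          f"{ds.classify(score)}")
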