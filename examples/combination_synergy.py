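"""Combination screening walkthrough: an IC20-primed double combination and
a 4x4 triple-design matrix, both with a known injected Bliss excess.

The mean synergy score is the average observed inhibition above the Bliss
independence prediction, in percentage points: the simulator injects 10
points, so recovered scores near +10 (double) and a clearly positive
synergy sum (triple) are the expected outcome.  The delta-DSS line shows
how much the priming drug adds to the partner's own sensitivity score over
the identical concentration range.
"""

import drugscreen as ds

bortezomib = ds.GroundTruthProfile("bortezomib", ic50=10.0)
dexamethasone = ds.GroundTruthProfile("dexamethasone", ic50=200.0)
panobinostat = ds.GroundTruthProfile("panobinostat", ic50=100.0)

synergy = ds.InteractionModel("bliss_shifted", delta=0.10)

# priming dose = bortezomib's IC20 on its true curve (unit slope: ic50/4)
ic20 = 2.5

double, _ = ds.simulate_double_primed(
    bortezomib, ic20, dexamethasone, interaction=synergy,
    noise=ds.NoiseModel(cv=0.05, seed=7), plate_id="DBL",
    sample_id="MM01")
triple, _ = ds.simulate_triple_matrix(
    bortezomib, dexamethasone, background=panobinostat,
    background_conc=25.0, interaction=synergy,
    noise=ds.NoiseModel(cv=0.05, seed=8), plate_id="TRI",
    sample_id="MM01")

res = ds.run_pipeline([double, triple], ds.load_config())

for _, row in res.synergy.iterrows():
    print(f"{row['combination_label']}: design={row['design']} "
          f"mean synergy = {row['mean_synergy']:+.1f} points, "
          f"synergy sum = {row['synergy_sum']:+.1f}, "
          f"synergistic: {row['synergistic']}")

dbl = res.dss_combo[res.dss_combo["source"] == "combo_double"].iloc[0]
print(f"combination DSS {dbl['dss_combo']:.1f} vs partner alone "
      f"{dbl['dss_single']:.1f}: delta-DSS = {dbl['delta_dss']:+.1f}")
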