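import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import drugscreen as ds
from drugscreen.plates import Plate, Treatment, Well
from drugscreen.qc import QcError


def control_plate(neg, pos, plate_id="P1"):
    """Plate holding only control wells with the given raw signals."""
    wells = []
    for i, s in enumerate(neg):
        wells.append(Well(plate_id, ("A", i + 1), "S1",
                          Treatment(role="negative_control"), s))
    for i, s in enumerate(pos):
        wells.append(Well(plate_id, ("B", i + 1), "S1",
                          Treatment(role="positive_control"), s))
    return Plate(plate_id=plate_id, sample_id="S1", wells=wells)


class TestZPrime:
    def test_zero_variance_gives_one(self):
        rep = ds.zprime(control_plate([10000, 10000], [500, 500]))
        assert rep.zprime == 1.0
        assert rep.usable

    def test_hand_computed_value(self):
        # mu_pos=500 sd_pos=50, mu_neg=10000 sd_neg=450:
        # Z' = 1 - 3*(50+450)/9500 = 0.84210...
        neg = [10000 - 450, 10000 + 450]
        pos = [500 - 50, 500 + 50]
        # sample SD of a symmetric pair {m-d, m+d} is d*sqrt(2); rescale
        neg = [10000 - 450 / np.sqrt(2), 10000 + 450 / np.sqrt(2)]
        pos = [500 - 50 / np.sqrt(2), 500 + 50 / np.sqrt(2)]
        rep = ds.zprime(control_plate(neg, pos))
        assert rep.zprime == pytest.approx(1 - 3 * 500 / 9500, abs=1e-9)
        assert rep.zprime == pytest.approx(0.8421, abs=1e-4)

    def test_degenerate_controls_unusable(self):
        rep = ds.zprime(control_plate([5000, 5000], [5000, 5000]))
        assert not rep.usable
        assert "degenerate" in rep.note

    def test_inverted_controls_unusable(self):
        rep = ds.zprime(control_plate([100, 110], [9000, 9100]))
        assert not rep.usable

    def test_missing_controls_rejected(self):
        with pytest.raises(QcError, match="control"):
            ds.zprime(control_plate([10000], [500, 500]))

    @settings(derandomize=True, max_examples=30)
    @given(sd=st.floats(min_value=0.0, max_value=400.0),
           bump=st.floats(min_value=1.0, max_value=400.0))
    def test_monotone_decreasing_in_control_sd(self, sd, bump):
        def z(s):
            neg = [10000 - s / np.sqrt(2), 10000 + s / np.sqrt(2)]
            return ds.zprime(control_plate(neg, [500.0, 500.0])).zprime
        assert z(sd + bump) < z(sd)


class TestNormalize:
    def make(self, signals):
        plate = control_plate([10000 - 450 / np.sqrt(2),
                               10000 + 450 / np.sqrt(2)],
                              [500 - 50 / np.sqrt(2), 500 + 50 / np.sqrt(2)])
        for i, s in enumerate(signals):
            plate.wells.append(Well("P1", ("C", i + 1), "S1",
                                    Treatment(drugs=(("d", 1.0),)), s))
        return plate

    def test_anchor_points(self):
        norm = ds.normalize(self.make([10000, 500, 5250]))
        t = norm[norm["role"] == "treated"]["viability_pct"].to_numpy()
        assert t[0] == pytest.approx(100.0)
        assert t[1] == pytest.approx(0.0)
        assert t[2] == pytest.approx(50.0)

    def test_control_means_map_to_100_and_0(self):
        norm = ds.normalize(self.make([7000]))
        assert norm[norm["role"] == "negative_control"][
            "viability_pct"].mean() == pytest.approx(100.0)
        assert norm[norm["role"] == "positive_control"][
            "viability_pct"].mean() == pytest.approx(0.0)

    def test_affine_invariance_under_rescaling(self):
        plate = self.make([8000, 3000, 600])
        norm1 = ds.normalize(plate)
        for w in plate.wells:
            w.raw_signal *= 3.7
        norm2 = ds.normalize(plate)
        np.testing.assert_allclose(norm1["viability_pct"],
                                   norm2["viability_pct"], rtol=1e-12)

    def test_inhibition_clamped_viability_not(self):
        norm = ds.normalize(self.make([12000, 100]))
        t = norm[norm["role"] == "treated"]
        assert t["viability_pct"].iloc[0] > 100.0    # unclamped overshoot
        assert t["inhibition_frac"].iloc[0] == 0.0   # clamped for Bliss
        assert 0.0 <= t["inhibition_frac"].iloc[1] <= 1.0

    def test_unusable_plate_needs_override(self):
        plate = control_plate([5000, 5000], [5000, 5000])
        with pytest.raises(QcError, match="failed QC"):
            ds.normalize(plate)


class TestOutlierScreen:
    def frame(self, viabilities, label="d@1"):
        return pd.DataFrame({
            "plate_id": "P1", "well": [f"A{i+1:02d}" for i in
                                       range(len(viabilities))],
            "sample_id": "S1", "role": "treated", "treatment_label": label,
            "n_drugs": 1, "drug1": "d", "conc1_nM": 1.0,
            "drug2": "", "conc2_nM": np.nan, "drug3": "", "conc3_nM": np.nan,
            "raw_signal": 1.0, "viability_pct": viabilities,
            "inhibition_frac": 0.5, "outlier": False, "excluded": False,
            "qc_override": False})

    def test_gross_replicate_outlier_flagged(self):
        out = ds.flag_outliers(self.frame([48.0, 52.0, 150.0]),
                               residual_rule=False)
        assert list(out["outlier"]) == [False, False, True]

    def test_pairs_not_adjudicated_by_replicate_rule(self):
        out = ds.flag_outliers(self.frame([48.0, 52.0]), residual_rule=False)
        assert not out["outlier"].any()

    def test_screen_performance_on_labeled_plates(self, drug_panel):
        """Sensitivity >= 0.8 and false-flag rate <= 0.02 against the
        simulator's ground-truth outlier labels (200 seeded plates)."""
        tp = fp = fn = tn = 0
        for seed in range(200):
            noise = ds.NoiseModel(cv=0.05, outlier_rate=0.02,
                                  outlier_scale=3.0, seed=900 + seed)
            plate, truth = ds.simulate_single_agent(drug_panel, noise=noise)
            norm = ds.flag_outliers(ds.normalize(plate))
            t = norm[norm["role"] == "treated"]
            truth_wells = {w for _, w in truth.outlier_wells}
            is_out = t["well"].isin(truth_wells)
            fl = t["outlier"]
            tp += (is_out & fl).sum()
            fp += (fl & ~is_out).sum()
            fn += (is_out & ~fl).sum()
            tn += (~fl & ~is_out).sum()
        assert tp + fn > 100  # enough labeled outliers to score against
        assert tp / (tp + fn) >= 0.8
        assert fp / (fp + tn) <= 0.02

    def test_flagged_wells_kept_in_table(self):
        df = self.frame([48.0, 52.0, 150.0])
        out = ds.flag_outliers(df, residual_rule=False)
        assert len(out) == len(df)


class TestReplicateCorrelation:
    def test_identical_replicates_give_one(self, drug_panel):
        noise = ds.NoiseModel(cv=0.05, seed=3)
        plate, _ = ds.simulate_single_agent(drug_panel, noise=noise)
        norm = ds.normalize(plate)
        assert ds.replicate_correlation(norm, norm) == pytest.approx(1.0)

    def test_simulated_replicate_pair_highly_correlated(self, drug_panel):
        p1, _ = ds.simulate_single_agent(drug_panel,
                                         noise=ds.NoiseModel(cv=0.05, seed=21))
        p2, _ = ds.simulate_single_agent(drug_panel,
                                         noise=ds.NoiseModel(cv=0.05, seed=22))
        r2 = ds.replicate_correlation(ds.normalize(p1), ds.normalize(p2))
        assert r2 >= 0.9

    def test_constant_replicate_rejected(self):
        df = TestOutlierScreen().frame([50.0, 50.0, 50.0])
        other = TestOutlierScreen().frame([40.0, 60.0, 80.0])
        # distinct labels so >= 3 matched treatments exist
        for d, vals in ((df, [50.0] * 3), (other, [40.0, 60.0, 80.0])):
            d["treatment_label"] = [f"d@{i}" for i in range(3)]
        with pytest.raises(QcError, match="constant"):
            ds.replicate_correlation(df, other)

    def test_too_few_matches_rejected(self):
        df = TestOutlierScreen().frame([50.0, 60.0])
        with pytest.raises(QcError, match="matched"):
            ds.replicate_correlation(df, df.iloc[:1])
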