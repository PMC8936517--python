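import numpy as np
import pytest

import drugscreen as ds
from drugscreen.plates import wells_to_frame


def treated_signals(plate, drug=None, conc=None):
    out = []
    for w in plate.wells:
        if w.treatment.role != "treated":
            continue
        if drug is not None and w.treatment.drugs[0][0] != drug:
            continue
        if conc is not None and not np.isclose(w.treatment.drugs[0][1], conc):
            continue
        out.append(w.raw_signal)
    return np.array(out)


class TestSingleAgent:
    def test_half_max_signal_by_construction(self, quiet):
        prof = ds.GroundTruthProfile("d", ic50=10.0, hill_slope=1.0)
        plate, _ = ds.simulate_single_agent([prof], noise=quiet)
        sig = treated_signals(plate, conc=10.0)
        np.testing.assert_allclose(sig, 0.5 * quiet.neg_ctrl_signal)

    def test_seeded_runs_are_bit_identical(self, drug_panel):
        noise = ds.NoiseModel(cv=0.05, outlier_rate=0.05, seed=42)
        p1, t1 = ds.simulate_single_agent(drug_panel, noise=noise)
        p2, t2 = ds.simulate_single_agent(drug_panel, noise=noise)
        assert wells_to_frame(p1.wells).equals(wells_to_frame(p2.wells))
        assert t1.outlier_wells == t2.outlier_wells

    def test_empirical_cv_matches_noise_model(self):
        prof = ds.GroundTruthProfile("d", ic50=10.0)
        noise = ds.NoiseModel(cv=0.05, seed=7)
        plate, _ = ds.simulate_single_agent([prof], concentrations=[1.0, 10.0, 100.0],
                                            noise=noise, n_replicates=100)
        sig = treated_signals(plate, conc=10.0)
        assert len(sig) == 100
        cv = sig.std(ddof=1) / sig.mean()
        assert 0.03 <= cv <= 0.07

    def test_non_increasing_grid_rejected(self, drug_panel, quiet):
        with pytest.raises(ValueError, match="strictly increasing"):
            ds.simulate_single_agent(drug_panel, concentrations=[10.0, 1.0],
                                     noise=quiet)

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError, match="cv"):
            ds.NoiseModel(cv=-0.1)


class TestDoublePrimed:
    def setup_method(self):
        self.primer = ds.GroundTruthProfile("bortezomib", ic50=10.0)
        self.partner = ds.GroundTruthProfile("dexamethasone", ic50=50.0)

    def test_independence_multiplies_survival(self, quiet):
        plate, _ = ds.simulate_double_primed(self.primer, 2.5, self.partner,
                                             noise=quiet)
        s_primer = float(self.primer.survival(2.5))
        for w in plate.wells:
            if w.treatment.role == "treated" and len(w.treatment.drugs) == 2:
                conc = dict(w.treatment.drugs)["dexamethasone"]
                expected = s_primer * float(self.partner.survival(conc))
                assert w.raw_signal == pytest.approx(
                    expected * quiet.neg_ctrl_signal)

    def test_shifted_model_adds_exact_excess(self, quiet):
        inter = ds.InteractionModel("bliss_shifted", delta=0.1)
        plate, _ = ds.simulate_double_primed(self.primer, 2.5, self.partner,
                                             interaction=inter, noise=quiet)
        s_primer = float(self.primer.survival(2.5))
        for w in plate.wells:
            if w.treatment.role == "treated" and len(w.treatment.drugs) == 2:
                conc = dict(w.treatment.drugs)["dexamethasone"]
                bliss = s_primer * float(self.partner.survival(conc))
                observed = w.raw_signal / quiet.neg_ctrl_signal
                assert observed == pytest.approx(max(bliss - 0.1, 0.0),
                                                 abs=1e-12)

    def test_wrong_titration_length_rejected(self, quiet):
        with pytest.raises(ValueError, match="5 partner concentrations"):
            ds.simulate_double_primed(self.primer, 2.5, self.partner,
                                      partner_concs=[0.1, 1, 10, 100],
                                      noise=quiet)

    def test_nonpositive_primer_conc_rejected(self, quiet):
        with pytest.raises(ValueError, match="primer"):
            ds.simulate_double_primed(self.primer, 0.0, self.partner,
                                      noise=quiet)


class TestTripleMatrix:
    def setup_method(self):
        self.a = ds.GroundTruthProfile("a", ic50=10.0)
        self.b = ds.GroundTruthProfile("b", ic50=50.0)
        self.bg = ds.GroundTruthProfile("bg", ic50=40.0)

    def test_background_composes_multiplicatively(self, quiet):
        # choose the background dose so its survival is 0.8 and drug A's is 0.5
        bg_conc = 10.0  # survival 40/(40+10) = 0.8
        plate, _ = ds.simulate_triple_matrix(
            self.a, self.b, background=self.bg, background_conc=bg_conc,
            noise=quiet)
        assert float(self.bg.survival(bg_conc)) == pytest.approx(0.8)
        for w in plate.wells:
            drugs = dict(w.treatment.drugs)
            if set(drugs) == {"a", "bg"} and np.isclose(drugs["a"], 10.0):
                viab = 100.0 * w.raw_signal / quiet.neg_ctrl_signal
                assert viab == pytest.approx(40.0)  # 0.5 * 0.8

    def test_independent_matrix_has_zero_conditional_excess(self, quiet):
        plate, _ = ds.simulate_triple_matrix(
            self.a, self.b, background=self.bg, background_conc=10.0,
            noise=quiet)
        s_bg = float(self.bg.survival(10.0))
        for w in plate.wells:
            drugs = dict(w.treatment.drugs)
            if set(drugs) == {"a", "b", "bg"}:
                s_obs = w.raw_signal / quiet.neg_ctrl_signal
                s_expected = (float(self.a.survival(drugs["a"]))
                              * float(self.b.survival(drugs["b"])) * s_bg)
                assert s_obs == pytest.approx(s_expected, abs=1e-12)

    def test_wrong_grid_rejected(self, quiet):
        with pytest.raises(ValueError, match="4x4"):
            ds.simulate_triple_matrix(self.a, self.b, grid_a=[0.1, 1, 10],
                                      noise=quiet)

    def test_seeded_reproducibility(self):
        noise = ds.NoiseModel(cv=0.1, seed=5)
        p1, _ = ds.simulate_triple_matrix(self.a, self.b, background=self.bg,
                                          background_conc=10.0, noise=noise)
        p2, _ = ds.simulate_triple_matrix(self.a, self.b, background=self.bg,
                                          background_conc=10.0, noise=noise)
        assert wells_to_frame(p1.wells).equals(wells_to_frame(p2.wells))


class TestCohort:
    def test_zero_heterogeneity_gives_identical_samples(self, drug_panel, quiet):
        plates, truth = ds.simulate_cohort(3, drug_panel, heterogeneity=0.0,
                                           noise=quiet)
        per_sample = truth.table.groupby("sample_id")["ic50"].apply(tuple)
        assert per_sample.nunique() == 1

    def test_two_group_labels_and_fold_shift(self, drug_panel, quiet):
        plates, truth = ds.simulate_cohort(
            4, drug_panel, heterogeneity=0.0, noise=quiet, two_group=True,
            fold_shift=100.0, shifted_drug_fraction=0.5)
        t = truth.table
        assert set(t["group_label"]) == {"sensitive", "resistant"}
        shifted = sorted(p.drug_name for p in drug_panel)[:0]  # order-free check
        by_drug = t.pivot(index="sample_id", columns="drug", values="ic50")
        groups = t.groupby("sample_id")["group_label"].first()
        ratio = (by_drug[groups == "resistant"].iloc[0]
                 / by_drug[groups == "sensitive"].iloc[0])
        assert sorted(ratio)[:3] == pytest.approx([1.0, 1.0, 1.0])
        assert sorted(ratio)[3:] == pytest.approx([100.0, 100.0, 100.0])

    def test_cohort_design_arithmetic(self, quiet):
        drugs = [ds.GroundTruthProfile(f"d{i}", ic50=10.0 * (i + 1))
                 for i in range(30)]
        plates, truth = ds.simulate_cohort(5, drugs, noise=quiet)
        assert len(plates) == 5
        for plate in plates:
            treated = [w for w in plate.wells
                       if w.treatment.role == "treated"]
            assert len(treated) == 180  # 30 drugs x 6 concentrations

    def test_negative_heterogeneity_rejected(self, drug_panel, quiet):
        with pytest.raises(ValueError, match="heterogeneity"):
            ds.simulate_cohort(3, drug_panel, heterogeneity=-1.0, noise=quiet)


def test_noiseless_pipeline_recovers_true_dss(drug_panel, quiet):
    """cv=0, no outliers: normalize -> fit -> DSS matches analytic truth."""
    plate, truth = ds.simulate_single_agent(drug_panel, noise=quiet)
    norm = ds.normalize(plate)
    t = norm[norm["role"] == "treated"]
    for drug, grp in t.groupby("drug1"):
        curve = ds.fit_curve(grp["conc1_nM"].to_numpy(float),
                             grp["viability_pct"].to_numpy(float))
        value = ds.dss(curve)
        true = float(truth.table.set_index("drug").loc[drug, "true_dss"])
        assert value == pytest.approx(true, abs=0.1)
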