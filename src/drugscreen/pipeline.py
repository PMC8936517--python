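"""End-to-end screening pipeline: qc -> normalize -> outliers -> fit -> DSS
-> synergy -> cohort, with every stage's table written under the run
directory.

Treatment groups are classified by structure: one-drug titrations are
single agents; two-drug groups with one fixed and one varying
concentration are primed doubles; three-drug groups with two varying
concentrations are 4x4 triple matrices whose fixed drug is the background.
The two-drug monotherapy arms of a triple plate (drug + background) are
consumed as the matrix's zero-dose row/column rather than re-analyzed as
doubles.  Triple synergy uses conditional two-way Bliss: all inhibition
fractions are renormalized to the background-alone wells so the fixed
drug's effect sits in the baseline.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import qc as qc_mod
from .config import RunConfig, dump_config
from .cohort import assemble, cluster, to_newick, CohortError
from .dss import DssConfig, DssRecord, classify, combo_dss_double, combo_dss_triple, dss
from .fitting import DoseResponseCurve, FitError, fit_curve, ic_value
from .plates import Plate, read_plate_table, write_results
from .synergy import DoseMatrix, excess_matrix, landscape_export, primed_double_synergy


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    qc: pd.DataFrame = field(default_factory=pd.DataFrame)
    normalized: pd.DataFrame = field(default_factory=pd.DataFrame)
    curves: pd.DataFrame = field(default_factory=pd.DataFrame)
    dss_single: pd.DataFrame = field(default_factory=pd.DataFrame)
    dss_combo: pd.DataFrame = field(default_factory=pd.DataFrame)
    synergy: pd.DataFrame = field(default_factory=pd.DataFrame)
    landscape: pd.DataFrame = field(default_factory=pd.DataFrame)
    cohort_matrix: Optional[pd.DataFrame] = None
    clusters: Optional[pd.DataFrame] = None
    newick: Optional[str] = None
    log: list[str] = field(default_factory=list)


def _curve_row(sample_id: str, label: str, curve: DoseResponseCurve) -> dict:
    ic20 = ic_value(curve, 20.0)
    ic50 = ic_value(curve, 50.0)
    return {"sample_id": sample_id, "treatment_label": label,
            "model": curve.model, "top": curve.top, "bottom": curve.bottom,
            "slope": curve.slope, "midpoint_nM": curve.midpoint_nM,
            "rss": curve.rss, "converged": curve.converged,
            "ic20_nM": np.nan if ic20 is None else ic20,
            "ic50_nM": np.nan if ic50 is None else ic50}


def _group_kind(grp: pd.DataFrame) -> tuple[str, list[str], list[str]]:
    """Classify a treatment group: (kind, varying drugs, fixed drugs)."""
    drugs, varying, fixed = [], [], []
    for i in (1, 2, 3):
        names = [n for n in grp[f"drug{i}"].unique() if isinstance(n, str) and n]
        if not names:
            continue
        name = str(names[0])
        drugs.append(name)
        if grp[f"conc{i}_nM"].nunique() > 1:
            varying.append(name)
        else:
            fixed.append(name)
    if len(drugs) == 1:
        return "single", varying, fixed
    if len(drugs) == 2 and len(varying) == 1:
        return "double", varying, fixed
    if len(drugs) == 3 and len(varying) == 2:
        return "triple", varying, fixed
    return "other", varying, fixed


def _conc_column(grp: pd.DataFrame, drug: str) -> str:
    for i in (1, 2, 3):
        vals = [n for n in grp[f"drug{i}"].unique() if isinstance(n, str) and n]
        if vals and str(vals[0]) == drug:
            return f"conc{i}_nM"
    raise KeyError(drug)


def _cell_means(grp: pd.DataFrame, cols: list[str], value: str) -> pd.Series:
    good = grp[~grp["outlier"] & ~grp["excluded"]]
    return good.groupby(cols)[value].mean()


def run_pipeline(plates: list[Plate], config: RunConfig,
                 outdir: Optional[str | Path] = None) -> PipelineResult:
    res = PipelineResult()
    dss_cfg = DssConfig(activity_threshold=config.dss_threshold,
                        grid_n=config.dss_grid_n)

    # --- stage: qc ---
    reports = []
    for plate in plates:
        try:
            reports.append(qc_mod.zprime(plate, floor=config.zprime_floor))
        except qc_mod.QcError as e:
            raise PipelineError("qc", str(e)) from e
    res.qc = pd.DataFrame([asdict(r) for r in reports])
    for r in reports:
        res.log.append(f"qc: plate {r.plate_id} Z'={r.zprime:.4f} "
                       f"usable={r.usable}{' (' + r.note + ')' if r.note else ''}")

    # --- stage: normalize (+ outlier screen) ---
    norm_frames = []
    for plate, report in zip(plates, reports):
        if not report.usable and not config.force_normalize:
            res.log.append(f"normalize: plate {plate.plate_id} skipped (failed QC)")
            continue
        norm = qc_mod.normalize(plate, report, override=config.force_normalize,
                                floor=config.zprime_floor)
        norm_frames.append(norm)
    if not norm_frames:
        raise PipelineError("normalize", "no usable plates")
    normalized = pd.concat(norm_frames, ignore_index=True)
    normalized = qc_mod.flag_outliers(normalized,
                                      replicate_rule=config.replicate_rule,
                                      residual_rule=config.residual_rule)
    res.normalized = normalized
    n_flagged = int(normalized["outlier"].sum())
    res.log.append(f"outliers: {n_flagged} well(s) flagged")
    n_out = normalized.groupby("plate_id")["outlier"].sum()
    res.qc["n_outliers_flagged"] = res.qc["plate_id"].map(n_out).fillna(0).astype(int)

    treated = normalized[normalized["role"] == "treated"]
    drug_cols = ["drug1", "drug2", "drug3"]
    groups = {key: grp for key, grp in
              treated.groupby(["sample_id"] + drug_cols, sort=True)}

    # --- stage: fit + dss (single agents) ---
    curve_rows, single_records = [], []
    single_curves: dict[tuple[str, str], DoseResponseCurve] = {}
    fallback_count = 0
    triple_arm_keys: set = set()

    # identify triple matrices first so their two-drug arms are not doubles
    triples = []
    for key, grp in groups.items():
        kind, varying, fixed = _group_kind(grp)
        if kind == "triple":
            triples.append((key, grp, varying, fixed))
            sample_id = key[0]
            bg = fixed[0]
            for v in varying:
                names = tuple(sorted([v, bg]))
                triple_arm_keys.add((sample_id, names))
            triple_arm_keys.add((sample_id, (bg,)))

    for key, grp in sorted(groups.items()):
        kind, varying, fixed = _group_kind(grp)
        sample_id = key[0]
        if kind != "single":
            continue
        drug = varying[0] if varying else fixed[0]
        cc = _conc_column(grp, drug)
        good = grp[~grp["outlier"] & ~grp["excluded"]]
        if good[cc].nunique() < 4:
            continue  # fixed-dose monotherapy anchors, not a titration
        try:
            curve = fit_curve(good[cc].to_numpy(float),
                              good["viability_pct"].to_numpy(float))
        except FitError as e:
            raise PipelineError("fit", f"sample {sample_id} drug {drug}: {e}") from e
        if curve.model == "L4":
            fallback_count += 1
        single_curves[(sample_id, drug)] = curve
        curve_rows.append(_curve_row(sample_id, drug, curve))
        value = dss(curve, curve.conc_range, dss_cfg)
        single_records.append(DssRecord(sample_id=sample_id,
                                        treatment_label=drug, dss=value,
                                        conc_range=curve.conc_range,
                                        t=dss_cfg.activity_threshold,
                                        source="single"))
    res.log.append(f"fit: {len(curve_rows)} single-agent curves, "
                   f"{fallback_count} logistic fallback(s)")

    # --- stage: combos (primed doubles) ---
    combo_rows, synergy_rows, landscape_frames = [], [], []
    for key, grp in sorted(groups.items()):
        kind, varying, fixed = _group_kind(grp)
        sample_id = key[0]
        if kind != "double":
            continue
        partner, primer = varying[0], fixed[0]
        if (sample_id, tuple(sorted([partner, primer]))) in triple_arm_keys:
            continue
        pc = _conc_column(grp, partner)
        primer_conc = float(grp[_conc_column(grp, primer)].iloc[0])
        label = f"{primer}@{primer_conc:g}+{partner}"
        good = grp[~grp["outlier"] & ~grp["excluded"]]
        combo_viab = good.groupby(pc)["viability_pct"].mean()
        concs = combo_viab.index.to_numpy(float)
        if len(concs) < 4:
            res.log.append(f"combo: {sample_id} {label}: too few doses, skipped")
            continue
        try:
            combo_curve = fit_curve(concs, combo_viab.to_numpy(float))
        except FitError as e:
            raise PipelineError("fit", f"sample {sample_id} combo {label}: {e}") from e
        curve_rows.append(_curve_row(sample_id, label, combo_curve))

        # partner-alone wells on the same plates provide the single-agent
        # reference; fall back to a pre-fitted cohort curve when absent
        mono = treated[(treated["sample_id"] == sample_id)
                       & (treated["n_drugs"] == 1)
                       & (treated["drug1"] == partner)
                       & ~treated["outlier"] & ~treated["excluded"]]
        partner_curve = single_curves.get((sample_id, partner))
        if partner_curve is None and len(mono) >= 4:
            mv = mono.groupby("conc1_nM")["viability_pct"].mean()
            if mv.index.nunique() >= 4:
                partner_curve = fit_curve(mv.index.to_numpy(float),
                                          mv.to_numpy(float))
        if partner_curve is None:
            res.log.append(f"combo: {sample_id} {label}: no partner "
                           "monotherapy curve, DSS comparison skipped")
            continue
        rng = (float(concs.min()), float(concs.max()))
        d_combo, d_single, delta = combo_dss_double(
            combo_curve, partner_curve, conc_range=rng, config=dss_cfg)
        combo_rows.append({"sample_id": sample_id, "treatment_label": label,
                           "source": "combo_double", "dss_combo": d_combo,
                           "dss_single": d_single, "delta_dss": delta,
                           "band": classify(max(min(d_combo, 100.0), 0.0)),
                           "range_min_nM": rng[0], "range_max_nM": rng[1]})

        # Bliss synergy along the titration; inhibition fractions are
        # replicate means clamped after averaging (clamping each well first
        # would bias near-zero cells upward)
        def _inh(viab_mean):
            return np.clip((100.0 - viab_mean) / 100.0, 0.0, 1.0)

        combo_inh = _inh(_cell_means(grp, [pc], "viability_pct"))
        if len(mono):
            partner_inh = _inh(mono.groupby("conc1_nM")["viability_pct"].mean())
        else:  # evaluate the fitted single-agent curve at the combo doses
            partner_inh = pd.Series(
                np.clip(partner_curve.inhibition(combo_inh.index.to_numpy(float))
                        / 100.0, 0, 1), index=combo_inh.index)
        primer_mono = treated[(treated["sample_id"] == sample_id)
                              & (treated["n_drugs"] == 1)
                              & (treated["drug1"] == primer)
                              & ~treated["outlier"] & ~treated["excluded"]]
        at_fixed = primer_mono[np.isclose(primer_mono["conc1_nM"].astype(float),
                                          primer_conc)]
        if len(at_fixed):
            primer_inh = float(at_fixed["inhibition_frac"].mean())
        elif (sample_id, primer) in single_curves:
            pcv = single_curves[(sample_id, primer)]
            primer_inh = float(np.clip(pcv.inhibition(primer_conc) / 100.0, 0, 1))
        else:
            res.log.append(f"synergy: {sample_id} {label}: no primer "
                           "monotherapy inhibition, skipped")
            continue
        shared = [c for c in combo_inh.index if c in partner_inh.index]
        syn = primed_double_synergy(
            shared, combo_inh.loc[shared].to_numpy(float),
            primer_inh, partner_inh.loc[shared].to_numpy(float),
            primer_name=primer, partner_name=partner)
        synergy_rows.append({"sample_id": sample_id, "combination_label": label,
                             "design": syn.design,
                             "mean_synergy": syn.mean_synergy,
                             "synergy_sum": syn.synergy_sum,
                             "synergistic": syn.synergistic})
        land = landscape_export(syn)
        land.insert(0, "combination_label", label)
        land.insert(0, "sample_id", sample_id)
        landscape_frames.append(land)

    # --- stage: triples ---
    for key, grp, varying, fixed in sorted(triples, key=lambda t: t[0]):
        sample_id = key[0]
        drug_a, drug_b = sorted(varying)
        bg = fixed[0]
        ca_col, cb_col = _conc_column(grp, drug_a), _conc_column(grp, drug_b)
        bg_conc = float(grp[_conc_column(grp, bg)].iloc[0])
        label = f"{drug_a}+{drug_b}+{bg}@{bg_conc:g}"
        cells = _cell_means(grp, [ca_col, cb_col], "viability_pct")
        concs_a = np.array(sorted(cells.index.get_level_values(0).unique()))
        concs_b = np.array(sorted(cells.index.get_level_values(1).unique()))
        try:
            viab = np.array([[cells.loc[(a, b)] for b in concs_b]
                             for a in concs_a])
        except KeyError:
            raise PipelineError("synergy", f"sample {sample_id} {label}: "
                                "incomplete dose matrix")
        mean_dss, per_row, _ = combo_dss_triple(viab, concs_b, config=dss_cfg)
        combo_rows.append({"sample_id": sample_id, "treatment_label": label,
                           "source": "combo_triple", "dss_combo": mean_dss,
                           "dss_single": np.nan, "delta_dss": np.nan,
                           "band": classify(max(min(mean_dss, 100.0), 0.0)),
                           "range_min_nM": float(concs_b.min()),
                           "range_max_nM": float(concs_b.max())})

        # conditional two-way Bliss against the background-alone baseline
        def _arm(drug, col_drug):
            arm = treated[(treated["sample_id"] == sample_id)
                          & (treated["n_drugs"] == 2)
                          & ~treated["outlier"] & ~treated["excluded"]]
            arm = arm[((arm["drug1"] == drug) | (arm["drug2"] == drug))
                      & ((arm["drug1"] == bg) | (arm["drug2"] == bg))]
            cc = "conc1_nM" if (arm["drug1"] == drug).any() else "conc2_nM"
            return arm.groupby(cc)["viability_pct"].mean()

        bg_alone = treated[(treated["sample_id"] == sample_id)
                           & (treated["n_drugs"] == 1)
                           & (treated["drug1"] == bg)
                           & np.isclose(treated["conc1_nM"].astype(float), bg_conc)
                           & ~treated["outlier"] & ~treated["excluded"]]
        if not len(bg_alone):
            res.log.append(f"synergy: {sample_id} {label}: no background-alone "
                           "wells, synergy skipped")
            continue
        v_bg = float(bg_alone["viability_pct"].mean())
        if v_bg <= 0:
            res.log.append(f"synergy: {sample_id} {label}: background kills "
                           "everything, conditional Bliss undefined")
            continue
        arm_a, arm_b = _arm(drug_a, ca_col), _arm(drug_b, cb_col)
        if not all(c in arm_a.index for c in concs_a) or \
           not all(c in arm_b.index for c in concs_b):
            res.log.append(f"synergy: {sample_id} {label}: missing monotherapy "
                           "arm doses, synergy skipped")
            continue
        cond = lambda v: float(np.clip(1.0 - v / v_bg, 0.0, 1.0))
        matrix = DoseMatrix(
            drug_a=drug_a, drug_b=drug_b, concs_a=concs_a, concs_b=concs_b,
            inhibition=np.vectorize(cond)(viab),
            mono_a=np.array([cond(arm_a.loc[c]) for c in concs_a]),
            mono_b=np.array([cond(arm_b.loc[c]) for c in concs_b]),
            background=(bg, bg_conc),
            monotherapy_source=config.synergy_monotherapy_source)
        syn = excess_matrix(matrix)
        synergy_rows.append({"sample_id": sample_id, "combination_label": label,
                             "design": "triple_matrix",
                             "mean_synergy": syn.mean_synergy,
                             "synergy_sum": syn.synergy_sum,
                             "synergistic": syn.synergistic})
        land = landscape_export(syn)
        land.insert(0, "combination_label", label)
        land.insert(0, "sample_id", sample_id)
        landscape_frames.append(land)

    res.curves = pd.DataFrame(curve_rows)
    res.dss_single = pd.DataFrame(
        [{"sample_id": r.sample_id, "treatment_label": r.treatment_label,
          "source": r.source, "dss": r.dss, "band": r.band,
          "range_min_nM": r.conc_range[0], "range_max_nM": r.conc_range[1],
          "t": r.t} for r in single_records])
    res.dss_combo = pd.DataFrame(combo_rows)
    res.synergy = pd.DataFrame(synergy_rows)
    res.landscape = (pd.concat(landscape_frames, ignore_index=True)
                     if landscape_frames else pd.DataFrame(
                         columns=["sample_id", "combination_label",
                                  "concA_nM", "concB_nM", "excess"]))

    # --- stage: cohort ---
    if (len(res.dss_single) and res.dss_single["sample_id"].nunique() >= 2
            and res.dss_single["treatment_label"].nunique() >= 2):
        try:
            cm = assemble(res.dss_single)
            res.cohort_matrix = cm.dss
            cl = cluster(cm, axis="samples", k=config.cluster_k,
                         z_score=config.z_score)
            res.newick = to_newick(cl, cm.dss.index)
            if cl.labels is not None:
                res.clusters = cl.labels.rename_axis("sample_id").reset_index()
            res.log.append(f"cohort: clustered {len(cm.samples)} samples x "
                           f"{len(cm.treatments)} treatments "
                           f"({cl.imputed_cells} imputed cells)")
        except CohortError as e:
            res.log.append(f"cohort: skipped ({e})")

    if outdir is not None:
        _write_outputs(res, config, Path(outdir))
    return res


def _write_outputs(res: PipelineResult, config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    dump_config(config, outdir / "config.yaml")
    tables = {"qc_report.csv": res.qc, "normalized_wells.csv": res.normalized,
              "curves.csv": res.curves, "dss_single.csv": res.dss_single,
              "dss_combo.csv": res.dss_combo, "synergy.csv": res.synergy,
              "synergy_landscape.csv": res.landscape}
    if res.cohort_matrix is not None:
        tables["cohort_matrix.csv"] = res.cohort_matrix.reset_index()
    if res.clusters is not None:
        tables["clusters.csv"] = res.clusters
    for name, df in tables.items():
        write_results(df, outdir / name)
    if res.newick is not None:
        (outdir / "dendrogram_samples.nwk").write_text(res.newick + "\n")
    cfg_hash = hashlib.sha256(
        (outdir / "config.yaml").read_bytes()).hexdigest()[:12]
    log = res.log + [f"config sha256: {cfg_hash}"]
    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")


def run_from_files(input_paths: list[str | Path], config: RunConfig,
                   outdir: Optional[str | Path] = None) -> PipelineResult:
    plates = []
    for p in input_paths:
        plates.extend(read_plate_table(p))
    plates.sort(key=lambda pl: pl.plate_id)
    return run_pipeline(plates, config, outdir=outdir)
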