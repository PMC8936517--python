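"""Plate quality control and control-based viability normalization.

Z'-factor gauges separation of the positive (full-kill) and negative
(vehicle) controls:

    Z' = 1 - 3 * (sd_pos + sd_neg) / |mu_pos - mu_neg|

Viability is normalized so that the negative-control mean maps to 100% and
the positive-control mean to 0%; viability is left unclamped for curve
fitting (slight overshoot carries information), while the inhibition
fraction used by synergy scoring is clamped to [0, 1].

The outlier screen is a two-stage automated stand-in for manual curation:
a replicate rule (median/MAD within identical treatments) and a residual
rule against a preliminary curve fit, standardized on the relative scale
because luminescence noise is multiplicative.  Flagged wells are excluded
from fits but never deleted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .plates import Plate
from .fitting import FitError, fit_curve

MAD_SCALE = 1.4826          # MAD -> sigma for a normal distribution
REPLICATE_Z = 3.0           # replicate-rule cutoff in robust SDs
REPLICATE_FLOOR = 15.0      # ... but never flag within 15 viability points
RESIDUAL_Z = 3.0            # residual-rule cutoff in robust SDs
_REL_FLOOR = 0.5            # viability floor (%) for relative residuals
_ABS_FLOOR = 0.5            # minimum residual scale in viability points
PAIR_Z = 6.0                # replicate-pair spread cutoff in pair-noise SDs
_PAIR_FLOOR = 0.2           # viability floor (%) for the pair denominator


class QcError(ValueError):
    pass


@dataclass
class QcReport:
    plate_id: str
    zprime: float
    mu_neg: float
    sd_neg: float
    mu_pos: float
    sd_pos: float
    n_outliers_flagged: int = 0
    usable: bool = True
    note: str = ""


def zprime(plate: Plate, floor: float = 0.4) -> QcReport:
    """Z'-factor QC for one plate; ``usable`` requires Z' >= ``floor`` and
    non-inverted controls (negative mean above positive mean)."""
    neg = [w.raw_signal for w in plate.wells_with_role("negative_control")]
    pos = [w.raw_signal for w in plate.wells_with_role("positive_control")]
    if len(neg) < 2 or len(pos) < 2:
        raise QcError(f"plate {plate.plate_id}: need >= 2 wells of each "
                      f"control role, got {len(neg)} negative / {len(pos)} positive")
    mu_neg, sd_neg = float(np.mean(neg)), float(np.std(neg, ddof=1))
    mu_pos, sd_pos = float(np.mean(pos)), float(np.std(pos, ddof=1))
    if mu_neg == mu_pos:
        return QcReport(plate.plate_id, float("-inf"), mu_neg, sd_neg,
                        mu_pos, sd_pos, usable=False,
                        note="degenerate controls: mu_neg == mu_pos")
    z = 1.0 - 3.0 * (sd_pos + sd_neg) / abs(mu_pos - mu_neg)
    usable = z >= floor and mu_neg > mu_pos
    note = "" if mu_neg > mu_pos else "inverted controls: mu_neg <= mu_pos"
    return QcReport(plate.plate_id, z, mu_neg, sd_neg, mu_pos, sd_pos,
                    usable=usable, note=note)


def normalize(plate: Plate, report: Optional[QcReport] = None,
              override: bool = False, floor: float = 0.4) -> pd.DataFrame:
    """Normalize raw signals to percent viability against the plate's controls.

    Returns one row per well with ``viability_pct`` (unclamped) and
    ``inhibition_frac`` (clamped to [0, 1]).  An unusable plate is rejected
    unless ``override`` is set (the override is recorded in the table).
    """
    if report is None:
        report = zprime(plate, floor=floor)
    if not report.usable and not override:
        raise QcError(f"plate {plate.plate_id} failed QC "
                      f"(Z'={report.zprime:.3f}; {report.note or 'below floor'}); "
                      "pass override to normalize anyway")
    span = report.mu_neg - report.mu_pos
    rows = []
    for w in plate.wells:
        viab = 100.0 * (w.raw_signal - report.mu_pos) / span
        rec = {"plate_id": w.plate_id, "well": w.label,
               "sample_id": w.sample_id, "role": w.treatment.role,
               "treatment_label": w.treatment.label,
               "n_drugs": len(w.treatment.drugs),
               "drug1": "", "conc1_nM": np.nan, "drug2": "",
               "conc2_nM": np.nan, "drug3": "", "conc3_nM": np.nan,
               "raw_signal": w.raw_signal, "viability_pct": viab,
               "inhibition_frac": float(np.clip((100.0 - viab) / 100.0, 0, 1)),
               "outlier": "outlier" in w.qc_flags,
               "excluded": "excluded" in w.qc_flags,
               "qc_override": override and not report.usable}
        for i, (name, conc) in enumerate(w.treatment.drugs, start=1):
            rec[f"drug{i}"] = name
            rec[f"conc{i}_nM"] = conc
        rows.append(rec)
    return pd.DataFrame(rows)


def _varying_axis(group: pd.DataFrame) -> Optional[str]:
    """Column name of the single varying concentration in a titration group."""
    varying = [c for c in ("conc1_nM", "conc2_nM", "conc3_nM")
               if group[c].notna().any() and group[c].nunique() > 1]
    return varying[0] if len(varying) == 1 else None


def _pooled_sigma_rel(treated: pd.DataFrame) -> Optional[float]:
    """Relative noise scale estimated from replicate agreement.

    Pools within-group deviations across all replicated treatments (groups
    with median viability above 5% — below that the relative scale is
    uninformative); the median across groups is robust to the occasional
    outlier-contaminated group.  Returns None when too few replicate groups
    exist.
    """
    pair_draws, mad_draws = [], []
    for _, g in treated.groupby(["plate_id", "sample_id", "treatment_label"]):
        v = g["viability_pct"].to_numpy(float)
        med = np.median(v)
        if len(v) < 2 or abs(med) < 5.0:
            continue
        if len(v) == 2:
            pair_draws.append(abs(v[0] - v[1]) / (math.sqrt(2) * abs(med)))
        else:
            mad_draws.append(MAD_SCALE * np.median(np.abs(v - med)) / abs(med))
    if len(pair_draws) >= 8:
        return float(np.median(pair_draws) / 0.6745)  # half-normal median
    if len(mad_draws) >= 3:
        return float(np.median(mad_draws))
    return None


def flag_outliers(normalized: pd.DataFrame,
                  replicate_rule: bool = True,
                  residual_rule: bool = True) -> pd.DataFrame:
    """Two-stage automated outlier screen on a normalized-well table.

    Stage 1 (replicate rule): within wells sharing an identical treatment,
    flag wells whose viability sits further from the group median than
    ``max(3 * 1.4826 * MAD, 15 points)``; pairs are never adjudicated.

    Stage 2 (residual rule): within each titration (same sample and drug
    set, one concentration varying over >= 4 levels), fit a preliminary
    curve and flag wells with a relative standardized residual above 3.

    Returns a copy with the boolean ``outlier`` column updated; wells are
    flagged, never dropped.
    """
    df = normalized.copy()
    treated = df["role"] == "treated"
    flagged = df["outlier"].copy()

    if replicate_rule:
        for _, grp in df[treated].groupby(["sample_id", "treatment_label"]):
            if len(grp) < 3:
                continue
            v = grp["viability_pct"].to_numpy()
            med = np.median(v)
            mad = np.median(np.abs(v - med))
            cut = max(REPLICATE_Z * MAD_SCALE * mad, REPLICATE_FLOOR)
            bad = np.abs(v - med) > cut
            flagged.loc[grp.index[bad]] = True

    if residual_rule:
        pooled_sigma = _pooled_sigma_rel(df[treated])
        drug_cols = ["drug1", "drug2", "drug3"]
        for _, grp in df[treated].groupby(["sample_id"] + drug_cols):
            axis = _varying_axis(grp)
            if axis is None or grp[axis].nunique() < 4:
                continue
            conc = grp[axis].to_numpy(dtype=float)
            viab = grp["viability_pct"].to_numpy(dtype=float)
            try:
                curve = fit_curve(conc, viab)
            except FitError:
                continue
            pred = curve.viability(conc)
            resid = viab - pred
            # noise is multiplicative, so the per-point scale is sigma_rel *
            # predicted viability; sigma_rel is estimated robustly from points
            # well off the lower asymptote (elsewhere the signal carries no
            # scale information), and an absolute floor keeps asymptote-level
            # fit bias (a few tenths of a point) from registering as outliers
            if pooled_sigma is not None:
                sigma_rel = pooled_sigma
            else:  # no replicates: fall back to fit residuals
                informative = pred >= 5.0
                if informative.sum() >= 4:
                    rel = resid[informative] / pred[informative]
                else:
                    rel = resid / np.maximum(pred, _REL_FLOOR)
                sigma_rel = MAD_SCALE * np.median(np.abs(rel - np.median(rel)))
            if sigma_rel <= 0:
                continue
            bad = np.zeros(len(grp), dtype=bool)
            scale = np.maximum(sigma_rel * np.maximum(pred, 0.0), _ABS_FLOOR)
            # replicate consistency: with 6-point/4-parameter fits the curve
            # residual carries systematic lack-of-fit shared by replicates,
            # so replicated wells are adjudicated within their replicate
            # group on the multiplicative noise scale (which stays
            # informative down to the asymptote); the plain curve-residual
            # test is reserved for singleton wells
            for _, reps in grp.groupby(axis):
                loc = grp.index.get_indexer(reps.index)
                v = viab[loc]
                if len(v) == 1:
                    bad[loc] = np.abs(resid[loc]) > RESIDUAL_Z * scale[loc]
                elif len(v) == 2:
                    spread = abs(v[0] - v[1])
                    denom = math.sqrt(2) * sigma_rel * max(
                        min(abs(v[0]), abs(v[1])), _PAIR_FLOOR)
                    if spread > PAIR_Z * denom:
                        # the member farther from the fit is the culprit
                        bad[loc[np.argmax(np.abs(resid[loc]))]] = True
                else:
                    med = np.median(v)
                    denom = sigma_rel * max(abs(med), _PAIR_FLOOR)
                    bad[loc] |= np.abs(v - med) > 0.5 * PAIR_Z * math.sqrt(2) * denom
            flagged.loc[grp.index[bad]] = True

    df["outlier"] = flagged
    return df


def replicate_correlation(norm_a: pd.DataFrame, norm_b: pd.DataFrame) -> float:
    """Squared Pearson correlation of matched treated-well viabilities
    between two replicate plates (matched on treatment label)."""
    a = (norm_a[norm_a["role"] == "treated"]
         .groupby("treatment_label")["viability_pct"].mean())
    b = (norm_b[norm_b["role"] == "treated"]
         .groupby("treatment_label")["viability_pct"].mean())
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise QcError(f"only {len(common)} matched treatments; need >= 3")
    x, y = a.loc[common].to_numpy(), b.loc[common].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise QcError("constant replicate: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r
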