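"""Bliss-independence synergy scoring for dose matrices and primed doubles.

Bliss independence predicts the combined inhibition of two non-interacting
drugs on the fraction scale as

    E(fA, fB) = fA + fB - fA * fB

The per-cell synergy score is the observed excess over this prediction, in
percentage points: ``100 * (f_obs - E)``.  Positive excess means synergy,
negative antagonism.  A combination is classified synergistic when its mean
score is strictly greater than zero.  For the triple design the fixed
background drug is absorbed into the baseline (conditional two-way Bliss:
monotherapy and combination inhibitions are all measured in its presence);
an exploratory three-way mode treats the background as a third Bliss factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class SynergyError(ValueError):
    pass


def bliss_expected(f_a, f_b):
    """Expected combined inhibition fraction under Bliss independence."""
    f_a = np.asarray(f_a, dtype=float)
    f_b = np.asarray(f_b, dtype=float)
    if np.any((f_a < 0) | (f_a > 1)) or np.any((f_b < 0) | (f_b > 1)):
        raise SynergyError("inhibition fractions must lie in [0, 1]")
    out = f_a + f_b - f_a * f_b
    return float(out) if out.ndim == 0 else out


@dataclass
class DoseMatrix:
    """Observed inhibition fractions on a dose grid with monotherapy anchors.

    ``inhibition[i, j]`` is the (replicate-mean, clamped) inhibition at
    ``concsA[i]`` x ``concsB[j]``; ``mono_a``/``mono_b`` are the single-agent
    inhibitions at those same doses, taken either from zero-dose cells of the
    matrix or from external single-agent curves (``monotherapy_source``).
    When ``background`` names a fixed third drug, every fraction is
    understood to be measured in its presence.
    """

    drug_a: str
    drug_b: str
    concs_a: np.ndarray
    concs_b: np.ndarray
    inhibition: np.ndarray
    mono_a: np.ndarray
    mono_b: np.ndarray
    background: Optional[tuple[str, float]] = None
    mono_background: Optional[float] = None
    monotherapy_source: str = "zero_dose_cells"

    def __post_init__(self) -> None:
        self.concs_a = np.asarray(self.concs_a, dtype=float)
        self.concs_b = np.asarray(self.concs_b, dtype=float)
        self.inhibition = np.asarray(self.inhibition, dtype=float)
        self.mono_a = np.asarray(self.mono_a, dtype=float)
        self.mono_b = np.asarray(self.mono_b, dtype=float)
        if self.inhibition.shape != (len(self.concs_a), len(self.concs_b)):
            raise SynergyError(
                f"inhibition shape {self.inhibition.shape} does not match "
                f"grid {len(self.concs_a)}x{len(self.concs_b)}")
        if np.any(~np.isfinite(self.inhibition)):
            raise SynergyError("missing cells in the dose matrix")
        for name, arr, n in (("mono_a", self.mono_a, len(self.concs_a)),
                             ("mono_b", self.mono_b, len(self.concs_b))):
            if len(arr) != n or np.any(~np.isfinite(arr)):
                raise SynergyError(f"{name}: need finite monotherapy "
                                   f"inhibition for every grid dose")
        for arr in (self.inhibition, self.mono_a, self.mono_b):
            if np.any((arr < 0) | (arr > 1)):
                raise SynergyError("inhibition fractions must lie in [0, 1]")


@dataclass
class SynergyResult:
    excess: np.ndarray          # percentage points per cell
    mean_synergy: float
    synergy_sum: float
    synergistic: bool           # strictly > 0
    design: str = "matrix"
    concs_a: Optional[np.ndarray] = None
    concs_b: Optional[np.ndarray] = None


def excess_matrix(matrix: DoseMatrix, three_way: bool = False) -> SynergyResult:
    """Per-cell Bliss excess over a dose matrix, with mean and synergy sum.

    With a fixed background drug the default is conditional two-way Bliss
    (background absorbed into the baseline).  ``three_way=True`` instead
    scores the observed inhibition against ``1 - (1-fA)(1-fB)(1-fC)`` using
    the background monotherapy inhibition fC (requires ``mono_background``
    measured without the background in the other fractions).
    """
    fa = matrix.mono_a[:, None]
    fb = matrix.mono_b[None, :]
    expected = fa + fb - fa * fb
    if three_way:
        if matrix.mono_background is None:
            raise SynergyError("three-way scoring needs mono_background")
        fc = float(matrix.mono_background)
        expected = 1.0 - (1.0 - expected) * (1.0 - fc)
    excess = 100.0 * (matrix.inhibition - expected)
    mean = float(np.mean(excess))
    total = float(np.sum(excess))
    return SynergyResult(excess=excess, mean_synergy=mean, synergy_sum=total,
                         synergistic=mean > 0,
                         design="triple_matrix" if matrix.background else "matrix",
                         concs_a=matrix.concs_a, concs_b=matrix.concs_b)


def primed_double_synergy(partner_concs: Sequence[float],
                          combo_inhibition: Sequence[float],
                          primer_inhibition: float,
                          partner_inhibition: Sequence[float],
                          primer_name: str = "primer",
                          partner_name: str = "partner") -> SynergyResult:
    """Bliss excess along a partner titration at a fixed priming dose.

    ``primer_inhibition`` is the priming drug's single-agent inhibition at
    its fixed concentration (typically evaluated from its fitted curve);
    ``partner_inhibition`` gives the partner's single-agent inhibition at
    each titrated dose.  Scores are reported per concentration (a 1 x n
    grid) plus the mean and classification.
    """
    concs = np.asarray(partner_concs, dtype=float)
    m = DoseMatrix(drug_a=primer_name, drug_b=partner_name,
                   concs_a=np.array([1.0]), concs_b=concs,
                   inhibition=np.asarray(combo_inhibition, float)[None, :],
                   mono_a=np.array([primer_inhibition], float),
                   mono_b=np.asarray(partner_inhibition, float),
                   monotherapy_source="external_curves")
    res = excess_matrix(m)
    res.design = "double_primed"
    res.concs_a = np.array([1.0])
    res.concs_b = concs
    return res


def landscape_export(result: SynergyResult) -> pd.DataFrame:
    """Long-format (concA, concB, excess) table for contour plotting."""
    if result.concs_a is None or result.concs_b is None:
        raise SynergyError("result carries no dose grid")
    rows = [{"concA_nM": float(a), "concB_nM": float(b),
             "excess": float(result.excess[i, j])}
            for i, a in enumerate(result.concs_a)
            for j, b in enumerate(result.concs_b)]
    return pd.DataFrame(rows, columns=["concA_nM", "concB_nM", "excess"])
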