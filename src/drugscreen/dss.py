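"""Modified drug sensitivity score (DSS) and combination DSS.

The DSS summarizes a whole inhibition–concentration curve as a single
normalized area.  With x = log10(concentration), clamped inhibition
Î(x) = clamp(I(x), 0, 100) and activity threshold t (percent inhibition):

    x_t  = smallest x in [x_min, x_max] with Î(x) >= t   (x_max if never)
    A    = ∫_{x_t}^{x_max} (Î(x) - t) dx
    DSS  = 100 * A / ((100 - t) * (x_max - x_min))

This is the type-1 score with no division by the logarithm of the upper
limit: 0 means inactive over the tested range, 100 means complete kill
across the whole range.  Integration uses a fixed trapezoid grid on the
log10 axis (default 1024 points), which is agnostic to the fitted model
branch; the threshold crossing x_t is refined by bisection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fitting import DoseResponseCurve, fit_curve, RELAXED_BOUNDS

#: efficacy bands from mean DSS: low [0,10], intermediate (10,40], high (40,100]
BAND_EDGES = {"low": (0.0, 10.0), "intermediate": (10.0, 40.0),
              "high": (40.0, 100.0)}


@dataclass
class DssConfig:
    """Scoring configuration: activity threshold t (% inhibition) and grid size."""

    activity_threshold: float = 10.0
    grid_n: int = 1024

    def __post_init__(self) -> None:
        if not 0 <= self.activity_threshold < 100:
            raise ValueError("activity threshold must be in [0, 100)")
        if self.grid_n < 256:
            raise ValueError("grid_n must be >= 256")


@dataclass
class DssRecord:
    sample_id: str
    treatment_label: str
    dss: float
    conc_range: tuple[float, float]
    t: float
    source: str = "single"  # single | combo_double | combo_triple
    band: str = field(init=False)

    def __post_init__(self) -> None:
        self.band = classify(self.dss)


def _clamped_inhibition(curve: DoseResponseCurve, x: np.ndarray) -> np.ndarray:
    return np.clip(curve.inhibition(10.0 ** x), 0.0, 100.0)


def dss(curve: DoseResponseCurve,
        conc_range: Optional[tuple[float, float]] = None,
        config: Optional[DssConfig] = None) -> float:
    """Drug sensitivity score of a fitted curve over a concentration range (nM)."""
    config = config or DssConfig()
    c_min, c_max = conc_range if conc_range is not None else curve.conc_range
    if not (c_min > 0 and c_max > c_min):
        raise ValueError(f"degenerate concentration range ({c_min}, {c_max})")
    t = config.activity_threshold
    x_min, x_max = math.log10(c_min), math.log10(c_max)

    x = np.linspace(x_min, x_max, config.grid_n)
    ih = _clamped_inhibition(curve, x)
    above = ih >= t
    if not above.any():
        return 0.0
    i0 = int(np.argmax(above))
    if i0 == 0:
        x_t = x_min
    else:
        # refine the first crossing by bisection (inhibition is monotone for
        # the fitted families; on the grid cell it is effectively so)
        lo, hi = x[i0 - 1], x[i0]
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if float(_clamped_inhibition(curve, np.array([mid]))[0]) >= t:
                hi = mid
            else:
                lo = mid
        x_t = hi
    xs = np.linspace(x_t, x_max, config.grid_n)
    area = float(np.trapezoid(_clamped_inhibition(curve, xs) - t, xs))
    area = max(area, 0.0)
    value = 100.0 * area / ((100.0 - t) * (x_max - x_min))
    return float(min(max(value, 0.0), 100.0))


def classify(value: float) -> str:
    """Efficacy band of a DSS value: low [0,10], intermediate (10,40], high (40,100]."""
    if not 0 <= value <= 100:
        raise ValueError(f"DSS out of [0, 100]: {value}")
    if value <= 10.0:
        return "low"
    if value <= 40.0:
        return "intermediate"
    return "high"


def combo_dss_double(combo_curve: DoseResponseCurve,
                     single_curve: DoseResponseCurve,
                     conc_range: Optional[tuple[float, float]] = None,
                     config: Optional[DssConfig] = None,
                     allow_range_mismatch: bool = False
                     ) -> tuple[float, float, float]:
    """DSS of a primed double combination versus the partner drug alone.

    Both scores are computed over the identical partner concentration range
    (defaulting to the combination curve's tested range); the return value is
    ``(dss_combo, dss_single, delta)`` with ``delta = dss_combo - dss_single``.
    """
    if conc_range is None:
        if (not allow_range_mismatch
                and combo_curve.conc_range != single_curve.conc_range):
            raise ValueError(
                f"combination range {combo_curve.conc_range} != single-agent "
                f"range {single_curve.conc_range}; pass conc_range or set "
                "allow_range_mismatch")
        conc_range = combo_curve.conc_range
    d_combo = dss(combo_curve, conc_range, config)
    d_single = dss(single_curve, conc_range, config)
    return d_combo, d_single, d_combo - d_single


def combo_dss_triple(viability_matrix, concs_titrated: Sequence[float],
                     config: Optional[DssConfig] = None,
                     orientation: str = "rows"
                     ) -> tuple[float, list[float], list[DoseResponseCurve]]:
    """Averaged DSS over a 4x4 (+ fixed background) combination matrix.

    Each row of ``viability_matrix`` holds normalized viabilities (%) for one
    fixed level of the first drug while the second drug varies over
    ``concs_titrated``; a curve is fitted per row (relaxed asymptote bounds,
    since the fixed drugs depress the zero-dose viability) and its DSS
    computed over the titrated range.  The returned score is the arithmetic
    mean of the per-row scores.  ``orientation="columns"`` transposes first.
    """
    m = np.asarray(viability_matrix, dtype=float)
    if orientation == "columns":
        m = m.T
    elif orientation != "rows":
        raise ValueError("orientation must be 'rows' or 'columns'")
    concs = np.asarray(concs_titrated, dtype=float)
    if m.ndim != 2 or m.shape[1] != len(concs):
        raise ValueError(f"matrix shape {m.shape} does not match "
                         f"{len(concs)} titrated concentrations")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix has missing cells")
    rng = (float(concs.min()), float(concs.max()))
    per_row, curves = [], []
    for row in m:
        curve = fit_curve(concs, row, bounds=RELAXED_BOUNDS)
        curves.append(curve)
        per_row.append(dss(curve, rng, config))
    return float(np.mean(per_row)), per_row, curves


def records_to_wide(records: Sequence[DssRecord]):
    """Heatmap-ready samples x treatments DSS matrix."""
    import pandas as pd
    df = pd.DataFrame([{"sample_id": r.sample_id,
                        "treatment_label": r.treatment_label,
                        "dss": r.dss} for r in records])
    return df.pivot(index="sample_id", columns="treatment_label", values="dss")
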