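"""Synthetic 384-well screening plates with known ground truth.

The generator emulates the three screening designs — single-agent 6-point
titrations, IC20-primed double combinations, and 4x4 dose matrices with a
fixed third drug — so every downstream stage (normalization, fitting, DSS,
synergy, clustering) has a parameter-recovery test surface.

Each drug's true response follows the same four-parameter log-logistic
family the analysis fits; combinations are composed under Bliss
independence with an optional injected synergy excess ``delta``
(survival S_AB = clamp(S_A * S_B - delta, 0, 1) when both doses are
non-zero).  Measurement noise is multiplicative lognormal on the raw
luminescence signal — assays scale with cell number, and this keeps
signals non-negative — with an optional rate of gross outlier wells whose
signal is multiplied by a fixed factor.  Ground-truth labels (curve
parameters, analytic DSS, outlier wells, group membership) travel with the
plates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .plates import Plate, Treatment, Well, ROWS, N_COLS
from .fitting import DoseResponseCurve
from .dss import DssConfig, dss

SINGLE_AGENT_CONCS = (0.1, 1.0, 10.0, 100.0, 1000.0, 10000.0)  # nM
DOUBLE_PARTNER_CONCS = (0.1, 1.0, 10.0, 100.0, 1000.0)         # nM
TRIPLE_GRID_CONCS = (0.1, 1.0, 10.0, 100.0)                    # nM


@dataclass(frozen=True)
class GroundTruthProfile:
    """True log-logistic response of one drug in one sample.

    viability(conc) = bottom + (top - bottom) / (1 + (conc / ic50)^hill_slope)
    """

    drug_name: str
    ic50: float                  # nM
    hill_slope: float = 1.0
    top_viability: float = 100.0
    bottom_viability: float = 0.0

    def __post_init__(self) -> None:
        if self.ic50 <= 0 or self.hill_slope <= 0:
            raise ValueError("ic50 and hill_slope must be positive")
        if not 0 <= self.bottom_viability < self.top_viability:
            raise ValueError("need 0 <= bottom < top")

    def viability(self, conc) -> np.ndarray:
        x = np.asarray(conc, dtype=float)
        c, d = self.bottom_viability, self.top_viability
        return c + (d - c) / (1.0 + (x / self.ic50) ** self.hill_slope)

    def survival(self, conc) -> np.ndarray:
        """Surviving fraction in [0, 1] (viability relative to untreated)."""
        return self.viability(conc) / 100.0

    def as_curve(self, conc_range: tuple[float, float]) -> DoseResponseCurve:
        """The exact LL4 curve object for analytic DSS/IC computations."""
        return DoseResponseCurve(
            model="LL4", top=self.top_viability, bottom=self.bottom_viability,
            slope=self.hill_slope, midpoint=self.ic50, conc_range=conc_range,
            converged=True, rss=0.0, n_points=0)

    def true_dss(self, conc_range: tuple[float, float],
                 config: Optional[DssConfig] = None) -> float:
        return dss(self.as_curve(conc_range), conc_range, config)


@dataclass(frozen=True)
class InteractionModel:
    """Bliss-independent (delta=0) or uniformly shifted pairwise interaction.

    Combined survival for the interacting pair:
        S_AB(a, b) = clamp(S_A(a) * S_B(b) - delta, 0, 1)  when a > 0 and b > 0
    so a positive delta adds exactly ``100*delta`` percentage points of
    inhibition beyond the Bliss expectation in every combination cell.
    """

    kind: str = "bliss_independent"
    delta: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("bliss_independent", "bliss_shifted"):
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        if not -1.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [-1, 1]")
        if self.kind == "bliss_independent" and self.delta != 0.0:
            raise ValueError("bliss_independent requires delta = 0")

    def combined_survival(self, s_a: float, s_b: float,
                          both_dosed: bool = True) -> float:
        s = s_a * s_b
        if both_dosed:
            s -= self.delta
        return float(np.clip(s, 0.0, 1.0))


@dataclass(frozen=True)
class NoiseModel:
    """Measurement model for raw luminescence signals.

    ``cv`` is the coefficient of variation of the multiplicative lognormal
    noise; ``outlier_rate`` wells (treated wells only) have their signal
    multiplied by ``outlier_scale`` and are recorded as ground-truth
    outliers.  Identical seed and parameters give bit-identical plates.
    """

    cv: float = 0.05
    outlier_rate: float = 0.0
    outlier_scale: float = 3.0
    neg_ctrl_signal: float = 10000.0
    # a non-zero positive-control background shifts the normalized viability
    # scale away from the ground-truth scale; keep 0 unless studying that bias
    pos_ctrl_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if not 0 <= self.outlier_rate <= 0.1:
            raise ValueError("outlier_rate must lie in [0, 0.1]")
        if not 0 <= self.pos_ctrl_fraction <= 0.2:
            raise ValueError("pos_ctrl_fraction must lie in [0, 0.2]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def measure(self, expected_signal: float, rng: np.random.Generator,
                can_outlie: bool = False) -> tuple[float, bool]:
        """One noisy signal; returns (signal, is_outlier).

        The lognormal factor has mean 1 and the requested CV; drawing the
        noise and the outlier coin unconditionally keeps the random stream
        aligned across parameter settings.
        """
        if self.cv > 0:
            sigma = math.sqrt(math.log1p(self.cv ** 2))
            factor = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma)
        else:
            factor = 1.0
            rng.lognormal()  # keep stream position fixed
        u = rng.random()
        is_outlier = can_outlie and u < self.outlier_rate
        signal = expected_signal * factor
        if is_outlier:
            signal *= self.outlier_scale
        return max(signal, 0.0), is_outlier


@dataclass
class GroundTruth:
    """Sidecar truth for a simulated plate (or cohort)."""

    profiles: dict[str, GroundTruthProfile] = field(default_factory=dict)
    outlier_wells: set[tuple[str, str]] = field(default_factory=set)  # (plate, well)
    table: Optional[pd.DataFrame] = None


class _PlateBuilder:
    """Fills a 384-well plate row-major and measures wells through the noise model."""

    def __init__(self, plate_id: str, sample_id: str, noise: NoiseModel,
                 rng: np.random.Generator):
        self.plate = Plate(plate_id=plate_id, sample_id=sample_id)
        self.noise = noise
        self.rng = rng
        self._next = 0
        self.truth = GroundTruth()

    def _position(self) -> tuple[str, int]:
        if self._next >= len(ROWS) * N_COLS:
            raise ValueError(f"plate {self.plate.plate_id}: more than 384 wells")
        r, c = divmod(self._next, N_COLS)
        self._next += 1
        return ROWS[r], c + 1

    def add(self, treatment: Treatment, survival: float,
            can_outlie: bool = False) -> Well:
        expected = self.noise.neg_ctrl_signal * survival
        signal, is_out = self.noise.measure(expected, self.rng, can_outlie)
        well = Well(plate_id=self.plate.plate_id, position=self._position(),
                    sample_id=self.plate.sample_id, treatment=treatment,
                    raw_signal=signal)
        self.plate.wells.append(well)
        if is_out:
            self.truth.outlier_wells.add((self.plate.plate_id, well.label))
        return well

    def add_controls(self, n_neg: int, n_pos: int) -> None:
        for _ in range(n_neg):
            self.add(Treatment(role="negative_control"), 1.0)
        for _ in range(n_pos):
            self.add(Treatment(role="positive_control"),
                     self.noise.pos_ctrl_fraction)


def _check_grid(concs: Sequence[float], name: str = "concentrations") -> np.ndarray:
    arr = np.asarray(concs, dtype=float)
    if np.any(arr <= 0) or np.any(np.diff(arr) <= 0):
        raise ValueError(f"{name} must be strictly increasing and positive")
    return arr


def simulate_single_agent(profiles: Sequence[GroundTruthProfile],
                          concentrations: Sequence[float] = SINGLE_AGENT_CONCS,
                          n_ctrl_wells: int = 16,
                          noise: NoiseModel = NoiseModel(),
                          n_replicates: int = 2,
                          plate_id: str = "P1",
                          sample_id: str = "S1",
                          dss_config: Optional[DssConfig] = None
                          ) -> tuple[Plate, GroundTruth]:
    """One single-agent plate: each drug titrated over ``concentrations``.

    Treated signal = neg_ctrl_signal * viability/100 * lognormal noise;
    the ground truth carries each profile and its analytic DSS over the
    tested range.
    """
    concs = _check_grid(concentrations)
    rng = noise.rng()
    b = _PlateBuilder(plate_id, sample_id, noise, rng)
    b.add_controls(n_ctrl_wells, n_ctrl_wells)
    rng_range = (float(concs.min()), float(concs.max()))
    rows = []
    for prof in profiles:
        b.truth.profiles[prof.drug_name] = prof
        for conc in concs:
            s = float(prof.survival(conc))
            for _ in range(n_replicates):
                b.add(Treatment(drugs=((prof.drug_name, float(conc)),)), s,
                      can_outlie=True)
        rows.append({"sample_id": sample_id, "drug": prof.drug_name,
                     "ic50": prof.ic50, "slope": prof.hill_slope,
                     "top": prof.top_viability, "bottom": prof.bottom_viability,
                     "true_dss": prof.true_dss(rng_range, dss_config),
                     "group_label": ""})
    b.truth.table = pd.DataFrame(rows)
    return b.plate, b.truth


def simulate_double_primed(primer: GroundTruthProfile, primer_conc: float,
                           partner: GroundTruthProfile,
                           partner_concs: Sequence[float] = DOUBLE_PARTNER_CONCS,
                           interaction: InteractionModel = InteractionModel(),
                           noise: NoiseModel = NoiseModel(),
                           n_ctrl_wells: int = 16,
                           n_replicates: int = 2,
                           plate_id: str = "P1",
                           sample_id: str = "S1") -> tuple[Plate, GroundTruth]:
    """Primed-double plate: primer fixed (its IC20 in the screening design)
    plus a 5-point partner titration, with partner-alone and primer-alone
    monotherapy wells on the same plate."""
    concs = _check_grid(partner_concs, "partner_concs")
    if len(concs) != 5:
        raise ValueError(f"double design uses 5 partner concentrations, "
                         f"got {len(concs)}")
    if primer_conc <= 0:
        raise ValueError("primer concentration must be > 0")
    rng = noise.rng()
    b = _PlateBuilder(plate_id, sample_id, noise, rng)
    b.add_controls(n_ctrl_wells, n_ctrl_wells)
    b.truth.profiles = {primer.drug_name: primer, partner.drug_name: partner}
    s_primer = float(primer.survival(primer_conc))
    # combination wells
    for conc in concs:
        s = interaction.combined_survival(s_primer, float(partner.survival(conc)))
        for _ in range(n_replicates):
            b.add(Treatment(drugs=((primer.drug_name, float(primer_conc)),
                                   (partner.drug_name, float(conc)))),
                  s, can_outlie=True)
    # monotherapy wells at matching doses
    for conc in concs:
        for _ in range(n_replicates):
            b.add(Treatment(drugs=((partner.drug_name, float(conc)),)),
                  float(partner.survival(conc)), can_outlie=True)
    for _ in range(n_replicates):
        b.add(Treatment(drugs=((primer.drug_name, float(primer_conc)),)),
              s_primer, can_outlie=True)
    return b.plate, b.truth


def simulate_triple_matrix(drug_a: GroundTruthProfile,
                           drug_b: GroundTruthProfile,
                           grid_a: Sequence[float] = TRIPLE_GRID_CONCS,
                           grid_b: Sequence[float] = TRIPLE_GRID_CONCS,
                           background: Optional[GroundTruthProfile] = None,
                           background_conc: float = 0.0,
                           interaction: InteractionModel = InteractionModel(),
                           noise: NoiseModel = NoiseModel(),
                           n_ctrl_wells: int = 16,
                           n_replicates: int = 2,
                           plate_id: str = "P1",
                           sample_id: str = "S1") -> tuple[Plate, GroundTruth]:
    """Triple-design plate: 4x4 matrix of drugs A x B, each cell also dosed
    with the fixed background drug; monotherapy arms (A + background,
    B + background, background alone) provide the zero-dose row/column.

    Synergy ``delta`` applies to the (A, B) pair only; the background always
    composes multiplicatively.
    """
    ga = _check_grid(grid_a, "grid_a")
    gb = _check_grid(grid_b, "grid_b")
    if len(ga) != 4 or len(gb) != 4:
        raise ValueError(f"triple design uses a 4x4 grid, got "
                         f"{len(ga)}x{len(gb)}")
    if background is not None and background_conc <= 0:
        raise ValueError("background concentration must be > 0")
    rng = noise.rng()
    b = _PlateBuilder(plate_id, sample_id, noise, rng)
    b.add_controls(n_ctrl_wells, n_ctrl_wells)
    b.truth.profiles = {drug_a.drug_name: drug_a, drug_b.drug_name: drug_b}
    s_bg = 1.0
    bg_pair: tuple[tuple[str, float], ...] = ()
    if background is not None:
        b.truth.profiles[background.drug_name] = background
        s_bg = float(background.survival(background_conc))
        bg_pair = ((background.drug_name, float(background_conc)),)
    # 16 matrix cells
    for ca in ga:
        for cb in gb:
            s_ab = interaction.combined_survival(float(drug_a.survival(ca)),
                                                 float(drug_b.survival(cb)))
            for _ in range(n_replicates):
                b.add(Treatment(drugs=((drug_a.drug_name, float(ca)),
                                       (drug_b.drug_name, float(cb))) + bg_pair),
                      s_ab * s_bg, can_outlie=True)
    # zero-dose arms: A + background, B + background
    for ca in ga:
        for _ in range(n_replicates):
            b.add(Treatment(drugs=((drug_a.drug_name, float(ca)),) + bg_pair),
                  float(drug_a.survival(ca)) * s_bg, can_outlie=True)
    for cb in gb:
        for _ in range(n_replicates):
            b.add(Treatment(drugs=((drug_b.drug_name, float(cb)),) + bg_pair),
                  float(drug_b.survival(cb)) * s_bg, can_outlie=True)
    if background is not None:
        for _ in range(n_replicates):
            b.add(Treatment(drugs=bg_pair), s_bg, can_outlie=True)
    return b.plate, b.truth


def simulate_cohort(n_samples: int,
                    drugs: Sequence[GroundTruthProfile],
                    heterogeneity: float = 0.5,
                    noise: NoiseModel = NoiseModel(),
                    concentrations: Sequence[float] = SINGLE_AGENT_CONCS,
                    n_replicates: int = 1,
                    two_group: bool = False,
                    fold_shift: float = 100.0,
                    shifted_drug_fraction: float = 0.5,
                    n_ctrl_wells: int = 16,
                    dss_config: Optional[DssConfig] = None
                    ) -> tuple[list[Plate], GroundTruth]:
    """A cohort of single-agent plates with per-sample response heterogeneity.

    Per-sample IC50s are drawn lognormally around each drug's cohort-level
    value with log-SD ``heterogeneity`` (natural-log units; 0 makes every
    sample identical).  In ``two_group`` mode the second half of the cohort
    is made resistant: its IC50s are multiplied by ``fold_shift`` on the
    first ``shifted_drug_fraction`` of the drug panel, and group labels are
    recorded in the truth table for clustering recovery tests.
    """
    if n_samples < 2:
        raise ValueError("need n_samples >= 2")
    if heterogeneity < 0:
        raise ValueError("heterogeneity must be >= 0")
    concs = _check_grid(concentrations)
    master = np.random.default_rng(noise.seed)
    n_shift = int(round(shifted_drug_fraction * len(drugs)))
    plates: list[Plate] = []
    truth = GroundTruth()
    rows = []
    for i in range(n_samples):
        sample_id = f"S{i + 1:02d}"
        group = ""
        if two_group:
            group = "sensitive" if i < n_samples // 2 else "resistant"
        sample_profiles = []
        for j, prof in enumerate(drugs):
            ic50 = prof.ic50
            if heterogeneity > 0:
                ic50 *= float(np.exp(master.normal(0.0, heterogeneity)))
            if group == "resistant" and j < n_shift:
                ic50 *= fold_shift
            sample_profiles.append(replace(prof, ic50=ic50))
        plate_noise = replace(noise, seed=int(master.integers(2 ** 31)))
        plate, pt = simulate_single_agent(
            sample_profiles, concentrations=concs, n_ctrl_wells=n_ctrl_wells,
            noise=plate_noise, n_replicates=n_replicates,
            plate_id=f"P{i + 1:02d}", sample_id=sample_id,
            dss_config=dss_config)
        plates.append(plate)
        truth.outlier_wells |= pt.outlier_wells
        t = pt.table.copy()
        t["group_label"] = group
        rows.append(t)
    truth.table = pd.concat(rows, ignore_index=True)
    return plates, truth
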