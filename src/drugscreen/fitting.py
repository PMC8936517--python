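"""Concentration–response curve fitting.

Each treated titration is fitted with the four-parameter log-logistic model

    V(x) = c + (d - c) / (1 + exp(b * (ln x - ln e)))

with viability V in percent, concentration x in nM, slope b > 0, lower
asymptote c (bottom), upper asymptote d (top) and midpoint e (the IC50 when
c = 0, d = 100).  When the log-logistic fit fails to converge the ordinary
logistic model on the log10-concentration axis is used as a fallback:

    V(t) = c + (d - c) / (1 + exp(b * (t - e'))),   t = log10 x

with e' in log10 nM.  Inhibition is I(x) = 100 - V(x).

Fits use bounded nonlinear least squares with a small multi-start over the
midpoint (min, geometric mid, max of the tested range).  Convergence failure
is defined operationally: solver failure, non-finite parameters, or a
midpoint pinned at its bound while fitting worse than the constant model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

#: asymptote bounds keeping top/bottom identifiable on 6-point data
DEFAULT_BOUNDS = {"bottom": (-20.0, 50.0), "top": (50.0, 150.0),
                  "slope": (0.1, 10.0)}
#: relaxed bounds for short rows measured on top of a background drug,
#: where the zero-dose viability can start well below 50%
RELAXED_BOUNDS = {"bottom": (-20.0, 30.0), "top": (30.0, 150.0),
                  "slope": (0.1, 10.0)}

NOT_REACHED = None  # sentinel for ic_value


class FitError(ValueError):
    pass


@dataclass
class DoseResponseCurve:
    """A fitted concentration–response model.

    ``midpoint`` is in nM for the LL4 model and in log10 nM for L4.
    """

    model: str                      # "LL4" or "L4"
    top: float                      # upper viability asymptote d, %
    bottom: float                   # lower viability asymptote c, %
    slope: float                    # b, unitless
    midpoint: float                 # e
    conc_range: tuple[float, float]  # (c_min, c_max) tested, nM
    converged: bool = True
    rss: float = 0.0
    n_points: int = 0

    def viability(self, conc) -> np.ndarray:
        """Predicted viability (%) at concentration(s) in nM."""
        x = np.asarray(conc, dtype=float)
        c, d, b = self.bottom, self.top, self.slope
        if d == c:
            return np.full_like(x, d, dtype=float)
        if self.model == "LL4":
            with np.errstate(divide="ignore"):
                z = b * (np.log(x) - math.log(self.midpoint))
        else:  # L4 on log10 axis
            z = b * (np.log10(x) - self.midpoint)
        return c + (d - c) / (1.0 + np.exp(np.clip(z, -700, 700)))

    def inhibition(self, conc) -> np.ndarray:
        return 100.0 - self.viability(conc)

    @property
    def midpoint_nM(self) -> float:
        """Midpoint expressed in nM regardless of model branch."""
        return self.midpoint if self.model == "LL4" else 10.0 ** self.midpoint


def _constant_curve(conc: np.ndarray, viab: np.ndarray) -> DoseResponseCurve:
    mean = float(np.mean(viab))
    rss = float(np.sum((viab - mean) ** 2))
    return DoseResponseCurve(
        model="LL4", top=mean, bottom=mean, slope=0.0,
        midpoint=float(np.sqrt(conc.min() * conc.max())),
        conc_range=(float(conc.min()), float(conc.max())),
        converged=True, rss=rss, n_points=len(conc))


def _solve(xdata: np.ndarray, ydata: np.ndarray, log_axis: bool,
           bounds: dict, e_lo: float, e_hi: float,
           e_starts: Sequence[float]):
    """Bounded least squares with multi-start over the midpoint."""
    c_lo, c_hi = bounds["bottom"]
    d_lo, d_hi = bounds["top"]
    b_lo, b_hi = bounds["slope"]
    lo = np.array([b_lo, c_lo, d_lo, e_lo])
    hi = np.array([b_hi, c_hi, d_hi, e_hi])
    c0 = float(np.clip(ydata.min(), c_lo, c_hi))
    d0 = float(np.clip(ydata.max(), d_lo, d_hi))

    def resid(p):
        b, c, d, e = p
        z = np.clip(b * (xdata - e), -700, 700)
        return c + (d - c) / (1.0 + np.exp(z)) - ydata

    best = None
    for e0 in e_starts:
        p0 = np.clip(np.array([1.0, c0, d0, e0]), lo, hi)
        try:
            res = least_squares(resid, p0, bounds=(lo, hi), method="trf",
                                xtol=1e-10, ftol=1e-10, gtol=1e-10,
                                max_nfev=600)
        except Exception:
            continue
        # a max_nfev stop (status 0) still carries a usable solution; only
        # discard hard failures and non-finite parameters
        if res.status < 0 or not np.all(np.isfinite(res.x)):
            continue
        rss = float(np.sum(res.fun ** 2))
        if best is None or rss < best[1] - 1e-12:
            best = (res.x, rss)
        if rss < 1e-10:  # essentially interpolating: no better start exists
            break
    return best, (lo, hi)


def fit_curve(conc, viability, flags: Optional[Sequence[bool]] = None,
              bounds: Optional[dict] = None) -> DoseResponseCurve:
    """Fit an LL4 curve (L4 fallback) to (concentration nM, viability %) points.

    Parameters
    ----------
    conc, viability
        Concentrations in nM (> 0) and normalized viabilities in percent.
    flags
        Optional boolean mask; ``True`` marks a well excluded from the fit
        (flagged outlier).
    bounds
        Parameter-bound dict with keys ``bottom``, ``top``, ``slope``
        (default :data:`DEFAULT_BOUNDS`).  The midpoint is always bounded to
        the tested range extended by two decades.
    """
    conc = np.asarray(conc, dtype=float)
    viab = np.asarray(viability, dtype=float)
    if flags is not None:
        keep = ~np.asarray(flags, dtype=bool)
        conc, viab = conc[keep], viab[keep]
    if len(conc) != len(viab) or len(conc) == 0:
        raise FitError("need matching, non-empty concentration/viability arrays")
    if np.any(conc <= 0) or not np.all(np.isfinite(conc)):
        raise FitError("concentrations must be finite and positive")
    order = np.argsort(conc)
    conc, viab = conc[order], viab[order]
    n_distinct = len(np.unique(conc))
    if n_distinct < 3:
        raise FitError(f"need >= 3 distinct concentrations, got {n_distinct}")
    if np.ptp(viab) == 0:
        return _constant_curve(conc, viab)
    bounds = dict(bounds or DEFAULT_BOUNDS)

    c_min, c_max = float(conc.min()), float(conc.max())
    mean = float(np.mean(viab))
    rss_const = float(np.sum((viab - mean) ** 2))
    geo_mid = math.sqrt(c_min * c_max)

    # --- LL4 on the natural-log axis ---
    ln_x = np.log(conc)
    e_lo, e_hi = math.log(c_min / 100.0), math.log(c_max * 100.0)
    e_starts = [math.log(c_min), math.log(geo_mid), math.log(c_max)]
    best, (lo, hi) = _solve(ln_x, viab, True, bounds, e_lo, e_hi, e_starts)

    def pinned(e_val, elo, ehi):
        span = ehi - elo
        return e_val - elo < 1e-6 * span or ehi - e_val < 1e-6 * span

    ll4_ok = best is not None
    if ll4_ok:
        p, rss = best
        # a midpoint pinned at a bound that fits worse than a flat line is a
        # non-convergent fit, not a curve
        if pinned(p[3], e_lo, e_hi) and rss > rss_const:
            ll4_ok = False
    if ll4_ok and n_distinct >= 4:
        b, c, d, e = best[0]
        return DoseResponseCurve(model="LL4", top=float(d), bottom=float(c),
                                 slope=float(b), midpoint=float(math.exp(e)),
                                 conc_range=(c_min, c_max), converged=True,
                                 rss=best[1], n_points=len(conc))

    # --- L4 fallback on log10 concentration ---
    t = np.log10(conc)
    e_lo10, e_hi10 = math.log10(c_min) - 2.0, math.log10(c_max) + 2.0
    e_starts10 = [math.log10(c_min), math.log10(geo_mid), math.log10(c_max)]
    best4, _ = _solve(t, viab, False, bounds, e_lo10, e_hi10, e_starts10)
    if best4 is not None:
        p, rss = best4
        if not (pinned(p[3], e_lo10, e_hi10) and rss > rss_const):
            b, c, d, e = p
            return DoseResponseCurve(model="L4", top=float(d), bottom=float(c),
                                     slope=float(b), midpoint=float(e),
                                     conc_range=(c_min, c_max), converged=True,
                                     rss=rss, n_points=len(conc))
    if ll4_ok:  # 3 distinct concs: accept LL4 rather than nothing
        b, c, d, e = best[0]
        return DoseResponseCurve(model="LL4", top=float(d), bottom=float(c),
                                 slope=float(b), midpoint=float(math.exp(e)),
                                 conc_range=(c_min, c_max), converged=True,
                                 rss=best[1], n_points=len(conc))
    # last resort: the constant model, flagged as non-converged
    out = _constant_curve(conc, viab)
    out.converged = False
    return out


def ic_value(curve: DoseResponseCurve, level: float) -> Optional[float]:
    """Concentration (nM) at which the fitted curve reaches ``level`` % inhibition.

    The search spans the tested range extended one decade each side; if the
    curve never reaches the level over that span, ``None`` (not reached) is
    returned.  Extrapolations beyond the span are deliberately not reported.
    """
    if not 0 < level < 100:
        raise FitError(f"inhibition level must be in (0, 100), got {level}")
    lo = curve.conc_range[0] / 10.0
    hi = curve.conc_range[1] * 10.0
    i_lo = float(curve.inhibition(lo))
    i_hi = float(curve.inhibition(hi))
    i_max = max(i_lo, i_hi)
    if i_max < level:
        return NOT_REACHED
    if curve.top == curve.bottom:  # flat curve at/above level: no crossing
        return lo if (100.0 - curve.top) >= level else NOT_REACHED
    if i_lo >= level:  # crossing lies below the searchable span; clamp
        return lo
    from scipy.optimize import brentq
    f = lambda lx: float(curve.inhibition(10.0 ** lx)) - level
    return float(10.0 ** brentq(f, math.log10(lo), math.log10(hi),
                                xtol=1e-12, rtol=1e-14))


def cohort_ic20(curves: Sequence[DoseResponseCurve],
                level: float = 20.0) -> tuple[float, int]:
    """Geometric-mean IC at ``level`` across samples for one drug.

    Curves on which the level is not reached are excluded; the count of
    exclusions is returned alongside.  This fixed concentration is what the
    combination designs use for the priming drug.
    """
    ics = []
    n_excluded = 0
    for c in curves:
        ic = ic_value(c, level)
        if ic is NOT_REACHED:
            n_excluded += 1
        else:
            ics.append(ic)
    if not ics:
        raise FitError(f"no sample reaches {level}% inhibition")
    gm = float(np.exp(np.mean(np.log(ics))))
    return gm, n_excluded
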