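"""Hit calling, 4PL dose-response fitting and the combination index.

Hit rule (dual concentration): a compound/growth-factor pair is a hit
when, at *both* tested concentrations (screen design: 1.67 and
6.67 uM), it is not growth inhibitory (CCR >= 1.5) and inhibits
dispersion (CDR% <= 50).  Boundary values pass.

Dose-response: the four-parameter logistic on log-dose,

    y(x) = bottom + (top - bottom) / (1 + (x / IC50)^hill)

fit by least squares; an IC50 beyond the tested range (or a failed /
flat fit) is censored and reported as "> <max tested>", mirroring the
conventional "> 5000 nM" notation of screening tables.

Combination index (Chou-Talalay): at effect level f reached by the
fixed-ratio combination dose (D1, D2),

    CI = D1 / Dx1 + D2 / Dx2

where Dx_i is the single-agent dose producing f.  CI > 1.1 antagonism,
0.9-1.1 additive, 0.2-0.9 synergism, < 0.2 strong synergism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


@dataclass
class DoseResponseFit:
    """Result of a 4PL fit of CDR% against concentration."""

    compound_id: str
    growth_factor: str
    top: float
    bottom: float
    ic50: float
    hill_slope: float
    rss: float
    converged: bool
    censored: bool
    max_tested: float
    n_points: int

    @property
    def ic50_display(self) -> str:
        if self.censored or not self.converged:
            return f"> {self.max_tested:g}"
        return f"{self.ic50:g}"

    def predict(self, x):
        return _four_pl(np.asarray(x, dtype=float), self.top, self.bottom,
                        math.log(self.ic50), self.hill_slope)

    def inverse(self, y: float) -> float:
        """Dose at which the fitted curve passes through response ``y``."""
        lo, hi = sorted((self.top, self.bottom))
        if not (lo < y < hi):
            raise ValueError(
                f"effect level y={y} outside the fitted response range "
                f"({lo:.3g}, {hi:.3g})"
            )
        ratio = (self.top - y) / (y - self.bottom)
        return self.ic50 * ratio ** (1.0 / self.hill_slope)


@dataclass
class CombinationResult:
    """Chou-Talalay combination index at one effect level and dose ratio."""

    ratio: tuple
    effect: float
    d1: float
    d2: float
    dx1: float
    dx2: float
    ci: float
    classification: str


def call_hits(
    metrics: pd.DataFrame,
    ccr_threshold: float = 1.5,
    cdr_threshold: float = 50.0,
    n_concentrations: int = 2,
) -> tuple:
    """Dual-concentration hit calling.

    Parameters
    ----------
    metrics : DataFrame
        Columns ``compound_id, growth_factor, concentration, CCR,
        CDR_pct`` — one row per tested well condition.
    ccr_threshold, cdr_threshold : float
        Pass requires CCR >= ccr_threshold (not growth inhibitory) AND
        CDR_pct <= cdr_threshold (dispersion inhibited); both
        comparisons are inclusive.

    Returns
    -------
    (hits, excluded) : (DataFrame, DataFrame)
        One hit row per (compound, growth factor) present at all
        required concentrations; pairs with missing concentrations or
        non-finite metrics land in ``excluded`` with a reason, never
        silently dropped.
    """
    hit_rows, excluded = [], []
    for (comp, gf), grp in metrics.groupby(["compound_id", "growth_factor"], sort=True):
        concs = sorted(grp["concentration"].unique())
        if len(concs) < n_concentrations:
            excluded.append(
                dict(compound_id=comp, growth_factor=gf,
                     reason=f"only {len(concs)} of {n_concentrations} concentrations tested")
            )
            continue
        if grp[["CCR", "CDR_pct"]].isna().any().any():
            excluded.append(
                dict(compound_id=comp, growth_factor=gf, reason="undefined CCR or CDR%")
            )
            continue
        per_conc = grp.groupby("concentration")[["CCR", "CDR_pct"]].mean()
        pass_ccr = per_conc["CCR"] >= ccr_threshold
        pass_cdr = per_conc["CDR_pct"] <= cdr_threshold
        row = dict(compound_id=comp, growth_factor=gf,
                   is_hit=bool((pass_ccr & pass_cdr).all()))
        for i, conc in enumerate(per_conc.index):
            row[f"conc_{i}"] = conc
            row[f"CCR_{i}"] = per_conc.loc[conc, "CCR"]
            row[f"CDR_pct_{i}"] = per_conc.loc[conc, "CDR_pct"]
            row[f"pass_ccr_{i}"] = bool(pass_ccr.loc[conc])
            row[f"pass_cdr_{i}"] = bool(pass_cdr.loc[conc])
        hit_rows.append(row)
    return pd.DataFrame(hit_rows), pd.DataFrame(excluded)


def _four_pl(x, top, bottom, log_ic50, hill):
    # evaluated on log-dose for numerical stability
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (np.log(x) - log_ic50)))


def fit_dose_response(
    concentrations,
    responses,
    compound_id: str = "",
    growth_factor: str = "",
    constrain_top: float | None = None,
    constrain_bottom: float | None = None,
    min_span: float = 10.0,
) -> DoseResponseFit:
    """Fit the 4PL to a CDR% dose-response series.

    Requires >= 4 distinct positive concentrations spanning at least
    one decade (replicates allowed).  Initialisation is deterministic:
    top/bottom from the extreme-dose means, IC50 from the dose nearest
    the half-effect, hill = 1.  ``constrain_top`` / ``constrain_bottom``
    optionally pin the asymptotes (e.g. 100 and 0).  The fit is
    censored (``censored=True``, IC50 reported as "> max tested") when
    optimisation fails, the response span is below ``min_span`` CDR%
    points (flat or rising curve), or the IC50 lands beyond the tested
    range.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise ValueError("concentrations and responses differ in length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    distinct = np.unique(x)
    if len(distinct) < 4:
        raise ValueError("need >= 4 distinct concentrations")
    if np.log10(distinct.max() / distinct.min()) < 1.0:
        raise ValueError("concentrations must span at least one decade")
    max_tested = float(distinct.max())

    lo_mean = float(y[x == distinct[0]].mean())
    hi_mean = float(y[x == distinct[-1]].mean())
    top0 = constrain_top if constrain_top is not None else lo_mean
    bot0 = constrain_bottom if constrain_bottom is not None else hi_mean
    half = (top0 + bot0) / 2.0
    ic50_0 = float(distinct[np.argmin(np.abs(
        np.array([y[x == d].mean() for d in distinct]) - half))])

    free_top = constrain_top is None
    free_bot = constrain_bottom is None

    def unpack(p):
        i = 0
        top = p[i] if free_top else constrain_top
        i += free_top
        bottom = p[i] if free_bot else constrain_bottom
        i += free_bot
        return top, bottom, p[i], p[i + 1]

    def resid(p):
        top, bottom, log_ic50, hill = unpack(p)
        return _four_pl(x, top, bottom, log_ic50, hill) - y

    p0, lo, hi = [], [], []
    if free_top:
        p0.append(top0); lo.append(-1e3); hi.append(1e3)
    if free_bot:
        p0.append(bot0); lo.append(-1e3); hi.append(1e3)
    p0 += [math.log(ic50_0), 1.0]
    lo += [math.log(distinct.min()) - math.log(1e4), 1e-3]
    hi += [math.log(max_tested) + math.log(1e4), 20.0]

    result = least_squares(resid, p0, bounds=(lo, hi), method="trf")
    top, bottom, log_ic50, hill = unpack(result.x)
    ic50 = float(math.exp(log_ic50))
    converged = bool(result.success) and np.isfinite(result.cost)
    span = top - bottom
    censored = (not converged) or span < min_span or ic50 > max_tested
    return DoseResponseFit(
        compound_id=compound_id,
        growth_factor=growth_factor,
        top=float(top),
        bottom=float(bottom),
        ic50=ic50,
        hill_slope=float(hill),
        rss=float(2 * result.cost),
        converged=converged,
        censored=bool(censored),
        max_tested=max_tested,
        n_points=int(len(x)),
    )


def classify_ci(ci: float) -> str:
    """Chou-Talalay CI classes: >1.1 antagonism, 0.9-1.1 additive,
    0.2-0.9 synergism, <0.2 strong synergism."""
    if ci > 1.1:
        return "antagonism"
    if ci >= 0.9:
        return "additive"
    if ci >= 0.2:
        return "synergism"
    return "strong_synergism"


def combination_index(
    fit1: DoseResponseFit,
    fit2: DoseResponseFit,
    combo_fit: DoseResponseFit,
    ratio: tuple = (1, 1),
    effect: float = 0.5,
) -> CombinationResult:
    """Combination index of a fixed-ratio two-drug combination.

    Parameters
    ----------
    fit1, fit2 : DoseResponseFit
        Converged single-agent fits (same dose units).
    combo_fit : DoseResponseFit
        Fit of response against the *total* combination dose, acquired
        at the fixed ``ratio`` (parts of drug 1 : parts of drug 2).
    effect : float
        Fraction affected f in (0, 1); on the CDR% scale the target
        response is ``100 * (1 - f)`` (f = 0.5 is the midpoint, 50%).

    Raises
    ------
    ValueError
        If a fit did not converge or the effect level is outside the
        achievable response range of either single agent.
    """
    for f in (fit1, fit2, combo_fit):
        if not f.converged:
            raise ValueError(f"fit for {f.compound_id!r} did not converge")
    if not (0.0 < effect < 1.0):
        raise ValueError("effect must be strictly between 0 and 1")
    y_target = 100.0 * (1.0 - effect)
    r1, r2 = float(ratio[0]), float(ratio[1])
    if r1 < 0 or r2 < 0 or r1 + r2 == 0:
        raise ValueError("ratio parts must be nonnegative and not both zero")
    d_total = combo_fit.inverse(y_target)
    d1 = d_total * r1 / (r1 + r2)
    d2 = d_total * r2 / (r1 + r2)
    dx1 = fit1.inverse(y_target)
    dx2 = fit2.inverse(y_target)
    ci = d1 / dx1 + d2 / dx2
    return CombinationResult(
        ratio=(r1, r2), effect=effect, d1=d1, d2=d2, dx1=dx1, dx2=dx2,
        ci=float(ci), classification=classify_ci(float(ci)),
    )
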