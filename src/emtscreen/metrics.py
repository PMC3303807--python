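"""Well-level ratios (CCR, CDR), control normalisation and plate QC.

CCR = count(T2) / count(T1) measures colony growth; CDR =
sp(T2) / sp(T1) measures dispersion.  CDR is rescaled per plate so that
the positive controls (dispersion fully inhibited) sit at 0% and the
negative controls (full dispersion) at 100%:

    CDR% = 100 * (CDR - CDR_pos) / (CDR_neg - CDR_pos)

Values outside [0, 100] are legitimate (a well can disperse more than
the negative controls) and are flagged, never clipped.  Assay quality
is summarised by the Z-factor

    Z = 1 - 3 * (sd_pos + sd_neg) / |mean_pos - mean_neg|

(sample standard deviations); Z > 0.5 indicates a robust screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PlateControls:
    """Per-plate control aggregates used for CDR% and the Z-factor."""

    cdr_neg: float
    cdr_pos: float
    sd_neg: float
    sd_pos: float
    n_neg: int
    n_pos: int


def cell_count_ratio(count_t1: float, count_t2: float) -> float:
    """CCR = count_T2 / count_T1; NaN (caller flags) when count_T1 = 0."""
    if count_t1 is None or count_t1 <= 0 or not math.isfinite(float(count_t1)):
        return float("nan")
    return float(count_t2) / float(count_t1)


def cell_dispersion_ratio(sp_t1: float, sp_t2: float) -> float:
    """CDR = sp_T2 / sp_T1; NaN (caller flags) when sp_T1 is 0 or undefined."""
    sp_t1 = float(sp_t1)
    if not math.isfinite(sp_t1) or sp_t1 <= 0:
        return float("nan")
    return float(sp_t2) / sp_t1


def normalize_cdr(cdr: float, controls: PlateControls) -> float:
    """Normalise a CDR against the plate's control boundaries (percent)."""
    span = controls.cdr_neg - controls.cdr_pos
    if span == 0 or not math.isfinite(span):
        raise ValueError("degenerate plate: CDR_neg equals CDR_pos")
    return 100.0 * (float(cdr) - controls.cdr_pos) / span


def z_factor(neg_values, pos_values) -> float:
    """Z-factor between control groups (sample sd, symmetric in groups).

    Returns ``-inf`` when the group means coincide (zero dynamic
    range); callers report that as a QC failure flag.
    """
    neg = np.asarray(neg_values, dtype=float)
    pos = np.asarray(pos_values, dtype=float)
    if len(neg) < 2 or len(pos) < 2:
        raise ValueError("z_factor needs >= 2 values per control group")
    band = abs(neg.mean() - pos.mean())
    if band == 0:
        return float("-inf")
    return 1.0 - 3.0 * (neg.std(ddof=1) + pos.std(ddof=1)) / band


def plate_controls(
    metrics: pd.DataFrame, aggregate: str = "mean"
) -> PlateControls:
    """Aggregate control-well CDRs of one plate (mean, or median for robustness)."""
    agg = {"mean": np.mean, "median": np.median}[aggregate]
    neg = metrics.loc[metrics["role"] == "negative_control", "CDR"].dropna()
    pos = metrics.loc[metrics["role"] == "positive_control", "CDR"].dropna()
    if len(neg) == 0 or len(pos) == 0:
        raise ValueError("plate lacks analyzable control wells for normalization")
    return PlateControls(
        cdr_neg=float(agg(neg)),
        cdr_pos=float(agg(pos)),
        sd_neg=float(np.std(neg, ddof=1)) if len(neg) > 1 else float("nan"),
        sd_pos=float(np.std(pos, ddof=1)) if len(pos) > 1 else float("nan"),
        n_neg=int(len(neg)),
        n_pos=int(len(pos)),
    )


def compute_plate_metrics(
    measurements: pd.DataFrame,
    plate_map: pd.DataFrame,
    aggregate: str = "mean",
):
    """Combine T1/T2 colony measurements into per-well metrics + plate QC.

    Parameters
    ----------
    measurements : DataFrame
        One row per (well, timepoint) with columns ``well, timepoint,
        cell_count, sp_um`` (and optionally ``flags``).
    plate_map : DataFrame
        Columns ``plate, well, role, compound_id, concentration``
        (``growth_factor`` optional).

    Returns
    -------
    (metrics, qc) : (DataFrame, dict)
        ``metrics`` has one row per well: CCR, CDR, CDR_pct, qc_flags.
        ``qc`` carries the control aggregates and the Z-factor.
    """
    piv = measurements.pivot_table(
        index="well", columns="timepoint", values=["cell_count", "sp_um"],
        aggfunc="first",
    )
    rows = []
    for _, m in plate_map.iterrows():
        well = m["well"]
        flags = []
        if well not in piv.index:
            rows.append(_metric_row(m, np.nan, np.nan, ["missing_well"]))
            continue
        try:
            c1 = piv.loc[well, ("cell_count", "T1")]
            c2 = piv.loc[well, ("cell_count", "T2")]
            s1 = piv.loc[well, ("sp_um", "T1")]
            s2 = piv.loc[well, ("sp_um", "T2")]
        except KeyError:
            rows.append(_metric_row(m, np.nan, np.nan, ["missing_timepoint"]))
            continue
        if pd.isna(c1) or pd.isna(c2):
            rows.append(_metric_row(m, np.nan, np.nan, ["missing_timepoint"]))
            continue
        ccr = cell_count_ratio(c1, c2)
        cdr = cell_dispersion_ratio(s1, s2)
        if not math.isfinite(ccr):
            flags.append("ccr_undefined")
        if not math.isfinite(cdr):
            flags.append("cdr_undefined")
        rows.append(_metric_row(m, ccr, cdr, flags))
    metrics = pd.DataFrame(rows)

    controls = plate_controls(metrics, aggregate)
    metrics["CDR_pct"] = [
        normalize_cdr(c, controls) if math.isfinite(c) else float("nan")
        for c in metrics["CDR"]
    ]
    out_of_range = (metrics["CDR_pct"] < 0) | (metrics["CDR_pct"] > 100)
    metrics.loc[out_of_range, "qc_flags"] = metrics.loc[out_of_range, "qc_flags"].apply(
        lambda f: f + "|cdr_pct_out_of_range" if f else "cdr_pct_out_of_range"
    )

    neg = metrics.loc[metrics["role"] == "negative_control", "CDR"].dropna()
    pos = metrics.loc[metrics["role"] == "positive_control", "CDR"].dropna()
    z = z_factor(neg, pos) if len(neg) >= 2 and len(pos) >= 2 else float("nan")
    qc = {
        "cdr_neg": controls.cdr_neg,
        "cdr_pos": controls.cdr_pos,
        "sd_neg": controls.sd_neg,
        "sd_pos": controls.sd_pos,
        "n_neg": controls.n_neg,
        "n_pos": controls.n_pos,
        "z_factor": z,
        "z_pass": bool(math.isfinite(z) and z > 0.5),
        "flags": [] if math.isfinite(z) and z > float("-inf") else ["z_factor_degenerate"],
    }
    return metrics, qc


def _metric_row(map_row, ccr, cdr, flags):
    return dict(
        plate=map_row.get("plate", ""),
        well=map_row["well"],
        role=map_row["role"],
        compound_id=map_row.get("compound_id", ""),
        concentration=map_row.get("concentration", float("nan")),
        growth_factor=map_row.get("growth_factor", ""),
        CCR=ccr,
        CDR=cdr,
        qc_flags="|".join(flags),
    )
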