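"""End-to-end orchestration: images -> measurements -> metrics -> hits.

``run_pipeline`` ties the stages together for one or more plates: it
reads the image manifest, segments each well at each timepoint,
measures the primary colony, computes CCR/CDR/CDR% with per-plate
control normalisation and Z-factor QC, and calls hits.  Results are
written as CSV/JSON with stable ordering and formatting, so reruns on
identical inputs are byte-identical; a run log records the package
version, a hash of the configuration and per-stage counts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import metrics as metrics_mod
from .colony import measure_well
from .platemap import RunConfig, read_manifest, validate_plate_map
from .screening import call_hits
from .segmentation import segment_well

_FLOAT_FMT = "%.10g"


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def measure_plate_wells(manifest: pd.DataFrame, config: RunConfig):
    """Segment and measure every (plate, well, timepoint) in a manifest.

    Wells missing one timepoint or any field are flagged and excluded;
    the run continues.  Returns ``(measurements, excluded)`` frames.
    """
    params = config.segmentation_params()
    rows, excluded = [], []
    for (plate, well), grp in manifest.groupby(["plate", "well"], sort=True):
        tps = set(grp["timepoint"])
        if tps != {"T1", "T2"}:
            excluded.append(
                dict(plate=plate, well=well,
                     reason=f"missing timepoint(s): {sorted({'T1', 'T2'} - tps)}")
            )
            continue
        ok = True
        for tp in ("T1", "T2"):
            sub = grp[grp["timepoint"] == tp].sort_values("field")
            if sorted(sub["field"]) != [0, 1, 2, 3]:
                excluded.append(
                    dict(plate=plate, well=well,
                         reason=f"{tp}: expected fields 0..3, got {sorted(sub['field'])}")
                )
                ok = False
                break
            images = [tifffile.imread(p).astype(float) for p in sub["path"]]
            well_mask, centroids = segment_well(images, params)
            meas = measure_well(
                well_mask.labels, centroids, pixel_size=config.pixel_size,
                disk_diameter_px=config.disk_diameter_px,
                well_id=well, timepoint=tp,
            )
            rows.append(
                dict(plate=plate, well=well, timepoint=tp,
                     cell_count=meas.cell_count,
                     sp_um=meas.spreading_coefficient_um,
                     n_outlier_regions=meas.n_outlier_regions,
                     n_outlier_cells=meas.n_outlier_cells,
                     flags="|".join(meas.flags))
            )
        if not ok:
            continue
    return pd.DataFrame(rows), pd.DataFrame(excluded)


def run_pipeline(
    manifest_path,
    plate_map: pd.DataFrame,
    config: RunConfig,
    out_dir,
):
    """Run the full analysis for every plate in the manifest.

    Parameters
    ----------
    manifest_path : path
        CSV manifest (plate, well, timepoint, field, path).
    plate_map : DataFrame
        Validated plate map covering the manifest's plates.
    out_dir : path
        Destination for ``well_measurements.csv``, ``well_metrics.csv``,
        ``hits.csv``, ``excluded_wells.csv``, ``qc.json`` and
        ``run_log.json``.

    Returns
    -------
    dict
        Bundle with the measurement/metric/hit frames and QC per plate.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plate_map = validate_plate_map(plate_map)
    manifest = read_manifest(manifest_path)

    measurements, excluded = measure_plate_wells(manifest, config)

    all_metrics, qc_by_plate = [], {}
    for plate, pmap in plate_map.groupby("plate"):
        meas = measurements[measurements["plate"] == plate] if len(measurements) else measurements
        if len(meas) == 0:
            continue
        mtx, qc = metrics_mod.compute_plate_metrics(
            meas, pmap, aggregate=config.control_aggregate
        )
        all_metrics.append(mtx)
        qc_by_plate[str(plate)] = qc
    metrics = (
        pd.concat(all_metrics, ignore_index=True)
        if all_metrics
        else pd.DataFrame()
    )

    test_metrics = metrics[metrics["role"] == "test"] if len(metrics) else metrics
    n_concs = (
        test_metrics.groupby(["compound_id", "growth_factor"])["concentration"]
        .nunique()
        .max()
        if len(test_metrics)
        else 0
    )
    if n_concs and n_concs >= 2:
        hits, hit_excluded = call_hits(
            test_metrics, ccr_threshold=config.ccr_threshold,
            cdr_threshold=config.cdr_threshold,
        )
    else:
        hits, hit_excluded = pd.DataFrame(), pd.DataFrame()

    _write_csv(measurements.sort_values(["plate", "well", "timepoint"]) if len(measurements) else measurements,
               out_dir / "well_measurements.csv")
    _write_csv(metrics.sort_values(["plate", "well"]) if len(metrics) else metrics,
               out_dir / "well_metrics.csv")
    _write_csv(hits.sort_values(["compound_id", "growth_factor"]) if len(hits) else hits,
               out_dir / "hits.csv")
    _write_csv(excluded, out_dir / "excluded_wells.csv")
    with open(out_dir / "qc.json", "w") as fh:
        json.dump(qc_by_plate, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")

    from . import __version__

    log = dict(
        package_version=__version__,
        config=config.to_dict(),
        config_hash=_config_hash(config),
        n_manifest_rows=int(len(manifest)),
        n_wells_measured=int(len(measurements) // 2) if len(measurements) else 0,
        n_wells_excluded=int(len(excluded)),
        n_hits=int(hits["is_hit"].sum()) if len(hits) else 0,
        n_hit_pairs_excluded=int(len(hit_excluded)),
    )
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return dict(
        measurements=measurements,
        metrics=metrics,
        hits=hits,
        excluded=excluded,
        hit_excluded=hit_excluded,
        qc=qc_by_plate,
        log=log,
    )


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_csv(df: pd.DataFrame, path):
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
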