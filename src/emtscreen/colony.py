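"""Primary-colony isolation and the spreading coefficient.

A well of the spot-migration assay contains one large cell colony (the
initial spot) and, typically, a handful of much smaller satellite
clusters — single cells, debris, dust.  Cell bodies are approximated by
dilating the nucleus segmentation with a disk of 30 px (48 um at
1.6 um/px) diameter; contiguous dilated regions form candidate
colonies, the region holding the most nuclei is the primary colony and
every other nucleus is an outlier.  Dispersion of the primary colony is
summarised by the spreading coefficient

    sp = sqrt( (1/n) * sum_c [ (c_x - mx)^2 + (c_y - my)^2 ] )

the RMS distance of the n colony nuclei from their centroid (mx, my).
sp is homogeneous with a distance and is reported in micrometres.  Note
the population (1/n) normalisation: "standard deviation of the cell
positions relative to the colony centre" is taken literally, not with
Bessel's n-1 correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as sk_label


@dataclass
class ColonyRegions:
    """Candidate-colony decomposition of a well mask.

    Attributes
    ----------
    region_labels : ndarray of int
        Label grid of dilated regions (0 = background).
    nucleus_region : dict
        Maps each nucleus label to the region label containing it.
    region_areas : dict
        Region label -> pixel area of the dilated region.
    region_counts : dict
        Region label -> number of member nuclei.
    """

    region_labels: np.ndarray
    nucleus_region: dict
    region_areas: dict
    region_counts: dict


@dataclass
class ColonyMeasurement:
    """Per-well, per-timepoint primary-colony measurement."""

    well_id: str
    timepoint: str
    cell_count: int
    centroid_um: tuple | None
    spreading_coefficient_um: float
    n_outlier_regions: int
    n_outlier_cells: int
    flags: list = field(default_factory=list)


def spreading_coefficient(positions) -> float:
    """RMS distance of points from their centroid, in the input units.

    Parameters
    ----------
    positions : array-like, shape (n, 2)
        Nucleus positions, usually (x, y) in micrometres.

    Returns
    -------
    float
        ``sqrt(var_x + var_y)`` with population (1/n) normalisation.
        A single point gives exactly 0.

    Raises
    ------
    ValueError
        If ``positions`` is empty.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        raise ValueError("spreading coefficient of an empty point set is undefined")
    if pos.ndim != 2 or pos.shape[1] != 2:
        raise ValueError(f"positions must have shape (n, 2), got {pos.shape}")
    if pos.shape[0] == 1:
        return 0.0
    centred = pos - pos.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred**2, axis=1))))


def dilate_to_colonies(labels: np.ndarray, disk_diameter_px: int = 30) -> ColonyRegions:
    """Group nuclei into candidate colonies by morphological dilation.

    The binary nucleus mask is dilated with a Euclidean disk of the
    given diameter (default 30 px = 48 um at 1.6 um/px); each connected
    dilated region is one candidate colony.  The disk is the set of
    pixels whose centre lies within ``disk_diameter_px / 2`` of the
    origin, implemented exactly via a Euclidean distance transform.

    Parameters
    ----------
    labels : ndarray of int
        Nucleus label grid (0 = background).
    disk_diameter_px : int
        Diameter of the dilation disk in pixels.

    Returns
    -------
    ColonyRegions
        Every nucleus label is assigned to exactly one region.  An
        empty mask yields an empty region map (no error).
    """
    labels = np.asarray(labels)
    if disk_diameter_px < 1:
        raise ValueError("disk_diameter_px must be >= 1")
    radius = disk_diameter_px / 2.0
    binary = labels > 0
    if not binary.any():
        return ColonyRegions(np.zeros_like(labels), {}, {}, {})
    dist = ndimage.distance_transform_edt(~binary)
    dilated = dist <= radius
    regions = sk_label(dilated, connectivity=2)

    areas = np.bincount(regions.ravel())
    region_areas = {int(r): int(areas[r]) for r in range(1, len(areas)) if areas[r] > 0}

    # each (connected) nucleus lies inside a single dilated region;
    # one representative pixel per nucleus suffices
    nuc_labels = np.unique(labels)
    nuc_labels = nuc_labels[nuc_labels > 0]
    nucleus_region: dict = {}
    pos = ndimage.find_objects(labels)
    for lab in nuc_labels:
        sl = pos[lab - 1]
        sub = labels[sl]
        rr, cc = np.nonzero(sub == lab)
        r0, c0 = rr[0] + sl[0].start, cc[0] + sl[1].start
        nucleus_region[int(lab)] = int(regions[r0, c0])

    region_counts: dict = {r: 0 for r in region_areas}
    for reg in nucleus_region.values():
        region_counts[reg] = region_counts.get(reg, 0) + 1
    return ColonyRegions(regions, nucleus_region, region_areas, region_counts)


def select_primary_colony(regions: ColonyRegions):
    """Pick the primary colony and summarise the outliers.

    The primary colony is the region with the most member nuclei; ties
    are broken by larger pixel area, then by lower region label, so the
    choice is deterministic.

    Returns
    -------
    (member_labels, outlier_summary) : (list of int, dict)
        ``member_labels`` are the nucleus labels of the primary colony.
        ``outlier_summary`` has keys ``n_outlier_regions``,
        ``n_outlier_cells``, ``primary_region`` and ``flags``.
    """
    if not regions.region_counts:
        return [], {
            "n_outlier_regions": 0,
            "n_outlier_cells": 0,
            "primary_region": 0,
            "flags": ["empty_well"],
        }
    best = max(
        regions.region_counts,
        key=lambda r: (regions.region_counts[r], regions.region_areas.get(r, 0), -r),
    )
    members = sorted(l for l, r in regions.nucleus_region.items() if r == best)
    outliers = [l for l, r in regions.nucleus_region.items() if r != best]
    n_regions_with_cells = len({r for r in regions.nucleus_region.values()})
    flags = []
    if len(members) <= 1:
        flags.append("degenerate_colony")
    return members, {
        "n_outlier_regions": max(n_regions_with_cells - 1, 0),
        "n_outlier_cells": len(outliers),
        "primary_region": int(best),
        "flags": flags,
    }


def measure_well(
    labels: np.ndarray,
    centroids: pd.DataFrame,
    pixel_size: float = 1.6,
    disk_diameter_px: int = 30,
    well_id: str = "",
    timepoint: str = "",
) -> ColonyMeasurement:
    """Measure cell count and spreading coefficient of the primary colony.

    Parameters
    ----------
    labels : ndarray of int
        Stitched well nucleus label grid.
    centroids : DataFrame
        Per-nucleus table with columns ``label``, ``x_px``, ``y_px``
        (as produced by :func:`emtscreen.segmentation.segment_well`).
    pixel_size : float
        Micrometres per pixel; sp is reported in um.
    disk_diameter_px : int
        Colony-merging dilation disk diameter.

    Returns
    -------
    ColonyMeasurement
        Zero-nuclei wells are flagged (``empty_well``) with count 0 and
        sp reported as NaN rather than raising.
    """
    cent = centroids
    if len(cent) == 0:
        return ColonyMeasurement(
            well_id, timepoint, 0, None, float("nan"), 0, 0, ["empty_well"]
        )
    # restrict the grid to bona fide nuclei (drops oversized/debris labels)
    keep = np.zeros(int(labels.max()) + 1, dtype=bool)
    keep[cent["label"].to_numpy(dtype=int)] = True
    labels = np.where(keep[labels], labels, 0)
    regions = dilate_to_colonies(labels, disk_diameter_px)
    members, summary = select_primary_colony(regions)
    member_set = set(members)
    rows = cent[cent["label"].isin(member_set)]
    positions = rows[["x_px", "y_px"]].to_numpy(dtype=float) * pixel_size
    flags = list(summary["flags"])
    if len(positions) == 0:
        return ColonyMeasurement(
            well_id, timepoint, 0, None, float("nan"),
            summary["n_outlier_regions"], summary["n_outlier_cells"],
            flags + ["empty_well"],
        )
    sp = spreading_coefficient(positions)
    cx, cy = positions.mean(axis=0)
    return ColonyMeasurement(
        well_id,
        timepoint,
        int(len(positions)),
        (float(cx), float(cy)),
        sp,
        summary["n_outlier_regions"],
        summary["n_outlier_cells"],
        flags,
    )
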