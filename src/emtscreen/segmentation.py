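"""Nuclei segmentation: a-trous wavelet detection + intensity watershed.

Each well is acquired as four adjacent, non-overlapping fields; fields
are segmented independently (so a partially-imaged nucleus at a field
border never contaminates its neighbour's statistics) and the four
label masks are then stitched into one well-sized mask, merging objects
that are split by a seam.

Detection uses the undecimated (a-trous) B3-spline wavelet transform,
the standard multiscale spot detector for fluorescence microscopy: the
band-pass detail planes carry nucleus-scale structure while smooth
inhomogeneous background lands in the coarse residual and pixel noise
is rejected by per-scale thresholding at ``k`` robust noise sigmas.
Touching nuclei are then split by a watershed on the (inverted) smoothed
intensity, seeded at local intensity maxima.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import label as sk_label
from skimage.measure import regionprops_table
from skimage.segmentation import watershed

_B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass
class SegmentationParams:
    """Tunable parameters of the nucleus segmentation.

    Attributes
    ----------
    n_wavelet_scales : int
        Number of a-trous detail planes computed (>= 2).
    detection_scales : tuple of int
        1-based detail planes whose thresholded supports are
        intersected to form the foreground mask.  Scales 2-3 match
        nucleus-sized blobs at 1.6 um/px.
    detection_threshold_k : float
        Multiplier of the per-scale robust noise sigma (MAD-based).
    min_nucleus_area, max_nucleus_area : int
        Area gates in px^2.  Labels below the minimum are removed;
        labels above the maximum are kept in the grid but flagged as
        oversized (debris) and excluded from nucleus tables.
    watershed_smoothing_sigma : float
        Gaussian sigma (px) applied to the intensity before seeding
        and flooding.
    seed_min_distance : int
        Minimum separation (px) between watershed seeds.
    seeding_scales : tuple of int
        Detail planes summed into the watershed seeding surface; the
        finer default (1, 2) resolves peaks of touching nuclei better
        than the detection band.
    declump_area_factor : float
        After the watershed, labels larger than this multiple of the
        median label area are split in two along their principal axis
        (deterministic 2-means) — the declumping pass that separates
        touching nuclei whose intensity dip is below the noise.  Set
        to ``inf`` to disable.
    centroid_mode : str
        'intensity' (intensity-weighted, default) or 'geometric'.
    """

    n_wavelet_scales: int = 3
    detection_scales: tuple = (2, 3)
    detection_threshold_k: float = 3.0
    min_nucleus_area: int = 20
    max_nucleus_area: int = 2000
    watershed_smoothing_sigma: float = 0.8
    seed_min_distance: int = 2
    seeding_scales: tuple = (1, 2)
    declump_area_factor: float = 1.8
    centroid_mode: str = "intensity"

    def __post_init__(self):
        if self.n_wavelet_scales < 2:
            raise ValueError("n_wavelet_scales must be >= 2")
        if not (0 < self.min_nucleus_area < self.max_nucleus_area):
            raise ValueError("need 0 < min_nucleus_area < max_nucleus_area")
        if max(self.detection_scales) > self.n_wavelet_scales:
            raise ValueError("detection_scales exceed n_wavelet_scales")
        if self.centroid_mode not in ("intensity", "geometric"):
            raise ValueError("centroid_mode must be 'intensity' or 'geometric'")


class FieldSegmentation(NamedTuple):
    labels: np.ndarray
    centroids: pd.DataFrame  # label, x_px, y_px, area_px2, oversized


class WellLabelMask(NamedTuple):
    labels: np.ndarray
    provenance: dict  # final label -> sorted tuple of source field indices
    oversized_labels: frozenset
    n_seam_merges: int


def atrous_b3(image: np.ndarray, n_scales: int):
    """Undecimated B3-spline wavelet transform.

    Returns ``(details, residual)`` where ``details[j]`` is the detail
    plane at scale j+1 (band-pass around blobs of radius ~2^j px) and
    ``residual`` is the remaining smooth approximation; the planes sum
    back to the input exactly.

    The image is extended by odd (anti-symmetric) reflection before
    filtering: unlike plain mirroring, this continues linear intensity
    trends exactly, so a smooth background gradient produces no detail
    response at the image borders.
    """
    img = np.asarray(image, dtype=float)
    pad = 2 * (2**n_scales - 1) + 2  # cumulative kernel reach
    pr = min(pad, img.shape[0] - 1)
    pc = min(pad, img.shape[1] - 1)
    c = np.pad(img, ((pr, pr), (pc, pc)), mode="reflect", reflect_type="odd")
    details = []
    for j in range(n_scales):
        # dilate the B3 kernel by 2^j (the "holes" of the a-trous scheme)
        step = 2**j
        kernel = np.zeros(4 * step + 1)
        kernel[::step] = _B3
        smooth = ndimage.convolve1d(c, kernel, axis=0, mode="mirror")
        smooth = ndimage.convolve1d(smooth, kernel, axis=1, mode="mirror")
        details.append(c - smooth)
        c = smooth
    crop = (slice(pr, c.shape[0] - pr), slice(pc, c.shape[1] - pc))
    return [d[crop] for d in details], c[crop]


def _robust_sigma(plane: np.ndarray) -> float:
    med = np.median(plane)
    return 1.4826 * float(np.median(np.abs(plane - med)))


def _threshold(w: np.ndarray, k: float, image_range: float) -> float:
    sigma = _robust_sigma(w)
    # the absolute floor keeps O(eps) round-off in analytically-zero
    # planes (constant or purely linear images) out of the support
    return max(k * sigma, 1e-9 * image_range)


def wavelet_detect(image: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Binary foreground mask of blob-scale (nucleus) structure.

    A pixel is foreground when any selected detail plane exceeds ``k``
    robust (MAD-based) noise sigmas for that plane.  The per-scale
    union keeps nuclei packed inside dense colonies, where the coarser
    planes dip negative; isolated noise excursions are removed later by
    the minimum-area gate.  The mask is invariant to adding a constant to
    the image (the transform annihilates constants) and excludes
    smooth background gradients, which live in the coarse residual.
    A constant image yields an empty mask.
    """
    params = params or SegmentationParams()
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    details, _ = atrous_b3(img, params.n_wavelet_scales)
    k = params.detection_threshold_k
    rng = float(img.max() - img.min())
    mask = np.zeros(img.shape, dtype=bool)
    for scale in params.detection_scales:
        w = details[scale - 1]
        mask |= w > _threshold(w, k, rng)
    return mask


def _core_map(intensity: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Pixels significant at the finest detection scale (nucleus cores)."""
    details, _ = atrous_b3(intensity, params.n_wavelet_scales)
    w = details[min(params.detection_scales) - 1]
    rng = float(intensity.max() - intensity.min())
    return w > _threshold(w, params.detection_threshold_k, rng)


def watershed_split(
    mask: np.ndarray,
    intensity: np.ndarray,
    params: SegmentationParams | None = None,
):
    """Split the foreground mask into individual nuclei.

    Seeds are local maxima of the Gaussian-smoothed blob-scale
    band-pass of the intensity (minimum separation
    ``seed_min_distance``) inside the mask — the band-pass removes the
    background slope, which would otherwise shift or swallow peaks of
    touching nuclei; flooding runs on the inverted smoothed surface
    restricted to the mask with 8-connectivity.  Components that receive no seed (flat plateaus)
    are kept as a single label.  Labels smaller than
    ``min_nucleus_area`` are removed; labels larger than
    ``max_nucleus_area`` are kept but reported as oversized.  Seed
    labelling and the final relabelling follow raster order, so equal
    plateaus resolve deterministically.

    Returns
    -------
    (labels, oversized) : (ndarray of int, frozenset of int)
    """
    params = params or SegmentationParams()
    mask = np.asarray(mask, dtype=bool)
    intensity = np.asarray(intensity, dtype=float)
    if mask.shape != intensity.shape:
        raise ValueError(
            f"mask shape {mask.shape} != intensity shape {intensity.shape}"
        )
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32), frozenset()

    details, _ = atrous_b3(intensity, params.n_wavelet_scales)
    surface = sum(details[s - 1] for s in params.seeding_scales)
    smoothed = ndimage.gaussian_filter(surface, params.watershed_smoothing_sigma)
    coords = peak_local_max(
        smoothed,
        min_distance=params.seed_min_distance,
        exclude_border=False,
        labels=mask,
    )
    components = sk_label(mask, connectivity=2)
    # ensure every component owns at least one seed
    seeded = set(components[tuple(coords.T)]) if len(coords) else set()
    extra = []
    n_comp = components.max()
    if len(seeded) < n_comp:
        for comp in range(1, n_comp + 1):
            if comp in seeded:
                continue
            rr, cc = np.nonzero(components == comp)
            vals = smoothed[rr, cc]
            k = int(np.argmax(vals))  # first (raster-order) maximum
            extra.append((rr[k], cc[k]))
    if extra:
        coords = np.vstack([coords, np.array(extra)]) if len(coords) else np.array(extra)
    # raster-order marker ids for reproducibility
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    coords = coords[order]
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    labels = watershed(-smoothed, markers, mask=mask, connectivity=2)
    # a genuine nucleus must own a handful of core-significant pixels;
    # labels carved from noise in the coarse-scale halo have almost none
    core = _core_map(intensity, params)
    counts = np.bincount(labels.ravel())
    core_counts = np.bincount(labels[core].ravel(), minlength=len(counts))
    min_core = max(1, params.min_nucleus_area // 2)
    lut = np.arange(len(counts), dtype=np.int32)
    lut[core_counts < min_core] = 0
    labels = lut[labels]
    labels, oversized = _filter_areas(labels, params)
    labels = _declump(labels, params)
    return _filter_areas(labels, params)[0], oversized


def _declump(labels: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Split labels much larger than the modal nucleus area in two.

    Touching nuclei whose mutual intensity dip is buried in noise
    survive the watershed as a single dumbbell-shaped label of about
    twice the typical area.  Any label exceeding
    ``declump_area_factor x median area`` (and at least twice the
    minimum area) is split by a deterministic 2-means on its pixel
    coordinates, initialised at the extremes of its principal axis.
    Repeats until stable (a fused triple splits progressively).
    """
    factor = params.declump_area_factor
    if not np.isfinite(factor):
        return labels
    for _ in range(4):
        counts = np.bincount(labels.ravel())
        areas = counts[1:][counts[1:] > 0]
        if len(areas) < 3:
            return labels
        med = float(np.median(areas))
        cut = max(factor * med, 2 * params.min_nucleus_area)
        big = [l for l in range(1, len(counts)) if counts[l] >= cut]
        if not big:
            return labels
        nxt = int(labels.max())
        changed = False
        slices = ndimage.find_objects(labels)
        for lab in big:
            sl = slices[lab - 1]
            rr, cc = np.nonzero(labels[sl] == lab)
            pts = np.c_[rr, cc].astype(float)
            ctr = pts.mean(axis=0)
            cov = np.cov((pts - ctr).T)
            _, vecs = np.linalg.eigh(cov)
            axis = vecs[:, -1]  # principal axis
            proj = (pts - ctr) @ axis
            c0, c1 = pts[np.argmin(proj)], pts[np.argmax(proj)]
            assign = None
            for _ in range(10):  # Lloyd iterations, deterministic
                d0 = np.sum((pts - c0) ** 2, axis=1)
                d1 = np.sum((pts - c1) ** 2, axis=1)
                new_assign = d1 < d0
                if assign is not None and np.array_equal(new_assign, assign):
                    break
                assign = new_assign
                if assign.all() or (~assign).all():
                    break
                c0 = pts[~assign].mean(axis=0)
                c1 = pts[assign].mean(axis=0)
            if assign is None or assign.all() or (~assign).all():
                continue
            if assign.sum() < params.min_nucleus_area or (~assign).sum() < params.min_nucleus_area:
                continue
            nxt += 1
            sub = labels[sl]
            sub[rr[assign], cc[assign]] = nxt
            changed = True
        if not changed:
            return labels
    return labels


def _filter_areas(labels: np.ndarray, params: SegmentationParams):
    """Apply the area gates and relabel contiguously in raster order."""
    counts = np.bincount(labels.ravel())
    remove = np.nonzero(counts < params.min_nucleus_area)[0]
    lut = np.arange(len(counts), dtype=np.int32)
    lut[remove] = 0
    lut[0] = 0
    labels = lut[labels]
    labels, mapping = _relabel_raster(labels)
    counts = np.bincount(labels.ravel())
    oversized = frozenset(
        int(l) for l in range(1, len(counts)) if counts[l] > params.max_nucleus_area
    )
    return labels, oversized


def _relabel_raster(labels: np.ndarray):
    """Relabel 1..K by order of first (raster) appearance; returns (labels, old->new)."""
    flat = labels.ravel()
    nz = np.nonzero(flat)[0]
    if len(nz) == 0:
        return labels.astype(np.int32), {}
    old = flat[nz]
    first_idx: dict = {}
    seen = np.zeros(int(old.max()) + 1, dtype=bool)
    order = []
    for v in old:
        if not seen[v]:
            seen[v] = True
            order.append(int(v))
    mapping = {o: i + 1 for i, o in enumerate(order)}
    lut = np.zeros(int(old.max()) + 1, dtype=np.int32)
    for o, n in mapping.items():
        lut[o] = n
    return lut[labels], mapping


def _centroid_table(labels, intensity, params, oversized):
    props = ["label", "area", "centroid"]
    if params.centroid_mode == "intensity" and intensity is not None:
        tbl = regionprops_table(
            labels, intensity_image=intensity,
            properties=["label", "area", "centroid_weighted"],
        )
        y = tbl["centroid_weighted-0"]
        x = tbl["centroid_weighted-1"]
    else:
        tbl = regionprops_table(labels, properties=props)
        y = tbl["centroid-0"]
        x = tbl["centroid-1"]
    df = pd.DataFrame(
        {
            "label": tbl["label"].astype(int),
            "x_px": x,
            "y_px": y,
            "area_px2": tbl["area"].astype(int),
        }
    )
    df["oversized"] = df["label"].isin(oversized)
    return df.sort_values("label", ignore_index=True)


def segment_field(image: np.ndarray, params: SegmentationParams | None = None) -> FieldSegmentation:
    """Segment one field: wavelet detection, watershed split, centroids.

    Returns the per-field label grid and a centroid table (columns
    ``label, x_px, y_px, area_px2, oversized``) in field coordinates.
    Oversized (debris) labels stay in the grid but are excluded from
    the nucleus rows used downstream.
    """
    params = params or SegmentationParams()
    mask = wavelet_detect(image, params)
    labels, oversized = watershed_split(mask, np.asarray(image, dtype=float), params)
    if labels.max() == 0:
        empty = pd.DataFrame(
            columns=["label", "x_px", "y_px", "area_px2", "oversized"]
        )
        return FieldSegmentation(labels, empty)
    df = _centroid_table(labels, np.asarray(image, dtype=float), params, oversized)
    return FieldSegmentation(labels, df)


def stitch_masks(field_labels: Sequence[np.ndarray],
                 field_oversized: Sequence[frozenset] | None = None) -> WellLabelMask:
    """Stitch four field label grids into one well mask.

    Field index convention: 0 = top-left, 1 = top-right, 2 =
    bottom-left, 3 = bottom-right; the montage is exactly 2x the field
    shape per axis with no overlap.  Labels are offset to be globally
    unique, then any two labels whose pixels are 8-adjacent across a
    seam are merged (a nucleus straddling a seam is one nucleus, not
    two), and the result is relabelled contiguously from 1 in raster
    order.

    Raises
    ------
    ValueError
        If a field is missing (names the index) or shapes disagree.
    """
    if len(field_labels) != 4:
        missing = [i for i in range(4) if i >= len(field_labels) or field_labels[i] is None]
        raise ValueError(f"stitching requires 4 fields; missing field index(es) {missing}")
    shapes = {f.shape for f in field_labels}
    if len(shapes) != 1:
        raise ValueError(f"field shapes disagree: {sorted(shapes)}")
    fr, fc = field_labels[0].shape
    montage = np.zeros((2 * fr, 2 * fc), dtype=np.int64)
    offsets = []
    running = 0
    oversized_global: set = set()
    provenance_field: dict = {}
    for i, lab in enumerate(field_labels):
        r0, c0 = (i // 2) * fr, (i % 2) * fc
        shifted = np.where(lab > 0, lab + running, 0)
        montage[r0 : r0 + fr, c0 : c0 + fc] = shifted
        offsets.append(running)
        for l in np.unique(lab):
            if l > 0:
                provenance_field[int(l) + running] = i
        if field_oversized is not None:
            oversized_global.update(int(l) + running for l in field_oversized[i])
        running += int(lab.max())

    parent = {l: l for l in provenance_field}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    n_merges = 0

    def merge_pairs(left, right):
        nonlocal n_merges
        both = (left > 0) & (right > 0) & (left != right)
        for a, b in zip(left[both], right[both]):
            if find(int(a)) != find(int(b)):
                n_merges += 1
            union(int(a), int(b))

    # vertical seam (between column fc-1 and fc), incl. diagonals
    merge_pairs(montage[:, fc - 1], montage[:, fc])
    merge_pairs(montage[:-1, fc - 1], montage[1:, fc])
    merge_pairs(montage[1:, fc - 1], montage[:-1, fc])
    # horizontal seam (between row fr-1 and fr), incl. diagonals
    merge_pairs(montage[fr - 1, :], montage[fr, :])
    merge_pairs(montage[fr - 1, :-1], montage[fr, 1:])
    merge_pairs(montage[fr - 1, 1:], montage[fr, :-1])

    if provenance_field:
        lut = np.zeros(max(provenance_field) + 1, dtype=np.int64)
        for l in provenance_field:
            lut[l] = find(l)
        montage = lut[montage]
    montage, mapping = _relabel_raster(montage)
    provenance: dict = {}
    for old, fld in provenance_field.items():
        new = mapping.get(find(old))
        if new is not None:
            provenance.setdefault(new, set()).add(fld)
    provenance = {k: tuple(sorted(v)) for k, v in provenance.items()}
    oversized_final = frozenset(
        mapping[find(l)] for l in oversized_global if find(l) in mapping
    )
    return WellLabelMask(montage.astype(np.int32), provenance, oversized_final, n_merges)


def segment_well(
    field_images: Sequence[np.ndarray], params: SegmentationParams | None = None
):
    """Segment all four fields of a well and stitch the masks.

    Returns
    -------
    (well_mask, centroids) : (WellLabelMask, DataFrame)
        Centroids (columns ``label, x_px, y_px, area_px2, oversized``)
        are recomputed on the stitched montage, in montage pixel
        coordinates, excluding oversized/debris labels.
    """
    params = params or SegmentationParams()
    segs = [segment_field(img, params) for img in field_images]
    oversized = []
    for s in segs:
        ov = s.centroids.loc[s.centroids["oversized"], "label"] if len(s.centroids) else []
        oversized.append(frozenset(int(l) for l in ov))
    well = stitch_masks([s.labels for s in segs], oversized)
    # seam merges can push an object over the area gate; recheck on the montage
    counts = np.bincount(well.labels.ravel())
    grown = {
        int(l) for l in range(1, len(counts)) if counts[l] > params.max_nucleus_area
    }
    well = WellLabelMask(
        well.labels,
        well.provenance,
        frozenset(well.oversized_labels) | frozenset(grown),
        well.n_seam_merges,
    )
    if well.labels.max() == 0:
        empty = pd.DataFrame(columns=["label", "x_px", "y_px", "area_px2", "oversized"])
        return well, empty
    fr, fc = field_images[0].shape
    montage_img = np.zeros((2 * fr, 2 * fc), dtype=float)
    for i, img in enumerate(field_images):
        r0, c0 = (i // 2) * fr, (i % 2) * fc
        montage_img[r0 : r0 + fr, c0 : c0 + fc] = img
    df = _centroid_table(well.labels, montage_img, params, set(well.oversized_labels))
    df = df[~df["oversized"]].reset_index(drop=True)
    return well, df
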