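"""Synthetic spot-migration plates: colony geometry, rendering, ground truth.

The generator emulates the assay the analysis pipeline was built for: a
0.5 ul droplet of dense cell suspension (~2,500 cells) deposited at the
well centre forms a compact colony, imaged at T1; after overnight
compound treatment and 24 h of growth-factor induced EMT the colony has
roughly doubled (CCR ~ 2) and — unless dispersion is inhibited — spread
to about twice its spreading coefficient (CDR ~ 2.2).  Each well is
rendered as a 2x2 montage of adjacent, non-overlapping fields
(default 1000 x 1000 px at 1.6 um/px, i.e. a 3.2 x 3.2 mm montage) with
Gaussian nucleus blobs, a smooth inhomogeneous background and additive
sensor noise, plus a few outlier cells outside the main colony.

Everything is deterministic given (specs, seed), and every well carries
exact ground truth: nucleus centres in the montage frame, colony
membership, counts, spreading coefficients, CCR and CDR.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .colony import spreading_coefficient


class PackingError(RuntimeError):
    """Raised when a colony cannot be packed at the requested separation."""


@dataclass
class ColonySpec:
    """Geometry of one simulated colony.

    ``target_sp`` is the spreading coefficient (um) the generated point
    set is rescaled to; ``min_separation`` is the smallest allowed
    distance between nucleus centres (um), reflecting nuclear exclusion.
    """

    n_cells: int = 2500
    center: tuple = (1600.0, 1600.0)
    target_sp: float = 495.0
    placement_model: str = "uniform_disk"
    min_separation: float = 10.0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.target_sp < 0:
            raise ValueError("target_sp must be >= 0")
        if self.target_sp == 0 and self.n_cells > 1:
            raise ValueError("target_sp = 0 requires n_cells = 1")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if self.placement_model not in ("uniform_disk", "gaussian"):
            raise ValueError("placement_model must be 'uniform_disk' or 'gaussian'")


@dataclass
class RenderSpec:
    """Imaging model of one well.

    A 2x2 tiling of ``image_shape`` fields covers the montage; the
    default pixel size of 1.6 um/px makes a 30 px disk span 48 um.
    Nuclei are radially symmetric Gaussian blobs with
    sigma = nucleus_radius / 2.  Intensities are arbitrary detector
    units on a 16-bit range.
    """

    image_shape: tuple = (1000, 1000)
    n_fields: int = 4
    pixel_size: float = 1.6
    nucleus_radius: float = 6.4
    nucleus_peak_intensity: float = 3000.0
    background_gradient_amplitude: float = 300.0
    background_offset: float = 100.0
    noise_sd: float = 300.0
    n_outlier_cells: int = 8

    def __post_init__(self):
        if self.n_fields != 4:
            raise ValueError("only the 2x2 four-field tiling is supported")
        if self.n_outlier_cells < 0:
            raise ValueError("n_outlier_cells must be >= 0")

    @property
    def montage_shape(self) -> tuple:
        return (2 * self.image_shape[0], 2 * self.image_shape[1])

    @property
    def montage_extent_um(self) -> tuple:
        """(x, y) extent of the montage in um."""
        return (
            self.montage_shape[1] * self.pixel_size,
            self.montage_shape[0] * self.pixel_size,
        )


def scaled_render(scale: float = 0.256) -> RenderSpec:
    """A dimensionally scaled-down RenderSpec (same pixel size, smaller field)."""
    side = int(round(1000 * scale))
    return RenderSpec(image_shape=(side, side))


@dataclass
class FieldImage:
    """One acquired tile of a well."""

    pixels: np.ndarray
    field_index: int
    pixel_size: float
    well_id: str
    timepoint: str


@dataclass
class GroundTruth:
    """Exact truth for one simulated well.

    ``centers_*`` are (x, y) nucleus positions in um in the montage
    frame (index i of the pixel grid sits at i * pixel_size);
    ``is_colony_*`` flags the members of the deposited colony (the rest
    are planted outliers).  Spreading coefficients, CCR and CDR are
    computed from the stored colony centres, so recomputing them from
    this object reproduces the stored values exactly.
    """

    well_id: str
    centers_t1: np.ndarray
    centers_t2: np.ndarray
    is_colony_t1: np.ndarray
    is_colony_t2: np.ndarray
    count_t1: int
    count_t2: int
    sp_t1: float
    sp_t2: float
    ccr: float
    cdr: float
    cdr_pct_true: float = float("nan")

    def nuclei_frame(self) -> pd.DataFrame:
        rows = []
        for tp, centers, flags in (
            ("T1", self.centers_t1, self.is_colony_t1),
            ("T2", self.centers_t2, self.is_colony_t2),
        ):
            for (x, y), c in zip(centers, flags):
                rows.append((self.well_id, tp, x, y, bool(c)))
        return pd.DataFrame(
            rows, columns=["well", "timepoint", "x_um", "y_um", "in_colony"]
        )


@dataclass
class EffectModel:
    """True dose-response of one compound acting on dispersion."""

    ic50: float  # molar
    hill: float = 1.0

    def cdr_pct(self, concentration: float) -> float:
        """True CDR% at a concentration (100 = full dispersion, 50 at IC50)."""
        if concentration <= 0:
            return 100.0
        return 100.0 / (1.0 + (concentration / self.ic50) ** self.hill)


@dataclass
class SimulationModel:
    """Plate-level true effect sizes and biological variability."""

    cdr_neg_true: float = 2.2
    cdr_pos_true: float = 1.05
    ccr_true: float = 2.0
    control_cv: float = 0.03
    ccr_cv: float = 0.05
    effects: Mapping[str, EffectModel] = field(default_factory=dict)


def rescale_to_spread(positions: np.ndarray, target_sp: float) -> np.ndarray:
    """Rescale a point set about its centroid to an exact spreading coefficient."""
    pos = np.asarray(positions, dtype=float)
    sp = spreading_coefficient(pos)
    if sp == 0:
        raise ValueError("cannot rescale a zero-spread point set to a nonzero sp")
    centroid = pos.mean(axis=0)
    return centroid + (pos - centroid) * (target_sp / sp)


def _min_nn_dist(pos: np.ndarray) -> float:
    if len(pos) < 2:
        return np.inf
    d, _ = cKDTree(pos).query(pos, k=2)
    return float(d[:, 1].min())


def _components(pos: np.ndarray, link_um: float):
    tree = cKDTree(pos)
    graph = tree.sparse_distance_matrix(tree, link_um, output_type="coo_matrix")
    return connected_components(graph, directed=False)


def _finalize_colony(
    pos: np.ndarray, min_sep: float, target_sp: float, link_um: float
) -> np.ndarray:
    """Alternate projections onto the three colony constraints.

    A deposited epithelial colony is a contiguous sheet of
    non-overlapping nuclei with a prescribed spread, so the returned
    point set must be (a) one connected component at linkage radius
    ``link_um``, (b) a hard-core pattern at ``min_sep`` and (c) of
    spreading coefficient exactly ``target_sp``.  Stray satellites are
    pulled to just inside the linkage radius of the main body,
    overlapping pairs are pushed apart symmetrically, and the set is
    rescaled about its centroid; iterated until all three hold.
    """
    pos = pos.copy()
    for _ in range(200):
        moved = False
        n_comp, comp = _components(pos, link_um)
        if n_comp > 1:
            moved = True
            main = int(np.argmax(np.bincount(comp)))
            main_pts = pos[comp == main]
            tree = cKDTree(main_pts)
            for i in np.nonzero(comp != main)[0]:
                _, j = tree.query(pos[i])
                anchor = main_pts[j]
                vec = pos[i] - anchor
                dist = float(np.hypot(*vec))
                if dist < 1e-9:
                    vec, dist = np.array([1.0, 0.0]), 1.0
                pos[i] = anchor + vec / dist * 0.8 * link_um
        pairs = cKDTree(pos).query_pairs(min_sep, output_type="ndarray")
        if len(pairs):
            moved = True
            for i, j in pairs:
                vec = pos[j] - pos[i]
                dist = float(np.hypot(*vec))
                if dist < 1e-9:
                    vec, dist = np.array([1.0, 0.0]), 1.0
                push = (min_sep * 1.05 - dist) / 2.0
                pos[i] -= vec / dist * push
                pos[j] += vec / dist * push
        pos = rescale_to_spread(pos, target_sp)
        if not moved:
            if (
                _min_nn_dist(pos) >= min_sep
                and _components(pos, link_um)[0] == 1
            ):
                return pos
    raise PackingError("colony constraints did not converge")


def sample_colony(spec: ColonySpec, seed: int) -> np.ndarray:
    """Sample nucleus centres for one colony.

    Points are drawn from the placement model (uniform disk of radius
    sp*sqrt(2), or isotropic Gaussian with sigma = sp/sqrt(2)) by dart
    throwing until the ``min_separation`` hard-core constraint holds,
    then rescaled about their centroid so the empirical spreading
    coefficient equals ``target_sp`` exactly, and finally nudged into a
    single connected cluster.  Deterministic given (spec, seed).

    Raises
    ------
    PackingError
        If the separation constraint cannot be met within a bounded
        number of retries (packing infeasible).
    """
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0xC0])
    center = np.asarray(spec.center, dtype=float)
    if spec.n_cells == 1:
        return center.reshape(1, 2)

    link = max(4.5 * spec.min_separation, 45.0)
    for _ in range(20):  # bounded restarts
        pts = _dart_throw(spec, rng, center)
        if pts is None:
            continue
        scaled = rescale_to_spread(pts, spec.target_sp)
        try:
            return _finalize_colony(scaled, spec.min_separation, spec.target_sp, link)
        except PackingError:
            continue
    raise PackingError(
        f"could not place {spec.n_cells} cells at sp={spec.target_sp} um "
        f"with min_separation={spec.min_separation} um"
    )


def _dart_throw(spec: ColonySpec, rng, center):
    n = spec.n_cells
    pts = np.empty((n, 2))
    placed = 0
    max_tries = 400 * n
    tries = 0
    while placed < n and tries < max_tries:
        tries += 1
        if spec.placement_model == "uniform_disk":
            r = spec.target_sp * np.sqrt(2.0) * np.sqrt(rng.uniform())
        else:
            # polar radius of an isotropic 2-D Gaussian with sigma = sp/sqrt(2)
            r = spec.target_sp / np.sqrt(2.0) * np.sqrt(-2.0 * np.log(rng.uniform(1e-12, 1.0)))
        theta = rng.uniform(0, 2 * np.pi)
        cand = center + r * np.array([np.cos(theta), np.sin(theta)])
        if placed and spec.min_separation > 0:
            d2 = np.sum((pts[:placed] - cand) ** 2, axis=1)
            if d2.min() < spec.min_separation**2:
                continue
        pts[placed] = cand
        placed += 1
    return pts if placed == n else None


def _background(render: RenderSpec) -> np.ndarray:
    rows, cols = render.montage_shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    xn, yn = xx / cols, yy / rows
    amp = render.background_gradient_amplitude
    hump = np.exp(-(((xn - 0.3) ** 2 + (yn - 0.6) ** 2) / (2 * 0.35**2)))
    return render.background_offset + amp * (0.6 * xn + 0.4 * yn) + 0.5 * amp * hump


def render_montage(positions_um: np.ndarray, render: RenderSpec, rng=None) -> np.ndarray:
    """Render nuclei + background (+ noise if an rng is given) as one montage."""
    rows, cols = render.montage_shape
    img = _background(render)
    sigma = render.nucleus_radius / 2.0 / render.pixel_size
    half = int(np.ceil(4 * sigma)) + 1
    for x, y in np.asarray(positions_um, dtype=float).reshape(-1, 2):
        cx, cy = x / render.pixel_size, y / render.pixel_size
        r0, r1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
        c0, c1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
        r0c, r1c = max(r0, 0), min(r1, rows)
        c0c, c1c = max(c0, 0), min(c1, cols)
        if r0c >= r1c or c0c >= c1c:
            continue
        yy, xx = np.mgrid[r0c:r1c, c0c:c1c].astype(float)
        img[r0c:r1c, c0c:c1c] += render.nucleus_peak_intensity * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2)
        )
    if rng is not None and render.noise_sd > 0:
        img = img + rng.normal(0.0, render.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 65535.0)


def split_fields(montage: np.ndarray) -> list:
    """Cut a montage into the four field tiles (0=TL, 1=TR, 2=BL, 3=BR)."""
    fr, fc = montage.shape[0] // 2, montage.shape[1] // 2
    return [
        montage[(i // 2) * fr : (i // 2 + 1) * fr, (i % 2) * fc : (i % 2 + 1) * fc]
        for i in range(4)
    ]


def _check_bounds(positions, render: RenderSpec, well_id: str):
    ext_x, ext_y = render.montage_extent_um
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    for x, y in pos:
        if not (0 <= x < ext_x and 0 <= y < ext_y):
            raise ValueError(
                f"well {well_id!r}: position ({x:.1f}, {y:.1f}) um outside "
                f"montage extent ({ext_x:.1f}, {ext_y:.1f}) um"
            )


def render_well(
    positions_t1,
    positions_t2,
    render: RenderSpec,
    seed: int,
    well_id: str = "well",
    is_colony_t1=None,
    is_colony_t2=None,
):
    """Render both timepoints of a well into four fields each.

    Returns ``(fields_t1, fields_t2, GroundTruth)``; fields are
    :class:`FieldImage` objects.  Nuclei straddling a field border
    appear partially in each adjacent field because the montage is
    rendered as a whole and then cut along the seams.
    """
    positions_t1 = np.asarray(positions_t1, dtype=float).reshape(-1, 2)
    positions_t2 = np.asarray(positions_t2, dtype=float).reshape(-1, 2)
    _check_bounds(positions_t1, render, well_id)
    _check_bounds(positions_t2, render, well_id)
    if is_colony_t1 is None:
        is_colony_t1 = np.ones(len(positions_t1), dtype=bool)
    if is_colony_t2 is None:
        is_colony_t2 = np.ones(len(positions_t2), dtype=bool)
    base = int(seed) & 0x7FFFFFFF
    fields = []
    for tp, pos in (("T1", positions_t1), ("T2", positions_t2)):
        rng = np.random.default_rng([base, 1 if tp == "T1" else 2])
        montage = render_montage(pos, render, rng)
        fields.append(
            [
                FieldImage(f, i, render.pixel_size, well_id, tp)
                for i, f in enumerate(split_fields(montage))
            ]
        )
    truth = _ground_truth(
        well_id, positions_t1, positions_t2, np.asarray(is_colony_t1), np.asarray(is_colony_t2)
    )
    return fields[0], fields[1], truth


def _ground_truth(well_id, pos_t1, pos_t2, col_t1, col_t2, cdr_pct_true=float("nan")):
    c1, c2 = pos_t1[col_t1], pos_t2[col_t2]
    sp1 = spreading_coefficient(c1) if len(c1) else float("nan")
    sp2 = spreading_coefficient(c2) if len(c2) else float("nan")
    return GroundTruth(
        well_id=well_id,
        centers_t1=pos_t1,
        centers_t2=pos_t2,
        is_colony_t1=col_t1,
        is_colony_t2=col_t2,
        count_t1=int(col_t1.sum()),
        count_t2=int(col_t2.sum()),
        sp_t1=sp1,
        sp_t2=sp2,
        ccr=float(col_t2.sum() / col_t1.sum()) if col_t1.sum() else float("nan"),
        cdr=float(sp2 / sp1) if len(c1) > 1 else float("nan"),
        cdr_pct_true=cdr_pct_true,
    )


def _place_outliers(rng, colony_pts, n, render: RenderSpec, min_gap=80.0):
    """Scatter outlier cells outside the colony footprint."""
    if n == 0:
        return np.empty((0, 2))
    ext_x, ext_y = render.montage_extent_um
    center = colony_pts.mean(axis=0)
    tree = cKDTree(colony_pts)
    out = []
    tries = 0
    margin = 20.0
    while len(out) < n and tries < 4000:
        tries += 1
        cand = np.array(
            [rng.uniform(margin, ext_x - margin), rng.uniform(margin, ext_y - margin)]
        )
        if tree.query(cand)[0] < min_gap:
            continue
        if out and np.min(np.sum((np.array(out) - cand) ** 2, axis=1)) < 60.0**2:
            continue
        out.append(cand)
    return np.array(out) if out else np.empty((0, 2))


def simulate_well(
    colony: ColonySpec,
    render: RenderSpec,
    seed: int,
    well_id: str = "well",
    cdr_true: float = 2.2,
    ccr_true: float = 2.0,
    division_jitter: float = 3.0,
):
    """Simulate one well: T1 colony, grown + dispersed T2 colony, outliers.

    T2 is built from T1 by (a) cell division — duplicating cells with a
    short random offset until the count reaches ``ccr_true * n`` —
    and (b) dispersion — an isotropic rescale about the colony centroid
    (plus a small jitter) that drives the spreading coefficient to
    ``cdr_true * sp(T1)``.  Outlier cells (``render.n_outlier_cells``)
    are planted outside the colony at both timepoints.

    Returns ``(fields_t1, fields_t2, GroundTruth)``.
    """
    base = int(seed) & 0x7FFFFFFF
    rng = np.random.default_rng([base, 3])
    pts1 = sample_colony(colony, seed)
    sp1 = spreading_coefficient(pts1) if len(pts1) > 1 else 0.0

    n2 = max(int(round(ccr_true * colony.n_cells)), 1)
    if n2 >= len(pts1):
        parents = rng.integers(0, len(pts1), size=n2 - len(pts1))
        theta = rng.uniform(0, 2 * np.pi, size=len(parents))
        dist = rng.uniform(colony.min_separation, 2 * colony.min_separation, size=len(parents))
        daughters = pts1[parents] + np.c_[np.cos(theta), np.sin(theta)] * dist[:, None]
        pts2 = np.vstack([pts1, daughters])
    else:
        keep = rng.choice(len(pts1), size=n2, replace=False)
        pts2 = pts1[np.sort(keep)]
    if len(pts2) > 1:
        pts2 = pts2 + rng.normal(0.0, division_jitter, size=pts2.shape)
        if sp1 > 0:
            pts2 = rescale_to_spread(pts2, cdr_true * sp1)
            pts2 = _enforce_separation(pts2, colony.min_separation, cdr_true * sp1)
        pts2 = _clamp_to_montage(pts2, render)

    out1 = _place_outliers(rng, pts1, render.n_outlier_cells, render)
    walk = rng.normal(0.0, 8.0, size=out1.shape) if len(out1) else out1
    out2 = np.clip(
        out1 + walk,
        20.0,
        [render.montage_extent_um[0] - 20.0, render.montage_extent_um[1] - 20.0],
    ) if len(out1) else out1

    all1 = np.vstack([pts1, out1]) if len(out1) else pts1
    all2 = np.vstack([pts2, out2]) if len(out2) else pts2
    col1 = np.r_[np.ones(len(pts1), bool), np.zeros(len(out1), bool)]
    col2 = np.r_[np.ones(len(pts2), bool), np.zeros(len(out2), bool)]
    return render_well(all1, all2, render, seed, well_id, col1, col2)


def _enforce_separation(pts: np.ndarray, min_sep: float, target_sp: float) -> np.ndarray:
    """Soft-sphere relaxation: nuclei are impenetrable, so push apart any
    pair closer than ``min_sep`` and re-rescale to the target spread."""
    if min_sep <= 0:
        return pts
    pts = pts.copy()
    for _ in range(60):
        tree = cKDTree(pts)
        pairs = tree.query_pairs(min_sep, output_type="ndarray")
        if len(pairs) == 0:
            return pts
        for i, j in pairs:
            vec = pts[j] - pts[i]
            dist = float(np.hypot(*vec))
            if dist < 1e-9:
                vec, dist = np.array([1.0, 0.0]), 1.0
            push = (min_sep * 1.05 - dist) / 2.0
            if push > 0:
                pts[i] -= vec / dist * push
                pts[j] += vec / dist * push
        pts = rescale_to_spread(pts, target_sp)
    return pts


def _clamp_to_montage(pts, render: RenderSpec, margin=12.0):
    ext_x, ext_y = render.montage_extent_um
    return np.clip(pts, margin, [ext_x - margin, ext_y - margin])


def _well_seed(seed: int, plate: str, well: str) -> int:
    h = hashlib.sha256(f"{int(seed)}:{plate}:{well}".encode()).digest()
    return int.from_bytes(h[:4], "big") & 0x7FFFFFFF


def simulate_plate(
    layout: pd.DataFrame,
    model: SimulationModel,
    colony: ColonySpec | None = None,
    render: RenderSpec | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
):
    """Simulate a whole plate from a plate map and a true effect model.

    Parameters
    ----------
    layout : DataFrame
        Plate map with columns ``plate, well, role, compound_id,
        concentration`` (molar; ``growth_factor`` optional).  Roles:
        negative controls get full T2 dispersion, positive controls get
        an essentially undispersed T2, and test wells get a dispersion
        interpolated through the compound's true 4PL effect model at
        the well concentration.
    model : SimulationModel
        True control CDRs, growth rate, well-to-well variability and
        the per-compound :class:`EffectModel` map (compounds absent
        from the map are inert).
    out_dir : path, optional
        When given, fields are written as 16-bit grayscale TIFFs named
        ``<plate>_<well>_<T1|T2>_f<0..3>.tif`` together with a manifest
        CSV and ground-truth CSVs, and per-well images are not kept in
        memory.

    Returns
    -------
    (wells, truth_table) : (dict or None, DataFrame)
        ``wells`` maps well id -> (fields_t1, fields_t2, GroundTruth)
        when ``out_dir`` is None; the truth table has one row per well
        with true counts, sp, CCR, CDR and true CDR%.
    """
    colony = colony or ColonySpec()
    render = render or RenderSpec()
    _validate_layout(layout)
    wells = {} if out_dir is None else None
    rows = []
    nuclei_frames = []
    manifest_rows = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    for _, row in layout.sort_values(["plate", "well"]).iterrows():
        plate, well, role = str(row["plate"]), str(row["well"]), str(row["role"])
        conc = float(row.get("concentration", 0.0) or 0.0)
        compound = str(row.get("compound_id", "") or "")
        wseed = _well_seed(seed, plate, well)
        wrng = np.random.default_rng([wseed, 9])
        if role == "negative_control":
            pct = 100.0
        elif role == "positive_control":
            pct = 0.0
        else:
            eff = model.effects.get(compound)
            pct = eff.cdr_pct(conc) if eff is not None else 100.0
        cdr_nom = model.cdr_pos_true + pct / 100.0 * (model.cdr_neg_true - model.cdr_pos_true)
        cdr_t = cdr_nom * float(np.exp(wrng.normal(0.0, model.control_cv)))
        ccr_t = model.ccr_true * float(np.exp(wrng.normal(0.0, model.ccr_cv)))
        f1, f2, truth = simulate_well(
            colony, render, wseed, well_id=well, cdr_true=cdr_t, ccr_true=ccr_t
        )
        truth.cdr_pct_true = pct
        rows.append(
            dict(
                plate=plate, well=well, role=role, compound_id=compound,
                concentration=conc,
                growth_factor=str(row.get("growth_factor", "") or ""),
                count_t1=truth.count_t1, count_t2=truth.count_t2,
                sp_t1_um=truth.sp_t1, sp_t2_um=truth.sp_t2,
                ccr_true=truth.ccr, cdr_true=truth.cdr, cdr_pct_true=pct,
            )
        )
        if out_dir is None:
            wells[well] = (f1, f2, truth)
        else:
            for tp, flds in (("T1", f1), ("T2", f2)):
                for fi, fimg in enumerate(flds):
                    name = f"{plate}_{well}_{tp}_f{fi}.tif"
                    tifffile.imwrite(
                        out_dir / name, np.round(fimg.pixels).astype(np.uint16)
                    )
                    manifest_rows.append(
                        dict(plate=plate, well=well, timepoint=tp, field=fi, path=name)
                    )
            nuclei_frames.append(truth.nuclei_frame())
    truth_table = pd.DataFrame(rows)
    if out_dir is not None:
        truth_table.to_csv(out_dir / "ground_truth_wells.csv", index=False)
        pd.concat(nuclei_frames, ignore_index=True).to_csv(
            out_dir / "ground_truth_nuclei.csv", index=False
        )
        pd.DataFrame(manifest_rows).to_csv(out_dir / "manifest.csv", index=False)
    return wells, truth_table


def _validate_layout(layout: pd.DataFrame):
    required = {"plate", "well", "role"}
    missing = required - set(layout.columns)
    if missing:
        raise ValueError(f"plate layout missing columns: {sorted(missing)}")
    roles = set(layout["role"])
    if "negative_control" not in roles or "positive_control" not in roles:
        raise ValueError(
            "plate layout must contain negative_control and positive_control "
            "wells (control normalization is impossible without them)"
        )


def default_layout(
    plate: str = "P1",
    compounds=None,
    concentration: float = 6.67e-6,
    growth_factor: str = "EGF",
    n_rows: int = 8,
) -> pd.DataFrame:
    """A 96-well-style layout: column 1 negative controls, column 12
    positive controls, columns 2-11 test compounds (row-major)."""
    rows = "ABCDEFGH"[:n_rows]
    recs = []
    compounds = list(compounds or [])
    k = 0
    for r in rows:
        for c in range(1, 13):
            well = f"{r}{c:02d}"
            if c == 1:
                recs.append((plate, well, "negative_control", "DMSO", 0.0, growth_factor))
            elif c == 12:
                recs.append((plate, well, "positive_control", "REF", concentration, growth_factor))
            else:
                comp = compounds[k % len(compounds)] if compounds else f"CPD{k:03d}"
                recs.append((plate, well, "test", comp, concentration, growth_factor))
                k += 1
    return pd.DataFrame(
        recs, columns=["plate", "well", "role", "compound_id", "concentration", "growth_factor"]
    )
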