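"""Plate-map and run-configuration handling.

A plate map is a CSV with one row per well: ``plate, well, role,
compound_id, concentration, growth_factor``.  Wells use the 96-well
letter-number convention A01-H12; roles are ``negative_control``,
``positive_control`` or ``test``.  The assay layout puts negative
controls in column 1 and positive controls in column 12, but any
layout with at least one well of each control role per plate is valid.
"""

from __future__ import annotations

import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

WELL_RE = re.compile(r"^[A-H](0[1-9]|1[0-2])$")
ROLES = {"negative_control", "positive_control", "test"}
PLATE_MAP_COLUMNS = ["plate", "well", "role", "compound_id", "concentration", "growth_factor"]


@dataclass
class RunConfig:
    """All tunables of a pipeline run, serialisable for provenance."""

    pixel_size: float = 1.6
    disk_diameter_px: int = 30
    n_wavelet_scales: int = 3
    detection_scales: tuple = (2, 3)
    detection_threshold_k: float = 3.0
    min_nucleus_area: int = 20
    max_nucleus_area: int = 2000
    watershed_smoothing_sigma: float = 0.8
    seed_min_distance: int = 2
    centroid_mode: str = "intensity"
    control_aggregate: str = "mean"
    ccr_threshold: float = 1.5
    cdr_threshold: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.disk_diameter_px < 1:
            raise ValueError("disk_diameter_px must be >= 1")
        if self.control_aggregate not in ("mean", "median"):
            raise ValueError("control_aggregate must be 'mean' or 'median'")
        self.detection_scales = tuple(self.detection_scales)

    def segmentation_params(self):
        from .segmentation import SegmentationParams

        return SegmentationParams(
            n_wavelet_scales=self.n_wavelet_scales,
            detection_scales=self.detection_scales,
            detection_threshold_k=self.detection_threshold_k,
            min_nucleus_area=self.min_nucleus_area,
            max_nucleus_area=self.max_nucleus_area,
            watershed_smoothing_sigma=self.watershed_smoothing_sigma,
            seed_min_distance=self.seed_min_distance,
            centroid_mode=self.centroid_mode,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["detection_scales"] = list(self.detection_scales)
        return d

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_file(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def validate_plate_map(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a plate map, returning it with normalised dtypes.

    Checks well-id syntax (A01-H12), per-plate well uniqueness, known
    roles and the presence of both control roles on every plate.
    """
    missing = {"plate", "well", "role"} - set(df.columns)
    if missing:
        raise ValueError(f"plate map missing columns: {sorted(missing)}")
    df = df.copy()
    df["well"] = df["well"].astype(str).str.strip()
    df["role"] = df["role"].astype(str).str.strip()
    bad_wells = [w for w in df["well"] if not WELL_RE.match(w)]
    if bad_wells:
        raise ValueError(f"invalid well id(s) for a 96-well grid: {bad_wells[:5]}")
    bad_roles = sorted(set(df["role"]) - ROLES)
    if bad_roles:
        raise ValueError(f"unknown role(s): {bad_roles}")
    dup = df.duplicated(subset=["plate", "well"])
    if dup.any():
        pairs = df.loc[dup, ["plate", "well"]].values.tolist()
        raise ValueError(f"duplicate plate/well assignment(s): {pairs[:5]}")
    for plate, grp in df.groupby("plate"):
        roles = set(grp["role"])
        if "negative_control" not in roles:
            raise ValueError(f"plate {plate!r} has no negative_control wells")
        if "positive_control" not in roles:
            raise ValueError(f"plate {plate!r} has no positive_control wells")
    if "concentration" in df.columns:
        df["concentration"] = pd.to_numeric(df["concentration"])
    else:
        df["concentration"] = 0.0
    for col in ("compound_id", "growth_factor"):
        if col not in df.columns:
            df[col] = ""
        df[col] = df[col].fillna("").astype(str)
    return df[PLATE_MAP_COLUMNS]


def read_plate_map(path) -> pd.DataFrame:
    return validate_plate_map(pd.read_csv(path))


def write_plate_map(df: pd.DataFrame, path):
    validate_plate_map(df).to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    """Read an image manifest CSV (plate, well, timepoint, field, path).

    Paths are resolved relative to the manifest's directory.  Malformed
    rows abort with their line number.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"plate", "well", "timepoint", "field", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    for i, row in df.iterrows():
        if str(row["timepoint"]) not in ("T1", "T2"):
            raise ValueError(
                f"manifest line {i + 2}: timepoint must be T1 or T2, "
                f"got {row['timepoint']!r}"
            )
        if not (0 <= int(row["field"]) <= 3):
            raise ValueError(f"manifest line {i + 2}: field index {row['field']} not in 0..3")
    df = df.copy()
    df["path"] = [str((path.parent / p)) for p in df["path"]]
    return df
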