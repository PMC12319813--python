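"""File I/O and core containers: NIfTI quantitative/label maps and the cohort table.

The long-format cohort table (TSV) is the single tabular interchange between
pipeline stages.  Every record is keyed by
(subject_id, roi, hemisphere, metric, statistic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("qmrinorm")

#: required columns of a cohort table, in canonical order
COHORT_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "hemisphere",
    "roi",
    "metric",
    "statistic",
    "value",
]

_COHORT_KEY = ["subject_id", "roi", "hemisphere", "metric", "statistic"]

#: accepted spellings of sex, normalized to the centered +-1/2 coding
SEX_CODES = {"F": 0.5, "female": 0.5, "1": 0.5, "M": -0.5, "male": -0.5, "0": -0.5}
#: hemisphere coding: right = +1/2, left = -1/2
HEMI_CODES = {"R": 0.5, "right": 0.5, "L": -0.5, "left": -0.5}


def sex_to_centered(values) -> np.ndarray:
    """Map sex labels ({M, F}, {0, 1}, ...) to the centered +-0.5 coding."""
    out = np.empty(len(values), dtype=float)
    for i, v in enumerate(values):
        key = str(v).strip()
        if key not in SEX_CODES:
            raise ValueError(f"unrecognized sex value {v!r}; accepted: {sorted(SEX_CODES)}")
        out[i] = SEX_CODES[key]
    return out


def hemisphere_to_centered(values) -> np.ndarray:
    """Map hemisphere labels (L/R) to the centered +-0.5 coding (right = +0.5)."""
    out = np.empty(len(values), dtype=float)
    for i, v in enumerate(values):
        key = str(v).strip()
        if key not in HEMI_CODES:
            raise ValueError(f"unrecognized hemisphere value {v!r}; accepted: L, R")
        out[i] = HEMI_CODES[key]
    return out


@dataclass
class QuantitativeMap:
    """A 3D quantitative parameter map (R1 [1/s], R2* [1/s] or chi [ppm]) + affine."""

    data: np.ndarray
    affine: np.ndarray
    units: str | None = None
    metric: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"quantitative map must be 3D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3 from the affine."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass
class LabelMap:
    """An integer parcellation label image on the same grid conventions."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise ValueError("label map contains non-integer values")
            self.data = np.round(self.data).astype(np.int32)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"label map must be 3D, got shape {self.data.shape}")

    @property
    def labels(self) -> np.ndarray:
        """Sorted non-zero labels present in the map."""
        u = np.unique(self.data)
        return u[u != 0]

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


def read_map(path: str | Path) -> QuantitativeMap:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got {img.ndim}D; select a single volume first"
        )
    return QuantitativeMap(np.asarray(img.dataobj, dtype=float), img.affine)


def write_map(qmap: QuantitativeMap, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(qmap.data.astype(np.float64), qmap.affine), str(path))


def read_labels(path: str | Path) -> LabelMap:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label volume, got {img.ndim}D")
    return LabelMap(np.asarray(img.dataobj), img.affine)


def write_labels(labels: LabelMap, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(labels.data.astype(np.int32), labels.affine), str(path))


def check_same_grid(*maps: QuantitativeMap | LabelMap) -> None:
    """Raise if maps do not share shape and affine (to 1e-6)."""
    shapes = [m.data.shape for m in maps]
    if len(set(shapes)) > 1:
        raise ValueError(f"maps are on different grids: shapes {shapes}")
    a0 = maps[0].affine
    for m in maps[1:]:
        if not np.allclose(m.affine, a0, atol=1e-6):
            raise ValueError("maps have mismatching affines")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a long-format cohort TSV, validating schema and key uniqueness."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty cohort file") from None
    if df.empty:
        raise ValueError(f"{path}: cohort file has a header but no rows")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns and c != "group"]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    if "group" not in df.columns:
        df["group"] = "control"
    dup = df.duplicated(subset=_COHORT_KEY)
    if dup.any():
        bad = df.loc[dup, _COHORT_KEY].iloc[0].to_dict()
        raise ValueError(f"{path}: duplicate cohort key, e.g. {bad}")
    df["age"] = df["age"].astype(float)
    df["value"] = df["value"].astype(float)
    df["subject_id"] = df["subject_id"].astype(str)
    # validate covariate dialects early so downstream stages get clean values
    sex_to_centered(df["sex"].unique())
    hemisphere_to_centered(df["hemisphere"].unique())
    logger.info("read cohort %s: %d rows, %d subjects", path, len(df), df["subject_id"].nunique())
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    ordered = [c for c in COHORT_COLUMNS if c in df.columns]
    ordered += [c for c in df.columns if c not in ordered]
    df[ordered].to_csv(path, sep="\t", index=False)


@dataclass
class PipelineConfig:
    """Parameters steering an end-to-end run (see pipeline.run_pipeline)."""

    seed: int = 0
    out_dir: str = "qmrinorm_out"
    cohort_path: str | None = None  # if None, a synthetic cohort is simulated
    n_subjects: int = 260
    n_patients: int = 0
    age_range: tuple[float, float] = (18.0, 79.0)
    metrics: tuple[str, ...] = ("R1", "R2star", "chi")
    statistic: str = "median"
    cv_k: int = 10
    gpr_restarts: int = 5
    fdr_q: float = 0.05
    network_thresholds: tuple[float, ...] = (0.4, 0.6)
    erosion_n: int = 1
    pool_hemispheres: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("age_range", "metrics", "network_thresholds"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)
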