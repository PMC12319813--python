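"""Per-ROI univariate statistics, normalized volumes, and spatial-gradient fits.

All anatomical reasoning goes through the affine: voxel indices are mapped to
mm coordinates (RAS assumed), so gradient coefficients are in units/mm along
the lateral-medial (L-M), posterior-anterior (P-A) and inferior-superior
(I-S) axes.  Right-hemisphere masks have the x-offset sign flipped before
fitting, so the L-M gradient shares one direction convention across
hemispheres and can be pooled with a hemisphere regressor downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from nibabel.affines import apply_affine
from scipy import ndimage, stats

from .io import LabelMap, QuantitativeMap

logger = logging.getLogger("qmrinorm")

#: ROIs large enough for a reliable first-order spatial fit at ~1 mm resolution
GRADIENT_DEFAULT_ROIS = ("Pu", "Cau")


class ROIStatistics(NamedTuple):
    median: float
    iqr: float
    skewness: float
    n_voxels: int
    n_invalid: int


@dataclass
class SpatialGradientFit:
    """First-order spatial model qMRI = p0 + p1*dx + p2*dy + p3*dz around the ROI centre."""

    p0: float
    p1: float  # units/mm, L-M
    p2: float  # units/mm, P-A
    p3: float  # units/mm, I-S
    centre: tuple[float, float, float]  # mm
    n_voxels_used: int
    rmse: float
    degenerate_axes: tuple[int, ...] = ()

    @property
    def gradient(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3])

    @property
    def grad_mean(self) -> float:
        """Mean absolute gradient magnitude over the three axes (units/mm)."""
        return float(np.nanmean(np.abs(self.gradient)))


@dataclass
class VolumeMetrics:
    v_roi_raw: float  # mm^3
    icv: float  # mm^3
    v_roi: float  # fraction of ICV
    v_mean: float | None = None  # cohort mean fraction
    v_pct: float | None = None  # percent change vs cohort mean


def roi_statistics(qmap: QuantitativeMap, labels: LabelMap, roi: int) -> ROIStatistics:
    """Median, IQR (Q75-Q25, linear-interpolated) and bias-corrected skewness of an ROI.

    Non-finite voxels are excluded and counted; an ROI with < 3 valid voxels
    has undefined (NaN) skewness.
    """
    values = qmap.data[labels.data == roi]
    if values.size == 0:
        raise ValueError(f"ROI {roi} is empty on this grid")
    finite = np.isfinite(values)
    n_invalid = int(values.size - finite.sum())
    values = values[finite]
    if values.size == 0:
        raise ValueError(f"ROI {roi} contains only invalid voxels")
    q25, med, q75 = np.percentile(values, [25.0, 50.0, 75.0])
    skew = float(stats.skew(values, bias=False)) if values.size >= 3 else float("nan")
    if values.size >= 3 and np.ptp(values) == 0:
        skew = 0.0  # constant ROI: symmetric by convention
    return ROIStatistics(float(med), float(q75 - q25), skew, int(values.size), n_invalid)


def erode_mask(mask: np.ndarray, n: int = 1, roi_name=None) -> np.ndarray:
    """Morphological erosion with a 3x3x3 box (one voxel in all 26 directions), n times."""
    m = np.asarray(mask)
    if m.dtype != bool and not np.isin(np.unique(m), (0, 1)).all():
        raise ValueError("mask must be binary")
    m = m.astype(bool)
    if n < 1:
        return m.copy()
    out = ndimage.binary_erosion(m, structure=np.ones((3, 3, 3), dtype=bool), iterations=n)
    if not out.any():
        name = f" ({roi_name})" if roi_name is not None else ""
        raise ValueError(f"erosion by {n} voxel(s) left mask{name} empty")
    return out


def fit_spatial_gradient(
    qmap: QuantitativeMap,
    roi_mask: np.ndarray,
    hemisphere: str = "L",
) -> SpatialGradientFit:
    """OLS fit of the first-order spatial model over an (eroded) ROI mask.

    The centre (x0, y0, z0) is the unweighted centre of mass of the mask in
    mm.  For ``hemisphere='R'`` the x-offsets are sign-flipped so p1 points
    lateral-to-medial on both sides.  A planar/degenerate mask yields a rank
    warning; the affected coefficient(s) are flagged NaN and listed in
    ``degenerate_axes``.
    """
    mask = np.asarray(roi_mask, dtype=bool)
    idx = np.argwhere(mask)
    if len(idx) < 8:
        raise ValueError(f"spatial-gradient fit needs >= 8 voxels, got {len(idx)}")
    coords = apply_affine(qmap.affine, idx)
    centre = coords.mean(axis=0)
    d = coords - centre
    if hemisphere not in ("L", "R"):
        raise ValueError("hemisphere must be 'L' or 'R'")
    if hemisphere == "R":
        d = d.copy()
        d[:, 0] *= -1.0
    y = qmap.data[mask]

    # detect flat directions before solving
    sv = np.linalg.svd(d, compute_uv=False)
    tol = sv[0] * 1e-8 if sv[0] > 0 else 1.0
    spread = d.std(axis=0)
    degenerate = tuple(int(a) for a in range(3) if spread[a] <= tol)
    if degenerate:
        logger.warning(
            "spatial-gradient fit: mask is flat along axis/axes %s; coefficients flagged NaN",
            degenerate,
        )
    keep = [a for a in range(3) if a not in degenerate]
    X = np.column_stack([d[:, keep], np.ones(len(d))])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    grads = np.full(3, np.nan)
    for j, a in enumerate(keep):
        grads[a] = beta[j]
    p0 = float(beta[-1])
    fitted = X @ beta
    rmse = float(np.sqrt(np.mean((y - fitted) ** 2)))
    return SpatialGradientFit(
        p0=p0,
        p1=float(grads[0]),
        p2=float(grads[1]),
        p3=float(grads[2]),
        centre=tuple(float(c) for c in centre),
        n_voxels_used=int(len(idx)),
        rmse=rmse,
        degenerate_axes=degenerate,
    )


def volume_pct(v_roi: float, v_mean: float) -> float:
    """Percent change of a normalized ROI volume versus the cohort mean."""
    return (v_roi - v_mean) / v_mean * 100.0


def volume_metrics(
    labels: LabelMap,
    roi: int,
    icv_mask: np.ndarray,
    population_values=None,
) -> VolumeMetrics:
    """ROI volume normalized by intracranial volume, optionally as percent change.

    ``population_values`` is the cohort's collection of normalized volumes
    (fractions) for this ROI; when given, the percent change versus their
    mean is filled in.
    """
    icv_mask = np.asarray(icv_mask, dtype=bool)
    if not icv_mask.any():
        raise ValueError("ICV mask is empty")
    n_roi = int(np.sum(labels.data == roi))
    if n_roi == 0:
        raise ValueError(f"ROI {roi} absent from label map")
    voxvol = labels.voxel_volume
    v_roi_raw = n_roi * voxvol
    icv = float(icv_mask.sum()) * voxvol
    v_roi = v_roi_raw / icv
    v_mean = v_pct = None
    if population_values is not None:
        pop = np.asarray(list(population_values), dtype=float)
        if pop.size == 0:
            raise ValueError("population_values is empty")
        v_mean = float(pop.mean())
        v_pct = volume_pct(v_roi, v_mean)
    return VolumeMetrics(v_roi_raw, icv, v_roi, v_mean, v_pct)


def combine_labels(labels: LabelMap, label_set, new_label: int) -> LabelMap:
    """Rewrite every label in ``label_set`` to ``new_label`` (e.g. whole thalamus)."""
    label_set = set(int(v) for v in label_set)
    if not label_set:
        raise ValueError("label_set is empty")
    present = set(int(v) for v in labels.labels)
    if not (label_set & present):
        raise ValueError(f"none of the labels {sorted(label_set)} are present in the map")
    if new_label in (present - label_set):
        raise ValueError(
            f"new label {new_label} collides with an existing label outside the combined set"
        )
    data = labels.data.copy()
    data[np.isin(data, list(label_set))] = int(new_label)
    return LabelMap(data, labels.affine)
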