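"""R1-chi hybrid image construction and ROI-median contrast matching.

The hybrid image  hybrid = mu0 + mu1*chi + mu2*R1_norm  combines the
normalized R1 map (0-255, 1% histogram clipping within the brain mask) with
the susceptibility map to sharpen subcortical contrast for nonlinear
registration to a subcortical atlas.  Contrast matching maps a subject's
per-ROI medians onto an atlas template's medians with a low-order
polynomial (order 2 for R1, order 1 for chi); the hybrid coefficients can
then be re-derived from the template's own hybrid medians.  Registration
itself is delegated to external tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: default Eq.-style hybrid weights (offset, per-ppm, per-normalized-R1-unit)
DEFAULT_HYBRID = (0.0, 400.0, 1.0)

_POLY_ORDER = {"R1": 2, "chi": 1}


@dataclass(frozen=True)
class HybridCoefficients:
    mu0: float = 0.0
    mu1: float = 400.0
    mu2: float = 1.0

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.mu0, self.mu1, self.mu2])):
            raise ValueError("hybrid coefficients must be finite")


@dataclass
class ContrastMatch:
    """A fitted subject-to-template polynomial over common ROI medians."""

    source_metric: str
    poly_order: int
    coefficients: np.ndarray  # highest order first (numpy.polyval convention)
    roi_labels_used: list
    residuals: np.ndarray

    def apply(self, values):
        return np.polyval(self.coefficients, np.asarray(values, dtype=float))


def normalize_r1(r1_map, brain_mask):
    """Rescale in-mask R1 linearly so percentiles 1/99 map to 0/255, clipping outside.

    Out-of-mask voxels are set to 0.  Percentiles use linear interpolation
    between order statistics.
    """
    r1 = np.asarray(r1_map, dtype=float)
    mask = np.asarray(brain_mask, dtype=bool)
    if r1.shape != mask.shape:
        raise ValueError("r1_map and brain_mask shapes differ")
    if not mask.any():
        raise ValueError("brain mask is empty")
    vals = r1[mask]
    p1, p99 = np.percentile(vals, [1.0, 99.0])
    if p1 == p99:
        raise ValueError("degenerate histogram: 1st and 99th percentiles coincide")
    out = np.zeros_like(r1)
    out[mask] = np.clip((r1[mask] - p1) / (p99 - p1), 0.0, 1.0) * 255.0
    return out


def compute_hybrid(chi_map, r1norm_map, coeffs: HybridCoefficients | None = None):
    """Voxelwise mu0 + mu1*chi + mu2*R1norm."""
    if coeffs is None:
        coeffs = HybridCoefficients()
    chi = np.asarray(chi_map, dtype=float)
    r1n = np.asarray(r1norm_map, dtype=float)
    if chi.shape != r1n.shape:
        raise ValueError(f"grid mismatch: chi {chi.shape} vs R1norm {r1n.shape}")
    return coeffs.mu0 + coeffs.mu1 * chi + coeffs.mu2 * r1n


def contrast_match(subject_roi_medians, template_roi_medians, metric: str) -> ContrastMatch:
    """Least-squares polynomial from subject ROI medians to template ROI medians.

    Order 2 for R1, order 1 for chi; fitted on the ROI labels common to both
    mappings.
    """
    if metric not in _POLY_ORDER:
        raise ValueError(f"metric must be one of {sorted(_POLY_ORDER)}, got {metric!r}")
    order = _POLY_ORDER[metric]
    common = sorted(set(subject_roi_medians) & set(template_roi_medians))
    if len(common) < order + 1:
        raise ValueError(
            f"need >= {order + 1} common ROI labels for an order-{order} fit, got {len(common)}"
        )
    x = np.array([subject_roi_medians[k] for k in common], dtype=float)
    y = np.array([template_roi_medians[k] for k in common], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("rank-deficient fit: subject medians are all identical")
    coeffs = np.polyfit(x, y, order)
    residuals = y - np.polyval(coeffs, x)
    return ContrastMatch(metric, order, coeffs, common, residuals)


def derive_hybrid_coefficients(
    template_hybrid_roi_medians, matched_r1_medians, matched_chi_medians
) -> HybridCoefficients:
    """OLS fit of the three hybrid weights to template hybrid ROI medians."""
    h = np.asarray(template_hybrid_roi_medians, dtype=float)
    r1 = np.asarray(matched_r1_medians, dtype=float)
    chi = np.asarray(matched_chi_medians, dtype=float)
    if not (h.shape == r1.shape == chi.shape) or h.ndim != 1:
        raise ValueError("median vectors must be 1D and aligned")
    if len(h) < 3:
        raise ValueError("need at least 3 ROIs to identify the three coefficients")
    X = np.column_stack([np.ones_like(h), chi, r1])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("collinear regressors: hybrid coefficients are unidentifiable")
    beta, *_ = np.linalg.lstsq(X, h, rcond=None)
    return HybridCoefficients(mu0=float(beta[0]), mu1=float(beta[1]), mu2=float(beta[2]))
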