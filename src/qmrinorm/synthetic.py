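"""Synthetic study generator.

Emulates the statistical structure the analysis assumes: a healthy-ageing
cohort (~260 subjects, near-uniform age 18-79, balanced sex) with per-ROI
age trajectories of the qMRI metrics (quadratic for R1, linear for R2* and
chi), additive sex and hemisphere offsets, optional age-dependent noise, and
latent cross-ROI covariance forming two deviation "networks" (caudate +
putamen; pallidum / nigra / red nucleus / subthalamic / ventral pallidum
group).  A patient group can carry planted elevations (e.g. SNc/SNr).

Also generates voxel-level ellipsoidal ROI phantoms with planted linear
spatial gradients, and forward MP2RAGE inversion images for the R1-fitting
stage.  All randomness flows through a single seeded Generator per call.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .io import LabelMap, QuantitativeMap, hemisphere_to_centered, sex_to_centered
from .r1_dictionary import MP2RAGEProtocol, mp2rage_forward

METRICS = ("R1", "R2star", "chi")
METRIC_UNITS = {"R1": "1/s", "R2star": "1/s", "chi": "ppm"}

#: the two planted deviation networks
NETWORK_A = ("Cau", "Pu")
NETWORK_B = ("GPe", "GPi", "SNc", "SNr", "RN", "STN", "VP")


@dataclass(frozen=True)
class TrajectorySpec:
    """Generative per-(ROI, metric) trajectory: counterpart of the GLM regressors.

    value = intercept + beta_age*age + beta_age2*age^2 + beta_sex*sex_c
            + beta_hemi*hemi_c + network_loading*latent + noise,
    with sex_c/hemi_c coded +-1/2, latent a per-subject standard normal
    shared within a network, and noise sd = noise_sd0 + noise_sd_slope*(age-18).
    """

    roi: str
    metric: str
    intercept: float
    beta_age: float = 0.0
    beta_age2: float = 0.0
    beta_sex: float = 0.0
    beta_hemi: float = 0.0
    noise_sd0: float = 0.0
    noise_sd_slope: float = 0.0
    network_id: str = "none"  # {"A", "B", "none"}
    network_loading: float = 1.0

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; expected one of {METRICS}")
        if self.noise_sd0 < 0:
            raise ValueError("noise_sd0 must be >= 0")
        for age in (18.0, 80.0):
            if self.noise_sd0 + self.noise_sd_slope * (age - 18.0) < 0:
                raise ValueError(
                    f"noise sd becomes negative at age {age} for ({self.roi}, {self.metric})"
                )
        if self.network_id not in ("A", "B", "none"):
            raise ValueError("network_id must be 'A', 'B' or 'none'")

    def mean_value(self, age, sex_c=0.0, hemi_c=0.0):
        """Deterministic trajectory value (no noise, no latent)."""
        age = np.asarray(age, dtype=float)
        return (
            self.intercept
            + self.beta_age * age
            + self.beta_age2 * age**2
            + self.beta_sex * sex_c
            + self.beta_hemi * hemi_c
        )

    def noise_sd(self, age):
        return self.noise_sd0 + self.noise_sd_slope * (np.asarray(age, dtype=float) - 18.0)


@dataclass(frozen=True)
class CohortDesign:
    """Cohort demographics and planted patient effects."""

    n_subjects: int = 260
    age_range: tuple[float, float] = (18.0, 79.0)
    sex_balance: float = 0.5  # fraction female
    seed: int = 0
    n_patients: int = 0
    #: planted elevation added to patient values, keyed by (roi, metric)
    patient_effect: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be increasing")
        if not 0.0 <= self.sex_balance <= 1.0:
            raise ValueError("sex_balance must be in [0, 1]")


def default_trajectory_specs(path=None) -> list[TrajectorySpec]:
    """Load the shipped default trajectory parameter set (10 basal-ganglia ROIs).

    Values qualitatively reproduce the field's known behaviour — quadratic R1
    peaking at 45-60 y, linearly increasing R2* and chi — and are
    illustrative, not fitted to any cohort.
    """
    if path is None:
        ref = importlib.resources.files("qmrinorm") / "data" / "default_trajectories.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return [TrajectorySpec(**entry) for entry in raw["trajectories"]]


def _spec_index(specs) -> dict:
    idx = {}
    for s in specs:
        key = (s.roi, s.metric)
        if key in idx:
            raise ValueError(f"duplicate trajectory spec for {key}")
        idx[key] = s
    return idx


def generate_cohort(
    design: CohortDesign,
    specs: list[TrajectorySpec],
    require: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Simulate a long-format cohort table (two hemisphere rows per subject/ROI/metric).

    ``require`` optionally names (roi, metric) pairs that must be covered by
    ``specs``; a missing pair raises naming it.
    """
    idx = _spec_index(specs)
    if require is not None:
        for pair in require:
            if tuple(pair) not in idx:
                raise ValueError(f"no trajectory spec for requested (roi, metric) = {tuple(pair)}")

    rng = np.random.default_rng(design.seed)
    n = design.n_subjects + design.n_patients
    ages = rng.uniform(design.age_range[0], design.age_range[1], size=n)
    n_female = int(round(design.sex_balance * n))
    sexes = np.array(["F"] * n_female + ["M"] * (n - n_female))
    rng.shuffle(sexes)
    groups = np.array(["control"] * design.n_subjects + ["patient"] * design.n_patients)
    subject_ids = np.array([f"sub-{i:04d}" for i in range(n)])
    latents = {net: rng.standard_normal(n) for net in ("A", "B")}
    sex_c = sex_to_centered(sexes)

    frames = []
    for spec in specs:
        base = spec.intercept + spec.beta_age * ages + spec.beta_age2 * ages**2
        base = base + spec.beta_sex * sex_c
        if spec.network_id != "none":
            base = base + spec.network_loading * latents[spec.network_id]
        delta = design.patient_effect.get((spec.roi, spec.metric), 0.0)
        base = base + np.where(groups == "patient", delta, 0.0)
        sd = spec.noise_sd(ages)
        for hemi in ("L", "R"):
            hemi_c = hemisphere_to_centered([hemi])[0]
            eps = rng.standard_normal(n) * sd if np.any(sd > 0) else np.zeros(n)
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": subject_ids,
                        "group": groups,
                        "age": ages,
                        "sex": sexes,
                        "hemisphere": hemi,
                        "roi": spec.roi,
                        "metric": spec.metric,
                        "statistic": "median",
                        "value": base + spec.beta_hemi * hemi_c + eps,
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True)
    return df


@dataclass(frozen=True)
class VoxelPhantomSpec:
    """Ellipsoidal-ROI phantom with planted linear spatial gradients (per ROI)."""

    grid_shape: tuple[int, int, int] = (40, 40, 40)
    voxel_size: float = 1.0  # mm, isotropic
    roi_centres: tuple = ((20.0, 20.0, 20.0),)  # mm
    roi_semiaxes: tuple = ((8.0, 6.0, 5.0),)  # mm
    gradient_truth: tuple = ((0.0, 0.0, 0.0),)  # (p1, p2, p3) units/mm
    mean_truth: tuple = (1.0,)  # p0, units
    noise_sd: float = 0.0
    labels: tuple | None = None

    def __post_init__(self) -> None:
        k = len(self.roi_centres)
        for name in ("roi_semiaxes", "gradient_truth", "mean_truth"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} must have one entry per ROI")
        min_ax = 3.0 * self.voxel_size
        for c, ax in zip(self.roi_centres, self.roi_semiaxes):
            if min(ax) < min_ax:
                raise ValueError(
                    f"semiaxes {ax} too small: need >= 3 voxels ({min_ax} mm) so "
                    "one-voxel erosion leaves a core"
                )
            for d in range(3):
                lo, hi = c[d] - ax[d], c[d] + ax[d]
                if lo < 0 or hi > self.grid_shape[d] * self.voxel_size:
                    raise ValueError(f"ellipsoid {c} +- {ax} does not fit inside the grid")


def generate_voxel_phantom(
    spec: VoxelPhantomSpec, seed: int = 0
) -> tuple[QuantitativeMap, LabelMap]:
    """Render ellipsoidal ROIs carrying first-order spatial fields plus noise.

    Inside ROI k the value is p0 + p1*(x-x0) + p2*(y-y0) + p3*(z-z0) + noise,
    with (x0, y0, z0) the ROI's voxel centre of mass in mm (RAS affine);
    background is 0.  Overlapping ellipsoids raise.
    """
    rng = np.random.default_rng(seed)
    shape = spec.grid_shape
    affine = np.diag([spec.voxel_size] * 3 + [1.0])
    grid = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).astype(float) * spec.voxel_size  # mm coordinates of voxel centres

    data = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int32)
    label_values = spec.labels or tuple(range(1, len(spec.roi_centres) + 1))
    for lab, centre, semiax, grad, p0 in zip(
        label_values, spec.roi_centres, spec.roi_semiaxes, spec.gradient_truth, spec.mean_truth
    ):
        rel = (grid - np.asarray(centre)) / np.asarray(semiax)
        mask = np.sum(rel**2, axis=-1) <= 1.0
        if np.any(labels[mask] != 0):
            raise ValueError(f"ellipsoid for label {lab} overlaps a previous ROI")
        com = grid[mask].mean(axis=0)
        offsets = grid[mask] - com
        values = p0 + offsets @ np.asarray(grad, dtype=float)
        if spec.noise_sd > 0:
            values = values + rng.normal(0.0, spec.noise_sd, size=len(values))
        data[mask] = values
        labels[mask] = lab
    return QuantitativeMap(data, affine), LabelMap(labels, affine)


def generate_mp2rage_signals(
    r1_truth,
    b1_truth=1.0,
    protocol: MP2RAGEProtocol | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    m0: float = 1.0,
):
    """Forward-simulate paired MP2RAGE inversion images with complex Gaussian noise.

    Returns complex (S_TI1, S_TI2) arrays shaped like ``r1_truth``.  M0 is 1
    by default — the matching stage is invariant to overall scale — but is
    exposed for the scale-invariance contract.
    """
    if protocol is None:
        protocol = MP2RAGEProtocol()
    r1 = np.asarray(r1_truth, dtype=float)
    b1 = np.asarray(b1_truth, dtype=float)
    if np.any(r1 <= 0):
        raise ValueError("r1_truth must be positive")
    if np.any(b1 <= 0):
        raise ValueError("b1_truth must be positive")
    s1, s2 = mp2rage_forward(r1, b1, protocol, m0=m0)
    s1 = s1.astype(complex)
    s2 = s2.astype(complex)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        for s in (s1, s2):
            s += rng.normal(0.0, noise_sd, s.shape) + 1j * rng.normal(0.0, noise_sd, s.shape)
    return s1, s2
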