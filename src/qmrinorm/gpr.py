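"""Gaussian-process normative trajectories and deviation z-scores.

A per-(ROI, metric, statistic) GP of the sex/hemisphere-corrected values as a
function of age.  Inputs are standardized; the kernel is the sum of a linear
term, a squared-exponential term and white noise, capturing both the linear
R2*/chi trends and the curved (inverted-U) R1 trend.  Hyperparameters
maximize the exact log marginal likelihood with seeded optimizer restarts.

The predictive standard deviation includes the noise variance, so the
deviation z = (value - mean)/sd describes a *new observation*: about 95% of
healthy values fall within |z| <= 1.96.  Reference-cohort z-scores are
cross-validated (10 folds, age-decile stratified, both hemispheres of a
subject share a fold); external cohorts are scored against the frozen
full-data model after correction with the reference cohort's GLM betas.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, DotProduct, WhiteKernel


def _make_kernel():
    # linear + squared-exponential + white noise, on standardized inputs
    return (
        ConstantKernel(1.0, (1e-3, 1e3)) * RBF(1.0, (1e-2, 1e2))
        + ConstantKernel(0.1, (1e-6, 1e3)) * DotProduct(sigma_0=1e-10, sigma_0_bounds="fixed")
        + WhiteKernel(0.1, (1e-10, 1e1))
    )


@dataclass
class NormativeModel:
    """A frozen GP normative trajectory plus everything needed to score new data."""

    gp: GaussianProcessRegressor
    age_mean: float
    age_sd: float
    value_mean: float
    value_sd: float
    train_ages: np.ndarray  # native units (years)
    train_values: np.ndarray  # native units
    roi: str | None = None
    metric: str | None = None
    statistic: str = "median"
    correction_betas: tuple[float, float] | None = None  # (beta_sex, beta_hemi)
    seed: int = 0

    @property
    def kernel_hyperparams(self) -> dict:
        k = self.gp.kernel_
        return {
            "signal_variance": float(k.k1.k1.k1.constant_value),
            "length_scale": float(k.k1.k1.k2.length_scale),
            "linear_variance": float(k.k1.k2.k1.constant_value),
            "noise_variance": float(k.k2.noise_level),
        }

    @classmethod
    def from_json(cls, path: str | Path) -> "NormativeModel":
        """Rebuild a frozen model: stored hyperparameters, no re-optimization."""
        payload = json.loads(Path(path).read_text())
        std = payload["standardization"]
        hp = payload["kernel_hyperparams"]
        kernel = (
            ConstantKernel(hp["signal_variance"], "fixed")
            * RBF(hp["length_scale"], "fixed")
            + ConstantKernel(hp["linear_variance"], "fixed")
            * DotProduct(sigma_0=1e-10, sigma_0_bounds="fixed")
            + WhiteKernel(hp["noise_variance"], "fixed")
        )
        ages = np.asarray(payload["train_ages"], dtype=float)
        values = np.asarray(payload["train_values"], dtype=float)
        gp = GaussianProcessRegressor(kernel=kernel, optimizer=None, normalize_y=False)
        gp.fit(
            ((ages - std["age_mean"]) / std["age_sd"])[:, None],
            (values - std["value_mean"]) / std["value_sd"],
        )
        betas = payload.get("correction_betas")
        return cls(
            gp=gp,
            age_mean=std["age_mean"],
            age_sd=std["age_sd"],
            value_mean=std["value_mean"],
            value_sd=std["value_sd"],
            train_ages=ages,
            train_values=values,
            roi=payload.get("roi"),
            metric=payload.get("metric"),
            statistic=payload.get("statistic", "median"),
            correction_betas=tuple(betas) if betas is not None else None,
            seed=payload.get("seed", 0),
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "roi": self.roi,
            "metric": self.metric,
            "statistic": self.statistic,
            "seed": self.seed,
            "standardization": {
                "age_mean": self.age_mean,
                "age_sd": self.age_sd,
                "value_mean": self.value_mean,
                "value_sd": self.value_sd,
            },
            "kernel_hyperparams": self.kernel_hyperparams,
            "correction_betas": self.correction_betas,
            "train_ages": self.train_ages.tolist(),
            "train_values": self.train_values.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class PredictionResult:
    mean: np.ndarray  # native units
    sd: np.ndarray  # native units; includes the noise term
    extrapolated: np.ndarray  # True where the age lies outside the training range


def fit_gpr(
    ages,
    values,
    seed: int = 0,
    n_restarts: int = 5,
    roi: str | None = None,
    metric: str | None = None,
    statistic: str = "median",
    correction_betas=None,
) -> NormativeModel:
    """Fit the normative GP of (corrected) values versus age.

    Standardizes both axes, then maximizes the exact log marginal likelihood
    with ``n_restarts`` seeded restarts.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if ages.shape != values.shape or ages.ndim != 1:
        raise ValueError("ages and values must be aligned 1D arrays")
    if len(ages) < 20:
        raise ValueError(f"need >= 20 observations to fit a normative model, got {len(ages)}")
    if not (np.isfinite(ages).all() and np.isfinite(values).all()):
        raise ValueError("ages and values must be finite")
    v_sd = float(values.std())
    if v_sd < 1e-12 * max(1.0, abs(float(values.mean()))):
        raise ValueError("values have (near-)zero variance; normative model is degenerate")
    a_mean, a_sd = float(ages.mean()), float(ages.std())
    if a_sd == 0:
        raise ValueError("all ages identical; cannot model an age trajectory")
    v_mean = float(values.mean())
    xs = ((ages - a_mean) / a_sd)[:, None]
    ys = (values - v_mean) / v_sd
    gp = GaussianProcessRegressor(
        kernel=_make_kernel(),
        n_restarts_optimizer=n_restarts,
        random_state=int(seed) % (2**31),
        normalize_y=False,
    )
    with warnings.catch_warnings():
        # a kernel component unused by the data (e.g. the RBF term on purely
        # linear trends) legitimately sits at its variance bound
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(xs, ys)
    return NormativeModel(
        gp=gp,
        age_mean=a_mean,
        age_sd=a_sd,
        value_mean=v_mean,
        value_sd=v_sd,
        train_ages=ages.copy(),
        train_values=values.copy(),
        roi=roi,
        metric=metric,
        statistic=statistic,
        correction_betas=tuple(correction_betas) if correction_betas is not None else None,
        seed=int(seed),
    )


def predict(model: NormativeModel, ages) -> PredictionResult:
    """Exact GP posterior mean and predictive sd (noise included) in native units."""
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    xs = ((ages - model.age_mean) / model.age_sd)[:, None]
    mean_s, sd_s = model.gp.predict(xs, return_std=True)
    lo, hi = model.train_ages.min(), model.train_ages.max()
    return PredictionResult(
        mean=mean_s * model.value_sd + model.value_mean,
        sd=sd_s * model.value_sd,
        extrapolated=(ages < lo) | (ages > hi),
    )


def deviation_z(model: NormativeModel, ages, values) -> np.ndarray:
    pred = predict(model, ages)
    return (np.asarray(values, dtype=float) - pred.mean) / pred.sd


def _stratified_subject_folds(subject_ages: pd.Series, k: int, rng: np.random.Generator):
    """Assign subjects to k folds, shuffled within age deciles (round-robin deal)."""
    subjects = subject_ages.index.to_numpy()
    ages = subject_ages.to_numpy()
    order = np.argsort(ages, kind="stable")
    deciles = np.array_split(order, 10)
    fold_of = {}
    slot = 0
    for dec in deciles:
        dec = rng.permutation(dec)
        for i in dec:
            fold_of[subjects[i]] = slot % k
            slot += 1
    return fold_of


def zscore_crossval(
    rows: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    n_restarts: int = 5,
) -> pd.DataFrame:
    """Cross-validated deviation z-scores for a reference cohort.

    ``rows`` holds one (roi, metric, statistic) slice of a *corrected* cohort
    table (columns subject_id, age, value; hemispheres as separate rows).
    Subjects are dealt into ``k`` folds stratified by age decile; both
    hemisphere rows of a subject share a fold; each row is scored by the
    model fitted on the other folds.
    """
    subj_ages = rows.groupby("subject_id")["age"].first()
    n_subj = len(subj_ages)
    if n_subj < 2 * k:
        raise ValueError(f"need >= {2 * k} subjects for {k}-fold CV, got {n_subj}")
    rng = np.random.default_rng(seed)
    fold_of = _stratified_subject_folds(subj_ages, k, rng)
    folds = rows["subject_id"].map(fold_of).to_numpy()
    counts = np.bincount([fold_of[s] for s in subj_ages.index], minlength=k)
    if counts.min() < 2:
        raise ValueError(f"fold with fewer than 2 subjects (sizes: {counts.tolist()})")

    out = rows.copy()
    out["z"] = np.nan
    out["predicted_mean"] = np.nan
    out["predicted_sd"] = np.nan
    ages = rows["age"].to_numpy(dtype=float)
    values = rows["value"].to_numpy(dtype=float)
    for f in range(k):
        test = folds == f
        model = fit_gpr(ages[~test], values[~test], seed=seed + f, n_restarts=n_restarts)
        pred = predict(model, ages[test])
        out.loc[test, "predicted_mean"] = pred.mean
        out.loc[test, "predicted_sd"] = pred.sd
        out.loc[test, "z"] = (values[test] - pred.mean) / pred.sd
    out["source"] = "crossval"
    out["fold"] = folds
    return out


def zscore_apply(
    model: NormativeModel,
    rows: pd.DataFrame,
    corrected: bool | None = None,
) -> pd.DataFrame:
    """Deviation z-scores of a new cohort against a frozen normative model.

    The input must already be corrected with the *reference* cohort's GLM
    betas; pass ``corrected=True`` or a frame whose ``attrs['corrected']``
    flag was set by ``glm.residualize_table`` — otherwise the call is refused.
    """
    if corrected is None:
        corrected = bool(rows.attrs.get("corrected", False))
    if not corrected:
        raise ValueError(
            "input not marked as corrected; residualize with the reference cohort's "
            "GLM betas first (glm.residualize_table)"
        )
    pred = predict(model, rows["age"].to_numpy(dtype=float))
    out = rows.copy()
    out["predicted_mean"] = pred.mean
    out["predicted_sd"] = pred.sd
    out["z"] = (rows["value"].to_numpy(dtype=float) - pred.mean) / pred.sd
    out["source"] = "applied"
    return out
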