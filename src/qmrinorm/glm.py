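"""Covariate general linear model per (ROI, metric, statistic).

The design has five columns — intercept, age, age^2, centered sex (+-1/2)
and centered hemisphere (+-1/2) — fitted by ordinary least squares (QR
factorization).  t-statistics are converted to z-statistics through the
sign-preserving quantile map z = Phi^-1(F_t(t; dof)), evaluated through
log-space tail probabilities so large |t| stay finite and monotone.
Sex/hemisphere residualization moves every observation to the cohort-average
covariate level; for an external cohort the reference cohort's betas are
applied unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import ndtri_exp

from .io import hemisphere_to_centered, sex_to_centered

logger = logging.getLogger("qmrinorm")

DESIGN_COLUMNS = ("intercept", "age", "age2", "sex_c", "hemi_c")


@dataclass
class DesignMatrix:
    X: np.ndarray  # n x 5
    columns: tuple[str, ...] = DESIGN_COLUMNS

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class GLMResult:
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    z: np.ndarray
    dof: int
    sigma2: float
    columns: tuple[str, ...] = DESIGN_COLUMNS
    n_dropped: int = 0

    def __getitem__(self, name: str) -> float:
        return float(self.beta[self.columns.index(name)])


def build_design(rows: pd.DataFrame) -> DesignMatrix:
    """Assemble the five-column design from cohort rows (age, sex, hemisphere).

    Age enters raw and squared raw; sex and hemisphere are centered +-1/2.
    A single-sex or single-hemisphere cohort is refused by name, since the
    corresponding column would be collinear with the intercept.
    """
    for col in ("age", "sex", "hemisphere"):
        if col not in rows.columns:
            raise ValueError(f"cohort rows missing required column {col!r}")
    age = rows["age"].to_numpy(dtype=float)
    sex_c = sex_to_centered(rows["sex"].to_numpy())
    hemi_c = hemisphere_to_centered(rows["hemisphere"].to_numpy())
    for name, col in (("sex_c", sex_c), ("hemi_c", hemi_c)):
        if len(np.unique(col)) < 2:
            raise ValueError(f"design is rank deficient: column {name!r} is constant")
    X = np.column_stack([np.ones_like(age), age, age**2, sex_c, hemi_c])
    return DesignMatrix(X)


def fit_glm(y, design: DesignMatrix) -> GLMResult:
    """OLS with classical standard errors; t = beta/se, dof = n - 5.

    Rows with non-finite y are dropped (count logged); all-dropped raises.
    """
    y = np.asarray(y, dtype=float)
    X = design.X
    if y.shape[0] != X.shape[0]:
        raise ValueError("y and design have different numbers of rows")
    keep = np.isfinite(y)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("fit_glm: dropped %d row(s) with non-finite values", n_dropped)
        y, X = y[keep], X[keep]
    if y.size == 0:
        raise ValueError("all rows dropped: no finite values to fit")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more than {p} rows, got {n}")
    Q, R = linalg.qr(X, mode="economic")
    if np.min(np.abs(np.diag(R))) < 1e-10 * np.max(np.abs(np.diag(R))):
        raise ValueError("design matrix is numerically rank deficient")
    beta = linalg.solve_triangular(R, Q.T @ y)
    resid = y - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid / dof)
    Rinv = linalg.solve_triangular(R, np.eye(p))
    xtx_inv = Rinv @ Rinv.T
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    t = beta / se
    z = t_to_z(t, dof)
    return GLMResult(beta, se, t, np.asarray(z), dof, sigma2, n_dropped=n_dropped)


def t_to_z(t, dof: int):
    """Sign-preserving quantile map z = Phi^-1(F_t(t; dof)).

    Computed from log tail probabilities (scipy's ``ndtri_exp``) so that the
    map stays finite and strictly increasing even for very large |t|.
    """
    if dof < 1:
        raise ValueError("dof must be >= 1")
    t = np.asarray(t, dtype=float)
    # upper tail for positive t, lower tail for negative: both via logsf of |t|
    log_tail = stats.t.logsf(np.abs(t), dof)
    z_mag = -ndtri_exp(log_tail)
    return np.sign(t) * z_mag


def residualize(y, sex_c, hemi_c, beta_sex: float, beta_hemi: float):
    """Remove the fitted sex and hemisphere offsets: y - b_sex*sex_c - b_hemi*hemi_c."""
    y = np.asarray(y, dtype=float)
    sex_c = np.asarray(sex_c, dtype=float)
    hemi_c = np.asarray(hemi_c, dtype=float)
    if sex_c.shape != y.shape or hemi_c.shape != y.shape:
        raise ValueError("covariates and y must be aligned")
    return y - beta_sex * sex_c - beta_hemi * hemi_c


def residualize_table(rows: pd.DataFrame, result: GLMResult) -> pd.DataFrame:
    """Residualize the ``value`` column of cohort rows using fitted GLM betas.

    For an external cohort, pass the reference cohort's ``GLMResult``.  The
    returned frame carries ``attrs['corrected'] = True`` so downstream
    z-scoring can verify the contract.
    """
    out = rows.copy()
    sex_c = sex_to_centered(rows["sex"].to_numpy())
    hemi_c = hemisphere_to_centered(rows["hemisphere"].to_numpy())
    out["value"] = residualize(
        rows["value"].to_numpy(dtype=float),
        sex_c,
        hemi_c,
        result["sex_c"],
        result["hemi_c"],
    )
    out.attrs["corrected"] = True
    return out
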