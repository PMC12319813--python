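"""Reproducible simulation experiments exercising the pipeline end to end.

Each function simulates data with the synthetic generator under the study's
statistical structure, runs the relevant analysis stages, and returns the
measured operating characteristics (type-I error, coverage, recovery error,
detection rates).  All randomness is seeded; problem sizes are chosen so
each experiment runs in minutes on one CPU (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .deviation import bh_fdr, compare_groups, corr_matrix, threshold_network, welch_ttest
from .glm import build_design, fit_glm, residualize_table
from .gpr import fit_gpr, predict, zscore_apply
from .pipeline import fit_glm_per_key, pool_hemisphere_rows
from .r1_dictionary import MP2RAGEProtocol, build_dictionary, dictionary_match
from .roi_metrics import erode_mask, fit_spatial_gradient
from .synthetic import (
    NETWORK_A,
    NETWORK_B,
    CohortDesign,
    TrajectorySpec,
    VoxelPhantomSpec,
    default_trajectory_specs,
    generate_cohort,
    generate_mp2rage_signals,
    generate_voxel_phantom,
)

#: quadratic R1-like reference trajectory used by the calibration experiments
R1_LIKE = TrajectorySpec(
    roi="Pu",
    metric="R1",
    intercept=0.7375,
    beta_age=0.0045,
    beta_age2=-4.5e-5,
    noise_sd0=0.005,
)


def _seed_seq(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def glm_null_calibration(n_cohorts: int = 1000, n_subjects: int = 260, seed: int = 0) -> dict:
    """Type-I error of the covariate GLM and recovery of the age coefficients.

    Simulates cohorts with a quadratic age trajectory, homoscedastic noise
    and a *null* sex effect; measures the fraction of |z_sex| > 1.96 and the
    fraction of runs where beta_age and beta_age2 land within 3 standard
    errors of truth.
    """
    spec = TrajectorySpec(
        roi="Pu", metric="R1", intercept=0.7375, beta_age=0.0045, beta_age2=-4.5e-5,
        beta_sex=0.0, beta_hemi=0.01, noise_sd0=0.03,
    )
    n_reject = n_recovered = 0
    for s in _seed_seq(seed, n_cohorts):
        design = CohortDesign(n_subjects=n_subjects, seed=s)
        df = generate_cohort(design, [spec])
        res = fit_glm(df["value"].to_numpy(), build_design(df))
        if abs(res.z[res.columns.index("sex_c")]) > 1.96:
            n_reject += 1
        i_a, i_a2 = res.columns.index("age"), res.columns.index("age2")
        ok_a = abs(res.beta[i_a] - spec.beta_age) <= 3 * res.se[i_a]
        ok_a2 = abs(res.beta[i_a2] - spec.beta_age2) <= 3 * res.se[i_a2]
        if ok_a and ok_a2:
            n_recovered += 1
    return {
        "null_rejection_rate": n_reject / n_cohorts,
        "age_recovery_rate": n_recovered / n_cohorts,
        "n_cohorts": n_cohorts,
    }


def gpr_heldout_coverage(
    n_train: int = 260, n_test: int = 2000, seed: int = 0, n_restarts: int = 5
) -> dict:
    """Calibration of the GP deviation z: fraction of held-out |z| <= 1.96.

    Trains on a quadratic trajectory with Gaussian noise and scores an
    independent draw from the same generative model.
    """
    rng = np.random.default_rng(seed)
    spec = R1_LIKE

    def draw(n):
        ages = rng.uniform(18, 79, n)
        vals = spec.mean_value(ages) + rng.normal(0, spec.noise_sd0, n)
        return ages, vals

    ages, vals = draw(n_train)
    model = fit_gpr(ages, vals, seed=seed, n_restarts=n_restarts)
    a_test, v_test = draw(n_test)
    pred = predict(model, a_test)
    z = (v_test - pred.mean) / pred.sd
    return {
        "coverage_1p96": float(np.mean(np.abs(z) <= 1.96)),
        "mean_z": float(np.mean(z)),
        "n_test": n_test,
    }


def gpr_peak_age_error(
    n_seeds: int = 50, n_train: int = 260, seed: int = 0, n_restarts: int = 2
) -> dict:
    """Error of the GP posterior-mean peak age versus the generative quadratic peak.

    Noise is 10% of the trajectory's dynamic range over 18-79 years.
    """
    spec = R1_LIKE
    peak_true = -spec.beta_age / (2 * spec.beta_age2)
    grid = np.linspace(18, 79, 400)
    dyn = float(np.ptp(spec.mean_value(grid)))
    errors = []
    for s in _seed_seq(seed, n_seeds):
        rng = np.random.default_rng(s)
        ages = rng.uniform(18, 79, n_train)
        vals = spec.mean_value(ages) + rng.normal(0, 0.1 * dyn, n_train)
        model = fit_gpr(ages, vals, seed=s, n_restarts=n_restarts)
        peak_est = grid[np.argmax(predict(model, grid).mean)]
        errors.append(peak_est - peak_true)
    return {
        "peak_age_true": float(peak_true),
        "mean_abs_error_years": float(np.mean(np.abs(errors))),
        "mean_error_years": float(np.mean(errors)),
        "n_seeds": n_seeds,
    }


def dictionary_matching_error(seed: int = 0, n_voxels: int = 500, r1_step: float = 0.05) -> dict:
    """R1 recovery error of B1-aware dictionary matching vs a fixed-B1 dictionary.

    Noiseless forward signals at random (R1, B1) with B1 in [0.7, 1.3]; the
    B1-aware dictionary should bound the error by one R1 grid step while the
    B1=1 slice does not.
    """
    rng = np.random.default_rng(seed)
    protocol = MP2RAGEProtocol()
    r1_true = rng.uniform(0.5, 2.5, n_voxels)
    b1_true = rng.uniform(0.7, 1.3, n_voxels)
    s1, s2 = generate_mp2rage_signals(r1_true, b1_true, protocol, noise_sd=0.0)
    d_aware = build_dictionary(protocol, (0.05, 4.0), r1_step, (0.7, 1.3))
    d_fixed = build_dictionary(protocol, (0.05, 4.0), r1_step, (1.0, 1.0))
    err_aware = np.abs(dictionary_match(s1, s2, b1_true, d_aware) - r1_true)
    err_fixed = np.abs(dictionary_match(s1, s2, np.ones(n_voxels), d_fixed) - r1_true)
    return {
        "max_error_b1_aware": float(err_aware.max()),
        "max_error_b1_fixed": float(err_fixed.max()),
        "r1_step": r1_step,
        "n_voxels": n_voxels,
    }


def gradient_recovery(n_phantoms: int = 100, seed: int = 0) -> dict:
    """Spatial-gradient recovery on noisy ellipsoid phantoms (noise 5% of p0).

    Returns the worst absolute coefficient error in units of its standard
    error across phantoms, and the bias of each coefficient.
    """
    truth = np.array([0.02, -0.01, 0.005])  # units/mm
    p0 = 1.0
    errors = []
    for s in _seed_seq(seed, n_phantoms):
        spec = VoxelPhantomSpec(
            gradient_truth=(tuple(truth),), mean_truth=(p0,), noise_sd=0.05 * p0
        )
        qmap, labels = generate_voxel_phantom(spec, seed=s)
        mask = erode_mask(labels.data == 1, 1)
        fit = fit_spatial_gradient(qmap, mask)
        errors.append(fit.gradient - truth)
    errors = np.asarray(errors)
    se = errors.std(axis=0, ddof=1)
    return {
        "fraction_within_3se": float(np.mean(np.abs(errors) / se <= 3.0)),
        "max_abs_error_over_se": float(np.max(np.abs(errors) / se)),
        "bias_over_se": [float(b) for b in np.abs(errors.mean(axis=0)) / se],
        "n_phantoms": n_phantoms,
    }


def fdr_calibration(n_reps: int = 1000, seed: int = 0, q: float = 0.05) -> dict:
    """Empirical FDR of BH under 20 true nulls + 5 strong alternatives per repetition."""
    n_null, n_alt, n = 20, 5, 30
    fdp = []
    for s in _seed_seq(seed, n_reps):
        rng = np.random.default_rng(s)
        null_a = rng.normal(0, 1, (n_null, n))
        null_b = rng.normal(0, 1, (n_null, n))
        alt_a = rng.normal(0, 1, (n_alt, n))
        alt_b = rng.normal(1.5, 1, (n_alt, n))
        p = [welch_ttest(a, b)[2] for a, b in zip(null_a, null_b)]
        p += [welch_ttest(a, b)[2] for a, b in zip(alt_a, alt_b)]
        _, reject = bh_fdr(np.array(p), q=q)
        n_false = int(reject[:n_null].sum())
        n_total = int(reject.sum())
        fdp.append(n_false / max(n_total, 1))
    return {"empirical_fdr": float(np.mean(fdp)), "q": q, "n_reps": n_reps}


def network_recovery(n_seeds: int = 50, n_subjects: int = 260, seed: int = 0, threshold: float = 0.4) -> dict:
    """Recovery of the planted two-network partition from deviation correlations.

    Cohorts carry unit network loadings against unit-scale noise; residual
    deviations (GLM residuals) are correlated across ROIs and thresholded.
    """
    rois = list(NETWORK_A) + list(NETWORK_B) + ["NAcc"]
    specs = [
        TrajectorySpec(
            roi=r, metric="R2star", intercept=20.0, beta_age=0.05, noise_sd0=1.0,
            network_id=("A" if r in NETWORK_A else "B" if r in NETWORK_B else "none"),
            network_loading=1.0,
        )
        for r in rois
    ]
    n_correct = 0
    for s in _seed_seq(seed, n_seeds):
        df = generate_cohort(CohortDesign(n_subjects=n_subjects, seed=s), specs)
        resid = {}
        for roi, grp in df.groupby("roi"):
            design = build_design(grp)
            res = fit_glm(grp["value"].to_numpy(), design)
            resid[roi] = grp["value"].to_numpy() - design.X @ res.beta
        corr = corr_matrix(pd.DataFrame(resid))
        _, components = threshold_network(corr, threshold)
        found = {frozenset(c) for c in components if len(c) > 1}
        if found == {frozenset(NETWORK_A), frozenset(NETWORK_B)}:
            n_correct += 1
    return {"partition_recovery_rate": n_correct / n_seeds, "n_seeds": n_seeds}


def detection_experiment(
    n_seeds: int = 20,
    n_reference: int = 260,
    n_app_controls: int = 44,
    n_app_patients: int = 316,
    metrics: tuple[str, ...] = ("R2star", "chi"),
    shift_noise_sd: float = 1.5,
    affected_rois: tuple[str, ...] = ("SNc", "SNr"),
    seed: int = 0,
    q: float = 0.05,
    n_restarts: int = 1,
) -> dict:
    """End-to-end disease detection on synthetic reference + applied cohorts.

    Per seed: a reference cohort is simulated, GLM-corrected,
    hemisphere-pooled and fitted with per-(ROI, metric) normative GPs.  An
    independent applied cohort (controls + patients with the affected ROIs
    shifted upward by ``shift_noise_sd`` noise standard deviations) is
    corrected with the *reference* betas, scored against the frozen models,
    and compared (Welch + BH within each metric).  Reports how often all
    affected (ROI, metric) pairs are flagged with no null ROI flagged, and
    the per-ROI median z of the applied healthy controls averaged over seeds.
    """
    specs = [s for s in default_trajectory_specs() if s.metric in metrics]
    spec_by_key = {(s.roi, s.metric): s for s in specs}
    mean_age = (18.0 + 79.0) / 2.0

    def residual_sd(spec):
        # full subject-level deviation scale: measurement noise + network latent
        lat = spec.network_loading if spec.network_id != "none" else 0.0
        return float(np.hypot(spec.noise_sd(mean_age), lat))

    patient_effect = {
        (roi, m): shift_noise_sd * residual_sd(spec_by_key[(roi, m)])
        for roi in affected_rois
        for m in metrics
    }
    affected = {(roi, m) for roi in affected_rois for m in metrics}

    n_success = 0
    n_all_affected = 0
    n_no_null = 0
    median_z_sums: dict = {}
    for s in _seed_seq(seed, n_seeds):
        ref = generate_cohort(CohortDesign(n_subjects=n_reference, seed=s), specs)
        glm_table, glm_results = fit_glm_per_key(ref)
        ref_corr = pool_hemisphere_rows(
            pd.concat(
                [residualize_table(g, glm_results[k]) for k, g in ref.groupby(["roi", "metric", "statistic"])],
                ignore_index=True,
            )
        )
        models = {}
        for key, grp in ref_corr.groupby(["roi", "metric", "statistic"]):
            models[key] = fit_gpr(
                grp["age"].to_numpy(), grp["value"].to_numpy(),
                seed=s, n_restarts=n_restarts, roi=key[0], metric=key[1], statistic=key[2],
            )

        app = generate_cohort(
            CohortDesign(
                n_subjects=n_app_controls, n_patients=n_app_patients,
                seed=s + 1, patient_effect=patient_effect,
            ),
            specs,
        )
        app_corr = pool_hemisphere_rows(
            pd.concat(
                [residualize_table(g, glm_results[k]) for k, g in app.groupby(["roi", "metric", "statistic"])],
                ignore_index=True,
            )
        )
        app_corr.attrs["corrected"] = True
        z_parts = []
        for key, grp in app_corr.groupby(["roi", "metric", "statistic"]):
            z_parts.append(zscore_apply(models[key], grp, corrected=True))
        app_z = pd.concat(z_parts, ignore_index=True)

        ctrl_z = app_z[app_z["group"] == "control"]
        pat_z = app_z[app_z["group"] == "patient"]
        comp = compare_groups(pat_z, ctrl_z, q=q, pool_hemispheres=False)
        flagged = {(r.roi, r.metric) for r in comp.itertuples() if r.significant}
        elevated = {
            (r.roi, r.metric) for r in comp.itertuples() if r.significant and r.mean_a > r.mean_b
        }
        all_affected = affected <= elevated
        no_null = not (flagged - affected)
        n_all_affected += all_affected
        n_no_null += no_null
        n_success += all_affected and no_null
        for (roi, metric, _stat), grp in ctrl_z.groupby(["roi", "metric", "statistic"]):
            key = (roi, metric)
            median_z_sums[key] = median_z_sums.get(key, 0.0) + float(grp["z"].median())

    median_z = {f"{r}_{m}": v / n_seeds for (r, m), v in sorted(median_z_sums.items())}
    return {
        "success_rate": n_success / n_seeds,
        "all_affected_flagged_rate": n_all_affected / n_seeds,
        "no_null_flag_rate": n_no_null / n_seeds,
        "applied_control_median_z": median_z,
        "max_abs_median_z": float(max(abs(v) for v in median_z.values())),
        "n_seeds": n_seeds,
    }
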