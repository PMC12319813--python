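"""End-to-end orchestration: metrics table -> GLM -> correction -> GPR ->
deviation z-scores -> correlation networks -> group comparison.

Stages run in dependency order and every artefact is written as TSV/JSON
under the configured output directory, together with a manifest recording
the seed, parameters and per-stage row counts.  Reruns with an identical
config reproduce identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .deviation import compare_groups, corr_matrix, pivot_deviations, threshold_network
from .glm import build_design, fit_glm, residualize_table
from .gpr import fit_gpr, zscore_apply, zscore_crossval
from .io import PipelineConfig, read_cohort, write_cohort
from .synthetic import CohortDesign, default_trajectory_specs, generate_cohort

logger = logging.getLogger("qmrinorm")

KEY = ["roi", "metric", "statistic"]


def pool_hemisphere_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Average the two hemisphere rows of each subject into one 'pooled' row."""
    group_cols = [c for c in df.columns if c not in ("hemisphere", "value")]
    out = df.groupby(group_cols, as_index=False, sort=False)["value"].mean()
    out["hemisphere"] = "pooled"
    out.attrs = dict(df.attrs)
    return out


def fit_glm_per_key(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Fit the covariate GLM for every (roi, metric, statistic); return table + results."""
    rows = []
    results = {}
    for key, grp in cohort.groupby(KEY, sort=True):
        design = build_design(grp)
        res = fit_glm(grp["value"].to_numpy(dtype=float), design)
        results[key] = res
        for j, col in enumerate(res.columns):
            rows.append(
                {
                    "roi": key[0], "metric": key[1], "statistic": key[2],
                    "regressor": col, "beta": res.beta[j], "se": res.se[j],
                    "t": res.t[j], "z": res.z[j], "dof": res.dof,
                }
            )
    return pd.DataFrame(rows), results


def correct_cohort(cohort: pd.DataFrame, glm_results: dict) -> pd.DataFrame:
    """Residualize sex/hemisphere per key using the supplied GLM results."""
    parts = []
    for key, grp in cohort.groupby(KEY, sort=True):
        if key not in glm_results:
            raise KeyError(f"no GLM result for {key}")
        parts.append(residualize_table(grp, glm_results[key]))
    out = pd.concat(parts, ignore_index=True)
    out.attrs["corrected"] = True
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages on a loaded or simulated cohort; returns the output dir."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = {}

    stage = "cohort"
    try:
        if config.cohort_path is not None:
            cohort = read_cohort(config.cohort_path)
        else:
            specs = [
                s for s in default_trajectory_specs() if s.metric in config.metrics
            ]
            design = CohortDesign(
                n_subjects=config.n_subjects,
                n_patients=config.n_patients,
                age_range=config.age_range,
                seed=config.seed,
            )
            cohort = generate_cohort(design, specs)
        write_cohort(cohort, out_dir / "cohort.tsv")
        counts["cohort_rows"] = len(cohort)

        controls = cohort[cohort["group"] == "control"].reset_index(drop=True)
        patients = cohort[cohort["group"] == "patient"].reset_index(drop=True)

        stage = "glm"
        glm_table, glm_results = fit_glm_per_key(controls)
        glm_table.to_csv(out_dir / "glm.tsv", sep="\t", index=False)
        counts["glm_fits"] = len(glm_results)

        stage = "correction"
        corrected = correct_cohort(controls, glm_results)
        if config.pool_hemispheres:
            corrected = pool_hemisphere_rows(corrected)
        write_cohort(corrected, out_dir / "corrected.tsv")
        counts["corrected_rows"] = len(corrected)

        stage = "gpr"
        z_parts = []
        models = {}
        for key, grp in corrected.groupby(KEY, sort=True):
            grp = grp.reset_index(drop=True)
            z_parts.append(
                zscore_crossval(
                    grp, k=config.cv_k, seed=config.seed, n_restarts=config.gpr_restarts
                )
            )
            res = glm_results[key]
            models[key] = fit_gpr(
                grp["age"].to_numpy(dtype=float),
                grp["value"].to_numpy(dtype=float),
                seed=config.seed,
                n_restarts=config.gpr_restarts,
                roi=key[0], metric=key[1], statistic=key[2],
                correction_betas=(res["sex_c"], res["hemi_c"]),
            )
        zscores = pd.concat(z_parts, ignore_index=True)
        write_cohort(zscores, out_dir / "zscores.tsv")
        counts["zscore_rows"] = len(zscores)
        models_dir = out_dir / "models"
        models_dir.mkdir(exist_ok=True)
        for (roi, metric, statistic), model in models.items():
            model.to_json(models_dir / f"{roi}_{metric}_{statistic}.json")

        stage = "correlation"
        dev = pivot_deviations(zscores)
        networks = {}
        for metric in sorted({k[1] for k in models}):
            sub = dev.loc[:, dev.columns.get_level_values("metric") == metric]
            sub = sub.droplevel(["metric", "statistic"], axis=1)
            corr = corr_matrix(sub)
            corr.to_csv(out_dir / f"corr_rois_{metric}.tsv", sep="\t")
            networks[metric] = {
                str(thr): {
                    "edges": [list(e) for e in threshold_network(corr, thr)[0]],
                    "components": threshold_network(corr, thr)[1],
                }
                for thr in config.network_thresholds
            }
        (out_dir / "networks.json").write_text(json.dumps(networks, indent=1))

        if len(patients) > 0:
            stage = "comparison"
            pat_corr = correct_cohort(patients, glm_results)
            if config.pool_hemispheres:
                pat_corr = pool_hemisphere_rows(pat_corr)
            pat_parts = []
            for key, grp in pat_corr.groupby(KEY, sort=True):
                pat_parts.append(zscore_apply(models[key], grp, corrected=True))
            pat_z = pd.concat(pat_parts, ignore_index=True)
            write_cohort(pat_z, out_dir / "zscores_patients.tsv")
            comparison = compare_groups(pat_z, zscores, q=config.fdr_q)
            comparison.to_csv(out_dir / "comparison.tsv", sep="\t", index=False)
            counts["comparisons"] = len(comparison)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "counts": counts,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("pipeline complete: %s", out_dir)
    return out_dir
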