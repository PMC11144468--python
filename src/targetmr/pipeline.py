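"""End-to-end orchestration of the drug-target genetic-score analysis.

transform -> jackknifed locus weights -> score -> endpoints -> stratified
associations -> IVW-FE pooling -> orientation to per-1-SD-lower-LDL-C ->
multiplicity control. Writes result TSVs and a machine-readable run log
(seeds, exclusion counts, strata dropped). All randomness flows from the
single config seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, io, meta, score as score_mod, transform
from .simulate import LOCUS_SNPS, Cohort, simulate_cohort, default_outcome_models

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "prepare_exposure", "default_endpoints"]


def prepare_exposure(cohort: Cohort, config: io.PipelineConfig) -> pd.Series:
    """Stratum-wise residualize + RINT of measured LDL-C."""
    pheno = cohort.participants.copy()
    pheno["age2"] = pheno["age"] ** 2
    pheno["fasting_time2"] = pheno["fasting_time"] ** 2
    spec = transform.TransformSpec(
        covariates=[c for c in [*config.covariates, "fasting_time2"] if c in pheno.columns],
        strata=config.stratum_col,
        rint_offset=config.rint_offset,
        min_stratum_size=config.min_stratum_size,
    )
    return transform.stratified_transform(pheno["ldl_mmol"], pheno, spec)


def default_endpoints(cohort: Cohort) -> list[assoc.EndpointDefinition]:
    """Endpoint definitions for the outcome models present in the cohort."""
    defs = []
    for om in cohort.config.outcome_models:
        kwargs = {}
        if om.code.startswith("I2") or om.code.startswith("I6"):
            kwargs["control_set"] = "common-vascular"
        if om.code.startswith("J0"):
            kwargs["min_event_year"] = 2009
        defs.append(
            assoc.EndpointDefinition(
                outcome_id=om.outcome_id, case_codes=(om.code,), **kwargs
            )
        )
    return defs


def run_pipeline(config: io.PipelineConfig, cohort: Cohort | None = None) -> dict:
    """Run the full pipeline; returns a results bundle (dict of DataFrames
    and paths) and writes TSVs plus run_log.json under ``config.output_dir``."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "stages": {}}

    if cohort is None:
        if config.phenotype_path:
            cohort = Cohort(
                participants=io.read_phenotypes(config.phenotype_path),
                dosages=io.read_dosages(config.dosage_path)[0],
                events=io.read_events(config.event_path),
                config=config.simulation_config(),
            )
        else:
            sim_cfg = config.simulation_config()
            if not sim_cfg.outcome_models:
                sim_cfg.outcome_models = default_outcome_models()
            cohort = simulate_cohort(sim_cfg)
    n_total = len(cohort.participants)
    log["stages"]["cohort"] = {"n_participants": n_total, "n_events": len(cohort.events)}

    # Exposure transform
    rint_ldl = prepare_exposure(cohort, config)
    n_measured = int(np.isfinite(rint_ldl.to_numpy()).sum())
    log["stages"]["transform"] = {
        "n_measured": n_measured,
        "n_unmeasured_or_dropped": n_total - n_measured,
    }

    # Jackknifed locus weights and score
    pheno = cohort.participants.copy()
    pheno["age2"] = pheno["age"] ** 2
    pheno["fasting_time2"] = pheno["fasting_time"] ** 2
    cov_cols = [c for c in [*config.covariates, "fasting_time2"] if c in pheno.columns]
    pc_cols = [c for c in pheno.columns if c.startswith("pc")]
    model = score_mod.LocusScoreModel(
        snp_cols=LOCUS_SNPS,
        covariate_cols=cov_cols + pc_cols,
        stratum_col=config.stratum_col,
        n_blocks=config.n_blocks,
        jackknife=True,
        random_state=config.seed,
    )
    X = pheno.join(cohort.dosages)
    model.fit(X, rint_ldl)
    gene_score = model.transform(X)
    diag = score_mod.instrument_strength(
        gene_score.loc[rint_ldl.index[np.isfinite(rint_ldl)]],
        rint_ldl[np.isfinite(rint_ldl)],
        pheno.loc[np.isfinite(rint_ldl), cov_cols + pc_cols],
    )
    log["stages"]["weights"] = {
        "snp_ids": model.weights_.snp_ids,
        "betas": [float(b) for b in model.betas_],
        "ses": [float(s) for s in model.ses_],
        "n_estimation": model.n_estimation_,
        "n_blocks": config.n_blocks,
        "r_squared": diag.r_squared,
        "f_statistic": diag.f_statistic,
    }
    io.write_weights(model.weights_, outdir / "weights.tsv", outdir / "weights_blocks.tsv")

    # Endpoint associations
    assoc_cov = pheno[[c for c in [*config.assoc_covariates] if c in pheno.columns] + pc_cols]
    strata = pheno[config.stratum_col].to_numpy()
    estimates = []
    endpoint_counts = {}
    for defn in default_endpoints(cohort):
        try:
            labels = assoc.build_endpoint(cohort, defn)
            endpoint_counts[defn.outcome_id] = {
                "cases": int((labels == 1).sum()),
                "controls": int((labels == 0).sum()),
                "excluded": int((labels == -1).sum()),
            }
            est = assoc.logistic_assoc(
                labels.to_numpy(), gene_score.to_numpy(), assoc_cov, strata,
                min_cases=config.min_stratum_cases, outcome_id=defn.outcome_id,
            )
            estimates.append(assoc.orient_per_sd_lower_ldl(est))
        except ValueError as exc:
            logger.warning("endpoint %s failed: %s", defn.outcome_id, exc)
            endpoint_counts[defn.outcome_id] = {"error": str(exc)}
    log["stages"]["endpoints"] = endpoint_counts

    if estimates:
        pvals = [e.p for e in estimates]
        flags = meta.bh_fdr(pvals, 0.05)
        bonf = meta.bonferroni_threshold(0.05, len(estimates), sig=None)
        results = pd.DataFrame(
            {
                "outcome_id": [e.outcome_id for e in estimates],
                "n_cases": [e.n_cases for e in estimates],
                "n_controls": [e.n_controls for e in estimates],
                "beta": [e.beta for e in estimates],
                "se": [e.se for e in estimates],
                "or": [e.odds_ratio for e in estimates],
                "p": pvals,
                "fdr_reject": flags,
                "bonferroni_reject": [p < bonf for p in pvals],
                "strata_pooled": [e.n_strata for e in estimates],
            }
        ).set_index("outcome_id")
    else:
        results = pd.DataFrame()
    io.write_results(results, outdir / "associations.tsv")

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return {
        "cohort": cohort,
        "score": gene_score,
        "weights": model.weights_,
        "results": results,
        "log": log,
        "output_dir": str(outdir),
    }
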