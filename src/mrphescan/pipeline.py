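"""End-to-end orchestration: simulate -> rules -> scan -> thresholds ->
follow-up -> two-sample MR, with reproducible seeding and a run manifest.

One global seed is expanded into per-stage seeds through a fixed counter
scheme (``stage_seed = global_seed * 1000 + stage_index``), so toggling a
stage on or off never changes the draws of the others.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .followup import two_stage_probit
from .instruments import build_allele_score, first_stage, snp_outcome_assocs, summary_stats
from .mr import run_suite
from .multiplicity import effective_tests, spearman_matrix, threshold_set
from .phenome import build_outcome_dataset, fields_from_tables
from .scan import qq_data, run_scan
from .synthetic import SimulationConfig, simulate_cohort, truth_report, write_cohort

STAGES = ("simulate", "rules", "scan", "thresholds", "followup", "mr")


@dataclass
class RunConfig:
    outdir: str = "mrphescan_run"
    seed: int = 0
    alpha: float = 0.05
    stages: tuple[str, ...] = STAGES
    simulation: SimulationConfig | None = None
    covariate_set: str = "10PC"  # or "40PC"
    n_followup: int = 3  # top binary hits taken to IV follow-up
    mr_bootstrap_reps: int = 200
    phi: float = 0.75
    extra: dict = field(default_factory=dict)


def stage_seed(global_seed: int, stage: str) -> int:
    return (global_seed * 1000 + STAGES.index(stage)) % (2**31 - 1)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _covariate_frame(cohort, covariate_set: str) -> pd.DataFrame:
    n_pc = 40 if covariate_set == "40PC" else 10
    cols = ["age", "sex"] + [
        c for c in cohort.covariates.columns if c.startswith("pc")
    ][:n_pc]
    return cohort.covariates[cols]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in config.stages},
        "alpha": config.alpha,
        "stages": list(config.stages),
        "outputs": {},
        "counts": {},
    }

    sim_cfg = config.simulation or SimulationConfig()
    sim_cfg.seed = stage_seed(config.seed, "simulate")
    cohort = simulate_cohort(sim_cfg)
    if "simulate" in config.stages:
        paths = write_cohort(cohort, outdir / "cohort")
        manifest["outputs"]["cohort"] = {k: str(v) for k, v in paths.items()}

    covs = _covariate_frame(cohort, config.covariate_set)
    score = build_allele_score(cohort.dosages, cohort.panel)
    fs = first_stage(score, cohort.exposure, covs)
    manifest["first_stage"] = {"beta": fs.beta, "se": fs.se, "f_statistic": fs.f_statistic,
                               "n": fs.n}

    results = thresholds = None
    outcomes = counts = None
    if {"rules", "scan", "thresholds", "followup", "mr"} & set(config.stages):
        fields = fields_from_tables(cohort.phenome, cohort.dictionary)
        outcomes, counts = build_outcome_dataset(fields)
        manifest["counts"]["rules"] = {
            k: v for k, v in counts.items() if k != "dropped_ids"
        }

    if {"scan", "thresholds", "followup", "mr"} & set(config.stages):
        results = run_scan(score, outcomes, covs)
        rpath = outdir / "scan_results.tsv"
        qpath = outdir / "qq_data.tsv"
        qq_data(results).to_csv(qpath, sep="\t", index=False)
        manifest["outputs"]["qq_data"] = str(qpath)
        manifest["counts"]["scan_tests"] = int(results["p_value"].notna().sum())

    if "thresholds" in config.stages and results is not None:
        tested = results.dropna(subset=["p_value"])
        eligible = [o for o in outcomes if o.data_type != "unordered_categorical"
                    and not o.exposure_phenotype]
        mat = pd.DataFrame({o.outcome_id: o.values for o in eligible})
        corr, excluded = spearman_matrix(mat)
        n_unordered = sum(
            1 for o in outcomes
            if o.data_type == "unordered_categorical" and not o.exposure_phenotype
        )
        t_eff = effective_tests(corr.to_numpy())
        thresholds = threshold_set(
            tested["p_value"].to_numpy(), config.alpha,
            t_effective=t_eff, n_unordered=n_unordered,
        )
        tpath = outdir / "thresholds.json"
        tpath.write_text(json.dumps(thresholds.to_dict(), indent=1))
        manifest["outputs"]["thresholds"] = str(tpath)

    if results is not None:
        rpath = outdir / "scan_results.tsv"
        write_results_table(results, thresholds, rpath)
        manifest["outputs"]["scan_results"] = str(rpath)

    def _binary_field_hits(res):
        # direct binary fields only (expanded field#code outcomes have no
        # raw phenome column to feed the follow-up models)
        ok = res["outcome_id"].isin(cohort.phenome.columns)
        return res[(res["data_type"] == "binary") & res["p_value"].notna() & ok]

    if "followup" in config.stages and results is not None:
        hits = _binary_field_hits(results).head(config.n_followup)
        rows = []
        for fid in hits["outcome_id"]:
            res = two_stage_probit(
                cohort.phenome[fid], cohort.exposure_sd_units, score, covs,
                se_method="plugin", outcome_id=fid,
                seed=stage_seed(config.seed, "followup"),
            )
            rows.append(res.__dict__)
        fpath = outdir / "followup.tsv"
        pd.DataFrame(rows).to_csv(fpath, sep="\t", index=False)
        manifest["outputs"]["followup"] = str(fpath)

    if "mr" in config.stages and results is not None:
        hits = _binary_field_hits(results)
        frames = []
        for fid in hits.head(1)["outcome_id"]:
            assoc = snp_outcome_assocs(
                cohort.dosages, cohort.phenome[fid], covs, outcome_type="binary"
            )
            stats_table = summary_stats(cohort.panel, assoc)
            suite = run_suite(
                stats_table, phi=config.phi, bootstrap_reps=config.mr_bootstrap_reps,
                seed=stage_seed(config.seed, "mr"),
            )
            suite.insert(0, "outcome_id", fid)
            frames.append(suite)
        if frames:
            mpath = outdir / "mr.tsv"
            pd.concat(frames, ignore_index=True).to_csv(mpath, sep="\t", index=False)
            manifest["outputs"]["mr"] = str(mpath)

    # truth + digests close the manifest
    tr = truth_report(cohort)
    trpath = outdir / "truth.tsv"
    tr.to_csv(trpath, sep="\t", index=False)
    manifest["outputs"]["truth"] = str(trpath)
    manifest["digests"] = {
        name: _digest(Path(p))
        for name, p in manifest["outputs"].items()
        if isinstance(p, str) and Path(p).is_file()
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return manifest


def write_results_table(results: pd.DataFrame, thresholds=None, path=None,
                        descriptions: dict | None = None) -> pd.DataFrame:
    """Ranked results TSV with per-threshold pass flags.

    Adds boolean columns flagging rows below the Bonferroni, FDR and
    correlation-based thresholds, and an optional description column that
    supports substring search over outcome labels.
    """
    if results.empty:
        raise ValueError("results table is empty")
    table = results.copy()
    if descriptions:
        table["description"] = table["outcome_id"].map(descriptions).fillna("")
    if thresholds is not None:
        table["pass_bonferroni"] = table["p_value"] < thresholds.bonferroni_p
        table["pass_fdr"] = table["p_value"] < thresholds.fdr_p
        if thresholds.correlation_p is not None:
            table["pass_correlation"] = table["p_value"] < thresholds.correlation_p
    else:
        table["pass_bonferroni"] = False
        table["pass_fdr"] = False
    if path is not None:
        table.to_csv(path, sep="\t", index=False)
    return table


def search_results(table: pd.DataFrame, term: str) -> pd.DataFrame:
    """Case-insensitive substring search over outcome descriptions/ids."""
    col = "description" if "description" in table.columns else "outcome_id"
    hit = table[col].astype(str).str.contains(term, case=False, na=False)
    return table[hit]
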