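"""End-to-end orchestration: simulate or load -> QC -> three PRS arms ->
stratification -> concordance -> evaluation, with a reproducible run directory.

A :class:`PipelineConfig` (constructed directly or from YAML) fixes every
stage's parameters and a mandatory global seed; re-running an identical
config reproduces identical numeric outputs. Every output table carries the
config hash as a '#' comment line, and a JSON summary plus a log file
document the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from ._utils import child_seeds
from .bayes import SpikeSlabPrior, cv_posterior_prs
from .bootstrap import CVBootConfig, cv_bootstrap_prs
from .containers import ThresholdSpec
from .evaluate import auc_model_grid, fit_or, or_table_mean_deciles
from .qc import QCConfig, compute_pcs, qc_filter
from .scoring import align_weights, score_fixed
from .simulate import CovariateModel, VariantSpec, simulate_study
from .stratify import (
    classify_certainty,
    concordance,
    decile_assignment,
    decile_certainty,
    rank_distribution,
)

logger = logging.getLogger("prscert")
if not logger.handlers:  # library default: informative console logging
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run. ``seed`` is mandatory."""

    seed: int
    # simulate (used when genotype/phenotype paths are absent)
    n_cases: int = 1717
    n_controls: int = 1289
    n_variants: int = 120
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 5
    ld_rho: float = 0.5
    p_causal: float = 0.05
    h2: float = 0.3
    pool_multiplier: float = 2.5
    # inputs (override simulation)
    genotypes_path: str | None = None
    phenotype_path: str | None = None
    weights_path: str | None = None
    n_fixed_snps: int = 16  # scored SNPs for the fixed / bootstrap arms
    # qc
    qc: QCConfig = field(default_factory=QCConfig)
    n_pcs: int = 10
    # bootstrap arm
    k_folds: int = 5
    n_boot: int = 1000
    # bayes arm
    bayes_n_iter: int = 700
    bayes_burn_in: int = 200
    bayes_thin: int = 1
    bayes_epsilon: float = 0.01
    # stratification / evaluation
    level: float = 0.95
    t_low: float = 10.0
    t_high: float = 90.0
    concordance_thresholds: tuple[float, ...] = (60, 70, 80, 90, 95)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for any stochastic stage")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must specify a seed")
        if "qc" in raw and isinstance(raw["qc"], dict):
            raw["qc"] = QCConfig(**raw["qc"])
        for key in ("maf_range", "concordance_thresholds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(_jsonable(asdict(self)), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def synthetic_weights(genotypes, effects, all_variant_ids, n_snps: int, seed: int):
    """External-style weight fixture over the largest-|effect| post-QC SNPs.

    Weights are the true effects perturbed by noise, mimicking
    literature-derived estimates rather than oracle truth.
    """
    from .scoring import WeightSet

    rng = np.random.default_rng(seed)
    post_ids = genotypes.variants["id"]
    if effects is not None:
        beta_by_id = pd.Series(effects.beta_true, index=all_variant_ids)
        sub = beta_by_id.loc[post_ids].to_numpy()
    else:
        sub = rng.normal(0, 0.1, len(post_ids))
    pick = np.sort(np.argsort(-np.abs(sub))[: min(n_snps, len(post_ids))])
    vt = genotypes.variants.iloc[pick]
    return WeightSet(
        table=pd.DataFrame(
            {
                "id": vt["id"].to_numpy(),
                "effect_allele": vt["effect_allele"].to_numpy(),
                "other_allele": vt["other_allele"].to_numpy(),
                "weight": sub[pick] + rng.normal(0, 0.02, len(pick)),
            }
        ),
        label="synthetic-literature",
    )


def _write_table(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=".", float_format="%.6g")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage and write tables, a JSON summary and a log.

    Returns the summary dictionary. Any stage failure propagates with a
    stage-labelled error message.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    log_path = out / "run.log"
    fh = logging.FileHandler(log_path, mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    summary: dict = {"config_hash": cfg_hash, "config": _jsonable(asdict(config)), "stages": {}}
    seeds = child_seeds(config.seed, 6)

    try:
        stage = "simulate/load"
        logger.info("stage %s (config hash %s)", stage, cfg_hash)
        if config.genotypes_path:
            genotypes = pio.read_genotypes(config.genotypes_path)
            phenotype, covariates, _ = pio.read_phenotype_tsv(config.phenotype_path)
            effects = None
        else:
            spec = VariantSpec(
                n_variants=config.n_variants,
                maf_range=config.maf_range,
                ld_block_size=config.ld_block_size,
                ld_rho=config.ld_rho,
            )
            cohort, effects = simulate_study(
                config.n_cases,
                config.n_controls,
                spec,
                config.p_causal,
                config.h2,
                CovariateModel(),
                pool_multiplier=config.pool_multiplier,
                seed=seeds[0],
            )
            genotypes, phenotype, covariates = (
                cohort.genotypes,
                cohort.phenotype,
                cohort.covariates,
            )
            pio.write_genotypes_tsv(genotypes, out / "genotypes.tsv")
            pio.write_phenotype_tsv(
                phenotype, covariates, genotypes.samples, out / "phenotype.tsv"
            )
            pio.write_effects_tsv(
                effects.beta_true,
                effects.causal_mask,
                genotypes.variants["id"],
                out / "true_effects.tsv",
            )
        summary["stages"][stage] = {
            "n": int(len(phenotype)),
            "n_cases": int(np.sum(phenotype)),
            "m": int(genotypes.m),
        }
        all_variant_ids = list(genotypes.variants["id"])

        stage = "qc"
        logger.info("stage %s", stage)
        genotypes, qc_report = qc_filter(genotypes, phenotype, config.qc)
        _write_table(qc_report, out / "qc_report.tsv", cfg_hash)
        pcs = compute_pcs(genotypes, k=min(config.n_pcs, genotypes.n - 1, genotypes.m))
        covariates_full = pd.concat(
            [covariates.reset_index(drop=True), pcs.reset_index(drop=True)], axis=1
        )
        summary["stages"][stage] = {
            "m_pass": int(qc_report["pass"].sum()),
            "m_fail": int((~qc_report["pass"]).sum()),
        }

        stage = "score-fixed"
        logger.info("stage %s", stage)
        if config.weights_path:
            weights = pio.read_weights(config.weights_path)
        else:
            weights = synthetic_weights(
                genotypes, effects, all_variant_ids, config.n_fixed_snps, seeds[1]
            )
            pio.write_weights(weights, out / "weights.tsv")
        aligned, align_report = align_weights(weights, genotypes)
        _write_table(align_report, out / "alignment_report.tsv", cfg_hash)
        prs_fixed_scores = score_fixed(genotypes, aligned)
        _write_table(
            pd.DataFrame({"sample_id": genotypes.samples, "prs_fixed": prs_fixed_scores}),
            out / "prs_fixed.tsv",
            cfg_hash,
        )
        summary["stages"][stage] = {"n_scored_variants": aligned.n_variants}

        stage = "score-cv"
        logger.info("stage %s", stage)
        boot_cfg = CVBootConfig(
            k_folds=config.k_folds,
            n_boot=config.n_boot,
            level=config.level,
            seed=seeds[2],
        )
        boot_draws, boot_diag = cv_bootstrap_prs(
            genotypes, phenotype, covariates_full, list(aligned.ids), boot_cfg
        )
        _write_table(
            boot_draws.summarize(config.level), out / "prs_cv.tsv", cfg_hash
        )
        summary["stages"][stage] = {
            "n_boot": config.n_boot,
            "ridge_refits": int(boot_diag.n_ridge_refits),
            "mean_individual_sd": float(boot_draws.summarize(config.level)["sd"].mean()),
        }

        stage = "score-bayes"
        logger.info("stage %s", stage)
        prior = SpikeSlabPrior(
            p_causal=config.p_causal, h2=config.h2, m=genotypes.m
        )
        bayes_draws = cv_posterior_prs(
            genotypes,
            phenotype,
            covariates_full,
            prior,
            k_folds=config.k_folds,
            n_iter=config.bayes_n_iter,
            burn_in=config.bayes_burn_in,
            thin=config.bayes_thin,
            epsilon=config.bayes_epsilon,
            seed=seeds[3],
        )
        _write_table(
            bayes_draws.summarize(config.level), out / "prs_bayes.tsv", cfg_hash
        )
        summary["stages"][stage] = {
            "n_draws": int(bayes_draws.n_draws),
            "mean_individual_sd": float(
                bayes_draws.summarize(config.level)["sd"].mean()
            ),
        }

        stage = "stratify"
        logger.info("stage %s", stage)
        spec_low = ThresholdSpec(t=config.t_low, side="lower", p=config.level)
        spec_high = ThresholdSpec(t=config.t_high, side="upper", p=config.level)
        tables = {}
        for name, draws in (("cv", boot_draws), ("bayes", bayes_draws)):
            cls = classify_certainty(draws, spec_low, spec_high)
            dec = decile_certainty(draws, p=config.level)
            _, per_decile = rank_distribution(draws)
            table2 = per_decile.merge(
                dec[["decile", "n_certain"]], on="decile"
            )
            _write_table(table2, out / f"rankings_{name}.tsv", cfg_hash)
            _write_table(cls.table, out / f"classification_{name}.tsv", cfg_hash)
            tables[name] = {"classification": cls, "deciles": dec}
        summary["stages"][stage] = {
            name: {k: int(v) for k, v in t["classification"].counts().items()}
            for name, t in tables.items()
        }

        stage = "concord"
        logger.info("stage %s", stage)
        thr = list(config.concordance_thresholds)
        conc = pd.concat(
            [
                concordance(prs_fixed_scores, boot_draws.means(), thr, ("PRS-fixed", "PRS-CV")),
                concordance(prs_fixed_scores, bayes_draws.means(), thr, ("PRS-fixed", "PRS-Bayes")),
                concordance(boot_draws.means(), bayes_draws.means(), thr, ("PRS-CV", "PRS-Bayes")),
            ],
            ignore_index=True,
        )
        _write_table(conc, out / "concordance.tsv", cfg_hash)
        summary["stages"][stage] = {
            row["estimators"] + f" t={row['threshold']}": row["pct_overlap"]
            for _, row in conc.iterrows()
            if row["threshold"] == 90
        }

        stage = "evaluate"
        logger.info("stage %s", stage)
        cls_cv = tables["cv"]["classification"]
        decile, _ = decile_assignment(boot_draws.means())
        decile = decile + 1
        adj = covariates[["age", "gender", "smoking_status"]]
        labels = cls_cv.table["label"].to_numpy()
        certain_mask = labels != "uncertain"
        n_high = int((labels == "certainly_high").sum())
        n_low = int((labels == "certainly_low").sum())
        # CI-based models need enough certain individuals to cross-validate
        ci_feasible = (
            n_high >= config.k_folds
            and n_low >= config.k_folds
            and len(np.unique(phenotype[certain_mask])) == 2
            and min(np.bincount(phenotype[certain_mask])) >= config.k_folds
        )
        if not ci_feasible:
            logger.warning(
                "certain subset too small for CI-based evaluation "
                "(%d certainly_high, %d certainly_low)", n_high, n_low
            )
        or_rows = []
        if ci_feasible:
            res_ci = fit_or(
                phenotype[certain_mask],
                (labels[certain_mask] == "certainly_high").astype(int),
                adj.loc[certain_mask],
                subgroup_label="certain extremes",
            )
            or_rows.append(
                {
                    "stratification": "ci_based",
                    "contrast": "certainly_high vs certainly_low",
                    "odds_ratio": res_ci.odds_ratio,
                    "ci_lower": res_ci.ci_lower,
                    "ci_upper": res_ci.ci_upper,
                    "p_value": res_ci.p_value,
                    "n": res_ci.n,
                }
            )
        mean_table = or_table_mean_deciles(phenotype, decile, adj)
        for _, row in mean_table.iterrows():
            or_rows.append(
                {
                    "stratification": "mean_based",
                    "contrast": f"decile {int(row['decile'])} vs 1",
                    "odds_ratio": row["odds_ratio"],
                    "ci_lower": row["ci_lower"],
                    "ci_upper": row["ci_upper"],
                    "p_value": row["p_value"],
                    "n": row["n"],
                }
            )
        or_table = pd.DataFrame(or_rows)
        _write_table(or_table, out / "odds_ratios.tsv", cfg_hash)

        extreme_mask = (decile == 1) | (decile == 10)
        auc_tables = []
        if ci_feasible:
            auc_ci = auc_model_grid(
                phenotype,
                (labels == "certainly_high").astype(int),
                covariates,
                subset=certain_mask,
                subset_label="ci_based",
                seed=seeds[4],
            )
            auc_ci["subset"] = "ci_based"
            auc_tables.append(auc_ci)
        auc_mean = auc_model_grid(
            phenotype,
            (decile == 10).astype(int),
            covariates,
            subset=extreme_mask,
            subset_label="mean_based",
            seed=seeds[5],
        )
        auc_mean["subset"] = "mean_based"
        auc_tables.append(auc_mean)
        auc_table = pd.concat(auc_tables, ignore_index=True)
        _write_table(auc_table, out / "auc.tsv", cfg_hash)
        summary["stages"][stage] = {
            "or_ci_based": or_rows[0]["odds_ratio"] if or_rows and or_rows[0]["stratification"] == "ci_based" else None,
            "or_mean_top_decile": float(mean_table.iloc[-1]["odds_ratio"]),
            "best_auc_ci_based": float(auc_tables[0]["auc"].max()) if ci_feasible else None,
        }
    except Exception as exc:  # label the failing stage before propagating
        logger.error("stage %s failed: %s", stage, exc)
        logger.removeHandler(fh)
        fh.close()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as jh:
        json.dump(_jsonable(summary), jh, indent=2)
    logger.info("pipeline complete: %s", out)
    logger.removeHandler(fh)
    fh.close()
    return summary
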