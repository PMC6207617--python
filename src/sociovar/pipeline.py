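"""End-to-end orchestration: score, standardize, fit, report.

``run_variance_partition`` fits the base variance-partition model (Model 1:
age/gender/wave fixed effects, three crossed random intercepts) and the
genotype model (Model 2: plus the cumulative risk score as a fixed effect and
its three variance-moderation terms), writing table-style CSVs, a JSON fit
record and a run log with dropped-row accounting.  ``run_snp_panel`` does
the same per single SNP and adds the per-indicator association grid.  All
stages consume and produce the canonical CSV schemas, never mutate inputs,
and are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genotypes as geno_mod
from . import lmm, scales
from .genotypes import SNP_IDS, SNPS

logger = logging.getLogger("sociovar")

BASE_FIXED = ("intercept", "age", "gender", "wave")


@dataclass
class RunConfig:
    """Paths and options driving one pipeline run."""

    phenotype_csv: str | None = None
    items_csv: str | None = None
    genotype_csv: str | None = None
    vcf: str | None = None
    reference_wave: int = scales.DEFAULT_REFERENCE_WAVE
    criterion: str = "reml"
    ci_method: str | None = None  # None, "profile" or "boot"
    out_dir: str = "results"
    seed: int = 0
    n_restarts: int = 3
    log_level: str = "INFO"
    min_indicator_individuals: int = 10

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _setup_logging(out_dir: Path, level: str):
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, level.upper()))
    return handler


def load_inputs(config: RunConfig):
    """Read (and if necessary score/standardize) phenotype and genotype tables."""
    if config.items_csv:
        items = pd.read_csv(config.items_csv, na_values=["", "NA"])
        obs = scales.score_items_frame(items)
        meta_cols = [c for c in ("age", "gender") if c in items.columns]
        if meta_cols:
            meta = items[["individual_id", "wave_year", *meta_cols]].drop_duplicates()
            obs = obs.merge(meta, on=["individual_id", "wave_year"], how="left")
        logger.info("scored %d item rows into %d observations", len(items), len(obs))
    elif config.phenotype_csv:
        obs = scales.read_phenotypes(config.phenotype_csv)
        logger.info("read %d person-observations from %s", len(obs), config.phenotype_csv)
    else:
        raise ValueError("config must name phenotype_csv or items_csv")

    if obs["wave_year"].nunique() < 2 or obs["indicator"].nunique() < 2:
        raise ValueError("need at least 2 indicators and 2 waves for a variance partition")

    if "score_std" not in obs.columns or obs["score_std"].isna().all():
        if config.reference_wave not in set(obs["wave_year"]):
            raise ValueError(f"reference wave {config.reference_wave} not observed")
        obs = scales.standardize_to_reference(obs, config.reference_wave)
        logger.info("standardized scores against reference wave %d", config.reference_wave)

    geno = None
    if config.genotype_csv:
        geno = geno_mod.read_genotypes(config.genotype_csv)
        logger.info("read genotypes for %d individuals", len(geno))
    elif config.vcf:
        geno = geno_mod.extract_from_vcf(config.vcf)
        logger.info("extracted genotypes for %d samples from VCF", len(geno))
    return obs, geno


def _model_table(result: lmm.FitResult) -> pd.DataFrame:
    """Table-4-style layout: fixed-effect rows then variance-component rows."""
    shares = result.components.shares()
    rows = []
    for _, r in result.betas.iterrows():
        rows.append(
            {"term": r["term"], "estimate": r["estimate"], "se": r["se"],
             "p_value": r["p_value"], "var": np.nan, "sd": np.nan, "var_pct": np.nan}
        )
    for name, v in result.components.variances.items():
        rows.append(
            {"term": name, "estimate": np.nan, "se": np.nan, "p_value": np.nan,
             "var": v, "sd": np.sqrt(v), "var_pct": shares[name]}
        )
    return pd.DataFrame(rows)


MODEL_TABLE_COLUMNS = ["term", "estimate", "se", "p_value", "var", "sd", "var_pct"]


def _validate_model_table(df: pd.DataFrame):
    if list(df.columns) != MODEL_TABLE_COLUMNS:
        raise AssertionError(f"model table schema mismatch: {list(df.columns)}")


def _attach_intervals(result: lmm.FitResult, config: RunConfig):
    if config.ci_method is None:
        return
    for comp in result.components.variances:
        try:
            result.components.intervals[comp] = lmm.profile_ci(
                result, comp, method=config.ci_method, seed=config.seed
            )
        except Exception as exc:  # pragma: no cover - diagnostic path
            logger.warning("CI for %s failed: %s", comp, exc)


def run_variance_partition(config: RunConfig) -> dict:
    """Fit Model 1 (base) and, when genotypes are available, Model 2 (risk score).

    Writes ``model1.csv``, ``model2.csv``, ``fit.json`` and ``run.log`` under
    ``config.out_dir`` and returns the fit results keyed by model name.
    """
    out_dir = Path(config.out_dir)
    handler = _setup_logging(out_dir, config.log_level)
    try:
        obs, geno = load_inputs(config)
        results: dict[str, lmm.FitResult] = {}

        spec1 = lmm.ModelSpec(fixed_terms=BASE_FIXED)
        design1 = lmm.build_design(obs, None, spec1)
        logger.info(
            "model1: %d observations, %d individuals (%d rows dropped)",
            design1.X.shape[0], design1.n_individuals, design1.n_dropped,
        )
        res1 = lmm.fit(design1, spec1, criterion=config.criterion,
                       n_restarts=config.n_restarts, seed=config.seed)
        _attach_intervals(res1, config)
        results["model1"] = res1
        t1 = _model_table(res1)
        _validate_model_table(t1)
        t1.to_csv(out_dir / "model1.csv", index=False)

        if geno is not None:
            gxe = lmm.fit_gxe_models(
                obs, geno, covariates=("risk_score",), base_fixed=BASE_FIXED,
                criterion=config.criterion, n_restarts=config.n_restarts, seed=config.seed,
            )
            res2 = gxe["risk_score"]
            logger.info(
                "model2: %d observations, %d individuals (of %d with phenotype; "
                "difference is genotype availability)",
                res2.n_obs, res2.n_individuals, design1.n_individuals,
            )
            _attach_intervals(res2, config)
            results["model2"] = res2
            t2 = _model_table(res2)
            _validate_model_table(t2)
            t2.to_csv(out_dir / "model2.csv", index=False)

        with open(out_dir / "fit.json", "w") as fh:
            json.dump({k: v.to_dict() for k, v in results.items()}, fh, indent=2)
        return results
    finally:
        logger.removeHandler(handler)
        handler.close()


def run_snp_panel(config: RunConfig) -> dict:
    """Per-SNP variance-moderation models plus the SNP-by-indicator grid.

    Writes one ``snp_<id>.csv`` model table per SNP and ``associations.csv``
    (one row per SNP x indicator with the risk group flagged).
    """
    out_dir = Path(config.out_dir)
    handler = _setup_logging(out_dir, config.log_level)
    try:
        obs, geno = load_inputs(config)
        if geno is None:
            raise ValueError("run_snp_panel requires a genotype table")

        snp_covs = tuple(f"{s}_risk" for s in SNP_IDS)
        fits = lmm.fit_gxe_models(
            obs, geno, covariates=snp_covs, base_fixed=BASE_FIXED,
            criterion=config.criterion, n_restarts=config.n_restarts, seed=config.seed,
        )
        for snp in SNP_IDS:
            res = fits.get(f"{snp}_risk")
            if res is None:
                continue
            table = _model_table(res)
            _validate_model_table(table)
            table.to_csv(out_dir / f"snp_{snp}.csv", index=False)

        assoc_rows = []
        indicators = sorted(obs["indicator"].unique())
        for snp in SNP_IDS:
            for indicator in indicators:
                a = lmm.test_indicator_association(
                    obs, geno, snp, indicator, n_restarts=config.n_restarts, seed=config.seed
                )
                risk_est, risk_se = a.deviations[a.risk_label]
                non_est, non_se = a.deviations[a.nonrisk_label]
                assoc_rows.append(
                    {
                        "snp": snp, "gene": SNPS[snp].gene, "indicator": indicator,
                        "risk_group": a.risk_label, "risk_estimate": risk_est,
                        "risk_se": risk_se, "nonrisk_group": a.nonrisk_label,
                        "nonrisk_estimate": non_est, "nonrisk_se": non_se,
                        "f_value": a.f_value, "p_value": a.p_value,
                        "ddf": a.ddf, "n_obs": a.n_obs,
                        "warnings": "; ".join(a.warnings),
                    }
                )
                for w in a.warnings:
                    logger.warning("%s x %s: %s", snp, indicator, w)
        assoc = pd.DataFrame(assoc_rows)
        assoc.to_csv(out_dir / "associations.csv", index=False)
        logger.info("association grid: %d SNPs x %d indicators", len(SNP_IDS), len(indicators))
        return {"models": fits, "associations": assoc}
    finally:
        logger.removeHandler(handler)
        handler.close()
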