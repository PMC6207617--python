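"""Synthetic accelerated-longitudinal cohorts with a known variance structure.

The generator emulates a six-birth-cohort study (default birth years 1962,
1965, ..., 1977) observed at four assessment waves (1997, 2001, 2007, 2012)
on five sociability indicators, one of which (NEO-FFI Extraversion) was
administered only at the last two waves.  Standardized scores are drawn from
the crossed random-intercept model

    y = b0 + b_age*age + b_gender*gender + b_wave*wave (+ b_geno*x)
        + gamma_individual + alpha_individual_x_indicator
        + delta_individual_x_wave (+ xi-terms scaled by x) + eps

so every generating parameter is known exactly and estimation can be tested
without any external data.  Genotypes at the four oxytocin-pathway SNPs are
drawn independently per SNP under Hardy-Weinberg proportions calibrated so
the marginal risk-group frequencies match the configured population values.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import DEFAULT_RISK_FREQS, SNPS, SNP_IDS, code_genotype_frame
from .scales import DEFAULT_SCALES

logger = logging.getLogger("sociovar")

DEFAULT_BIRTH_COHORTS = (1962, 1965, 1968, 1971, 1974, 1977)
DEFAULT_WAVES = (1997, 2001, 2007, 2012)

#: Age bands used for the design-occupancy table (3-year bands over the
#: adult span, with a wider 44-47 band so the grid closes at 50).
DEFAULT_AGE_BANDS = ((20, 22), (23, 25), (26, 28), (29, 31), (32, 34),
                     (35, 37), (38, 40), (41, 43), (44, 47), (48, 50))

#: Raw-scale means/SDs at the reference wave for optional raw-score emulation
#: (indicator -> (mean, sd) on the 1-5 metric).
DEFAULT_RAW_REFERENCE = {
    "NEO-FFI-E": (3.39, 0.55),
    "TCI-RD1-Sentimentality": (3.05, 0.54),
    "TCI-RD3-SocialAttachment": (3.57, 0.74),
    "TCI-RD4-Dependence": (3.37, 0.54),
    "EAS-Sociability": (3.27, 0.72),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for one synthetic cohort.

    Variance components and fixed effects default to the standardized-scale
    regime the estimation targets (trait 0.212, indicator 0.387, state 0.048,
    residual 0.298; gender effect -0.442).  ``gxe`` entries are
    ``(covariate, random_term, xi_var)`` triples adding carrier-scaled extra
    variance at one level.  ``missing_rate`` is completely-at-random
    observation dropout on top of the design-driven absences (an indicator
    not administered at a wave).
    """

    n_individuals: int = 800
    birth_cohorts: tuple[int, ...] = DEFAULT_BIRTH_COHORTS
    waves: tuple[int, ...] = DEFAULT_WAVES
    indicators: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {
            name: tuple(sorted(s.waves_administered)) for name, s in DEFAULT_SCALES.items()
        }
    )
    gamma_var: float = 0.212
    alpha_var: float = 0.387
    delta_var: float = 0.048
    eps_var: float = 0.298
    beta_intercept: float = 0.438
    beta_age: float = -0.007
    beta_gender: float = -0.442
    beta_wave: float = -0.001
    beta_genotype: float = 0.0
    gxe: tuple[tuple[str, str, float], ...] = ()
    genotype_freqs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RISK_FREQS))
    prop_women: float = 0.59
    missing_rate: float = 0.0
    genotype_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("gamma_var", "alpha_var", "delta_var", "eps_var"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for p in (self.prop_women, self.missing_rate, self.genotype_missing_rate,
                  *self.genotype_freqs.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if list(self.waves) != sorted(set(self.waves)):
            raise ValueError("waves must be strictly increasing")
        if not self.indicators or not self.waves:
            raise ValueError("indicator/wave grid is empty")
        for _, term, xv in self.gxe:
            if xv < 0:
                raise ValueError("xi variances must be nonnegative")


def _hwe_genotypes(snp_id: str, risk_freq: float, n: int, rng) -> np.ndarray:
    """Draw genotype strings under HWE with the risk group at ``risk_freq``.

    The risk group is either a single homozygote (frequency a^2 solves the
    allele frequency) or a dominant pair {homozygote, heterozygote}
    (frequency 1 - (1-a)^2).
    """
    d = SNPS[snp_id]
    risk = sorted(d.risk_genotypes)
    if len(risk) == 1:  # recessive-style single homozygote
        a = risk[0][0]
        p = float(np.sqrt(risk_freq))
    else:  # dominant pair AA/AB
        homo = [g for g in risk if g[0] == g[1]][0]
        a = homo[0]
        p = 1.0 - float(np.sqrt(1.0 - risk_freq))
    other = [al for al in sorted(d.alleles) if al != a][0]
    u = rng.random(n)
    out = np.where(
        u < p * p, a + a, np.where(u < p * p + 2 * p * (1 - p),
                                   "".join(sorted((a, other))), other + other)
    )
    return out


def simulate_genotypes(config: SimulationConfig, rng) -> pd.DataFrame:
    ids = np.arange(1, config.n_individuals + 1)
    cols = {"individual_id": ids}
    for snp in SNP_IDS:
        g = _hwe_genotypes(snp, config.genotype_freqs[snp], config.n_individuals, rng)
        if config.genotype_missing_rate > 0:
            g = pd.array(g, dtype="string")
            g[rng.random(config.n_individuals) < config.genotype_missing_rate] = pd.NA
        cols[snp] = g
    return code_genotype_frame(pd.DataFrame(cols))


def simulate_cohort(config: SimulationConfig):
    """Generate (observations, genotypes, truth) for one synthetic cohort.

    Observations are the canonical long phenotype frame with ``score_std``
    already on the standardized scale (no re-standardization is applied: the
    generating model is itself on that scale).  ``truth`` records every
    generating parameter and the realized latent draws' variances.
    Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    ids = np.arange(1, n + 1)

    genotypes = simulate_genotypes(config, rng)

    birth_year = rng.choice(config.birth_cohorts, size=n)
    gender = (rng.random(n) >= config.prop_women).astype(int)  # 1 = men
    gamma = rng.normal(0.0, np.sqrt(config.gamma_var), size=n)

    indicators = list(config.indicators)
    waves = list(config.waves)
    alpha = rng.normal(0.0, np.sqrt(config.alpha_var), size=(n, len(indicators)))
    delta = rng.normal(0.0, np.sqrt(config.delta_var), size=(n, len(waves)))

    # missing genotype covariates contribute nothing to the generated signal
    # (such individuals are later dropped from genetic fits anyway)
    risk_score_x = np.nan_to_num(genotypes["risk_score"].to_numpy(dtype=float))

    xi_draws = {}
    x_values = {}
    for cov, term, xi_var in config.gxe:
        x_values[cov] = np.nan_to_num(genotypes[cov].to_numpy(dtype=float))
        if term == "individual":
            xi_draws[(cov, term)] = rng.normal(0.0, np.sqrt(xi_var), size=n)
        elif term == "individual_indicator":
            xi_draws[(cov, term)] = rng.normal(0.0, np.sqrt(xi_var), size=(n, len(indicators)))
        elif term == "individual_wave":
            xi_draws[(cov, term)] = rng.normal(0.0, np.sqrt(xi_var), size=(n, len(waves)))
        else:
            raise ValueError(f"unknown gxe term {term!r}")

    rows = []
    for j, ind in enumerate(indicators):
        administered = set(config.indicators[ind])
        for t, wave in enumerate(waves):
            if wave not in administered:
                continue
            age = wave - birth_year
            mu = (
                config.beta_intercept
                + config.beta_age * age
                + config.beta_gender * gender
                + config.beta_wave * (wave - waves[0])
            )
            y = mu + gamma + alpha[:, j] + delta[:, t]
            if config.beta_genotype != 0.0:
                y = y + config.beta_genotype * risk_score_x
            for (cov, term), draws in xi_draws.items():
                x = x_values[cov]
                if term == "individual":
                    y = y + x * draws
                elif term == "individual_indicator":
                    y = y + x * draws[:, j]
                else:
                    y = y + x * draws[:, t]
            y = y + rng.normal(0.0, np.sqrt(config.eps_var), size=n)
            rows.append(
                pd.DataFrame(
                    {
                        "individual_id": ids,
                        "indicator": ind,
                        "wave_year": wave,
                        "age": age,
                        "gender": gender,
                        "score_raw": np.nan,
                        "score_std": y,
                    }
                )
            )
    obs = pd.concat(rows, ignore_index=True)
    if config.missing_rate > 0:
        obs = obs.loc[rng.random(len(obs)) >= config.missing_rate].reset_index(drop=True)
    obs = obs.sort_values(["individual_id", "indicator", "wave_year"], kind="stable").reset_index(
        drop=True
    )

    truth = {
        "config": _config_dict(config),
        "latent_sample_vars": {
            "gamma": float(np.var(gamma, ddof=1)),
            "alpha": float(np.var(alpha, ddof=1)),
            "delta": float(np.var(delta, ddof=1)),
        },
        "n_observations": int(len(obs)),
    }
    return obs, genotypes, truth


def _config_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["indicators"] = {k: list(v) for k, v in config.indicators.items()}
    d["gxe"] = [list(t) for t in config.gxe]
    return d


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=str)


def design_occupancy(
    observations: pd.DataFrame, age_bands=DEFAULT_AGE_BANDS
) -> pd.DataFrame:
    """Wave-by-age-band contingency table of person-observations with margins.

    Rows are assessment waves, columns age bands; the returned frame carries a
    ``Total`` row and column whose grand total equals the observation count.
    """
    labels = [f"{lo}-{hi}" for lo, hi in age_bands]
    waves = sorted(observations["wave_year"].unique()) if len(observations) else []
    table = pd.DataFrame(0, index=waves, columns=labels, dtype=int)
    if len(observations):
        ages = observations["age"].to_numpy()
        for (lo, hi), label in zip(age_bands, labels):
            mask = (ages >= lo) & (ages <= hi)
            counts = observations.loc[mask].groupby("wave_year").size()
            for w, c in counts.items():
                table.loc[w, label] += int(c)
        uncovered = ~np.logical_or.reduce(
            [(ages >= lo) & (ages <= hi) for lo, hi in age_bands]
        )
        if uncovered.any():
            logger.warning("%d observations fall outside the age bands", int(uncovered.sum()))
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    table.index.name = "wave"
    return table
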