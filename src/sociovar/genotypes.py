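"""Risk coding of the four oxytocin-pathway SNPs and the cumulative risk score.

Each SNP has a genotype group previously linked to social difficulties:
OXTR rs1042778 TT, OXTR rs2254298 GG, OXTR rs53576 AA/AG and CD38 rs3796863
CC.  Carrying the risk group is coded 0/1 per SNP and the cumulative genetic
risk score is the 0-4 sum of those indicators.  Genotypes are unordered
allele pairs ("GA" and "AG" are the same genotype); phase is ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("sociovar")


class GenotypeCodingError(ValueError):
    """Unknown SNP or an allele pair invalid for that SNP."""


@dataclass(frozen=True)
class SNPDefinition:
    id: str
    gene: str
    alleles: frozenset[str]
    risk_genotypes: frozenset[frozenset[str] | str]  # canonical sorted strings

    def canonical(self, genotype: str) -> str:
        g = genotype.strip().upper()
        if len(g) != 2 or any(a not in self.alleles for a in g):
            raise GenotypeCodingError(
                f"{self.id}: invalid genotype {genotype!r} (valid alleles: "
                f"{'/'.join(sorted(self.alleles))})"
            )
        return "".join(sorted(g))


SNPS: dict[str, SNPDefinition] = {
    "rs1042778": SNPDefinition("rs1042778", "OXTR", frozenset("GT"), frozenset({"TT"})),
    "rs2254298": SNPDefinition("rs2254298", "OXTR", frozenset("AG"), frozenset({"GG"})),
    "rs53576": SNPDefinition("rs53576", "OXTR", frozenset("AG"), frozenset({"AA", "AG"})),
    "rs3796863": SNPDefinition("rs3796863", "CD38", frozenset("AC"), frozenset({"CC"})),
}

SNP_IDS = tuple(SNPS)

#: Population frequency of each SNP's risk genotype group.
DEFAULT_RISK_FREQS: dict[str, float] = {
    "rs1042778": 0.154,
    "rs2254298": 0.843,
    "rs53576": 0.664,
    "rs3796863": 0.408,
}


def code_risk_allele(snp: str, genotype: str) -> int:
    """Return 1 when ``genotype`` belongs to the SNP's risk group, else 0.

    Allele order within the pair is irrelevant.  Raises
    :class:`GenotypeCodingError` for an unknown SNP or invalid alleles.
    """
    if snp not in SNPS:
        raise GenotypeCodingError(f"unknown SNP {snp!r}; expected one of {list(SNPS)}")
    d = SNPS[snp]
    return int(d.canonical(genotype) in d.risk_genotypes)


def risk_score(flags) -> int:
    """Sum four 0/1 risk flags into the cumulative 0-4 genetic risk score.

    Returns ``None`` (missing) if any flag is missing: individuals without a
    complete SNP panel are excluded from genetic models.
    """
    vals = list(flags.values()) if isinstance(flags, dict) else list(flags)
    if len(vals) != len(SNPS):
        raise ValueError(f"expected {len(SNPS)} flags, got {len(vals)}")
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
        return None
    if any(int(v) not in (0, 1) for v in vals):
        raise ValueError(f"risk flags must be 0/1, got {vals}")
    return int(sum(int(v) for v in vals))


@dataclass
class GenotypeRecord:
    """Per-individual genotypes, risk flags and cumulative risk score."""

    individual_id: object
    genotypes: dict[str, str | None]
    risk_flags: dict[str, int | None] = None
    risk_score: int | None = None

    def __post_init__(self) -> None:
        self.risk_flags = {
            snp: (None if g is None else code_risk_allele(snp, g))
            for snp, g in self.genotypes.items()
        }
        try:
            self.risk_score = risk_score([self.risk_flags.get(s) for s in SNP_IDS])
        except ValueError:
            self.risk_score = None


def code_genotype_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Add per-SNP ``<snp>_risk`` flags and ``risk_score`` to a genotype table.

    ``df`` columns: ``individual_id`` plus one two-letter genotype column per
    SNP (empty/NA for missing).
    """
    out = df.copy()
    for snp in SNP_IDS:
        if snp not in out.columns:
            raise ValueError(f"genotype table missing column {snp!r}")
        out[f"{snp}_risk"] = [
            np.nan if pd.isna(g) else code_risk_allele(snp, str(g)) for g in out[snp]
        ]
    flag_cols = [f"{s}_risk" for s in SNP_IDS]
    flags = out[flag_cols]
    score = flags.sum(axis=1)
    score[flags.isna().any(axis=1)] = np.nan
    out["risk_score"] = score
    n_missing = int(out["risk_score"].isna().sum())
    if n_missing:
        logger.info("risk score missing for %d of %d individuals", n_missing, len(out))
    return out


def read_genotypes(path) -> pd.DataFrame:
    """Read the canonical genotype CSV and derive risk flags and score."""
    df = pd.read_csv(path, na_values=["", "NA"], dtype={s: "string" for s in SNP_IDS})
    if "individual_id" not in df.columns:
        raise ValueError("genotype CSV missing 'individual_id' column")
    return code_genotype_frame(df)


def write_genotypes(df: pd.DataFrame, path) -> None:
    cols = ["individual_id", *SNP_IDS]
    df.to_csv(path, index=False, columns=[c for c in cols if c in df.columns])


def extract_from_vcf(vcf_path, id_map=None, loci=None) -> pd.DataFrame:
    """Decode the four SNPs from a VCF into the canonical genotype table.

    Loci are matched by the VCF ID field (or by ``loci`` = mapping of SNP id
    to ``(chrom, pos)``).  Sample GT fields are decoded against REF/ALT;
    missing calls ("./.") yield missing genotypes.  ``id_map`` optionally
    renames VCF sample names to study individual ids.  Requires ``cyvcf2``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    by_pos = {v: k for k, v in (loci or {}).items()}
    calls: dict[str, list] = {}
    for variant in vcf:
        snp = variant.ID if variant.ID in SNPS else by_pos.get((variant.CHROM, variant.POS))
        if snp is None:
            continue
        alleles = [variant.REF] + list(variant.ALT)
        col = []
        for gt in variant.genotypes:  # [a0, a1, phased]
            a = [i for i in gt[:2] if i is not None and i >= 0]
            if len(a) != 2:
                col.append(None)
            else:
                col.append("".join(sorted(alleles[i] for i in a)))
        calls[snp] = col
    for snp in SNP_IDS:
        if snp not in calls:
            logger.warning("locus %s not found in %s", snp, vcf_path)
            calls[snp] = [None] * len(samples)
    ids = [id_map.get(s, s) if id_map else s for s in samples]
    df = pd.DataFrame({"individual_id": ids, **{s: calls[s] for s in SNP_IDS}})
    return code_genotype_frame(df)
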