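"""Questionnaire scale scoring, reference-wave standardization and psychometrics.

Five sociability indicators are drawn from three self-report inventories
(NEO-FFI Extraversion; the three TCI Reward Dependence subscales; EAS
Sociability), each answered on a five-point Likert metric.  Items flagged as
reversed are mapped ``r -> max + min - r`` before averaging, a scale score is
the mean over answered items provided at least 75 % of the items were
answered, and every indicator is standardized against the sample mean and SD
of a designated reference assessment wave so that scores from different
instruments share a common metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("sociovar")

#: Minimum answered fraction for a scale score to be computed (inclusive).
MIN_ANSWERED_FRACTION = 0.75


class ScaleValidationError(ValueError):
    """An item response falls outside the scale's admissible range."""


class StandardizationError(ValueError):
    """An indicator cannot be standardized at the requested reference wave."""


@dataclass(frozen=True)
class ScaleDefinition:
    """Static description of one sociability indicator.

    Parameters
    ----------
    name
        Indicator label used throughout the pipeline.
    n_items
        Number of questionnaire items.
    reversed_items
        1-based indices of items keyed in the opposite direction.
    response_range
        Inclusive integer bounds of the Likert metric, e.g. ``(1, 5)``.
    waves_administered
        Calendar years at which the instrument was administered.
    """

    name: str
    n_items: int
    reversed_items: frozenset[int] = field(default_factory=frozenset)
    response_range: tuple[int, int] = (1, 5)
    waves_administered: frozenset[int] = frozenset({1997, 2001, 2007, 2012})

    def __post_init__(self) -> None:
        if self.n_items <= 0:
            raise ValueError(f"{self.name}: n_items must be positive")
        bad = set(self.reversed_items) - set(range(1, self.n_items + 1))
        if bad:
            raise ValueError(f"{self.name}: reversed item indices {sorted(bad)} out of 1..{self.n_items}")
        lo, hi = self.response_range
        if lo >= hi:
            raise ValueError(f"{self.name}: empty response range {self.response_range}")

    def reverse(self, value: float) -> float:
        lo, hi = self.response_range
        return hi + lo - value


#: The five indicators with their item counts and administration schedule.
#: The TCI Dependence subscale is keyed entirely in the reversed direction;
#: the NEO-FFI was administered only at the last two waves.
DEFAULT_SCALES: dict[str, ScaleDefinition] = {
    s.name: s
    for s in (
        ScaleDefinition("NEO-FFI-E", 12, waves_administered=frozenset({2007, 2012})),
        ScaleDefinition("TCI-RD1-Sentimentality", 10),
        ScaleDefinition("TCI-RD3-SocialAttachment", 8),
        ScaleDefinition("TCI-RD4-Dependence", 6, reversed_items=frozenset(range(1, 7))),
        ScaleDefinition("EAS-Sociability", 5),
    )
}

#: Default reference wave: first year at which all five indicators were administered.
DEFAULT_REFERENCE_WAVE = 2007


def score_scale(responses, scale: ScaleDefinition, *, row_label=None) -> float:
    """Score one respondent's item vector for one scale.

    ``responses`` is a sequence of length ``scale.n_items`` with ``None`` /
    ``NaN`` marking unanswered items.  Reversed items are re-keyed before
    averaging.  Returns the mean of the answered items when at least 75 % of
    the items were answered, otherwise ``NaN``.
    """
    vals = np.asarray(
        [np.nan if v is None else float(v) for v in responses], dtype=float
    )
    if vals.size != scale.n_items:
        raise ScaleValidationError(
            f"{scale.name}: expected {scale.n_items} responses, got {vals.size}"
            + (f" (row {row_label})" if row_label is not None else "")
        )
    answered = ~np.isnan(vals)
    lo, hi = scale.response_range
    bad = answered & ((vals < lo) | (vals > hi))
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ScaleValidationError(
            f"{scale.name}: response {vals[i]} for item {i + 1} outside [{lo}, {hi}]"
            + (f" (row {row_label})" if row_label is not None else "")
        )
    if answered.sum() / scale.n_items < MIN_ANSWERED_FRACTION:
        return float("nan")
    for idx in scale.reversed_items:
        if answered[idx - 1]:
            vals[idx - 1] = scale.reverse(vals[idx - 1])
    return float(np.nanmean(vals))


def score_items_frame(
    items: pd.DataFrame, scales: dict[str, ScaleDefinition] | None = None
) -> pd.DataFrame:
    """Score an item-level table into long per-indicator raw scores.

    ``items`` columns: ``individual_id, wave_year, scale, item_1..item_k``
    (unused trailing item columns may be empty for shorter scales).  Returns a
    long frame with ``individual_id, indicator, wave_year, score_raw``.
    """
    scales = scales or DEFAULT_SCALES
    item_cols = [c for c in items.columns if c.startswith("item_")]
    records = []
    for row_label, row in items.iterrows():
        scale = scales.get(str(row["scale"]))
        if scale is None:
            raise ScaleValidationError(f"unknown scale {row['scale']!r} (row {row_label})")
        wave = int(row["wave_year"])
        if wave not in scale.waves_administered:
            raise ScaleValidationError(
                f"{scale.name} was not administered in {wave} (row {row_label})"
            )
        responses = [row.get(f"item_{i}") for i in range(1, scale.n_items + 1)]
        responses = [None if pd.isna(v) else v for v in responses]
        # ensure no stray responses beyond the scale's item count
        for c in item_cols[scale.n_items:]:
            if not pd.isna(row.get(c)):
                raise ScaleValidationError(
                    f"{scale.name}: unexpected response in {c} (row {row_label})"
                )
        records.append(
            {
                "individual_id": row["individual_id"],
                "indicator": scale.name,
                "wave_year": wave,
                "score_raw": score_scale(responses, scale, row_label=row_label),
            }
        )
    return pd.DataFrame.from_records(records)


def standardize_to_reference(
    observations: pd.DataFrame, reference_wave: int = DEFAULT_REFERENCE_WAVE
) -> pd.DataFrame:
    """Fill ``score_std`` so every indicator has mean 0 and SD 1 at the reference wave.

    The reference-wave sample mean and SD (``ddof=1``) of each indicator are
    applied as an affine map to that indicator's scores at *all* waves, so
    non-reference waves keep their relative location and spread.
    """
    obs = observations.copy()
    out = np.full(len(obs), np.nan)
    for indicator, grp in obs.groupby("indicator", sort=False):
        ref = grp.loc[grp["wave_year"] == reference_wave, "score_raw"].dropna()
        if len(ref) < 2:
            raise StandardizationError(
                f"indicator {indicator!r} has {len(ref)} non-missing scores at "
                f"reference wave {reference_wave}; cannot standardize"
            )
        m, s = ref.mean(), ref.std(ddof=1)
        if s == 0:
            raise StandardizationError(
                f"indicator {indicator!r} has zero variance at reference wave {reference_wave}"
            )
        out[obs.index.get_indexer(grp.index)] = (grp["score_raw"] - m) / s
    obs["score_std"] = out
    return obs


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha for a complete items-by-respondents matrix.

    ``item_matrix`` is (n_rows, k_items) with no missing values.
    alpha = k/(k-1) * (1 - sum of item variances / variance of row sums).
    """
    m = np.asarray(item_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 items")
    if m.shape[0] < 3:
        raise ValueError("need at least 3 complete rows")
    if np.isnan(m).any():
        raise ValueError("item matrix must be complete (no missing values)")
    k = m.shape[1]
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ZeroDivisionError("total-score variance is zero; alpha undefined")
    return k / (k - 1) * (1.0 - m.var(axis=0, ddof=1).sum() / total_var)


def distribution_diagnostics(scores) -> tuple[float, float]:
    """Sample skewness and excess kurtosis (kurtosis minus 3) of a vector."""
    from scipy import stats

    x = np.asarray(scores, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 4:
        raise ValueError("need at least 4 values")
    if np.var(x) == 0:
        raise ZeroDivisionError("zero variance; skewness/kurtosis undefined")
    return float(stats.skew(x, bias=True)), float(stats.kurtosis(x, fisher=True, bias=True))


# ---------------------------------------------------------------------------
# canonical CSV interchange

PHENOTYPE_COLUMNS = [
    "individual_id",
    "indicator",
    "wave_year",
    "age",
    "gender",
    "score_raw",
    "score_std",
]


def read_phenotypes(path) -> pd.DataFrame:
    """Read the canonical long-format phenotype CSV."""
    df = pd.read_csv(path, na_values=["", "NA"])
    missing = set(PHENOTYPE_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype CSV missing columns: {sorted(missing)}")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    cols = [c for c in PHENOTYPE_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols)
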