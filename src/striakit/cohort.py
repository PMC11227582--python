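"""Food-addiction criterion classification and human-cohort frequency
arithmetic.

Three operant scores per animal — persistence (non-reinforced active
responses during the pellet-free period), motivation (progressive-ratio
breaking point) and compulsivity (shocks endured) — are each dichotomized
against the 75th percentile of the wild-type control distribution; an animal
strictly above threshold on at least two of the three criteria is classified
"addicted". Thresholds must come from the wild-type group of the same
experiment and training epoch as the animals being classified.

The cohort side provides carrier and minor-allele frequency arithmetic plus
an exact conditional test for 2×2 count tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from striakit.exceptions import DataError

__all__ = [
    "CRITERIA",
    "CohortCounts",
    "AddictionClassification",
    "criterion_thresholds",
    "classify_addiction",
    "correlate_criteria",
    "carrier_frequency",
    "allele_frequency",
    "fisher_exact_2x2",
]

CRITERIA = ("persistence", "motivation", "compulsivity")


@dataclass(frozen=True)
class CohortCounts:
    """Carrier and allele counts for one variant in one cohort."""

    n_carriers: int
    n_total: int
    n_risk_alleles: int = 0
    n_ref_alleles: int = 0

    def __post_init__(self) -> None:
        if self.n_carriers > self.n_total:
            raise DataError("more carriers than persons")
        if min(self.n_carriers, self.n_total,
               self.n_risk_alleles, self.n_ref_alleles) < 0:
            raise DataError("counts must be non-negative")


@dataclass(frozen=True)
class AddictionClassification:
    """Per-animal criterion calls plus the thresholds used.

    ``table`` has one row per classified animal with boolean columns per
    criterion, ``criteria_met`` in {0..3} and ``label`` in
    {"addicted", "non-addicted"}; ``excluded`` lists animals dropped for
    missing scores.
    """

    table: pd.DataFrame
    thresholds: dict[str, float]
    excluded: tuple = ()


def _check_scores(scores: pd.DataFrame) -> None:
    missing = set(CRITERIA) - set(scores.columns)
    if missing:
        raise DataError(f"score table lacks columns {sorted(missing)}")


def criterion_thresholds(
    wt_scores: pd.DataFrame, mode: str = "empirical"
) -> dict[str, float]:
    """75th-percentile threshold per criterion from the control group.

    ``mode="empirical"`` (default) uses the linear-interpolation empirical
    percentile; ``mode="gaussian"`` uses the normal quantile
    ``mean + 0.6745 * sd`` instead.
    """
    _check_scores(wt_scores)
    if len(wt_scores) < 4:
        raise DataError("need at least 4 control animals for a 75th percentile")
    out = {}
    for c in CRITERIA:
        v = wt_scores[c].to_numpy(dtype=float)
        if np.any(np.isnan(v)):
            raise DataError(f"control scores for {c!r} contain missing values")
        if mode == "empirical":
            out[c] = float(np.percentile(v, 75, method="linear"))
        elif mode == "gaussian":
            out[c] = float(np.mean(v) + stats.norm.ppf(0.75) * np.std(v, ddof=1))
        else:
            raise DataError(f"unknown percentile mode {mode!r}")
    return out


def classify_addiction(
    scores: pd.DataFrame, thresholds: dict[str, float]
) -> AddictionClassification:
    """Apply the 2-of-3 rule: criterion positive iff score strictly exceeds
    its threshold; animals with any missing score are excluded and flagged."""
    _check_scores(scores)
    missing_thr = set(CRITERIA) - set(thresholds)
    if missing_thr:
        raise DataError(f"thresholds missing for {sorted(missing_thr)}")
    work = scores.copy()
    if "animal" not in work.columns:
        work["animal"] = [f"animal-{i}" for i in range(len(work))]
    has_nan = work[list(CRITERIA)].isna().any(axis=1)
    excluded = tuple(work.loc[has_nan, "animal"])
    work = work.loc[~has_nan].copy()
    for c in CRITERIA:
        work[f"{c}_positive"] = work[c].astype(float) > thresholds[c]
    work["criteria_met"] = sum(
        work[f"{c}_positive"].astype(int) for c in CRITERIA)
    work["label"] = np.where(work["criteria_met"] >= 2,
                             "addicted", "non-addicted")
    return AddictionClassification(table=work.reset_index(drop=True),
                                   thresholds=dict(thresholds),
                                   excluded=excluded)


def correlate_criteria(
    classification: AddictionClassification,
) -> pd.DataFrame:
    """Pearson correlation of criteria-met count vs each raw score, per
    genotype. Returns rows (genotype, criterion, r, p, n); zero-variance
    pairs are flagged with NaN r and ``degenerate=True``."""
    table = classification.table
    if "genotype" in table.columns:
        groups = list(table.groupby("genotype", sort=True))
    else:
        groups = [("all", table)]
    rows = []
    for genotype, grp in groups:
        k = grp["criteria_met"].to_numpy(dtype=float)
        for c in CRITERIA:
            v = grp[c].to_numpy(dtype=float)
            degenerate = len(grp) < 3 or np.ptp(k) == 0 or np.ptp(v) == 0
            if degenerate:
                r, p = float("nan"), float("nan")
            else:
                r, p = stats.pearsonr(k, v)
            rows.append({"genotype": genotype, "criterion": c,
                         "r": float(r), "p": float(p), "n": len(grp),
                         "degenerate": degenerate})
    return pd.DataFrame(rows)


def carrier_frequency(c: CohortCounts) -> float:
    """Carrier prevalence as a percent, rendered to 1 decimal."""
    if c.n_total <= 0:
        raise DataError("n_total must be positive")
    return round(100.0 * c.n_carriers / c.n_total, 1)


def allele_frequency(c: CohortCounts) -> float:
    """Minor-allele frequency as a fraction of all alleles."""
    total = c.n_risk_alleles + c.n_ref_alleles
    if total <= 0:
        raise DataError("allele total must be positive")
    return c.n_risk_alleles / total


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Fisher's exact test on [[a, b], [c, d]].

    Returns the sample odds ratio ``(a*d)/(b*c)`` and the conditional
    two-sided p (sum of hypergeometric tables with probability not exceeding
    the observed one).
    """
    table = np.array([[a, b], [c, d]])
    if np.any(table < 0):
        raise DataError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DataError("Fisher test undefined for a zero margin")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)
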