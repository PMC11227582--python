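"""Summary statistics and percent-change arithmetic for vesicular-uptake
assays.

Vesicular synergy — the glutamate-dependent enhancement of vesicular ACh
accumulation — is quantified as the percent increase of uptake in the
presence of 1 mM glutamate over basal uptake. The contribution of a single
transporter to a total uptake is the difference between the total and the
residual uptake measured after knocking the transporter out, expressed both
absolutely (pmol·mg⁻¹·10 min⁻¹) and as a percent of total.

Rounding conventions are explicit parameters throughout because published
percent summaries mix conventions (nearest-integer vs truncation); the
default is no rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from striakit.exceptions import DataError

__all__ = [
    "UptakeCellSummary",
    "SynergyResult",
    "summarize_uptake",
    "percent_change",
    "transporter_contribution",
    "synergy",
    "compare_groups",
    "GroupComparison",
]

_ROUNDERS = {
    "nearest": lambda x: float(np.round(x)),
    "floor": lambda x: float(math.floor(x)),
    "none": lambda x: float(x),
}


def _apply_rounding(x: float, rounding: str) -> float:
    try:
        return _ROUNDERS[rounding](x)
    except KeyError:
        raise DataError(f"unknown rounding mode {rounding!r}") from None


@dataclass(frozen=True)
class UptakeCellSummary:
    """Mean, SEM and replicate count for one genotype × condition cell."""

    genotype: str
    condition: str
    mean: float
    sem: float  # NaN when n < 2
    n: int

    @property
    def sem_defined(self) -> bool:
        return self.n >= 2


@dataclass(frozen=True)
class SynergyResult:
    """Basal vs stimulated uptake with the percent increase."""

    basal_mean: float
    stimulated_mean: float
    percent_increase: float


def summarize_uptake(table: pd.DataFrame) -> list[UptakeCellSummary]:
    """Per-cell mean, SEM (sample sd / sqrt(n)) and n.

    ``table`` holds tidy rows (genotype, condition, value). Cells with a
    single replicate are kept but flagged with an undefined (NaN) SEM.
    """
    required = {"genotype", "condition", "value"}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"uptake table lacks columns {sorted(missing)}")
    if np.any(table["value"].to_numpy(dtype=float) < 0):
        raise DataError("uptake values must be non-negative")
    out = []
    for (genotype, condition), grp in table.groupby(
            ["genotype", "condition"], sort=True):
        v = grp["value"].to_numpy(dtype=float)
        sem = float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) >= 2 else float("nan")
        out.append(UptakeCellSummary(genotype=str(genotype),
                                     condition=str(condition),
                                     mean=float(np.mean(v)), sem=sem,
                                     n=len(v)))
    return out


def percent_change(reference: float, value: float, rounding: str = "none") -> float:
    """``100 * (value - reference) / reference`` with the requested rounding.

    ``rounding`` is one of ``"nearest"``, ``"floor"`` (truncation toward
    −∞) or ``"none"``.
    """
    if reference <= 0:
        raise DataError("reference must be positive")
    return _apply_rounding(100.0 * (value - reference) / reference, rounding)


def transporter_contribution(
    total_mean: float, residual_mean: float, rounding: str = "none"
) -> tuple[float, float]:
    """Transporter-attributable uptake from total and knockout-residual means.

    Returns ``(absolute, percent)`` where ``absolute = total - residual`` and
    ``percent = 100 * absolute / total``.
    """
    if not total_mean >= residual_mean >= 0:
        raise DataError("need total_mean >= residual_mean >= 0")
    if total_mean == 0:
        raise DataError("total_mean must be positive")
    absolute = total_mean - residual_mean
    percent = 100.0 * absolute / total_mean
    return _apply_rounding(absolute, rounding), _apply_rounding(percent, rounding)


def synergy(basal_mean: float, stimulated_mean: float,
            rounding: str = "none") -> SynergyResult:
    """Vesicular synergy: percent increase of stimulated over basal uptake."""
    return SynergyResult(
        basal_mean=basal_mean,
        stimulated_mean=stimulated_mean,
        percent_increase=percent_change(basal_mean, stimulated_mean, rounding),
    )


@dataclass(frozen=True)
class GroupComparison:
    """ANOVA summary: F and p per effect plus a pairwise post-hoc table."""

    design: str
    f_statistics: dict
    p_values: dict
    dof: dict
    posthoc: pd.DataFrame
    flags: tuple = ()


def _one_way(cells: dict[str, np.ndarray]) -> GroupComparison:
    groups = list(cells)
    arrays = [np.asarray(cells[g], dtype=float) for g in groups]
    flags = []
    if all(np.ptp(a) == 0 for a in arrays):
        flags.append("degenerate_variance")
        f, p = float("nan"), float("nan")
    else:
        f, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(arrays)
    labels = np.concatenate([[g] * len(a) for g, a in zip(groups, arrays)])
    if "degenerate_variance" in flags:
        posthoc = pd.DataFrame(columns=["group1", "group2", "meandiff",
                                        "p_adj", "reject"])
    else:
        tk = pairwise_tukeyhsd(values, labels)
        posthoc = pd.DataFrame(
            tk.summary().data[1:],
            columns=["group1", "group2", "meandiff", "p_adj", "lower",
                     "upper", "reject"],
        )[["group1", "group2", "meandiff", "p_adj", "reject"]]
    return GroupComparison(
        design="one_way",
        f_statistics={"group": float(f)},
        p_values={"group": float(p)},
        dof={"between": k - 1, "within": n - k},
        posthoc=posthoc,
        flags=tuple(flags),
    )


def _two_way(cells: dict[tuple[str, str], np.ndarray]) -> GroupComparison:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    rows = [
        {"a": fa, "b": fb, "value": float(v)}
        for (fa, fb), arr in cells.items()
        for v in np.asarray(arr, dtype=float)
    ]
    df = pd.DataFrame(rows)
    flags = []
    if df["value"].nunique() == 1:
        flags.append("degenerate_variance")
        empty = pd.DataFrame(columns=["group1", "group2", "meandiff",
                                      "p_adj", "reject"])
        return GroupComparison(design="two_way", f_statistics={},
                               p_values={}, dof={}, posthoc=empty,
                               flags=tuple(flags))
    model = smf.ols("value ~ C(a) * C(b)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    effects = {"C(a)": "a", "C(b)": "b", "C(a):C(b)": "a:b"}
    f_stats = {effects[k]: float(anova.loc[k, "F"]) for k in effects
               if k in anova.index}
    p_vals = {effects[k]: float(anova.loc[k, "PR(>F)"]) for k in effects
              if k in anova.index}
    dof = {effects[k]: float(anova.loc[k, "df"]) for k in effects
           if k in anova.index}
    dof["residual"] = float(anova.loc["Residual", "df"])

    # Bonferroni-corrected pairwise Welch-free t-tests across all cells
    keys = list(cells)
    comparisons = []
    m = len(keys) * (len(keys) - 1) // 2
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            x = np.asarray(cells[keys[i]], dtype=float)
            y = np.asarray(cells[keys[j]], dtype=float)
            t, p = stats.ttest_ind(x, y)
            comparisons.append({
                "group1": "/".join(keys[i]),
                "group2": "/".join(keys[j]),
                "meandiff": float(np.mean(y) - np.mean(x)),
                "p_adj": float(min(p * m, 1.0)),
                "reject": bool(min(p * m, 1.0) < 0.05),
            })
    return GroupComparison(
        design="two_way",
        f_statistics=f_stats,
        p_values=p_vals,
        dof=dof,
        posthoc=pd.DataFrame(comparisons),
        flags=tuple(flags),
    )


def compare_groups(cells: dict, design: str = "one_way") -> GroupComparison:
    """ANOVA with the named post-hoc procedure.

    ``design="one_way"``: ``cells`` maps group label → replicate array;
    Tukey HSD post hoc. ``design="two_way"``: ``cells`` maps (factor_a,
    factor_b) → replicate array; Bonferroni-corrected pairwise t-tests post
    hoc. Groups of identical constants are flagged ``degenerate_variance``.
    """
    if len(cells) < 2:
        raise DataError("need at least two groups")
    for key, arr in cells.items():
        if len(np.asarray(arr)) < 2:
            raise DataError(f"group {key} needs at least two replicates")
    if design == "one_way":
        return _one_way(cells)
    if design == "two_way":
        return _two_way(cells)
    raise DataError(f"unknown design {design!r}")
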