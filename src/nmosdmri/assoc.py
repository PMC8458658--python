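"""Per-feature NMOSD-vs-MS association statistics.

Each feature yields a 2x2 contingency table of presence counts over the
patients with relevant imaging (missing entries shrink the denominators).
Odds ratios use the Haldane-Anscombe continuity correction — +0.5 added to
all four cells — whenever any cell is zero, with a Woolf log-normal 95%
confidence interval computed on the same (possibly corrected) cells.
Ratios above 1 favour NMOSD.  An interval excluding 1 is read as a
significant association; no multiple-testing adjustment is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .catalog import FeatureCatalog
from .cohort import FeatureMatrix

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "contingency_from_matrix",
    "odds_ratio_ha",
    "sens_spec",
    "associate_all",
    "compare_lesion_counts",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """Feature-presence counts: a/b = NMOSD present/absent, c/d = MS."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_nmosd(self) -> int:
        return self.a + self.b

    @property
    def n_ms(self) -> int:
        return self.c + self.d

    def swapped(self) -> "ContingencyTable":
        """The same table with the class roles exchanged."""
        return ContingencyTable(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class AssociationResult:
    feature_id: str
    table: ContingencyTable
    odds_ratio: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    corrected: bool

    @property
    def significant(self) -> bool:
        """CI excludes 1 (no-association value)."""
        return self.ci_low > 1.0 or self.ci_high < 1.0


def contingency_from_matrix(
    matrix: FeatureMatrix, feature_id: str, which: str = "ever"
) -> ContingencyTable:
    """Count feature presence per class, excluding missing entries entirely."""
    if which not in ("first", "ever"):
        raise ValueError("which must be 'first' or 'ever'")
    if feature_id not in matrix.ever.columns:
        raise KeyError(f"unknown feature {feature_id!r}")
    col = getattr(matrix, which)[feature_id]
    is_nmosd = matrix.diagnosis == "NMOSD"
    nmosd = col[is_nmosd].dropna()
    ms = col[~is_nmosd].dropna()
    table = ContingencyTable(
        a=int((nmosd == 1).sum()),
        b=int((nmosd == 0).sum()),
        c=int((ms == 1).sum()),
        d=int((ms == 0).sum()),
    )
    if table.total == 0:
        warnings.warn(f"feature {feature_id!r}: all entries missing", stacklevel=2)
    return table


def odds_ratio_ha(table: ContingencyTable) -> tuple[float, float, float, bool]:
    """Odds ratio with Haldane-Anscombe correction and Woolf 95% CI.

    Returns ``(odds_ratio, ci_low, ci_high, corrected)``.  When any cell is
    zero, 0.5 is added to all four cells before both the point estimate and
    the interval are computed.
    """
    if table.total == 0:
        raise ValueError("odds ratio undefined for an all-zero table")
    corrected = 0 in (table.a, table.b, table.c, table.d)
    shift = 0.5 if corrected else 0.0
    a, b, c, d = (x + shift for x in (table.a, table.b, table.c, table.d))
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    return or_, math.exp(log_or - _Z95 * se), math.exp(log_or + _Z95 * se), corrected


def sens_spec(table: ContingencyTable) -> tuple[float, float]:
    """Sensitivity and specificity of the feature for detecting NMOSD.

    Sensitivity = a/(a+b); specificity = d/(c+d).  A zero margin yields NaN.
    """
    sens = table.a / table.n_nmosd if table.n_nmosd else float("nan")
    spec = table.d / table.n_ms if table.n_ms else float("nan")
    return sens, spec


def associate_all(
    matrix: FeatureMatrix, catalog: FeatureCatalog, which: str = "ever"
) -> list[AssociationResult]:
    """Association statistics for every feature with non-empty denominators.

    Features whose table is all-zero (no patient with relevant imaging) are
    omitted rather than raising.  Results are sorted by descending odds
    ratio, ties broken by feature_id.
    """
    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for fid in catalog.feature_ids:
            table = contingency_from_matrix(matrix, fid, which)
            if table.total == 0:
                continue
            or_, lo, hi, corrected = odds_ratio_ha(table)
            sens, spec = sens_spec(table)
            results.append(
                AssociationResult(fid, table, or_, lo, hi, sens, spec, corrected)
            )
    return sorted(results, key=lambda r: (-r.odds_ratio, r.feature_id))


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tabulate association results (one row per feature, forest-plot ready)."""
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "corrected": r.corrected,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def compare_lesion_counts(matrix: FeatureMatrix, count_key: str = "brain_T2_total"):
    """Mann-Whitney U comparison of a lesion count between the two classes.

    Thin convenience wrapper around the standard rank-sum routine; returns
    the scipy result object.
    """
    counts = matrix.max_count[count_key]
    is_nmosd = matrix.diagnosis == "NMOSD"
    x = counts[is_nmosd].dropna()
    y = counts[~is_nmosd].dropna()
    return stats.mannwhitneyu(x, y, alternative="two-sided")
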