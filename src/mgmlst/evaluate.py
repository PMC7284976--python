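"""Scoring predicted strain compositions and comparing cohorts.

Predicted group-fraction vectors are compared with expected (or
reference) compositions by Pearson's product-moment correlation over
the full reporting-group vector, zeros included.  Cohort differences in
per-group relative abundance are tested with a two-sided Mann-Whitney U
by default (a Welch t-test by flag); p-values are reported per group
with no multiplicity correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CompositionComparison",
    "CohortTestResult",
    "pearson",
    "compare_compositions",
    "cohort_compare",
    "write_comparison_table",
    "write_cohort_table",
]


@dataclass
class CompositionComparison:
    """Pearson correlation between aligned predicted/expected vectors."""

    sample: str
    pearson_r: float
    predicted: np.ndarray
    expected: np.ndarray


@dataclass
class CohortTestResult:
    """Per-group two-cohort comparison of relative abundances."""

    group: str
    statistic: float
    p_value: float
    cohort_medians: tuple[float, float]
    degenerate: bool = False


def pearson(predicted: Sequence[float], expected: Sequence[float]) -> float:
    """Pearson's r between two aligned fraction vectors.

    Returns NaN (flagged, with a warning) when either vector is exactly
    constant, where the correlation is undefined.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(expected, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least two aligned groups")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Pearson correlation undefined (NaN)")
        return math.nan
    return float(stats.pearsonr(x, y).statistic)


def compare_compositions(
    predicted: Mapping[str, Mapping[str, float]],
    expected: Mapping[str, Mapping[str, float]],
) -> list[CompositionComparison]:
    """Align per-sample predicted/expected group fractions and correlate.

    Vectors are aligned on the union of reporting groups per sample,
    absent groups taking fraction 0.
    """
    out = []
    for sample in predicted:
        if sample not in expected:
            raise KeyError(f"no expected composition for sample {sample!r}")
        groups = sorted(set(predicted[sample]) | set(expected[sample]))
        p = np.array([predicted[sample].get(g, 0.0) for g in groups])
        e = np.array([expected[sample].get(g, 0.0) for g in groups])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = pearson(p, e)
        out.append(CompositionComparison(sample=sample, pearson_r=r,
                                         predicted=p, expected=e))
    return out


def cohort_compare(
    abundances: pd.DataFrame,
    labels: Mapping[str, str],
    test: Literal["mannwhitney", "ttest"] = "mannwhitney",
) -> list[CohortTestResult]:
    """Compare per-group abundances between two cohorts.

    ``abundances`` is samples x groups (fractions); ``labels`` maps each
    sample to one of exactly two cohort labels.  Groups whose values are
    identical across all samples are flagged degenerate with p = 1.
    """
    cohorts = sorted(set(labels.values()))
    if len(cohorts) != 2:
        raise ValueError(f"need exactly two cohorts, got {cohorts}")
    a_idx = [s for s in abundances.index if labels.get(s) == cohorts[0]]
    b_idx = [s for s in abundances.index if labels.get(s) == cohorts[1]]
    if not a_idx or not b_idx:
        raise ValueError("both cohorts must be non-empty")
    out = []
    for group in abundances.columns:
        a = abundances.loc[a_idx, group].to_numpy(dtype=float)
        b = abundances.loc[b_idx, group].to_numpy(dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0:
            warnings.warn(f"group {group!r}: identical values in both cohorts")
            out.append(
                CohortTestResult(group=str(group), statistic=math.nan, p_value=1.0,
                                 cohort_medians=(float(np.median(a)), float(np.median(b))),
                                 degenerate=True)
            )
            continue
        if test == "ttest":
            res = stats.ttest_ind(a, b, equal_var=False)
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
        out.append(
            CohortTestResult(
                group=str(group),
                statistic=float(res.statistic),
                p_value=float(res.pvalue),
                cohort_medians=(float(np.median(a)), float(np.median(b))),
            )
        )
    return out


def write_comparison_table(
    comparisons: Sequence[CompositionComparison], path: str | Path
) -> None:
    """TSV: ``sample pearson_r``."""
    pd.DataFrame(
        [{"sample": c.sample, "pearson_r": c.pearson_r} for c in comparisons]
    ).to_csv(path, sep="\t", index=False)


def write_cohort_table(results: Sequence[CohortTestResult], path: str | Path) -> None:
    """TSV: ``group statistic p_value``."""
    pd.DataFrame(
        [
            {"group": r.group, "statistic": r.statistic, "p_value": r.p_value}
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)
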