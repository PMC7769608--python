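"""Cohort-level summaries of paranode-length and overlap measurements.

Operates on tidy tables with one row per measured paranode (group label,
block/animal id, length in um, optional block covariates).  The bespoke
content is the summary definitions (long-paranode proportions, exceedance
over a reference percentile); hypothesis tests and rank correlations are
delegated to standard scipy routines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_CUTOFFS_UM = (3.0, 4.0, 5.0)

REQUIRED_COLUMNS = ("group", "block", "length_um")


class CohortError(ValueError):
    pass


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise CohortError(f"cohort table missing column {col!r}")
    if (table["length_um"] <= 0).any():
        raise CohortError("paranode lengths must be > 0")
    return table


def proportion_above(lengths, cutoff: float) -> float:
    """Fraction of lengths strictly greater than the cutoff."""
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        raise CohortError("empty length array")
    return float(np.mean(lengths > cutoff))


def exceedance_vs_reference(
    test_lengths, reference_lengths, percentile: float = 75.0
) -> float:
    """Fraction of test lengths above the reference group's percentile.

    The reference percentile uses linear interpolation between order
    statistics (numpy's default rule).
    """
    test = np.asarray(test_lengths, dtype=float)
    ref = np.asarray(reference_lengths, dtype=float)
    if test.size == 0 or ref.size == 0:
        raise CohortError("empty length array")
    cutoff = float(np.percentile(ref, percentile))
    return proportion_above(test, cutoff)


def compare_groups(lengths_a, lengths_b):
    """Two-sided Mann-Whitney rank-sum comparison (routine).

    Returns (U statistic, p-value).
    """
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise CohortError("empty length array")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def rank_correlation(x, y):
    """Spearman rank correlation (routine).  Returns (rho, p-value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise CohortError("need equal-length arrays with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise CohortError("rank correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float
    q25: float
    median: float
    q75: float
    proportion_above: dict[float, float]


def summarize_groups(
    table: pd.DataFrame,
    cutoffs=DEFAULT_CUTOFFS_UM,
    reference_group: str | None = None,
    reference_percentile: float = 75.0,
) -> pd.DataFrame:
    """Per-group summary table: n, mean, SD, quartiles, long-paranode
    proportions and (optionally) exceedance over a reference group's
    percentile."""
    validate_cohort(table)
    rows = []
    ref_lengths = None
    if reference_group is not None:
        ref_lengths = table.loc[
            table["group"] == reference_group, "length_um"
        ].to_numpy()
        if ref_lengths.size == 0:
            raise CohortError(f"reference group {reference_group!r} not found")
    for group, sub in table.groupby("group", sort=False):
        lengths = sub["length_um"].to_numpy()
        row = {
            "group": group,
            "n": len(lengths),
            "mean_um": float(np.mean(lengths)),
            "sd_um": float(np.std(lengths, ddof=1)) if len(lengths) > 1 else 0.0,
            "q25_um": float(np.percentile(lengths, 25)),
            "median_um": float(np.percentile(lengths, 50)),
            "q75_um": float(np.percentile(lengths, 75)),
        }
        for c in cutoffs:
            row[f"prop_gt_{c:g}um"] = proportion_above(lengths, c)
        if ref_lengths is not None:
            row[f"prop_gt_ref_p{reference_percentile:g}"] = exceedance_vs_reference(
                lengths, ref_lengths, reference_percentile
            )
        rows.append(row)
    return pd.DataFrame(rows)


def block_means(table: pd.DataFrame, value: str = "length_um") -> pd.DataFrame:
    """Per-block mean of a measurement column, keeping block covariates."""
    validate_cohort(table) if value == "length_um" else None
    covariates = [
        c for c in table.columns if c not in ("group", "block", value)
    ]
    agg = {value: "mean", **{c: "first" for c in covariates}}
    return table.groupby(["group", "block"], as_index=False).agg(agg)
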