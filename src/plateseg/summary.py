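"""Replicate-level aggregation and between-condition statistics.

The statistical unit is the biological replicate, not the platelet:
thousands of cells from one donor/coverslip are not independent samples,
so per-platelet tests would pseudo-replicate.  Each (condition, replicate)
pair is reduced to its mean area, mean circularity and class percentages,
and conditions are compared on those replicate means by one-way ANOVA
followed by all pairwise two-sample t-tests with Bonferroni correction
over the number of pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MorphClass

__all__ = ["summarize", "compare_conditions", "ComparisonReport"]

_PERCENT_COLUMNS = {c: f"percent_{c.name.lower()}" for c in MorphClass}


def summarize(records: pd.DataFrame, manifest: pd.DataFrame,
              class_column: str = "predicted_class",
              include_border: bool = False) -> pd.DataFrame:
    """One summary row per (condition, replicate).

    ``manifest`` maps ``image_id`` to ``condition`` and ``replicate``.
    Objects flagged as touching the image border are excluded unless
    ``include_border`` is set.  Class percentages are computed from
    ``class_column`` and sum to 100 per row.
    """
    required = {"image_id", "condition", "replicate"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    unknown = set(records["image_id"]) - set(manifest["image_id"])
    if unknown:
        raise ValueError(f"records reference image ids missing from the "
                         f"manifest: {sorted(unknown)}")

    merged = records.merge(manifest[["image_id", "condition", "replicate"]],
                           on="image_id", how="left")
    if not include_border and "touches_border" in merged.columns:
        merged = merged[~merged["touches_border"].astype(bool)]

    rows = []
    for (condition, replicate), grp in merged.groupby(
            ["condition", "replicate"], sort=True):
        n = len(grp)
        row = {
            "condition": condition,
            "replicate": replicate,
            "n_platelets": n,
            "mean_area_um2": float(grp["area_um2"].mean()) if n else np.nan,
            "mean_circularity": float(grp["circularity"].mean()) if n else np.nan,
        }
        for cls, col in _PERCENT_COLUMNS.items():
            if n and class_column in grp.columns:
                row[col] = 100.0 * float(
                    (grp[class_column].astype(int) == int(cls)).sum()) / n
            else:
                row[col] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ComparisonReport:
    """ANOVA plus Bonferroni-corrected pairwise t-tests for one metric."""

    metric: str
    anova_p: float
    pairwise: pd.DataFrame  # condition_a, condition_b, raw_p, bonferroni_p

    @property
    def n_comparisons(self) -> int:
        return len(self.pairwise)


def compare_conditions(summaries: pd.DataFrame, metric: str,
                       equal_var: bool = True) -> ComparisonReport:
    """Compare conditions on a replicate-level metric.

    One-way ANOVA across all conditions, then every pairwise two-sample
    t-test (pooled-variance by default, matching the ANOVA assumptions;
    set ``equal_var=False`` for Welch) with Bonferroni factor equal to the
    number of condition pairs.
    """
    if metric not in summaries.columns:
        raise ValueError(f"metric {metric!r} not found in summaries")
    groups = {cond: grp[metric].to_numpy(dtype=float)
              for cond, grp in summaries.groupby("condition", sort=True)}
    if len(groups) < 2:
        raise ValueError("need at least two conditions to compare")
    too_small = [c for c, v in groups.items() if len(v) < 2]
    if too_small:
        raise ValueError(f"conditions with fewer than 2 replicates: {too_small}")

    anova_p = float(stats.f_oneway(*groups.values()).pvalue)
    pairs = list(itertools.combinations(sorted(groups), 2))
    n_pairs = len(pairs)
    rows = []
    for a, b in pairs:
        res = stats.ttest_ind(groups[a], groups[b], equal_var=equal_var)
        raw_p = float(res.pvalue)
        rows.append({
            "condition_a": a,
            "condition_b": b,
            "raw_p": raw_p,
            "bonferroni_p": min(1.0, raw_p * n_pairs),
        })
    return ComparisonReport(metric=metric, anova_p=anova_p,
                            pairwise=pd.DataFrame(rows))
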