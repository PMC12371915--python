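"""Region-level methylation profiles and cross-study concordance.

Regions are classified into four methylation classes from per-site means
pooled across all three study groups (unweighted by pathological status):

* hypomethylated — every site at most 3%
* hypermethylated — every site at least 85%
* low — not hypomethylated, median site mean <= 10% and maximum < 30%
* intermediate — everything else

The 3% bound is the field's working definition of a fully hypomethylated
CGI/promoter region; the 85% bound sits safely below the ~90-98% site means
seen in fully methylated exonic CGIs.  The low/intermediate boundary is an
explicit package choice separating regions that are mostly unmethylated
with isolated moderate sites from genuinely intermediate regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calling import MethylationMatrix

__all__ = [
    "RegionProfile",
    "classify_region",
    "profile_regions",
    "group_summary",
    "cross_study_correlation",
    "HYPO_MAX",
    "HYPER_MIN",
]

HYPO_MAX = 3.0
HYPER_MIN = 85.0
LOW_MEDIAN_MAX = 10.0
LOW_SITE_MAX = 30.0


@dataclass(frozen=True)
class RegionProfile:
    region_id: str
    site_means: tuple[float, ...]
    min: float
    max: float
    median: float
    methylation_class: str


def classify_region(site_means) -> str:
    """Four-class region label from pooled per-site mean methylation (%)."""
    means = np.asarray([m for m in np.asarray(site_means, float).ravel()
                        if np.isfinite(m)])
    if means.size == 0:
        raise ValueError("unclassifiable: all site means missing")
    if (means < 0).any() or (means > 100).any():
        raise ValueError("site means must lie in [0, 100]")
    if (means <= HYPO_MAX).all():
        return "hypomethylated"
    if (means >= HYPER_MIN).all():
        return "hypermethylated"
    if np.median(means) <= LOW_MEDIAN_MAX and means.max() < LOW_SITE_MAX:
        return "low"
    return "intermediate"


def profile_regions(matrix: MethylationMatrix) -> pd.DataFrame:
    """Per-region pooled profile and class, from all samples' calls."""
    pct = matrix.percent
    rows = []
    # preserve panel column order
    seen, ordered = set(), []
    for c in pct.columns:
        rid = c.split(":", 1)[0]
        if rid not in seen:
            seen.add(rid)
            ordered.append(rid)
    for rid in ordered:
        cols = [c for c in pct.columns if c.split(":", 1)[0] == rid]
        means = pct[cols].mean(axis=0, skipna=True).to_numpy()
        means = means[np.isfinite(means)]
        if means.size == 0:
            rows.append((rid, np.nan, np.nan, np.nan, "unclassifiable"))
            continue
        rows.append((rid, round(float(means.min()), 2),
                     round(float(means.max()), 2),
                     round(float(np.median(means)), 2),
                     classify_region(means)))
    return pd.DataFrame(rows, columns=["region_id", "min", "max", "median",
                                       "methylation_class"])


def group_summary(matrix: MethylationMatrix,
                  sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-group per-site mean, SD and n over non-missing cells.

    With a single non-missing sample the SD is reported as 0 with n = 1 (a
    flag for the reader, not an estimate).
    """
    pct = matrix.percent
    unlabelled = set(pct.index) - set(sample_sheet.index)
    if unlabelled:
        raise ValueError(f"samples missing from sheet: {sorted(unlabelled)[:5]}")
    groups = sample_sheet.loc[pct.index, "group"]
    rows = []
    for g in sorted(groups.unique()):
        block = pct.loc[groups[groups == g].index]
        n = block.notna().sum(axis=0)
        mean = block.mean(axis=0, skipna=True)
        sd = block.std(axis=0, ddof=1, skipna=True).where(n > 1, 0.0)
        for sid in pct.columns:
            rows.append((g, sid, float(mean[sid]) if n[sid] else np.nan,
                         float(sd[sid]) if n[sid] else np.nan, int(n[sid])))
    return pd.DataFrame(rows, columns=["group", "site_id", "mean", "sd", "n"])


def cross_study_correlation(site_values_a: pd.Series,
                            site_values_b: pd.Series) -> tuple[float, int]:
    """Pearson r between two studies' per-site methylation over shared sites.

    Site pairs with a missing value on either side are dropped; at least 3
    shared non-missing sites are required.  Returns (r, n_shared); r is NaN
    (undefined) when either vector has zero variance.
    """
    a, b = site_values_a.align(site_values_b, join="inner")
    keep = a.notna() & b.notna()
    a, b = a[keep].astype(float), b[keep].astype(float)
    n = len(a)
    if n < 3:
        raise ValueError("insufficient overlap: fewer than 3 shared sites")
    if a.std(ddof=0) == 0 or b.std(ddof=0) == 0:
        return float("nan"), n
    r, _ = stats.pearsonr(a, b)
    return float(r), n
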