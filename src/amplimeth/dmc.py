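"""Differentially methylated CpG (DMC) calling.

Per site, the methylation percentage is regressed by ordinary least squares
on the experiment batch (categorical) and the disease group (categorical,
CON as reference).  Modelling the batch separates systematic
experiment-level shifts from the disease effect; the disease deltas are the
model-adjusted group differences in percentage points for the three
contrasts HD-CON, LC-CON and HD-LC, with two-sided t-tests on the contrast.

A site is differentially methylated for a contrast when the adjusted delta
is at least ``delta_threshold`` percentage points in magnitude AND the
Benjamini-Hochberg adjusted p-value is below ``alpha``; BH is applied within
each contrast family across all tested sites of a run.  Defaults: 1.5 pp and
0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DmcModelSpec",
    "CONTRASTS",
    "GROUP_ORDER",
    "CollinearDesignError",
    "fit_site_model",
    "fit_many_sites",
    "adjust_bh",
    "call_dmcs",
    "DELTA_THRESHOLD",
    "ALPHA",
]

CONTRASTS = ("HD-CON", "LC-CON", "HD-LC")
GROUP_ORDER = ("CON", "HD", "LC")
DELTA_THRESHOLD = 1.5  # percentage points
ALPHA = 0.05
MIN_PER_GROUP = 3


@dataclass
class DmcModelSpec:
    """Design of the per-site regression."""

    include_batch: bool = True
    reference: str = "CON"
    stratify_sex: bool = False  # fit separately per sex (X-linked regions)


class CollinearDesignError(ValueError):
    pass


def _design(sheet: pd.DataFrame, spec: DmcModelSpec):
    """Design [intercept | batch dummies | group dummies]; CON-first reference."""
    present = [g for g in GROUP_ORDER if g in set(sheet["group"])]
    ref = spec.reference if spec.reference in present else present[0]
    cols = ["intercept"]
    mats = [np.ones((len(sheet), 1))]
    if spec.include_batch:
        for b in sorted(sheet["batch"].unique())[1:]:
            mats.append((sheet["batch"] == b).to_numpy(float)[:, None])
            cols.append(f"batch[{b}]")
    group_cols: dict[str, np.ndarray] = {ref: np.zeros(0)}  # placeholder
    for g in present:
        if g == ref:
            continue
        mats.append((sheet["group"] == g).to_numpy(float)[:, None])
        cols.append(f"group[{g}]")
    X = np.hstack(mats)
    vec = {}
    for g in present:
        v = np.zeros(X.shape[1])
        if g != ref:
            v[cols.index(f"group[{g}]")] = 1.0
        vec[g] = v
    return X, cols, vec


def _check_rank(X: np.ndarray, cols: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        confounded = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                confounded.append(cols[j])
        raise CollinearDesignError(
            f"collinear design: confounded columns {confounded or cols[1:]}")


def _fit_block(Y: np.ndarray, sheet: pd.DataFrame, spec: DmcModelSpec):
    """OLS of every column of Y (n_samples x n_sites) on the shared design.

    Returns {contrast: (delta, p)}; contrasts whose groups are absent from
    the block come out NaN.
    """
    n, n_sites = Y.shape
    X, cols, vec = _design(sheet, spec)
    _check_rank(X, cols)
    df = n - X.shape[1]
    nan = np.full(n_sites, np.nan)
    if df <= 0:
        return {c: (nan, nan) for c in CONTRASTS}

    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ (X.T @ Y)                       # (k, n_sites)
    resid = Y - X @ B
    sigma2 = (resid ** 2).sum(axis=0) / df

    out = {}
    for name in CONTRASTS:
        a, b = name.split("-")
        if a not in vec or b not in vec:
            out[name] = (nan, nan)
            continue
        c = vec[a] - vec[b]
        delta = c @ B
        se = np.sqrt(np.maximum(sigma2 * (c @ XtX_inv @ c), 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, delta / se, np.where(delta == 0, 0.0, np.inf))
        p = 2.0 * stats.t.sf(np.abs(t), df)
        out[name] = (delta, p)
    return out


def fit_many_sites(
    percent: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    spec: DmcModelSpec | None = None,
) -> pd.DataFrame:
    """Fit the site regression for every column of a percent matrix.

    Missing cells are excluded listwise per site; sites sharing a missingness
    pattern share one design factorisation.  A group contributes to a site's
    contrasts only with >= 3 non-missing samples there; contrasts lacking a
    group are NaN.

    Returns a long DataFrame: site_id, contrast, delta, p, n.
    """
    spec = spec or DmcModelSpec()
    sheet = sample_sheet.loc[percent.index]

    Y = percent.to_numpy(float)
    site_ids = list(percent.columns)
    obs = np.isfinite(Y)
    rows = []

    patterns: dict[bytes, list[int]] = {}
    for j in range(Y.shape[1]):
        patterns.setdefault(obs[:, j].tobytes(), []).append(j)

    for pat, cols_j in patterns.items():
        mask = np.frombuffer(pat, dtype=bool)
        sub_sheet = sheet.loc[mask]
        Yb = Y[mask][:, cols_j]
        counts = sub_sheet["group"].value_counts()
        enough = {g for g in GROUP_ORDER if counts.get(g, 0) >= MIN_PER_GROUP}
        nan = np.full(len(cols_j), np.nan)
        if len(enough) < 2:
            fits = {c: (nan, nan) for c in CONTRASTS}
        else:
            keep = sub_sheet["group"].isin(enough).to_numpy()
            fits = _fit_block(Yb[keep], sub_sheet.loc[keep], spec)
        for name in CONTRASTS:
            a, b = name.split("-")
            valid = a in enough and b in enough
            delta, p = fits[name]
            for jj, j in enumerate(cols_j):
                rows.append((site_ids[j], name,
                             float(delta[jj]) if valid else np.nan,
                             float(p[jj]) if valid else np.nan,
                             int(mask.sum())))

    out = pd.DataFrame(rows, columns=["site_id", "contrast", "delta", "p", "n"])
    key = {s: i for i, s in enumerate(site_ids)}
    out["__k"] = out["site_id"].map(key)
    out = out.sort_values(["__k", "contrast"], kind="stable").drop(columns="__k")
    return out.reset_index(drop=True)


def fit_site_model(
    site_values: pd.Series,
    sample_sheet: pd.DataFrame,
    spec: DmcModelSpec | None = None,
) -> dict[str, tuple[float, float]]:
    """Single-site convenience wrapper: {contrast: (delta, p)}."""
    frame = site_values.to_frame(name=site_values.name or "site")
    fits = fit_many_sites(frame, sample_sheet, spec)
    return {r.contrast: (r.delta, r.p) for r in fits.itertuples()}


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved).

    NaN entries stay NaN and do not count toward the family size.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def call_dmcs(
    fits: pd.DataFrame,
    delta_threshold: float = DELTA_THRESHOLD,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Apply BH (per contrast family) and the effect-size threshold.

    Adds p_adj, significant and direction columns.  ``significant`` iff
    |delta| >= delta_threshold and p_adj < alpha; ``direction`` is up/down by
    the sign of delta when past the threshold, flat otherwise.
    """
    if fits.empty:
        raise ValueError("no fitted sites")
    out = fits.copy()
    out["p_adj"] = np.nan
    for contrast in out["contrast"].unique():
        m = out["contrast"] == contrast
        out.loc[m, "p_adj"] = adjust_bh(out.loc[m, "p"].to_numpy())
    delta = out["delta"].to_numpy(float)
    passed = np.abs(delta) >= delta_threshold
    sig = passed & (out["p_adj"].to_numpy(float) < alpha)
    sig &= np.isfinite(delta) & np.isfinite(out["p_adj"].to_numpy(float))
    out["significant"] = sig
    out["direction"] = np.where(~np.isfinite(delta) | ~passed, "flat",
                                np.where(delta > 0, "up", "down"))
    return out
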