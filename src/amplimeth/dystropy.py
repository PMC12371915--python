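"""Direction patterns across the three groups and dystropy calls.

A CpG site's group pattern is read off its three model-adjusted contrasts
(HD-CON, LC-CON, HD-LC) together with the raw group means:

* flat — both disease deltas below the 1.5 pp flatness cutoff
* bidirectional — the two diseases move in opposite directions versus CON
  (the dystropic, inverse-comorbidity configuration)
* ordered_increase / ordered_decrease — strictly ordered means
  CON < LC < HD (resp. CON > LC > HD) with both diseases changed on the
  same side
* unidirectional — both diseases changed the same way (or only one changed)
  without the strict ordering

A site *supports dystropy* when its pattern is bidirectional AND the HD-LC
contrast is significant; a gene is flagged dystropic when at least one of
its sites supports it (configurable to a stricter k-of-n rule).

Methylation-expression concordance: per disease, the expression direction is
the majority sign of log fold-changes across datasets; a gene is
"inverse-concordant" when, for both diseases, methylation moved opposite to
expression — the configuration expected when regulatory-region methylation
represses transcription.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dmc import DELTA_THRESHOLD

__all__ = [
    "DirectionCall",
    "classify_direction",
    "classify_directions",
    "call_dystropic_genes",
    "expression_concordance",
    "welch_expression_summary",
]


@dataclass(frozen=True)
class DirectionCall:
    site_id: str
    mean_con: float
    mean_hd: float
    mean_lc: float
    dir_hd: str  # up | down | flat (relative to CON)
    dir_lc: str
    pattern: str  # bidirectional | unidirectional | ordered_* | flat | NA
    hd_vs_lc_significant: bool


def _pattern(dir_hd: str, dir_lc: str, means) -> str:
    con, hd, lc = means
    if dir_hd == "flat" and dir_lc == "flat":
        return "flat"
    if "flat" not in (dir_hd, dir_lc) and dir_hd != dir_lc:
        return "bidirectional"
    if dir_hd == dir_lc == "up" and con < lc < hd:
        return "ordered_increase"
    if dir_hd == dir_lc == "down" and con > lc > hd:
        return "ordered_decrease"
    return "unidirectional"


def classify_direction(site_dmc: pd.DataFrame,
                       means: tuple[float, float, float]) -> DirectionCall:
    """Direction call for one site.

    ``site_dmc`` holds the site's rows of a DMC report (needs contrast,
    delta, direction, significant); ``means`` are the raw group means
    (CON, HD, LC) in percent.  A missing contrast makes the pattern NA.
    """
    by = {r.contrast: r for r in site_dmc.itertuples()}
    sid = site_dmc["site_id"].iloc[0]
    con, hd, lc = means
    needed = ("HD-CON", "LC-CON", "HD-LC")
    if any(c not in by or not np.isfinite(by[c].delta) for c in needed):
        return DirectionCall(sid, con, hd, lc, "NA", "NA", "NA", False)
    dir_hd = by["HD-CON"].direction
    dir_lc = by["LC-CON"].direction
    return DirectionCall(sid, con, hd, lc, dir_hd, dir_lc,
                         _pattern(dir_hd, dir_lc, means),
                         bool(by["HD-LC"].significant))


def classify_directions(dmc_report: pd.DataFrame,
                        group_means: pd.DataFrame) -> pd.DataFrame:
    """Direction calls for every site of a DMC report.

    ``group_means`` is the group_summary frame (group, site_id, mean, ...).
    """
    means = group_means.pivot(index="site_id", columns="group", values="mean")
    rows = []
    for sid, block in dmc_report.groupby("site_id", sort=False):
        m = tuple(float(means.at[sid, g]) if sid in means.index and
                  g in means.columns else np.nan for g in ("CON", "HD", "LC"))
        c = classify_direction(block, m)
        rows.append((c.site_id, c.mean_con, c.mean_hd, c.mean_lc,
                     c.dir_hd, c.dir_lc, c.pattern, c.hd_vs_lc_significant))
    return pd.DataFrame(rows, columns=[
        "site_id", "mean_con", "mean_hd", "mean_lc",
        "dir_hd", "dir_lc", "pattern", "hd_vs_lc_significant"])


def call_dystropic_genes(direction_calls: pd.DataFrame,
                         site_to_gene: dict[str, str],
                         min_supporting: int = 1) -> pd.DataFrame:
    """Gene-level dystropy report.

    A site supports dystropy iff pattern == bidirectional and the HD-LC
    contrast is significant.  Sorted by supporting-site count descending,
    ties alphabetically by gene.
    """
    missing = set(direction_calls["site_id"]) - set(site_to_gene)
    if missing:
        raise ValueError(f"site->gene map missing sites: {sorted(missing)[:5]}")
    calls = direction_calls.copy()
    calls["gene"] = calls["site_id"].map(site_to_gene)
    rows = []
    for gene, block in calls.groupby("gene"):
        support = block[(block["pattern"] == "bidirectional")
                        & block["hd_vs_lc_significant"]]
        rows.append((gene, len(block), len(support),
                     len(support) >= min_supporting,
                     ",".join(sorted(support["site_id"])) or "."))
    out = pd.DataFrame(rows, columns=["gene", "n_sites_tested",
                                      "n_bidirectional_significant",
                                      "dystropic", "supporting_sites"])
    return out.sort_values(["n_bidirectional_significant", "gene"],
                           ascending=[False, True]).reset_index(drop=True)


def _majority_sign(logfcs: np.ndarray) -> str:
    pos = int((logfcs > 0).sum())
    neg = int((logfcs < 0).sum())
    if pos > neg:
        return "up"
    if neg > pos:
        return "down"
    return "tie"


def expression_concordance(gene_meth_directions: dict[str, tuple[str, str]],
                           expression: pd.DataFrame) -> pd.DataFrame:
    """Per-gene methylation-vs-expression direction verdicts.

    ``gene_meth_directions``: gene -> (dir_HD, dir_LC) methylation directions
    relative to CON.  ``expression`` needs columns gene, dataset, disease
    (HD/LC), logFC.  Verdicts:

    * inverse-concordant — both diseases: methylation opposite to expression
    * concordant — both diseases: same direction
    * inconsistent — expression datasets disagree (tied vote) for a disease
    * mixed — anything else (incl. flat methylation in a disease)
    * no data — gene absent from the table for at least one disease
    """
    opposite = {"up": "down", "down": "up"}
    rows = []
    for gene, (meth_hd, meth_lc) in gene_meth_directions.items():
        sub = expression[expression["gene"] == gene]
        expr_dir = {}
        for disease in ("HD", "LC"):
            d = sub[sub["disease"] == disease]
            expr_dir[disease] = _majority_sign(d["logFC"].to_numpy(float)) \
                if len(d) else "absent"
        if "absent" in expr_dir.values():
            verdict = "no data"
        elif "tie" in expr_dir.values():
            verdict = "inconsistent"
        else:
            meth = {"HD": meth_hd, "LC": meth_lc}
            inv = [meth[d] in opposite and expr_dir[d] == opposite[meth[d]]
                   for d in ("HD", "LC")]
            same = [meth[d] in opposite and expr_dir[d] == meth[d]
                    for d in ("HD", "LC")]
            if all(inv):
                verdict = "inverse-concordant"
            elif all(same):
                verdict = "concordant"
            else:
                verdict = "mixed"
        rows.append((gene, meth_hd, meth_lc, expr_dir["HD"], expr_dir["LC"],
                     verdict))
    return pd.DataFrame(rows, columns=["gene", "meth_dir_hd", "meth_dir_lc",
                                       "expr_dir_hd", "expr_dir_lc", "verdict"])


def welch_expression_summary(expr: pd.DataFrame, sample_groups: pd.Series,
                             disease: str, dataset: str) -> pd.DataFrame:
    """Two-group Welch t-test + BH on a genes x samples expression matrix.

    Small utility for synthetic tests of the concordance logic; it is not a
    microarray reanalysis.  ``sample_groups`` labels columns of ``expr`` as
    the disease or control; logFC is mean(disease) - mean(control) of the
    (assumed log-scale) values.
    """
    from scipy import stats as sps

    from .dmc import adjust_bh

    case_cols = sample_groups[sample_groups == disease].index
    ctrl_cols = sample_groups[sample_groups != disease].index
    case = expr[case_cols].to_numpy(float)
    ctrl = expr[ctrl_cols].to_numpy(float)
    t, p = sps.ttest_ind(case, ctrl, axis=1, equal_var=False)
    logfc = case.mean(axis=1) - ctrl.mean(axis=1)
    return pd.DataFrame({
        "gene": expr.index, "dataset": dataset, "disease": disease,
        "logFC": logfc, "p": p, "p_adj": adjust_bh(p),
    }).reset_index(drop=True)
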