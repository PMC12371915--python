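"""SNP detection from bisulfite reads, CpG gain/loss and meQTL association.

Bisulfite conversion destroys sequence information: on original-top (OT)
reads every unmethylated C reads as T, on original-bottom (OB) reads (in
reference orientation) every unmethylated-CpG G reads as A.  Variant
evidence is therefore evaluated in *collapsed bisulfite space* per strand
(OT: C folded onto T; OB: G folded onto A); a substitution is informative on
a strand only when its two alleles remain distinct after collapsing.  This
yields the assay's ambiguity classes:

* G/A substitutions — confounded on OB, genotyped from OT reads only;
* C/T substitutions — never genotyped: an observed T can always be an
  unmethylated converted C, so the assay reports them with ambiguity flag
  "both" and no genotype call (an observed C at a reference-T position
  still evidences a *methylated* C allele and is reported as confounded
  allele/methylation evidence);
* all other substitutions — informative on both strands.

A variant whose alternative allele completes or removes a CG dinucleotide
makes the CpG site allele-dependent; methylation at such sites is reported
per allele, with the destroyed allele shown as "site absent" rather than 0%.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calling import AssignmentResult, DEFAULT_MIN_DEPTH
from .panel import AmpliconPanel, AmpliconRegion, VariantLocus, enumerate_cpg_sites

__all__ = [
    "VariantCall",
    "AssociationResult",
    "AlleleMethylation",
    "detect_variants",
    "annotate_cpg_change",
    "allele_aware_methylation",
    "genotype_association",
    "association_scan",
    "write_vcf",
]

# genotype-call thresholds on the alt-allele read fraction
HOM_REF_MAX = 0.15
HET_MIN, HET_MAX = 0.35, 0.65
HOM_ALT_MIN = 0.85
DEFAULT_MIN_ALT_FRACTION = 0.2

_BASES = "ACGT"


def _collapse(base: str, strand: str) -> str:
    if strand == "OT" and base == "C":
        return "T"
    if strand == "OB" and base == "G":
        return "A"
    return base


def informative_strands(ref: str, alt: str) -> tuple[str, ...]:
    """Strands on which the ref/alt pair survives bisulfite collapsing.

    C/T pairs are treated as uninformative on both strands (the assay's
    stated caveat), although collapsing alone would leave OB informative.
    """
    if {ref, alt} == {"C", "T"}:
        return ()
    return tuple(s for s in ("OT", "OB")
                 if _collapse(ref, s) != _collapse(alt, s))


def ambiguity_flag(ref: str, alt: str) -> str | None:
    strands = informative_strands(ref, alt)
    if len(strands) == 2:
        return None
    if not strands:
        return "both"
    return "OB" if strands == ("OT",) else "OT"


@dataclass
class VariantCall:
    region_id: str
    offset: int  # 0-based
    ref: str
    alt: str
    ambiguity: str | None
    cpg_effect: str
    per_sample: pd.DataFrame  # index sample_id; ref_count, alt_count, genotype
    rs_label: str | None = None
    possible_polymerase_error: bool = False

    @property
    def variant_id(self) -> str:
        return f"{self.region_id}:{self.offset}{self.ref}>{self.alt}"

    @property
    def n_carrier_samples(self) -> int:
        g = self.per_sample["genotype"]
        return int(((g == "0/1") | (g == "1/1")).sum())


def _pileup(result: AssignmentResult, panel: AmpliconPanel):
    """counts[region][strand] = (sample x position x base) tensors."""
    samples = sorted({a.sample_id for a in result.assignments})
    s_idx = {s: i for i, s in enumerate(samples)}
    b_idx = {b: i for i, b in enumerate(_BASES)}
    piles = {rid: {st: np.zeros((len(samples), len(panel.regions[rid]), 4), int)
                   for st in ("OT", "OB")} for rid in panel.regions}
    for a in result.assignments:
        tensor = piles[a.region_id][a.strand]
        i = s_idx[a.sample_id]
        for k, base in enumerate(a.sequence):
            j = b_idx.get(base)
            if j is not None:
                tensor[i, a.offset + k, j] += 1
    return piles, samples


def _genotype(af: float, depth: int, min_depth: int) -> str:
    if depth < min_depth or not np.isfinite(af):
        return "./."
    if af < HOM_REF_MAX:
        return "0/0"
    if HET_MIN <= af <= HET_MAX:
        return "0/1"
    if af > HOM_ALT_MIN:
        return "1/1"
    return "./."


def _support_counts(piles_region, samples, pos, ref, alt):
    """(ref_counts, alt_counts) per sample over informative strands."""
    b_idx = {b: i for i, b in enumerate(_BASES)}
    strands = informative_strands(ref, alt)
    ref_n = np.zeros(len(samples), int)
    alt_n = np.zeros(len(samples), int)
    if not strands and {ref, alt} == {"C", "T"}:
        # confounded pair: raw descriptive counts; obs C evidences a
        # methylated C allele, obs T is ref-or-converted-C
        c_allele = "C"
        t_allele = "T"
        for st in ("OT", "OB"):
            obs = piles_region[st][:, pos, :]
            alt_col = obs[:, b_idx[c_allele if alt == "C" else t_allele]]
            ref_col = obs[:, b_idx[t_allele if alt == "C" else c_allele]]
            alt_n += alt_col
            ref_n += ref_col
        return ref_n, alt_n
    for st in strands:
        obs = piles_region[st][:, pos, :]
        ref_n += obs[:, b_idx[_collapse(ref, st)]]
        alt_n += obs[:, b_idx[_collapse(alt, st)]]
    return ref_n, alt_n


def detect_variants(
    result: AssignmentResult,
    panel: AmpliconPanel,
    min_alt_fraction: float = DEFAULT_MIN_ALT_FRACTION,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> list[VariantCall]:
    """Scan every amplicon position for non-reference alleles.

    A position is called when, in at least one sample, the alt-supporting
    fraction among informative reads reaches ``min_alt_fraction`` at
    informative depth >= ``min_depth``.  Reference-C positions with T-only
    evidence are never called (the conversion explanation wins); T-to-C
    candidates are reported with ambiguity "both" and genotype no-call.
    Variants carried by exactly one sample are flagged as possible
    polymerase errors and excluded from association by default.
    """
    piles, samples = _pileup(result, panel)
    known = {(v.region_id, v.offset): v for v in panel.variants}
    calls: list[VariantCall] = []
    for rid, region in panel.regions.items():
        pr = piles[rid]
        for pos, ref in enumerate(region.sequence):
            best = None
            for alt in _BASES:
                if alt == ref:
                    continue
                if ref == "C" and alt == "T":
                    continue  # indistinguishable from conversion
                ref_n, alt_n = _support_counts(pr, samples, pos, ref, alt)
                depth = ref_n + alt_n
                with np.errstate(invalid="ignore"):
                    af = np.where(depth > 0, alt_n / np.maximum(depth, 1), np.nan)
                hit = (depth >= min_depth) & (af >= min_alt_fraction)
                if not hit.any():
                    continue
                score = int(alt_n.sum())
                if best is None or score > best[0]:
                    best = (score, alt, ref_n, alt_n, depth, af)
            if best is None:
                continue
            _, alt, ref_n, alt_n, depth, af = best
            amb = ambiguity_flag(ref, alt)
            if amb == "both":
                genotypes = ["./."] * len(samples)
            else:
                genotypes = [_genotype(af[i], int(depth[i]), min_depth)
                             for i in range(len(samples))]
            per_sample = pd.DataFrame(
                {"ref_count": ref_n, "alt_count": alt_n, "genotype": genotypes},
                index=pd.Index(samples, name="sample_id"))
            known_v = known.get((rid, pos))
            locus = VariantLocus(rid, pos, ref, alt,
                                 rs_label=known_v.rs_label if known_v else None)
            effect = annotate_cpg_change(locus, region)
            if amb == "both":
                n_carriers = int(((af >= min_alt_fraction)
                                  & (depth >= min_depth)).sum())
            else:
                n_carriers = int(((per_sample["genotype"] == "0/1")
                                  | (per_sample["genotype"] == "1/1")).sum())
            calls.append(VariantCall(
                rid, pos, ref, alt, amb, effect, per_sample,
                rs_label=locus.rs_label,
                possible_polymerase_error=(n_carriers == 1)))
    return calls


def annotate_cpg_change(variant: VariantLocus, region: AmpliconRegion) -> str:
    """creates / destroys / neutral, by re-deriving CGs in the +/-1 bp window.

    A substitution next to a retained CpG is neutral unless the CG
    dinucleotide itself changes; when one CG is lost and another gained in
    the window the net effect is neutral.
    """
    if not 0 <= variant.offset < len(region):
        raise ValueError(f"variant offset {variant.offset} outside region "
                         f"{region.region_id!r}")
    seq = region.sequence
    alt_seq = seq[:variant.offset] + variant.alt_allele + seq[variant.offset + 1:]
    lo = max(0, variant.offset - 1)
    hi = min(len(seq) - 1, variant.offset + 1)
    ref_cg = {p for p in range(lo, hi + 1) if seq[p:p + 2] == "CG"}
    alt_cg = {p for p in range(lo, hi + 1) if alt_seq[p:p + 2] == "CG"}
    if len(alt_cg) > len(ref_cg):
        return "creates"
    if len(alt_cg) < len(ref_cg):
        return "destroys"
    return "neutral"


@dataclass
class AlleleMethylation:
    allele: str
    site_absent: bool
    meth: int = 0
    total: int = 0

    @property
    def percent(self) -> float | None:
        if self.site_absent or self.total == 0:
            return None
        return 100.0 * self.meth / self.total


def allele_aware_methylation(
    result: AssignmentResult,
    panel: AmpliconPanel,
    variant: VariantLocus,
    site_id: str,
    min_depth: int = DEFAULT_MIN_DEPTH,
    sample_ids=None,
) -> tuple[dict[str, AlleleMethylation], Counter]:
    """Methylation of a linked CpG partitioned by the allele a read carries.

    Reads must span both the variant and the site and lie on a strand
    informative for the allele pair; others are counted in the returned log.
    An allele on which the CG dinucleotide does not exist is reported as
    site absent (not 0%).  Alleles with fewer than ``min_depth`` informative
    reads have ``total`` reported but percent of low confidence; callers may
    filter on ``total``.
    """
    site = panel.get_site(site_id)
    if site.region_id != variant.region_id:
        raise ValueError("variant and site must lie on the same amplicon")
    region = panel.regions[variant.region_id]
    strands = informative_strands(variant.ref_allele, variant.alt_allele)
    log: Counter = Counter()

    seqs = {
        variant.ref_allele: region.sequence,
        variant.alt_allele: region.sequence[:variant.offset]
        + variant.alt_allele + region.sequence[variant.offset + 1:],
    }
    present = {a: s[site.offset:site.offset + 2] == "CG" for a, s in seqs.items()}
    out = {a: AlleleMethylation(a, site_absent=not present[a])
           for a in (variant.ref_allele, variant.alt_allele)}

    for a in result.assignments:
        if a.region_id != variant.region_id:
            continue
        if sample_ids is not None and a.sample_id not in sample_ids:
            continue
        if a.strand not in strands:
            log["uninformative_strand"] += 1
            continue
        lo, hi = a.offset, a.offset + len(a.sequence)
        site_pos = site.offset if a.strand == "OT" else site.offset + 1
        if not (lo <= variant.offset < hi and lo <= site_pos < hi):
            log["not_spanning"] += 1
            continue
        obs = a.sequence[variant.offset - lo]
        allele = None
        for cand in (variant.ref_allele, variant.alt_allele):
            if obs == _collapse(cand, a.strand):
                allele = cand
        if allele is None:
            log["allele_unresolved"] += 1
            continue
        est = out[allele]
        if est.site_absent:
            log[f"site_absent_{allele}"] += 1
            continue
        base = a.sequence[site_pos - lo]
        meth_base, unmeth_base = ("C", "T") if a.strand == "OT" else ("G", "A")
        if base == meth_base:
            est.meth += 1
            est.total += 1
        elif base == unmeth_base:
            est.total += 1
        else:
            log["site_base_ignored"] += 1
    for est in out.values():
        if not est.site_absent and est.total < min_depth:
            log[f"low_depth_{est.allele}"] += 1
    return out, log


@dataclass
class AssociationResult:
    site_id: str
    variant_id: str
    classes: dict[str, tuple[int, float]]  # genotype -> (n, median)
    kw_p: float | None
    pairwise: dict[tuple[str, str], tuple[float, str]] = field(default_factory=dict)
    kw_mode: str = "normal_approx"
    testable: bool = True
    reason: str = ""


def _mw_p(x: np.ndarray, y: np.ndarray) -> tuple[float, str]:
    """Two-sided Mann-Whitney p: exact when small and tie-free, else
    tie-corrected normal approximation."""
    combined = np.concatenate([x, y])
    ties = len(np.unique(combined)) < len(combined)
    if len(combined) <= 20 and not ties:
        mode = "exact"
    else:
        mode = "normal_approx"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if mode == "exact" else "asymptotic")
    return float(res.pvalue), mode


def genotype_association(methylation: pd.Series,
                         genotypes: pd.Series,
                         site_id: str = "",
                         variant_id: str = "") -> AssociationResult:
    """Kruskal-Wallis across genotype classes + pairwise Mann-Whitney tests."""
    m, g = methylation.align(genotypes, join="inner")
    keep = m.notna() & g.notna() & (g != "./.")
    m, g = m[keep].astype(float), g[keep]
    classes = {}
    values = {}
    for cls in sorted(g.unique()):
        v = m[g == cls].to_numpy()
        values[cls] = v
        classes[cls] = (len(v), float(np.median(v)) if len(v) else np.nan)
    big = [cls for cls, (n, _) in classes.items() if n >= 2]
    if len(classes) < 2:
        return AssociationResult(site_id, variant_id, classes, None,
                                 testable=False, reason="single genotype class")
    kw_p = None
    kw_mode = "normal_approx"
    if len(big) >= 2:
        samples = [values[c] for c in big]
        if np.ptp(np.concatenate(samples)) == 0:
            # identical values carry no rank information
            return AssociationResult(site_id, variant_id, classes, 1.0,
                                     {pair: (1.0, "degenerate")
                                      for pair in [(a, b) for i, a in
                                                   enumerate(sorted(values))
                                                   for b in sorted(values)[i + 1:]]},
                                     kw_mode="degenerate")
        try:
            if sum(len(v) for v in samples) <= 12:
                # exact permutation distribution of the KW statistic
                kw_mode = "exact"

                def _h(*s, axis):
                    return stats.kruskal(*s, axis=axis).statistic

                res = stats.permutation_test(
                    samples, _h, vectorized=True,
                    permutation_type="independent", alternative="greater",
                    n_resamples=np.inf)
                kw_p = float(res.pvalue)
            else:
                kw_p = float(stats.kruskal(*samples).pvalue)
        except ValueError:  # all values identical across classes
            kw_p = 1.0
    pairwise = {}
    keys = sorted(values)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a, b = keys[i], keys[j]
            if len(values[a]) >= 1 and len(values[b]) >= 1:
                try:
                    pairwise[(a, b)] = _mw_p(values[a], values[b])
                except ValueError:
                    pairwise[(a, b)] = (1.0, "degenerate")
    return AssociationResult(site_id, variant_id, classes, kw_p, pairwise,
                             kw_mode=kw_mode,
                             testable=kw_p is not None or bool(pairwise),
                             reason="" if kw_p is not None else "too few samples")


def association_scan(percent: pd.DataFrame, call: VariantCall,
                     sample_sheet: pd.DataFrame,
                     sites: list[str] | None = None) -> pd.DataFrame:
    """Genotype-methylation association per group and pooled.

    Runs ``genotype_association`` of every site (default: sites of the
    variant's region) against the variant's genotypes, within each study
    group and over the pooled cohort.
    """
    geno = call.per_sample["genotype"]
    if sites is None:
        sites = [c for c in percent.columns
                 if c.split(":", 1)[0] == call.region_id]
    rows = []
    scopes = [("pooled", percent.index)]
    for grp in sorted(sample_sheet["group"].unique()):
        scopes.append((grp, sample_sheet[sample_sheet["group"] == grp].index))
    for sid in sites:
        for scope, idx in scopes:
            idx = [i for i in idx if i in percent.index]
            res = genotype_association(percent.loc[idx, sid], geno.loc[idx],
                                       site_id=sid, variant_id=call.variant_id)
            rows.append((sid, call.variant_id, scope,
                         res.kw_p if res.testable else np.nan,
                         ";".join(f"{a}|{b}={p:.3g}({mode})"
                                  for (a, b), (p, mode) in res.pairwise.items())
                         or ".",
                         res.testable, res.reason))
    return pd.DataFrame(rows, columns=["site_id", "variant_id", "scope",
                                       "kw_p", "pairwise_mw", "testable",
                                       "reason"])


def write_vcf(calls: list[VariantCall], panel: AmpliconPanel, path,
              header_comment: str | None = None) -> None:
    """Minimal VCF: CHROM = region_id, POS 1-based within the region."""
    samples = sorted(set().union(
        *[set(c.per_sample.index) for c in calls])) if calls else []
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if header_comment:
            fh.write(f"##amplimeth={header_comment}\n")
        fh.write('##INFO=<ID=AMB,Number=1,Type=String,'
                 'Description="Bisulfite ambiguity strand scope">\n')
        fh.write('##INFO=<ID=CPG,Number=1,Type=String,'
                 'Description="Effect on CpG sites">\n')
        fh.write('##INFO=<ID=SINGLETON,Number=0,Type=Flag,'
                 'Description="Possible polymerase error (one carrier)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for rid, region in panel.regions.items():
            fh.write(f"##contig=<ID={rid},length={len(region)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for c in sorted(calls, key=lambda c: (c.region_id, c.offset)):
            info = [f"AMB={c.ambiguity or 'none'}", f"CPG={c.cpg_effect}"]
            if c.possible_polymerase_error:
                info.append("SINGLETON")
            gts = "\t".join(
                c.per_sample["genotype"].get(s, "./.").replace("/", "/")
                for s in samples)
            fh.write(f"{c.region_id}\t{c.offset + 1}\t{c.rs_label or '.'}\t"
                     f"{c.ref}\t{c.alt}\t.\tPASS\t{';'.join(info)}\tGT\t{gts}\n")
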