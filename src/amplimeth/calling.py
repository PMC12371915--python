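"""Bisulfite read assignment and per-CpG methylation calling.

Reads are assigned to amplicons by bisulfite-aware comparison: a read is
slid across each region on both bisulfite strands and scored by mismatches,
where C-in-reference vs T-in-read (original-top, OT) and G-in-reference vs
A-in-read (original-bottom, OB) differences are conversion-explainable and
not counted.  The methylation level of a CpG site is the percentage of reads
carrying methylated cytosine among all cytosine-informative reads at that
position: on OT reads the C of the CpG (C = methylated, T = unmethylated),
on OB reads the paired G (G = methylated, A = unmethylated); evidence from
both strands is pooled onto the forward-strand site.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .panel import AmpliconPanel

__all__ = [
    "ReadAssignment",
    "AssignmentResult",
    "MethylationMatrix",
    "assign_reads",
    "call_methylation",
    "conversion_qc",
]

_C, _G, _T, _A = (ord(b) for b in "CGTA")

DEFAULT_MIN_DEPTH = 10
DEFAULT_MAX_MISMATCH_RATE = 0.1
DEFAULT_MIN_READ_LENGTH = 30


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    sample_id: str
    region_id: str
    strand: str  # OT | OB
    offset: int  # alignment start within the region
    mismatches: int
    sequence: str


@dataclass
class AssignmentResult:
    assignments: list[ReadAssignment]
    discarded: Counter = field(default_factory=Counter)

    def by_sample(self) -> dict[str, list[ReadAssignment]]:
        out: dict[str, list[ReadAssignment]] = {}
        for a in self.assignments:
            out.setdefault(a.sample_id, []).append(a)
        return out


def _read_fastq(path) -> Iterable[tuple[str, str]]:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            yield header[1:].strip().split()[0], seq


def _mismatch_profile(windows: np.ndarray, strand: str, reads: np.ndarray):
    """Bisulfite-aware mismatch counts: reads (n, L) vs windows (m, L)."""
    diff = reads[:, None, :] != windows[None, :, :]
    if strand == "OT":
        allowed = (windows == _C)[None, :, :] & (reads == _T)[:, None, :]
    else:
        allowed = (windows == _G)[None, :, :] & (reads == _A)[:, None, :]
    return (diff & ~allowed).sum(axis=2)


def assign_reads(
    fastq_by_sample: Mapping[str, object],
    panel: AmpliconPanel,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
    min_read_length: int = DEFAULT_MIN_READ_LENGTH,
    chunk: int = 512,
) -> AssignmentResult:
    """Assign each read to the (region, strand, offset) minimising
    bisulfite-aware mismatches.

    Reads whose best mismatch rate exceeds ``max_mismatch_rate`` are
    discarded ("high_mismatch"); reads whose best score is tied between two
    regions are discarded as "ambiguous"; reads shorter than
    ``min_read_length`` are discarded as "too_short".  Within a region, ties
    across strand/offset resolve deterministically (OT first, lowest offset).
    """
    refs = {rid: np.frombuffer(r.sequence.encode(), dtype=np.uint8)
            for rid, r in panel.regions.items()}

    result = AssignmentResult([])
    window_cache: dict[tuple[str, int], np.ndarray] = {}

    for sample_id, path in fastq_by_sample.items():
        by_len: dict[int, list[tuple[str, str]]] = {}
        for read_id, seq in _read_fastq(path):
            if len(seq) < min_read_length:
                result.discarded["too_short"] += 1
                continue
            by_len.setdefault(len(seq), []).append((read_id, seq))

        for L, items in by_len.items():
            usable = [(rid, ref) for rid, ref in refs.items() if ref.size >= L]
            if not usable:
                result.discarded["no_region_long_enough"] += len(items)
                continue
            for lo in range(0, len(items), chunk):
                batch = items[lo:lo + chunk]
                reads = np.frombuffer(
                    "".join(s for _, s in batch).encode(), dtype=np.uint8
                ).reshape(len(batch), L)

                cand_keys: list[tuple[str, str]] = []
                cand_m: list[np.ndarray] = []
                cand_off: list[np.ndarray] = []
                for rid, ref in usable:
                    key = (rid, L)
                    if key not in window_cache:
                        window_cache[key] = np.lib.stride_tricks.sliding_window_view(
                            refs[rid], L)
                    windows = window_cache[key]
                    for strand in ("OT", "OB"):
                        mm = _mismatch_profile(windows, strand, reads)
                        cand_keys.append((rid, strand))
                        cand_m.append(mm.min(axis=1))
                        cand_off.append(mm.argmin(axis=1))

                M = np.stack(cand_m)            # (n_candidates, n_reads)
                O = np.stack(cand_off)
                order = np.argsort(M, axis=0, kind="stable")
                best_idx = order[0]
                best = M[best_idx, np.arange(len(batch))]
                # best score achieved in any *other* region (for tie discard)
                regions_arr = np.array([k[0] for k in cand_keys])
                other_best = np.full(len(batch), np.iinfo(np.int32).max)
                for c in range(len(cand_keys)):
                    differs = regions_arr[best_idx] != regions_arr[c]
                    other_best[differs] = np.minimum(other_best[differs],
                                                     M[c][differs])

                for i, (read_id, seq) in enumerate(batch):
                    if best[i] / L > max_mismatch_rate:
                        result.discarded["high_mismatch"] += 1
                        continue
                    if other_best[i] == best[i]:
                        result.discarded["ambiguous"] += 1
                        continue
                    rid, strand = cand_keys[best_idx[i]]
                    result.assignments.append(ReadAssignment(
                        read_id, sample_id, rid, strand,
                        int(O[best_idx[i], i]), int(best[i]), seq))
    return result


@dataclass
class MethylationMatrix:
    """Per-sample x per-site methylated / informative read counts.

    ``percent`` is 100 * methylated / total where total >= min_depth, NaN
    (missing) otherwise.  A site with zero covering reads is missing, never
    0%.
    """

    meth: pd.DataFrame
    total: pd.DataFrame
    min_depth: int = DEFAULT_MIN_DEPTH

    def __post_init__(self):
        if (self.meth.to_numpy() > self.total.to_numpy()).any():
            raise ValueError("methylated count exceeds total count")
        if (self.meth.to_numpy() < 0).any() or (self.total.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def percent(self) -> pd.DataFrame:
        total = self.total.to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.meth.to_numpy(float) / total
        pct[total < self.min_depth] = np.nan
        return pd.DataFrame(pct, index=self.meth.index, columns=self.meth.columns)

    def to_long(self) -> pd.DataFrame:
        pct = self.percent
        rows = []
        for sid in self.meth.columns:
            region, site = sid.split(":", 1)
            for sample in self.meth.index:
                rows.append((sample, region, site,
                             int(self.meth.at[sample, sid]),
                             int(self.total.at[sample, sid]),
                             round(float(pct.at[sample, sid]), 2)
                             if np.isfinite(pct.at[sample, sid]) else np.nan))
        return pd.DataFrame(rows, columns=["sample_id", "region_id", "site",
                                           "meth_count", "total", "percent"])

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_long().to_csv(fh, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path, min_depth: int = DEFAULT_MIN_DEPTH) -> "MethylationMatrix":
        table = pd.read_csv(path, sep="\t", comment="#")
        table["site_id"] = table["region_id"] + ":" + table["site"]
        meth = table.pivot(index="sample_id", columns="site_id", values="meth_count")
        total = table.pivot(index="sample_id", columns="site_id", values="total")
        return cls(meth.fillna(0).astype(int), total.fillna(0).astype(int),
                   min_depth=min_depth)


def _excluded_site_offsets(panel: AmpliconPanel, region_id: str) -> set[int]:
    """Sites whose C or G coincides with a variant locus.

    Methylation at such positions is allele-confounded and handled by
    allele-aware calling; they are missing in the plain matrix.
    """
    var_offsets = {v.offset for v in panel.variants_in(region_id)}
    out = set()
    for s in panel.sites[region_id]:
        if s.offset in var_offsets or s.offset + 1 in var_offsets:
            out.add(s.offset)
    return out


def call_methylation(
    result: AssignmentResult,
    panel: AmpliconPanel,
    min_depth: int = DEFAULT_MIN_DEPTH,
    samples: Iterable[str] | None = None,
) -> MethylationMatrix:
    """Pool strand evidence into the per-sample x per-CpG methylation matrix."""
    if not result.assignments and samples is None:
        raise ValueError("no assignments to call from")

    site_ids = panel.site_ids()
    col = {sid: j for j, sid in enumerate(site_ids)}
    sample_list = sorted({a.sample_id for a in result.assignments}
                         if samples is None else set(samples))
    row = {s: i for i, s in enumerate(sample_list)}
    meth = np.zeros((len(sample_list), len(site_ids)), dtype=int)
    total = np.zeros_like(meth)

    site_info: dict[str, list[tuple[int, int]]] = {}
    for rid in panel.regions:
        excluded = _excluded_site_offsets(panel, rid)
        site_info[rid] = [
            (s.offset, col[panel.site_id(s)])
            for s in panel.sites[rid]
            if s.offset not in excluded and not s.allele_dependent
        ]

    for a in result.assignments:
        seq = a.sequence
        end = a.offset + len(seq)
        i = row[a.sample_id]
        for off, j in site_info[a.region_id]:
            pos = off if a.strand == "OT" else off + 1
            if not (a.offset <= pos < end):
                continue
            base = seq[pos - a.offset]
            if a.strand == "OT":
                if base == "C":
                    meth[i, j] += 1
                    total[i, j] += 1
                elif base == "T":
                    total[i, j] += 1
            else:
                if base == "G":
                    meth[i, j] += 1
                    total[i, j] += 1
                elif base == "A":
                    total[i, j] += 1

    return MethylationMatrix(
        pd.DataFrame(meth, index=sample_list, columns=site_ids),
        pd.DataFrame(total, index=sample_list, columns=site_ids),
        min_depth=min_depth,
    )


def conversion_qc(
    result: AssignmentResult,
    panel: AmpliconPanel,
    qc_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-sample non-CpG cytosine retention rate (conversion failure QC).

    Non-CpG cytosines are unmethylated in somatic tissue, so retained Cs on
    OT reads (and retained Gs on OB reads) measure incomplete conversion.
    Samples with retention above ``qc_threshold`` are flagged.
    """
    import warnings

    noncpg: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    any_c = False
    for rid, region in panel.regions.items():
        seq = region.sequence
        cpg_c = {s.offset for s in panel.sites[rid]}
        var = {v.offset for v in panel.variants_in(rid)}
        c_pos = np.array([i for i, b in enumerate(seq)
                          if b == "C" and i not in cpg_c and i not in var],
                         dtype=int)
        g_pos = np.array([i for i, b in enumerate(seq)
                          if b == "G" and (i - 1) not in cpg_c and i not in var],
                         dtype=int)
        noncpg[rid] = (c_pos, g_pos)
        any_c = any_c or c_pos.size > 0
    if not any_c:
        warnings.warn("panel has no non-CpG cytosines: conversion QC unavailable")

    retained: Counter = Counter()
    converted: Counter = Counter()
    for a in result.assignments:
        c_pos, g_pos = noncpg[a.region_id]
        pos = c_pos if a.strand == "OT" else g_pos
        ret_base, conv_base = ("C", "T") if a.strand == "OT" else ("G", "A")
        lo, hi = a.offset, a.offset + len(a.sequence)
        for p in pos[(pos >= lo) & (pos < hi)]:
            base = a.sequence[p - lo]
            if base == ret_base:
                retained[a.sample_id] += 1
            elif base == conv_base:
                converted[a.sample_id] += 1

    rows = []
    for sample in sorted(set(retained) | set(converted)):
        tot = retained[sample] + converted[sample]
        rate = retained[sample] / tot if tot else np.nan
        rows.append((sample, retained[sample], tot, rate,
                     bool(tot and rate > qc_threshold)))
    return pd.DataFrame(rows, columns=["sample_id", "retained", "observations",
                                       "retention_rate", "flagged"])
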