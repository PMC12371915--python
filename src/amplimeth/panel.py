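"""Amplicon panel data model.

An amplicon panel is the set of reference regions targeted by a bisulfite
amplicon sequencing (BSAS) assay, together with the CpG sites they contain,
known variant loci, and CpG-island (CGI) context.  Coordinates are 0-based
half-open internally (BED convention); human-readable reports use 1-based
inclusive positions.

CpG sites are indexed by the forward-strand C of the palindromic CG
dinucleotide; methylation evidence from both bisulfite strands is folded onto
this single site downstream.  A variant whose alternative allele completes a
CG dinucleotide yields an *allele-dependent* site: one that exists only on
chromosomes carrying that allele (e.g. a T/G substitution immediately after a
cytosine creates a new CpG on the G allele).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "AmpliconRegion",
    "CpGSite",
    "CgiAnnotation",
    "VariantLocus",
    "AmpliconPanel",
    "enumerate_cpg_sites",
    "annotate_cgi_context",
    "load_panel",
]

_DNA = set("ACGT")

# CGI context radii in bp: shore within (0, SHORE]; shelf within (SHORE, SHELF].
SHORE_BP = 2000
SHELF_BP = 4000


class PanelError(ValueError):
    """Malformed panel input (FASTA/BED/variant table or inconsistent model)."""


@dataclass(frozen=True)
class AmpliconRegion:
    """One targeted reference region (amplicon) of the panel."""

    region_id: str
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    sequence: str
    gene: str = ""
    strand: str = "+"

    def __post_init__(self):
        if not self.sequence:
            raise PanelError(f"empty region: {self.region_id!r}")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if set(seq) - _DNA:
            bad = sorted(set(seq) - _DNA)
            raise PanelError(f"region {self.region_id!r}: non-ACGT characters {bad}")
        if self.end <= self.start:
            raise PanelError(f"region {self.region_id!r}: end must exceed start")
        if self.end - self.start != len(seq):
            raise PanelError(
                f"region {self.region_id!r}: interval length {self.end - self.start} "
                f"!= sequence length {len(seq)}"
            )
        if self.strand not in {"+", "-"}:
            raise PanelError(f"region {self.region_id!r}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CpGSite:
    """A CpG dinucleotide anchored at the forward-strand C.

    ``site_index`` is a 1-based ordinal, strictly increasing with ``offset``
    over all sites of the region (reference and allele-dependent together).
    ``label`` follows assay convention: reference sites are "CpG_k" by
    reference ordinal; a site created by a variant between reference sites k
    and k+1 is "CpG_k-1" (then "CpG_k-2", ...).
    """

    region_id: str
    site_index: int
    offset: int  # 0-based position of the C within the region
    label: str
    context: str = "open_sea"  # island | shore | shelf | open_sea
    allele_dependent: bool = False


@dataclass
class CgiAnnotation:
    """CpG-island intervals (0-based half-open), merged per chromosome."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        merged: dict[str, list[list[int]]] = {}
        for chrom, start, end in self.intervals:
            if end <= start:
                raise PanelError(f"CGI interval on {chrom}: start {start} >= end {end}")
            merged.setdefault(chrom, []).append([start, end])
        out: list[tuple[str, int, int]] = []
        for chrom in sorted(merged):
            ivs = sorted(merged[chrom])
            acc = [ivs[0]]
            for s, e in ivs[1:]:
                if s <= acc[-1][1]:
                    acc[-1][1] = max(acc[-1][1], e)
                else:
                    acc.append([s, e])
            out.extend((chrom, s, e) for s, e in acc)
        self.intervals = out

    def distance(self, chrom: str, pos: int) -> int | None:
        """bp separating ``pos`` from the nearest island on ``chrom``.

        0 if inside an island; None if the chromosome has no islands.  For a
        position right of an island [s, e), the distance is pos - (e - 1),
        i.e. the number of steps from the last island base.
        """
        best = None
        for c, s, e in self.intervals:
            if c != chrom:
                continue
            if s <= pos < e:
                return 0
            d = s - pos if pos < s else pos - (e - 1)
            best = d if best is None else min(best, d)
        return best


@dataclass(frozen=True)
class VariantLocus:
    """A known single-nucleotide substitution inside an amplicon."""

    region_id: str
    offset: int
    ref_allele: str
    alt_allele: str
    rs_label: str | None = None
    cpg_effect: str = "neutral"  # creates | destroys | adjacent_modifier | neutral

    def __post_init__(self):
        for name in ("ref_allele", "alt_allele"):
            a = getattr(self, name)
            if len(a) != 1 or a not in _DNA:
                raise PanelError(f"variant {self.variant_id}: bad {name} {a!r}")
        if self.ref_allele == self.alt_allele:
            raise PanelError(f"variant {self.variant_id}: ref == alt")

    @property
    def variant_id(self) -> str:
        return f"{self.region_id}:{self.offset}{self.ref_allele}>{self.alt_allele}"

    @property
    def bisulfite_ambiguity(self) -> str | None:
        """Strand scope on which this substitution is confounded with conversion.

        C/T pairs are indistinguishable from bisulfite conversion ("both");
        G/A pairs are confounded only on the original-bottom strand ("OB"),
        so they remain genotypeable from original-top reads.
        """
        pair = {self.ref_allele, self.alt_allele}
        if pair == {"C", "T"}:
            return "both"
        if pair == {"G", "A"}:
            return "OB"
        return None

    @property
    def bisulfite_ambiguous(self) -> bool:
        return self.bisulfite_ambiguity is not None


def _ref_cg_offsets(sequence: str) -> list[int]:
    return [m.start() for m in re.finditer("(?=CG)", sequence)]


def _apply_allele(sequence: str, offset: int, base: str) -> str:
    return sequence[:offset] + base + sequence[offset + 1:]


def enumerate_cpg_sites(
    region: AmpliconRegion,
    variants: Sequence[VariantLocus] = (),
    allele: str = "ref",
) -> list[CpGSite]:
    """Enumerate CpG sites of a region, ordered by offset.

    Every CG dinucleotide on the forward strand of the reference yields a
    site.  For each variant whose alternative allele completes a CG absent
    from the reference, an ``allele_dependent`` site is added at the C of the
    new dinucleotide.  With ``allele="alt"`` the enumeration is done on the
    sequence with all alt alleles applied instead (used for allele-aware
    analyses); allele-dependent labelling still refers to the reference
    numbering.
    """
    if not region.sequence:  # pragma: no cover - guarded by AmpliconRegion
        raise PanelError("empty region")
    for v in variants:
        if v.region_id != region.region_id:
            raise PanelError(
                f"variant {v.variant_id} does not belong to region {region.region_id!r}")
        if not (0 <= v.offset < len(region)):
            raise PanelError(f"variant {v.variant_id}: offset out of range")
        if region.sequence[v.offset] != v.ref_allele:
            raise PanelError(
                f"variant {v.variant_id}: reference base is "
                f"{region.sequence[v.offset]!r}, not {v.ref_allele!r}")

    ref_offsets = _ref_cg_offsets(region.sequence)
    ref_set = set(ref_offsets)

    extra: list[int] = []
    if allele == "ref":
        for v in variants:
            alt_seq = _apply_allele(region.sequence, v.offset, v.alt_allele)
            for off in range(max(0, v.offset - 1), min(len(region) - 1, v.offset) + 1):
                if alt_seq[off:off + 2] == "CG" and off not in ref_set:
                    extra.append(off)
    elif allele == "alt":
        seq = region.sequence
        for v in variants:
            seq = _apply_allele(seq, v.offset, v.alt_allele)
        ref_offsets = _ref_cg_offsets(seq)
        ref_set = set(ref_offsets)
    else:
        raise ValueError("allele must be 'ref' or 'alt'")

    merged = sorted(set(ref_offsets) | set(extra))
    sites: list[CpGSite] = []
    n_ref_before = 0
    sub = 0
    for i, off in enumerate(merged, start=1):
        if off in ref_set and off not in extra:
            n_ref_before += 1
            sub = 0
            label = f"CpG_{n_ref_before}"
            dep = False
        else:
            sub += 1
            label = f"CpG_{n_ref_before}-{sub}"
            dep = True
        sites.append(CpGSite(region.region_id, i, off, label, allele_dependent=dep))
    return sites


def annotate_cgi_context(chrom: str, abs_pos: int, cgi: CgiAnnotation) -> str:
    """Label a genomic position: island, shore (<=2 kb), shelf (2-4 kb), open_sea."""
    d = cgi.distance(chrom, abs_pos)
    if d is None:
        return "open_sea"
    if d == 0:
        return "island"
    if d <= SHORE_BP:
        return "shore"
    if d <= SHELF_BP:
        return "shelf"
    return "open_sea"


class AmpliconPanel:
    """Immutable collection of regions, sites, variants and CGI context."""

    def __init__(
        self,
        regions: Iterable[AmpliconRegion],
        cgi: CgiAnnotation | None = None,
        variants: Iterable[VariantLocus] = (),
        x_linked: Iterable[str] = (),
    ):
        self.regions: dict[str, AmpliconRegion] = {}
        for r in regions:
            if r.region_id in self.regions:
                raise PanelError(f"duplicate region_id {r.region_id!r}")
            self.regions[r.region_id] = r
        self.cgi = cgi or CgiAnnotation()
        self.variants: list[VariantLocus] = list(variants)
        for v in self.variants:
            if v.region_id not in self.regions:
                raise PanelError(f"variant {v.variant_id}: unknown region")
        self.x_linked = set(x_linked)
        unknown = self.x_linked - set(self.regions)
        if unknown:
            raise PanelError(f"x_linked region ids not in panel: {sorted(unknown)}")
        self.sites: dict[str, list[CpGSite]] = {}
        for rid, region in self.regions.items():
            rvars = [v for v in self.variants if v.region_id == rid]
            sites = enumerate_cpg_sites(region, rvars)
            self.sites[rid] = [
                replace(s, context=annotate_cgi_context(
                    region.chrom, region.start + s.offset, self.cgi))
                for s in sites
            ]

    def variants_in(self, region_id: str) -> list[VariantLocus]:
        return [v for v in self.variants if v.region_id == region_id]

    def site_id(self, site: CpGSite) -> str:
        return f"{site.region_id}:{site.label}"

    def all_sites(self) -> list[CpGSite]:
        return [s for rid in self.regions for s in self.sites[rid]]

    def site_ids(self) -> list[str]:
        return [self.site_id(s) for s in self.all_sites()]

    def get_site(self, site_id: str) -> CpGSite:
        rid, label = site_id.split(":", 1)
        for s in self.sites[rid]:
            if s.label == label:
                return s
        raise KeyError(site_id)

    # ---- serialization --------------------------------------------------

    def to_files(self, fasta_path, bed_cgi_path, variants_path) -> None:
        with open(fasta_path, "w") as fh:
            for r in self.regions.values():
                fh.write(
                    f">{r.region_id}|{r.gene}|{r.chrom}:{r.start}-{r.end}|{r.strand}\n")
                for i in range(0, len(r.sequence), 70):
                    fh.write(r.sequence[i:i + 70] + "\n")
        with open(bed_cgi_path, "w") as fh:
            for chrom, s, e in self.cgi.intervals:
                fh.write(f"{chrom}\t{s}\t{e}\n")
        with open(variants_path, "w") as fh:
            fh.write("region_id\toffset\tref\talt\trs_label\n")
            for v in self.variants:
                fh.write(f"{v.region_id}\t{v.offset}\t{v.ref_allele}\t"
                         f"{v.alt_allele}\t{v.rs_label or '.'}\n")


def _parse_fasta_header(header: str, path) -> tuple[str, str, str, int, int, str]:
    parts = header.split("|")
    if len(parts) != 4:
        raise PanelError(
            f"{path}: FASTA header {header!r} is not 'region_id|gene|chrom:start-end|strand'")
    region_id, gene, coord, strand = parts
    m = re.fullmatch(r"(\S+):(\d+)-(\d+)", coord)
    if not m:
        raise PanelError(f"{path}: bad coordinate field {coord!r} in header {header!r}")
    return region_id, gene, m.group(1), int(m.group(2)), int(m.group(3)), strand


def load_panel(fasta_path, bed_cgi_path=None, variants_table_path=None,
               x_linked: Iterable[str] = ()) -> AmpliconPanel:
    """Load a panel from FASTA (+ optional BED3 islands and variant TSV)."""
    regions = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        rid, gene, chrom, start, end, strand = _parse_fasta_header(
            rec.description, fasta_path)
        regions.append(AmpliconRegion(rid, chrom, start, end, str(rec.seq),
                                      gene=gene, strand=strand))
    if not regions:
        raise PanelError(f"{fasta_path}: no FASTA records")

    intervals = []
    if bed_cgi_path is not None and Path(bed_cgi_path).exists():
        with open(bed_cgi_path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise PanelError(f"{bed_cgi_path}: line {lineno}: expected >=3 columns")
                try:
                    intervals.append((fields[0], int(fields[1]), int(fields[2])))
                except ValueError as exc:
                    raise PanelError(
                        f"{bed_cgi_path}: line {lineno}: non-integer coordinate") from exc

    variants = []
    if variants_table_path is not None and Path(variants_table_path).exists():
        import pandas as pd

        table = pd.read_csv(variants_table_path, sep="\t", dtype=str)
        required = {"region_id", "offset", "ref", "alt"}
        missing = required - set(table.columns)
        if missing:
            raise PanelError(
                f"{variants_table_path}: missing columns {sorted(missing)}")
        for _, row in table.iterrows():
            rs = row.get("rs_label")
            rs = None if rs in (None, ".", "") or (isinstance(rs, float)) else rs
            variants.append(VariantLocus(row["region_id"], int(row["offset"]),
                                         row["ref"], row["alt"], rs_label=rs))

    return AmpliconPanel(regions, CgiAnnotation(intervals), variants,
                         x_linked=x_linked)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
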