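"""Synthetic BSAS cohorts and bisulfite amplicon reads with truth tables.

The generator emulates the structure of a three-group blood-leukocyte
methylation study: controls (CON) and two patient groups (HD, LC) of roughly
31/31/42 samples, per-CpG methylation in [0, 100] percent spanning four
region classes (hypomethylated, low, intermediate, hypermethylated), planted
unidirectional / bidirectional (dystropic) / ordered group effects,
experiment-level batch shifts, Hardy-Weinberg genotypes at planted SNPs
(including CpG-creating and CpG-destroying alleles), incomplete bisulfite
conversion and sequencing error.

Model for one sample's true methylation at one site::

    p = clip(CON_mean + delta_group + batch_shift + N(0, dispersion), 0, 100)

Reads are emitted in reference (forward) orientation, as after upstream read
orientation/merging: original-top (OT) molecules show C->T conversion at
unmethylated cytosines, original-bottom (OB) molecules show G->A conversion
at the guanine of the CpG (the bottom-strand cytosine).  Non-CpG cytosines
are always unmethylated (mammalian somatic assumption), so their retention
rate measures conversion failure.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import AmpliconPanel, AmpliconRegion, CgiAnnotation, VariantLocus

__all__ = [
    "CohortDesign",
    "EffectSpec",
    "ConversionModel",
    "TruthTable",
    "SimulatedReads",
    "Fixture",
    "simulate_cohort",
    "simulate_reads",
    "simulate_methylation_counts",
    "make_fixture",
    "PRESETS",
]

GROUPS = ("CON", "HD", "LC")

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class CohortDesign:
    """Group sizes, sex ratios and experiment-batch structure of a cohort."""

    n_con: int = 31
    n_hd: int = 31
    n_lc: int = 42
    female_fraction: float = 0.5
    # batch id -> additive shift in percentage points (systematic error)
    batch_shifts: dict[str, float] = field(
        default_factory=lambda: {"E1": 0.0, "E2": 1.5})

    def __post_init__(self):
        if min(self.n_con, self.n_hd, self.n_lc) <= 0:
            raise ValueError("group sizes must be positive")
        if not self.batch_shifts:
            raise ValueError("at least one batch required")
        for b, s in self.batch_shifts.items():
            if not np.isfinite(s):
                raise ValueError(f"batch {b}: shift must be finite")

    @property
    def n_total(self) -> int:
        return self.n_con + self.n_hd + self.n_lc


@dataclass(frozen=True)
class EffectSpec:
    """True CON-mean and group deltas (percentage points) for one CpG site."""

    site_id: str
    con_mean: float
    delta_hd: float = 0.0
    delta_lc: float = 0.0
    dispersion: float = 1.5  # biological between-sample SD, pp

    def __post_init__(self):
        if not 0.0 <= self.con_mean <= 100.0:
            raise ValueError(f"{self.site_id}: con_mean outside [0, 100]")
        if self.dispersion < 0:
            raise ValueError(f"{self.site_id}: negative dispersion")

    @property
    def pattern(self) -> str:
        """Truth pattern implied by the deltas.

        bidirectional: opposite signs (the dystropic configuration);
        ordered_increase/decrease: same sign with |delta_LC| < |delta_HD|
        (CON < LC < HD resp. CON > LC > HD); unidirectional: any other
        non-null same-direction combination; null: both zero.
        """
        dh, dl = self.delta_hd, self.delta_lc
        if dh == 0 and dl == 0:
            return "null"
        if dh * dl < 0:
            return "bidirectional"
        if dh > 0 and 0 < dl < dh:
            return "ordered_increase"
        if dh < 0 and dh < dl < 0:
            return "ordered_decrease"
        return "unidirectional"


@dataclass
class ConversionModel:
    """Bisulfite conversion, sequencing error and depth model."""

    conversion_rate: float = 0.995       # unmethylated C read as T
    inappropriate_conversion: float = 0.005  # methylated C read as T
    seq_error: float = 0.001             # per-base substitution rate
    depth: float = 200.0                 # mean reads per amplicon per sample
    read_length: int = 150
    paired: bool = False

    def __post_init__(self):
        for name in ("conversion_rate", "inappropriate_conversion", "seq_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")


@dataclass
class TruthTable:
    """Complete ground truth for a simulated cohort."""

    samples: pd.DataFrame        # index sample_id; columns group, sex, batch
    meth_prob: pd.DataFrame      # samples x site_id, true percent in [0, 100]
    genotypes: pd.DataFrame      # samples x variant_id, alt-allele dosage
    ploidy: pd.DataFrame         # samples x variant_id, 1 or 2
    patterns: pd.Series          # site_id -> pattern label
    effects: dict[str, EffectSpec]
    batch_shifts: dict[str, float]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.samples.to_csv(out / "sample_sheet.tsv", sep="\t",
                            index_label="sample_id")
        self.meth_prob.to_csv(out / "truth_methylation.tsv", sep="\t",
                              index_label="sample_id")
        self.genotypes.to_csv(out / "truth_genotypes.tsv", sep="\t",
                              index_label="sample_id")
        self.patterns.rename("pattern").to_csv(
            out / "truth_patterns.tsv", sep="\t", index_label="site_id")


@dataclass
class SimulatedReads:
    fastq_paths: dict[str, Path]         # sample_id -> FASTQ (R1 if paired)
    fastq_r2_paths: dict[str, Path]      # empty unless paired
    sidecar_path: Path | None            # read-level truth TSV


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_cohort(
    panel: AmpliconPanel,
    design: CohortDesign,
    effects: Sequence[EffectSpec],
    variant_freqs: Mapping[str, float] | None = None,
    seed=0,
) -> TruthTable:
    """Draw per-sample true methylation and genotypes for a cohort.

    ``effects`` must cover every site of the panel (including
    allele-dependent sites).  Genotypes are drawn under Hardy-Weinberg
    equilibrium at the given alt-allele frequencies; males are hemizygous at
    variants in X-linked regions.
    """
    rng = _rng(seed)
    variant_freqs = dict(variant_freqs or {})

    site_ids = panel.site_ids()
    by_id = {e.site_id: e for e in effects}
    unknown = set(by_id) - set(site_ids)
    if unknown:
        raise ValueError(f"effects reference unknown sites: {sorted(unknown)[:5]}")
    missing = set(site_ids) - set(by_id)
    if missing:
        raise ValueError(f"effects missing for sites: {sorted(missing)[:5]}")

    for vid, f in variant_freqs.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{vid}: allele frequency outside [0, 1]")

    # samples: ids, groups, sexes, balanced round-robin batch assignment
    rows = []
    batches = list(design.batch_shifts)
    for group, n in zip(GROUPS, (design.n_con, design.n_hd, design.n_lc)):
        n_f = int(round(n * design.female_fraction))
        sexes = rng.permutation(np.array(["F"] * n_f + ["M"] * (n - n_f)))
        for i in range(n):
            rows.append({"sample_id": f"{group}_{i + 1:03d}", "group": group,
                         "sex": sexes[i], "batch": batches[i % len(batches)]})
    samples = pd.DataFrame(rows).set_index("sample_id")

    shift = samples["batch"].map(design.batch_shifts).to_numpy(float)
    n = len(samples)
    probs = np.empty((n, len(site_ids)))
    patterns = {}
    for j, sid in enumerate(site_ids):
        e = by_id[sid]
        gdelta = samples["group"].map(
            {"CON": 0.0, "HD": e.delta_hd, "LC": e.delta_lc}).to_numpy(float)
        noise = rng.normal(0.0, e.dispersion, n) if e.dispersion > 0 else 0.0
        probs[:, j] = np.clip(e.con_mean + gdelta + shift + noise, 0.0, 100.0)
        patterns[sid] = e.pattern

    meth_prob = pd.DataFrame(probs, index=samples.index, columns=site_ids)

    vids = [v.variant_id for v in panel.variants]
    geno = pd.DataFrame(0, index=samples.index, columns=vids, dtype=int)
    ploidy = pd.DataFrame(2, index=samples.index, columns=vids, dtype=int)
    male = (samples["sex"] == "M").to_numpy()
    for v in panel.variants:
        f = variant_freqs.get(v.variant_id, 0.0)
        hemi = v.region_id in panel.x_linked
        pl = np.where(hemi & male, 1, 2)
        geno[v.variant_id] = rng.binomial(pl, f)
        ploidy[v.variant_id] = pl

    return TruthTable(samples, meth_prob, geno, ploidy,
                      pd.Series(patterns).reindex(site_ids),
                      by_id, dict(design.batch_shifts))


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


def _haplotype_arrays(region: AmpliconRegion, variants: list[VariantLocus],
                      dosage: dict[str, int], ploidy: int):
    """Sequences of the sample's haplotypes (het alts phased together)."""
    ref = _encode(region.sequence)
    haps = []
    for h in range(ploidy):
        seq = ref.copy()
        for v in variants:
            d = dosage.get(v.variant_id, 0)
            carries_alt = d >= ploidy or (d >= 1 and h == ploidy - 1)
            if carries_alt:
                seq[v.offset] = ord(v.alt_allele)
        haps.append(seq)
    return haps


def _cpg_prob_tracks(hap: np.ndarray, site_probs: dict[int, float]):
    """Per-position methylation probability for CpG C and CpG G positions."""
    L = hap.size
    p_c = np.zeros(L)
    p_g = np.zeros(L)
    is_c = hap == ord("C")
    is_g = hap == ord("G")
    for off, p in site_probs.items():
        if off + 1 < L and is_c[off] and is_g[off + 1]:  # CpG present on hap
            p_c[off] = p / 100.0
            p_g[off + 1] = p / 100.0
    return p_c, p_g


def simulate_reads(
    panel: AmpliconPanel,
    truth: TruthTable,
    model: ConversionModel,
    out_dir,
    seed=0,
    sidecar: bool = True,
) -> SimulatedReads:
    """Write per-sample FASTQ (gzip, Phred+33) plus a read-truth sidecar.

    Amplicons from all regions of a sample are pooled into one FASTQ, as in a
    pooled multi-amplicon library.  Byte-identical output for identical seed
    and inputs.
    """
    import warnings

    rng = _rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if model.depth == 0:
        warnings.warn("depth 0: emitting empty FASTQ files")

    site_probs_cols = {sid: truth.meth_prob[sid] for sid in truth.meth_prob}
    offsets_by_region = {
        rid: {panel.site_id(s): s.offset for s in panel.sites[rid]}
        for rid in panel.regions
    }

    fastq_paths: dict[str, Path] = {}
    r2_paths: dict[str, Path] = {}
    sidecar_rows: list[str] = []
    qual_cache: dict[int, bytes] = {}

    for sample_id in truth.samples.index:
        path = out / f"{sample_id}.fastq.gz"
        fastq_paths[sample_id] = path
        fh = gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"), mtime=0)
        fh2 = None
        if model.paired:
            path2 = out / f"{sample_id}.R2.fastq.gz"
            r2_paths[sample_id] = path2
            fh2 = gzip.GzipFile(filename="", mode="wb",
                                fileobj=open(path2, "wb"), mtime=0)
        counter = 0
        for rid, region in panel.regions.items():
            n = int(rng.poisson(model.depth))
            if n == 0:
                continue
            variants = panel.variants_in(rid)
            dosage = {v.variant_id: int(truth.genotypes.at[sample_id, v.variant_id])
                      for v in variants}
            pl = 2
            if variants:
                pl = int(truth.ploidy.at[sample_id, variants[0].variant_id])
            haps = _haplotype_arrays(region, variants, dosage, pl)
            probs = {off: float(site_probs_cols[sid].at[sample_id])
                     for sid, off in offsets_by_region[rid].items()}
            tracks = [_cpg_prob_tracks(h, probs) for h in haps]

            L = len(region)
            h_idx = rng.integers(0, pl, n)
            strand_ot = rng.random(n) < 0.5
            reads = np.stack([haps[h] for h in h_idx])
            PC = np.stack([tracks[h][0] for h in h_idx])
            PG = np.stack([tracks[h][1] for h in h_idx])

            meth_c = rng.random((n, L)) < PC
            meth_g = rng.random((n, L)) < PG
            conv_c = np.where(meth_c,
                              rng.random((n, L)) < model.inappropriate_conversion,
                              rng.random((n, L)) < model.conversion_rate)
            conv_g = np.where(meth_g,
                              rng.random((n, L)) < model.inappropriate_conversion,
                              rng.random((n, L)) < model.conversion_rate)
            ot_mask = strand_ot[:, None] & (reads == ord("C")) & conv_c
            ob_mask = (~strand_ot[:, None]) & (reads == ord("G")) & conv_g
            reads[ot_mask] = ord("T")
            reads[ob_mask] = ord("A")

            if model.seq_error > 0:
                err = rng.random((n, L)) < model.seq_error
                if err.any():
                    codes = np.zeros((n, L), dtype=np.uint8)
                    for b, c in _CODE.items():
                        codes[reads == ord(b)] = c
                    bump = rng.integers(1, 4, size=int(err.sum()))
                    codes[err] = (codes[err] + bump) % 4
                    reads = _BASES[codes]

            rl = min(model.read_length, L)
            if L > rl:
                starts = rng.integers(0, L - rl + 1, n)
            else:
                starts = np.zeros(n, dtype=int)
            idx = starts[:, None] + np.arange(rl)
            windows = np.take_along_axis(reads, idx, axis=1)
            if model.paired:
                starts = np.zeros(n, dtype=int)
                windows = reads[:, :rl]
                windows2 = reads[:, -rl:]
                starts2 = np.full(n, L - rl)

            qual = qual_cache.setdefault(rl, b"I" * rl)
            for i in range(n):
                counter += 1
                read_id = f"{sample_id}:r{counter:07d}"
                fh.write(f"@{read_id}\n".encode())
                fh.write(windows[i].tobytes() + b"\n+\n" + qual + b"\n")
                if fh2 is not None:
                    fh2.write(f"@{read_id}\n".encode())
                    fh2.write(windows2[i].tobytes() + b"\n+\n" + qual + b"\n")
                if sidecar:
                    strand = "OT" if strand_ot[i] else "OB"
                    sidecar_rows.append(
                        f"{read_id}\t{sample_id}\t{rid}\t{strand}\t{starts[i]}")
        fh.close()
        if fh2 is not None:
            fh2.close()

    sidecar_path = None
    if sidecar:
        sidecar_path = out / "read_truth.tsv"
        with open(sidecar_path, "w") as sfh:
            sfh.write("read_id\tsample_id\tregion_id\tstrand\toffset\n")
            sfh.write("\n".join(sidecar_rows))
            if sidecar_rows:
                sfh.write("\n")
    return SimulatedReads(fastq_paths, r2_paths, sidecar_path)


def simulate_methylation_counts(truth: TruthTable, depth: int, seed=0,
                                min_depth: int = 10):
    """Binomial read counts at fixed informative depth, per sample x site.

    Shortcut for statistical studies: at a covered site the read pipeline
    induces Binomial(depth, p/100) methylated counts, which this samples
    directly without generating sequence.
    """
    from .calling import MethylationMatrix

    rng = _rng(seed)
    p = truth.meth_prob.to_numpy() / 100.0
    meth = rng.binomial(depth, p)
    total = np.full_like(meth, depth)
    return MethylationMatrix(
        meth=pd.DataFrame(meth, index=truth.meth_prob.index,
                          columns=truth.meth_prob.columns),
        total=pd.DataFrame(total, index=truth.meth_prob.index,
                           columns=truth.meth_prob.columns),
        min_depth=min_depth,
    )


# ---------------------------------------------------------------------------
# fixture presets
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    preset: str
    seed: int
    panel: AmpliconPanel
    design: CohortDesign
    effects: list[EffectSpec]
    variant_freqs: dict[str, float]
    conversion: ConversionModel
    truth: TruthTable
    reads: SimulatedReads | None = None
    out_dir: Path | None = None

    @property
    def dystropic_genes(self) -> set[str]:
        genes = set()
        for e in self.effects:
            if e.pattern == "bidirectional":
                rid = e.site_id.split(":", 1)[0]
                genes.add(self.panel.regions[rid].gene)
        return genes

    @property
    def n_bidirectional_sites(self) -> int:
        return sum(1 for e in self.effects if e.pattern == "bidirectional")

    def analyzable_site_ids(self) -> list[str]:
        """Sites callable in the plain methylation matrix (reference CpGs
        not overlapping a variant locus)."""
        from .calling import _excluded_site_offsets

        ids = []
        for rid in self.panel.regions:
            excluded = _excluded_site_offsets(self.panel, rid)
            for s in self.panel.sites[rid]:
                if not s.allele_dependent and s.offset not in excluded:
                    ids.append(self.panel.site_id(s))
        return ids

    def expected_pooled_means(self) -> dict[str, float]:
        """Expected all-group pooled mean per site (clip-free arithmetic)."""
        sheet = self.truth.samples
        w = sheet.groupby("group").size()
        n = len(sheet)
        bshift = float(sheet["batch"].map(self.truth.batch_shifts).mean())
        return {e.site_id: e.con_mean + (w.get("HD", 0) * e.delta_hd
                                         + w.get("LC", 0) * e.delta_lc) / n + bshift
                for e in self.effects}

    def expected_region_classes(self) -> dict[str, str]:
        """Truth region class over the analyzable sites."""
        from .profiling import classify_region

        mu = self.expected_pooled_means()
        per_region: dict[str, list[float]] = {}
        for sid in self.analyzable_site_ids():
            per_region.setdefault(sid.split(":", 1)[0], []).append(mu[sid])
        return {rid: classify_region(v) for rid, v in per_region.items()}


def _random_region_sequence(rng: np.random.Generator, length: int,
                            cpg_offsets: Sequence[int],
                            keep: Sequence[int] = ()) -> str:
    """Random DNA with CG dinucleotides exactly at ``cpg_offsets``.

    Positions in ``keep`` are protected from the CG-scrubbing pass (used when
    a caller wants to place variant context bases explicitly afterwards).
    """
    seq = rng.choice(list("ACGT"), size=length).tolist()
    planted = set()
    for off in cpg_offsets:
        seq[off], seq[off + 1] = "C", "G"
        planted.add(off)
    protected = set(keep)
    for i in range(length - 1):
        if seq[i] == "C" and seq[i + 1] == "G" and i not in planted:
            if i + 1 in protected or i in protected:
                continue
            seq[i + 1] = "A"
    return "".join(seq)


def _region_plan_paper_like():
    """(region_id, gene, n_sites, class, con-mean range, site effects).

    Effects map: 1-based reference site ordinal -> (delta_hd, delta_lc).
    Region classes follow the four-class taxonomy; dystropic (bidirectional)
    sites are planted at sites with CON means in the 5-25% range, where a
    +/-3 pp shift does not truncate at 0.
    """
    bidir = (3.0, -3.0)
    plan = []
    hypo_genes = ["HTT", "PSEN1", "WRAP53", "EP300", "BDNF", "CYCS",
                  "NFKB1", "HSPA4", "KHDRBS1", "MLH1-p1", "NTRK2", "BCL2L1"]
    for g in hypo_genes:
        eff = {}
        if g == "PSEN1":
            eff = {1: (3.0, 0.0), 2: (3.0, 0.0)}  # HD-only, unidirectional
        plan.append((g, g.split("-")[0], 6, (0.3, 1.2), eff))
    # low-methylation regions carrying hypomethylated-gene-style dystropy
    plan.append(("GLS2", "GLS2", 6, (1.3, 6.7), {}))
    plan.append(("SETDB1", "SETDB1", 6, (1.0, 2.5), {3: bidir, 5: bidir}))
    plan.append(("TWIST1", "TWIST1", 6, (1.0, 2.5), {4: bidir, 5: bidir}))
    plan.append(("HDAC1", "HDAC1", 6, (1.0, 2.5), {6: bidir}))
    # intermediate regions
    plan.append(("GRIA2", "GRIA2", 8, (10.0, 30.0), {2: bidir, 5: bidir, 6: bidir}))
    plan.append(("SP1", "SP1", 6, (6.0, 22.0), {4: bidir}))
    plan.append(("LEP", "LEP", 6, (32.0, 50.0),
                 {2: (4.0, 2.0), 3: (4.0, 2.0), 4: (4.0, 2.0)}))  # CON<LC<HD
    plan.append(("BCL11B", "BCL11B", 6, (8.0, 16.0), {1: (4.0, 2.0), 2: (4.0, 2.0)}))
    plan.append(("MLH1-p2", "MLH1", 6, (32.0, 68.0), {}))  # CGI-shore fragment
    plan.append(("MIR10B", "MIR10B", 6, (12.0, 45.0), {}))  # X-linked
    plan.append(("MIR223", "MIR223", 6, (12.0, 55.0), {}))  # X-linked
    # hypermethylated region
    plan.append(("APOE", "APOE", 6, (91.0, 97.0), {}))
    return plan


def _low_site_means(rng, region_id, n_sites, lo, hi):
    means = rng.uniform(lo, hi, n_sites)
    if region_id == "GLS2":
        means = np.sort(means)[::-1]
        means[0] = 22.0  # one markedly higher site, GLS2-CpG_1 style
    return means


def _build_paper_like(seed: int, low_dispersion=1.5):
    rng = np.random.default_rng(seed)
    plan = _region_plan_paper_like()
    spacing = 34  # bp between planted CpGs
    regions, cgi_intervals, variants = [], [], []
    effects: list[EffectSpec] = []
    freqs: dict[str, float] = {}
    cursor = 10_000

    hypo_class = {rid for rid, *_ in plan[:12]}

    for rid, gene, n_sites, (lo, hi), eff in plan:
        length = spacing * (n_sites + 1)
        cpg_offsets = [spacing * (k + 1) for k in range(n_sites)]
        keep: list[int] = []
        # planted variant context per region
        if rid == "GRIA2":
            keep = [cpg_offsets[0] + 1]          # G of CpG_1, G/A destroys
        seq = _random_region_sequence(rng, length, cpg_offsets, keep=keep)
        chrom = ("chrX" if rid in ("MIR10B", "MIR223")
                 else f"chr{1 + len(regions) % 20}")
        start = cursor
        cursor += length + 6000
        if rid in hypo_class or rid in {"SETDB1", "TWIST1", "HDAC1", "GLS2"}:
            cgi_intervals.append((chrom, start - 200, start + length + 200))
        region = AmpliconRegion(rid, chrom, start, start + length, seq, gene=gene)

        if rid == "GRIA2":
            off = cpg_offsets[0] + 1
            variants.append(VariantLocus(rid, off, "G", "A", rs_label="rsGRIA2_GA"))
            freqs[f"{rid}:{off}G>A"] = 0.30
        elif rid == "HSPA4":
            # plant C,T just after the last CpG; T->G creates a new CpG
            off = cpg_offsets[-1] + 10
            seq = seq[:off] + "CT" + seq[off + 2:]
            if off + 2 < length and seq[off + 2] == "G":  # avoid accidental CG
                seq = seq[:off + 2] + "A" + seq[off + 3:]
            region = AmpliconRegion(rid, chrom, start, start + length, seq, gene=gene)
            variants.append(VariantLocus(rid, off + 1, "T", "G", rs_label="rsHSPA4_TG"))
            freqs[f"{rid}:{off + 1}T>G"] = 0.20
        elif rid == "APOE":
            # T/C substitution in a TG context: the C allele creates a CpG,
            # confounded with conversion on both strands
            off = cpg_offsets[2] + 12
            seq = seq[:off] + "TG" + seq[off + 2:]
            if off > 0 and seq[off - 1] == "C":
                seq = seq[:off - 1] + "A" + seq[off:]
            region = AmpliconRegion(rid, chrom, start, start + length, seq, gene=gene)
            variants.append(VariantLocus(rid, off, "T", "C", rs_label="rsAPOE_TC"))
            freqs[f"{rid}:{off}T>C"] = 0.15
        elif rid == "GLS2":
            # neutral A/G away from any CpG context
            off = cpg_offsets[1] + 15
            seq = seq[:off - 1] + "TAT" + seq[off + 2:]
            region = AmpliconRegion(rid, chrom, start, start + length, seq, gene=gene)
            variants.append(VariantLocus(rid, off, "A", "G", rs_label="rsGLS2_AG"))
            freqs[f"{rid}:{off}A>G"] = 0.30

        regions.append(region)

        if rid == "GLS2":
            means = _low_site_means(rng, rid, n_sites, lo, hi)
        else:
            means = rng.uniform(lo, hi, n_sites)
        if rid == "PSEN1":
            means[:2] = 0.8  # headroom: effect sites stay below the 3% bound
        for k in range(n_sites):
            dh, dl = eff.get(k + 1, (0.0, 0.0))
            if dh * dl < 0 and means[k] < 6.0:
                # dystropic sites need headroom so the negative delta is not
                # truncated at 0; matches their observed 5-25% niveau
                means[k] = 6.0 + k * 0.5
            effects.append(EffectSpec(f"{rid}:CpG_{k + 1}", float(round(means[k], 2)),
                                      dh, dl, dispersion=low_dispersion))

    panel = AmpliconPanel(regions, CgiAnnotation(cgi_intervals), variants,
                          x_linked={"MIR10B", "MIR223"})
    # effects for allele-dependent sites: new CpGs arise unmethylated in
    # hypomethylated context but acquire the regional level inside a
    # methylated region (the exon-CGI T/C-created site is methylated)
    covered = {e.site_id for e in effects}
    region_mean: dict[str, float] = {}
    for e in effects:
        region_mean.setdefault(e.site_id.split(":", 1)[0], []).append(e.con_mean)
    region_mean = {r: float(np.mean(v)) for r, v in region_mean.items()}
    for sid in panel.site_ids():
        if sid not in covered:
            rid = sid.split(":", 1)[0]
            con = 90.0 if region_mean.get(rid, 0.0) > 50.0 else 0.5
            effects.append(EffectSpec(sid, con, dispersion=0.5))
    return panel, effects, freqs


def _build_tiny(seed: int):
    rng = np.random.default_rng(seed)
    spacing = 24
    specs = [
        ("SP1", 4, [2.0, 8.0, 12.0, 20.0], {3: (3.0, -3.0)}),
        ("SETDB1", 4, [1.0, 5.0, 6.0, 2.0], {2: (3.0, -3.0)}),
        ("APOE", 3, [92.0, 94.0, 96.0], {}),
    ]
    regions, variants, effects = [], [], []
    freqs = {}
    cursor = 5000
    for rid, n_sites, means, eff in specs:
        length = spacing * (n_sites + 1)
        cpg_offsets = [spacing * (k + 1) for k in range(n_sites)]
        keep = [cpg_offsets[0] + 1] if rid == "SP1" else []
        seq = _random_region_sequence(rng, length, cpg_offsets, keep=keep)
        region = AmpliconRegion(rid, "chr1", cursor, cursor + length, seq, gene=rid)
        cursor += length + 5000
        if rid == "SP1":
            off = cpg_offsets[0] + 1
            variants.append(VariantLocus(rid, off, "G", "A", rs_label="rsTINY_GA"))
            freqs[f"{rid}:{off}G>A"] = 0.4
        regions.append(region)
        for k in range(n_sites):
            dh, dl = eff.get(k + 1, (0.0, 0.0))
            effects.append(EffectSpec(f"{rid}:CpG_{k + 1}", means[k], dh, dl,
                                      dispersion=1.0))
    cgi = CgiAnnotation([("chr1", 4900, 5400)])
    panel = AmpliconPanel(regions, cgi, variants)
    return panel, effects, freqs


PRESETS = ("tiny", "paper_like", "null_only")


def make_fixture(preset: str, seed: int, out_dir=None,
                 depth: float | None = None,
                 write_reads: bool | None = None) -> Fixture:
    """Build a named study fixture: panel + cohort truth (+ FASTQ if on disk).

    Presets: "tiny" (3 regions, 4/4/4 samples), "paper_like" (the full
    three-group 31/31/42 design with planted unidirectional, ordered and
    bidirectional effects and CpG-changing SNPs), "null_only" (paper_like
    structure with every group delta zero).  Fully reproducible from seed.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; available: {', '.join(PRESETS)}")

    if preset == "tiny":
        panel, effects, freqs = _build_tiny(seed)
        design = CohortDesign(n_con=4, n_hd=4, n_lc=4,
                              batch_shifts={"E1": 0.0, "E2": 1.5})
        conv = ConversionModel(depth=depth if depth is not None else 80.0,
                               read_length=100)
    else:
        panel, effects, freqs = _build_paper_like(seed)
        if preset == "null_only":
            effects = [EffectSpec(e.site_id, e.con_mean, 0.0, 0.0, e.dispersion)
                       for e in effects]
        design = CohortDesign()
        conv = ConversionModel(depth=depth if depth is not None else 60.0)

    truth = simulate_cohort(panel, design, effects, freqs, seed=seed + 1)
    reads = None
    if out_dir is not None and (write_reads is None or write_reads):
        reads = simulate_reads(panel, truth, conv, out_dir, seed=seed + 2)
        truth.write(out_dir)
        Path(out_dir, "panel").mkdir(exist_ok=True)
        panel.to_files(Path(out_dir, "panel", "panel.fasta"),
                       Path(out_dir, "panel", "cgi.bed"),
                       Path(out_dir, "panel", "variants.tsv"))
    return Fixture(preset, seed, panel, design, effects, freqs, conv, truth,
                   reads, Path(out_dir) if out_dir is not None else None)
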