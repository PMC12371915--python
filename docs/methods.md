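# Methods

`amplimeth` analyses targeted bisulfite amplicon sequencing (BSAS) data from
a three-group design — controls (CON) and two disease groups (HD, LC) — to
find CpG sites whose methylation moves in *opposite* directions in the two
diseases (the dystropy / inverse-comorbidity configuration), and to account
for SNPs inside the amplicons. This note records the model, the defaults
and why, what the synthetic generator does and does not emulate, and the
numerical choices.

## Panel model

Amplicons are reference regions with 0-based half-open coordinates
(1-based inclusive in human-readable reports). CpG sites are anchored at
the forward-strand C of the palindromic CG; evidence from both bisulfite
strands is folded onto this one site. A variant whose alternative allele
completes a CG yields an *allele-dependent* site, labelled by interleaving
the reference numbering (`CpG_3-1` between `CpG_3` and `CpG_4`).

CGI context: island = inside an annotated CpG-island interval; shore =
within 2000 bp of an island edge; shelf = within (2000, 4000] bp; open sea
otherwise. Distances count bp from the site's C to the nearest island
base.

## Bisulfite read model (simulator)

One read represents one molecule from one strand, emitted in reference
orientation:

* original-top (OT): every unmethylated C reads T; a methylated CpG C
  stays C (fails with probability `inappropriate_conversion`).
* original-bottom (OB), projected to forward coordinates: every
  unmethylated-CpG G reads A; non-CpG Gs always convert (the underlying
  bottom-strand C is non-CpG, hence unmethylated).

Non-CpG methylation is fixed at 0 (mammalian somatic leukocyte
assumption), so non-CpG C retention on OT reads (and G retention on OB
reads) directly measures conversion failure — the basis of `conversion_qc`.
Strands are drawn 50:50 per molecule; methylation states are drawn per
molecule per site. Read starts are uniform within the amplicon; PCR
duplicates, primers and realistic Illumina error profiles are *not*
modelled (per-base substitution errors are iid at `seq_error`). Defaults:
conversion 0.995, inappropriate conversion 0.005, sequencing error 0.001 —
typical bisulfite-kit figures; the assay itself does not pin them down.

True per-sample methylation of a site:

```
p = clip(CON_mean + delta_group + batch_shift + Normal(0, dispersion), 0, 100)
```

A truncated Gaussian on the percent scale (default dispersion 1.5 pp) is
used instead of a Beta so that truth arithmetic (deltas, batch shifts)
stays exactly additive and auditable. Genotypes are Hardy–Weinberg draws at
the given alt-allele frequencies; males are hemizygous in X-linked regions,
and reads are generated from the allele a molecule carries — CpGs destroyed
(or created) by the allele are absent (or present) on that molecule.

### The `paper_like` preset

Emulates the study conditions the pipeline is designed for: 31/31/42
samples (CON/HD/LC), two experiment batches with a +1.5 pp shift on the
second, 24 regions (23 genes, two MLH1 fragments) × 6–8 CpGs in four methylation classes (12
hypomethylated regions with CON means 0.3–1.2%, low regions such as a
GLS2-like profile with one ~22% site, intermediate regions at 6–50%, one
hypermethylated APOE-like region at 91–97%), and planted effects:

* bidirectional (dystropic): 9 sites in SETDB1, TWIST1, HDAC1, SP1, GRIA2
  with delta_HD = +3 pp, delta_LC = −3 pp. These sit at CON means ≥ 5–6%
  because a −3 pp shift on a <3% site would truncate at zero; observed
  dystropic sites in such assays sit at comparable levels.
* ordered (CON < LC < HD): LEP and BCL11B sites, +4/+2 pp.
* unidirectional: two PSEN1 sites, +3 pp in HD only (CON means kept at
  0.8% so the region's pooled means stay under the 3% hypomethylation
  bound).
* SNPs: a G/A substitution destroying a GRIA2 CpG (genotypeable from OT
  reads), a T/G substitution creating an HSPA4 CpG (which arises
  unmethylated), a T/C substitution in the hypermethylated region creating
  a methylated CpG (ambiguous on both strands, never genotyped), and a
  neutral A/G.

Allele-dependent sites default to the regional methylation niveau:
unmethylated (0.5%) in hypomethylated context, ~90% inside the
hypermethylated region.

What passing tests on this generator show: the pipeline recovers known
truth under an additive-Gaussian, batch-shifted, binomially sampled world
with independent sites. What they do not show: robustness to correlated
neighbouring CpGs, cell-composition confounding, PCR bias, primer or
mapping artefacts, or non-Gaussian biological variation — real-data
caveats that no synthetic check covers.

## Read assignment and methylation calling

Each read is scored against every amplicon on both strands at every offset;
mismatches exclude C(ref)/T(read) on OT and G(ref)/A(read) on OB.
Reads above `max_mismatch_rate` 0.1 (in this bisulfite-aware space) are
discarded; a best score tied between two *regions* discards the read as
ambiguous (amplicon panels are designed dissimilar); ties within a region
resolve deterministically (OT first, lowest offset). Reads shorter than 30
bp are discarded with a reason code.

Methylation percent follows the classical read-fraction definition, pooled
over strands; cells with fewer than `min_depth` = 10 informative reads are
missing (the assay's own low-depth exclusions motivate a cutoff; 10 is the
package default since no standard number exists). A site whose C or G
coincides with a variant locus is excluded from the plain matrix —
methylation there is allele-confounded and reported by
`allele_aware_methylation` instead.

## Differential methylation

Per site, OLS of percent on experiment batch (categorical dummies) and
group (CON reference), fitted by a vectorised least-squares across sites
sharing a missingness pattern (listwise deletion per site; ≥ 3 samples per
group required for a contrast). Deltas are model-adjusted group
differences in percentage points; p-values are two-sided t-tests on the
contrast. The batch term absorbs experiment-level shifts; with batch
confounded with disease and the term omitted, the disease delta inherits
the planted shift — the motivating failure mode, demonstrated in the tests.
Technical replicates should be averaged per sample before modelling; the
unit of analysis is the sample. Mixed models, beta regression and
region-level (DMR) calling are out of scope.

Significance: Benjamini–Hochberg within each contrast family (all sites of
a run × one contrast; three families per run), `p_adj < 0.05`, plus an
effect threshold `|delta| ≥ 1.5` pp — CGI/promoter methylation has a tiny
dynamic range, and shifts of this size can already matter. Direction is
up/down only past the same 1.5 pp cutoff, so "changed" means the same thing
everywhere downstream. X-linked regions are fitted separately per sex and
reported with a stratum label.

## Direction patterns and dystropy

From the three contrasts and raw group means, each fully observed site gets
exactly one pattern: flat (both disease deltas under 1.5 pp), bidirectional
(opposite non-flat directions), ordered_increase / ordered_decrease
(strictly ordered means CON < LC < HD or mirrored, both diseases moved the
same way), else unidirectional. A site supports dystropy iff bidirectional
AND the HD–LC contrast is significant; a gene is flagged with ≥ 1
supporting site (configurable `min_supporting` for a stricter rule — the
single-site default mirrors how such genes are reported in practice).

Expression concordance consumes precomputed per-dataset summaries (gene,
dataset, disease, logFC). Per disease the expression direction is the
majority sign across datasets (tie → "inconsistent"); the verdict is
"inverse-concordant" iff methylation and expression directions are opposite
in *both* diseases. Re-running differential expression is out of scope; a
Welch-t + BH helper exists only to fabricate summaries in synthetic tests.
The input table carries an explicit `disease` column because the
per-disease vote is undefined without it.

## SNPs in bisulfite space

Variant evidence is evaluated per strand after collapsing the conversion
pair (OT: C→T; OB: G→A): a substitution is informative on a strand only if
its alleles stay distinct after collapsing. Consequences: G/A variants are
genotyped from OT reads only; C/T variants are never genotyped — an
observed T can always be a converted C, so they carry ambiguity flag
"both"; an observed C at a reference-T position evidences a *methylated* C
allele and is reported as allele/methylation-confounded rather than
deconvolved. Reference-C positions with T-only evidence are never called.

Genotypes from the alt-read fraction: < 0.15 → 0/0, 0.35–0.65 → 0/1,
> 0.85 → 1/1, otherwise no-call; informative depth ≥ 10. The thresholds
are package choices giving ≥ 99% genotype accuracy at depth ≥ 100 on
simulated data. Variants carried by exactly one sample are flagged as
possible polymerase errors and excluded from association by default.

CpG gain/loss: re-derive the CG set in the ±1 bp window under ref vs alt;
more CGs → creates, fewer → destroys, else neutral (a substitution adjacent
to a retained CpG is neutral; the rare lose-one-gain-one case is net
neutral). The annotation is an involution: annotating the reverse
substitution on the alt sequence flips creates↔destroys.

Association: Kruskal–Wallis across genotype classes (exact permutation
distribution of H when total n ≤ 12, chi-square approximation otherwise)
and pairwise two-sided Mann–Whitney (exact enumeration when combined
n ≤ 20 and tie-free, tie-corrected normal approximation otherwise), run per
group and pooled. Identical values across classes return p = 1 by
convention.

## Numerical and reproducibility choices

* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; FASTQ gzip members are written with mtime 0,
  so identical seeds give byte-identical files.
* Reports are TSVs with a first-line comment (tool version, seed, config
  hash) and fixed float formatting; re-running an identical configuration
  reproduces byte-identical reports.
* BH is computed via `statsmodels.multipletests(method="fdr_bh")`; the test
  suite checks exact equality against a hand-written step-up oracle. KW/MW
  use scipy; exact modes are checked against enumeration oracles.
* Collinear designs (e.g. batch coinciding with a group) raise an error
  naming the confounded columns rather than silently dropping terms.
* Validation studies run at depths 500–1000 and 100 replicate cohorts;
  statistical replicates use count-level binomial sampling from truth
  (the exact per-site distribution the read pipeline induces), reserving
  full read simulation for the read-handling studies themselves.

## Known limitations

Single-end, indel-free alignment against dissimilar amplicons only (no
Bismark-class genome alignment); no PCR-duplicate or primer modelling; no
hemimethylation (strand-symmetric methylation is assumed); C/T SNPs are
declared unresolvable rather than attempting bottom-strand rescue, matching
the assay's stated practice; expression inputs are summary-level only; the
low/intermediate region-class boundary (median ≤ 10%, max < 30%) is a
package convention calibrated on the verbal descriptions of such regions,
not a community standard.
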