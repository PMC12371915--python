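# amplimeth

Targeted bisulfite amplicon sequencing (BSAS) methylation analysis for
three-group "inverse comorbidity" (dystropy) studies: per-CpG methylation
calling from bisulfite reads, batch-aware differential methylation between a
control group (CON) and two disease groups (HD, LC), bidirectional direction
classification, SNP/CpG-interplay analysis, and a synthetic data generator
with complete truth tables.

## The problem

Two diseases are *dystropic* (inversely comorbid) when they co-occur less
often than expected — the canonical pair being neurodegeneration versus
cancer. One candidate mechanism is regulatory-region DNA methylation moving
in *opposite* directions in the two diseases. Testing this requires a
pipeline that (i) quantifies methylation per CpG from deep bisulfite
amplicon reads, (ii) compares three groups while absorbing experiment-level
batch shifts, (iii) classifies per-site direction patterns, and (iv)
accounts for SNPs that create or destroy CpG sites inside the amplicons.
`amplimeth` implements that pipeline and, because such cohorts are rarely
public, ships a generator that emulates one (group sizes 31/31/42, four
region methylation classes, planted effects, batches, SNPs, incomplete
conversion, sequencing error) so every stage is testable against known
truth.

## The model

**Methylation calling.** The methylation level of a CpG in a sample is
`100 * m / n`, where `n` counts cytosine-informative reads at the position
(original-top reads: C = methylated, T = unmethylated at the CpG C;
original-bottom reads: G/A at the paired G) and `m` the methylated ones.
Cells with `n < min_depth` (default 10) are missing, never 0%.

**Differential methylation.** Per site, OLS of percent on experiment batch
(categorical) and disease group (CON reference):

```
percent ~ batch + group,    delta_c = contrast c in {HD-CON, LC-CON, HD-LC}
```

A site is a DMC for a contrast iff `|delta| >= 1.5` percentage points and
the Benjamini–Hochberg adjusted p (per contrast family) is `< 0.05`. The
1.5 pp threshold reflects the tiny dynamic range of CGI/promoter
methylation, where even such shifts can alter expression.

**Dystropy.** A site *supports dystropy* iff its two disease deltas are
opposite and non-flat (bidirectional) and HD-LC is significant; a gene with
≥ 1 supporting site is flagged. Ordered patterns (CON < LC < HD and its
mirror) are reported alongside. Expression summaries (per-dataset logFC)
yield an "inverse-concordant" verdict when methylation and expression move
oppositely in both diseases.

**SNPs.** Variant evidence is evaluated in collapsed bisulfite space: C/T
pairs are never genotyped (indistinguishable from conversion), G/A pairs
are genotyped from original-top reads only. Variants adding/removing a CG
make the site allele-dependent; methylation is then reported per allele,
with "site absent" for the destroyed allele.

## Worked example

```bash
amplimeth run-all --out-dir demo --seed 1 --preset tiny
```

runs simulate → call → profile → DMC → dystropy → SNP on a 12-sample
three-region fixture and prints the report paths. From Python (see
`examples/` for one script per capability):

```python
>>> from amplimeth import make_fixture, fit_many_sites, call_dmcs
>>> from amplimeth.synthetic import simulate_methylation_counts
>>> fx = make_fixture("paper_like", seed=1)
>>> m = simulate_methylation_counts(fx.truth, depth=500, seed=2)
>>> report = call_dmcs(fit_many_sites(m.percent, fx.truth.samples))
>>> report[report.significant].groupby("contrast").size()
contrast
HD-CON    16
HD-LC     15
LC-CON    12
```

Those counts are the significant DMCs per contrast on a cohort carrying 9
planted bidirectional sites (|delta| = 3 pp, moving up in HD and down in
LC, hence the strong HD-LC family), 5 ordered sites and 2 HD-only sites;
running
`examples/05_dystropy_calls.py` then flags exactly the five genes that
carry the bidirectional sites.

## Layout

```
src/amplimeth/
  panel.py        amplicon panel model, CpG enumeration, CGI context
  synthetic.py    cohort + bisulfite read simulator with truth tables
  calling.py      read assignment, methylation matrix, conversion QC
  profiling.py    region methylation classes, group summaries, Pearson r
  dmc.py          per-site OLS with batch covariate, BH, DMC calls
  dystropy.py     direction patterns, dystropic genes, expression verdicts
  snp.py          variant detection, CpG gain/loss, meQTL tests, VCF
  pipeline.py     stage orchestration with deterministic reports
  cli.py          `amplimeth` command-line interface
```

See `docs/methods.md` for the full statistical model, parameter defaults
and known limitations.
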