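"""Assign bisulfite reads to amplicons and call per-CpG methylation.

Each read is compared against the C->T-converted (original-top) and
G->A-converted (original-bottom) version of every amplicon; the methylation
of a CpG is the percentage of reads with a methylated cytosine among all
cytosine-informative reads at that position, pooled over both strands.
"""

from pathlib import Path

from amplimeth import assign_reads, call_methylation, conversion_qc, make_fixture

out = Path("example_output/calling")
fx = make_fixture("tiny", seed=1, out_dir=out)

result = assign_reads(fx.reads.fastq_paths, fx.panel)
print(f"assigned reads:   {len(result.assignments)}")
print(f"discarded:        {dict(result.discarded) or 'none'}")

matrix = call_methylation(result, fx.panel, min_depth=10)
print("\nper-sample methylation percent (first sites):")
print(matrix.percent.iloc[:4, :4].round(2))
# Cells below min_depth informative reads are NaN (missing), never 0%.

qc = conversion_qc(result, fx.panel)
print("\nconversion QC (non-CpG cytosine retention; >5% would be flagged):")
print(qc.head(4).to_string(index=False))
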