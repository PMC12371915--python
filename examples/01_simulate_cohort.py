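"""Generate a synthetic three-group BSAS cohort with full truth tables.

Builds the "paper_like" fixture: 31 controls (CON), 31 HD and 42 LC samples
over 22 amplicons, with planted bidirectional (dystropic), ordered and
unidirectional effects, two experiment batches and four SNPs, then writes
FASTQ reads, the sample sheet and the truth tables.
"""

from pathlib import Path

from amplimeth import make_fixture

out = Path("example_output/simulate")
fx = make_fixture("paper_like", seed=1, out_dir=out, depth=30)

print(f"regions:            {len(fx.panel.regions)}")
print(f"CpG sites:          {len(fx.panel.site_ids())}")
print(f"samples:            {len(fx.truth.samples)} "
      f"({dict(fx.truth.samples['group'].value_counts())})")
print(f"planted SNPs:       {[v.variant_id for v in fx.panel.variants]}")
print(f"bidirectional sites: {fx.n_bidirectional_sites}")
print(f"dystropic genes:    {sorted(fx.dystropic_genes)}")
print(f"FASTQ files in:     {out}")

# The truth tables are the reference for every downstream validation: the
# per-sample true methylation probabilities, the genotypes and the pattern
# label (null / unidirectional / bidirectional / ordered_*) of each site.
print(fx.truth.meth_prob.iloc[:3, :4].round(1))
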