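"""SNP detection from bisulfite reads and allele-aware methylation.

Bisulfite conversion makes C/T substitutions indistinguishable from
conversion (never genotyped) and G/A substitutions readable only from
original-top reads.  Variants that add or remove a CG dinucleotide make the
CpG allele-dependent: the destroyed allele is reported as "site absent",
not 0% methylation.
"""

from pathlib import Path

from amplimeth import (allele_aware_methylation, assign_reads,
                       call_methylation, detect_variants, genotype_association,
                       make_fixture)

out = Path("example_output/snp")
fx = make_fixture("tiny", seed=1, out_dir=out, depth=150)
result = assign_reads(fx.reads.fastq_paths, fx.panel)
calls = detect_variants(result, fx.panel)

for c in calls:
    print(f"{c.variant_id}: ambiguity={c.ambiguity or 'none'}, "
          f"cpg_effect={c.cpg_effect}, "
          f"carriers={c.n_carrier_samples}/{len(c.per_sample)}")

# the planted G/A substitution destroys the first SP1 CpG on the A allele
variant = next(v for v in fx.panel.variants if v.region_id == "SP1")
per_allele, log = allele_aware_methylation(result, fx.panel, variant,
                                           "SP1:CpG_1")
for allele, est in per_allele.items():
    state = "site absent" if est.site_absent else f"{est.percent:.1f}% " \
        f"({est.meth}/{est.total} reads)"
    print(f"allele {allele}: {state}")

# genotype-methylation association at a nearby site
c = calls[0]
matrix = call_methylation(result, fx.panel, min_depth=10)
res = genotype_association(matrix.percent["SP1:CpG_2"],
                           c.per_sample["genotype"], site_id="SP1:CpG_2",
                           variant_id=c.variant_id)
print(f"\nKruskal-Wallis p for SP1:CpG_2 by genotype: {res.kw_p:.3f} "
      f"({res.kw_mode}); class medians: "
      + ", ".join(f"{k}: {v[1]:.1f}% (n={v[0]})"
                  for k, v in res.classes.items()))
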