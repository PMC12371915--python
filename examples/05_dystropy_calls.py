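"""Direction patterns, dystropic genes and expression concordance.

A site is dystropic-supporting when its methylation moves in opposite
directions in the two diseases relative to controls (bidirectional) and the
HD-LC contrast is significant; a gene with at least one supporting site is
flagged.  Expression summaries (logFC per dataset per disease) then test
whether methylation and expression move inversely, the configuration
expected for repressive regulatory-region methylation.
"""

import pandas as pd

from amplimeth import (call_dmcs, call_dystropic_genes, classify_directions,
                       expression_concordance, fit_many_sites, group_summary,
                       make_fixture)
from amplimeth.synthetic import simulate_methylation_counts

fx = make_fixture("paper_like", seed=1)
matrix = simulate_methylation_counts(fx.truth, depth=500, seed=2)
dmc = call_dmcs(fit_many_sites(matrix.percent, fx.truth.samples))
calls = classify_directions(dmc, group_summary(matrix, fx.truth.samples))

print(calls.groupby("pattern").size().rename("sites"))

site_to_gene = {fx.panel.site_id(s): fx.panel.regions[s.region_id].gene
                for s in fx.panel.all_sites()}
genes = call_dystropic_genes(calls, site_to_gene)
print("\nflagged dystropic genes (planted: %s):" % sorted(fx.dystropic_genes))
print(genes[genes["dystropic"]].to_string(index=False))

# expression concordance: one gene with HD-down / LC-up expression
expr = pd.DataFrame(
    [("SP1", "studyA", "HD", -0.8, 0.001, 0.003),
     ("SP1", "studyB", "LC", 0.6, 0.0002, 0.0004)],
    columns=["gene", "dataset", "disease", "logFC", "p", "p_adj"])
verdicts = expression_concordance({"SP1": ("up", "down")}, expr)
print("\nmethylation up in HD / down in LC vs expression down in HD / up in LC:")
print(verdicts.to_string(index=False))
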