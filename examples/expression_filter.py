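"""Benjamini-Hochberg adjustment and the DE-gene filter.

Simulates a DE result table (90% null genes, down-regulation-dominated
alternatives), adjusts p-values with the step-up BH procedure and keeps
genes with padj < 0.05 and baseMean >= 100 -- the "significant and
adequately expressed" filter.
"""

from nanostress.expression import FilterConfig, benjamini_hochberg, classify_direction, filter_de_genes
from nanostress.synthetic import DeTableConfig, gen_de_table

table = gen_de_table(DeTableConfig(m_genes=1000, pi0=0.9), seed=1)
table["padj"] = benjamini_hochberg(table["pvalue"].to_numpy())
passing, counts = filter_de_genes(table, FilterConfig(basemean_min=100.0, padj_max=0.05))

print(f"genes tested: {len(table)}  (900 null, 100 with real effects)")
print(f"passing filter (padj < 0.05, baseMean >= 100): {counts['total']}")
print(f"  up-regulated:   {counts['up']}")
print(f"  down-regulated: {counts['down']}")
top = passing.reindex(passing["log2FoldChange"].abs().sort_values(ascending=False).index).head(3)
print("strongest hits:")
for row in top.itertuples():
    d = classify_direction(row.log2FoldChange)
    print(f"  {row.gene_id}: {d.fold:.1f}x {d.label}, padj = {row.padj:.1e}")
print("\nThe filter recovers mostly planted alternatives, dominated by")
print("down-regulation as configured; null genes rarely slip through.")
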