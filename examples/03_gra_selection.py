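"""Rank genes by five filter statistics aggregated with grey relational analysis.

Each gene is scored by |t|, symmetric KL entropy, Bhattacharyya distance,
standardized Wilcoxon and folded AUC on its transformed values; the five
scores are min-max normalized and collapsed into one grey relational grade.
"""

from gragp import SimConfig, simulate_counts, voom, score_all, select_top_k, recovery_report

cm, labels, truth = simulate_counts(
    SimConfig(n_genes=1000, n_per_class=(40, 40), de_fraction=0.01, dispersion=0.2, seed=3)
)
tm = voom(cm, labels)
table = score_all(tm, labels)
result, top10 = select_top_k(table, k=10)

print("top 10 genes by grey relational grade:")
for g in top10:
    i = result.gene_ids.index(g)
    mark = "*" if g in truth.de_gene_ids else " "
    print(f"  {g} {mark} grade={result.grades[i]:.4f}")

rep = recovery_report(top10, truth)
print(f"recovered {rep['n_recovered']:.0f}/{rep['n_de']:.0f} planted DE genes "
      f"(precision {rep['precision']:.2f}, recall {rep['recall']:.2f})")
# Genes marked * are truly differentially expressed; a high recall shows the
# aggregate grade concentrates the planted signal in the top of the ranking.
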