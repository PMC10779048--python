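"""Call differentially expressed genes with the shrinkage-F test.

Simulates a log2-ratio matrix, tests the top ZnO dose against the
time-matched control, and applies the |fc| >= 1.5, adjusted p < 0.05 rule.
"""

from toxpod import call_degs, differential_stats
from toxpod.synthetic import default_design, default_truth, simulate_expression

design = default_design(timepoints=(24,), replicates=4)
truth = default_truth(design, n_genes=200, n_sets=6, hub_size=40, seed=2)
matrix = simulate_expression(design, truth, seed=3)

stats = differential_stats(matrix, "ZnO_NP@50@24h", "control@24h",
                           n_perm=500, seed=4)
table = call_degs(stats)
print(table[table["is_deg"]].nlargest(8, "fs").to_string(index=False))
print(f"\n{table['is_deg'].sum()} DEGs "
      f"({table.attrs['n_up']} up / {table.attrs['n_down']} down) "
      f"of {len(table)} genes")
# fc is the signed fold change from group least-squares means; fs the
# variance-shrunk F statistic; p_raw its pooled permutation p-value.
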