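"""Filter an expression table for differential expression and qPCR validation.

Generates a per-gene table (FPKM per sample, fold change vs control,
p-value) with 12 planted differentially expressed genes, applies the
two-sided DE filter (|fold change| > 1.5, P < 0.01) and then picks
validation candidates expressed above 20 FPKM in every sample, as one would
before confirming RNA-seq calls by qPCR.
"""

from sirnakit import de_filter, gen_expression_table, validation_candidates

table, manifest = gen_expression_table(seed=3, n_genes=150, n_de=12)

de = de_filter(table)
print(f"{len(de)} of {len(table)} genes differentially expressed "
      f"(planted: {len(manifest['de_genes'])})")

candidates = validation_candidates(de, k=6, seed=3)
print("qPCR validation candidates (FPKM > 20 in all samples, up to 6 drawn):")
print(candidates[["gene_id", "fpkm_s1", "fpkm_s2", "fpkm_s3",
                  "fold_change", "p_value"]].round(3).to_string(index=False))
print()
print(
    "The DE filter keeps genes changed more than 1.5-fold in either "
    "direction at P < 0.01; the candidate filter then requires expression "
    "above 20 FPKM in every sample so qPCR can quantify them reliably."
)
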