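"""Contrast synonymous divergence (Ks) of a fast-evolving region vs background.

Simulates a genome pair whose duplicated region mutates 3.5x faster,
estimates Nei-Gojobori Ks for every ortholog pair, and tests the region
elevation with Welch's t.
"""

from ectoconv.evostats import nei_gojobori, region_contrast
from ectoconv.genome_io import extract_cds
from ectoconv.simulate import SimParams, simulate_dataset

params = SimParams(seed=5, region_rate_multiplier=3.5,
                   loss_prob_affected=0.0, loss_prob_background=0.0)
dataset = simulate_dataset(params)
region = set(dataset.ancestral_region_genes)

ks_region, ks_background = [], []
cds_b = {g.gene_id: extract_cds(g, dataset.genome_b)
         for g in dataset.genome_b.all_genes()}
for gene in dataset.genome_a.all_genes():
    anc = dataset.gene_to_ancestor[gene.gene_id]
    partner = f"B_{anc}"
    if partner not in cds_b:
        continue
    est = nei_gojobori(extract_cds(gene, dataset.genome_a), cds_b[partner])
    if est.Ks is not None:
        (ks_region if anc in region else ks_background).append(est.Ks)

c = region_contrast(ks_region, ks_background)
print(f"mean Ks region:     {c.mean_ks_affected:.3f}  (n={c.n_affected})")
print(f"mean Ks background: {c.mean_ks_background:.3f}  (n={c.n_background})")
print(f"fold elevation:     {c.ratio}")
print(f"Welch t = {c.t_stat:.2f}, p = {c.p_value:.2e}")
# The fold should sit near the configured 3.5x rate multiplier; the JC
# correction in Ks undoes multiple-hit saturation so the ratio is unbiased.
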