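"""Population scan for ectopic non-CG methylation and ibm1-like accessions.

Simulates a 20-accession panel in which 2 accessions carry ectopic mCHG in
many normally-gbM genes (a failing IBM1 pathway), classifies every gene in
every accession, and flags accessions by their ectopic-gene count.
"""

import methylsensor as ms

cfg = ms.SimulationConfig(seed=3, n_genes=800, n_accessions=20, n_ibm1_like=2,
                          n_ectopic_genes=60, n_ectopic_background=4)
sites_by_acc, acc_truth, _ = ms.simulate_panel(cfg)

classified = {
    acc: ms.classify_genes(ms.summarize_genes(ms.call_sites(sites, p0=cfg.p0)))
    for acc, sites in sites_by_acc.items()
}
panel = ms.AccessionPanel.from_classifications(classified)
counts = ms.ectopic_counts(panel)
# threshold scaled to this panel (the full-population analysis uses n > 120)
flags = ms.flag_ibm1_like(counts, threshold=20)

print(flags.sort_values("n_ectopic", ascending=False).head(6).to_string(index=False))
planted = sorted(acc_truth.loc[acc_truth["ibm1_like"], "accession"])
print(f"planted ibm1-like accessions: {planted}")
# A gene counts as ectopic in an accession when its mCHG and/or mCHH
# q-value is < 0.05 there while it is gbM in > 90% of the population.
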