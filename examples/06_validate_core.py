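"""Validate a mini-core against the entire collection.

Selects a core from a synthetic panel, then reports the classical
representativeness metrics (MD%, CR%, VR%, VD%), Shannon diversity, and
distribution tests per trait.
"""

import salicore as sc

table = sc.simulate_trait_table(sc.SyntheticSpec(n_genotypes=150, seed=7))
dist = sc.gower_matrix(table)
sel = sc.select_core(dist, fraction=0.20, seed=11, patience=3000)
report = sc.representativeness_metrics(table, table.subset(sel.genotype_ids))

cols = ["md_pct", "cr_pct", "vr_pct", "vd_pct", "p_wilcoxon"]
print(report.per_trait[cols].round(2).head(6))
s = report.summary
print(f"\nmean MD% = {s['mean_md_pct']:.2f} (want < 20), "
      f"mean CR% = {s['mean_cr_pct']:.2f} (want > 80)")
print(f"Shannon diversity: core {s['mean_h_core']:.2f} vs entire {s['mean_h_entire']:.2f} "
      f"-> loss {s['diversity_loss_pct']:.1f}%")
print(f"verdicts: {report.verdicts}")
print("\nLow MD% means core trait means track the whole collection; CR% near 100")
print("means the core spans nearly the full range of every trait.")
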