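"""Subtype single tumor cells on four immune-pathway scores.

Cells are scored on antigen processing and presentation, PD-L1/PD-1
checkpoint, JAK-STAT signaling and apoptosis, then clustered exactly like
bulk samples; the HLA-like gene block should be ordered ImH > ImM > ImL.
"""
from sklearn.metrics import adjusted_rand_score

import immsub as im

cells = im.generate_single_cell_dataset(im.SyntheticConfig(seed=7, n_cells=300))
assignment = im.subtype_single_cells(cells.expression, cells.pathway_sets, k=3)

ari = adjusted_rand_score(cells.truth.levels.values, assignment.labels.values)
print(f"cell subgroup recovery ARI = {ari:.3f}")

hla = cells.expression.data.loc[list(cells.hla_genes)]
groups = []
for lab in ("ImH", "ImM", "ImL"):
    members = assignment.samples_with(lab)
    print(f"{lab}: {len(members):3d} cells, "
          f"mean HLA-block expression = {hla[members].to_numpy().mean():.2f}")
    groups.append(hla[members].mean(axis=0).to_numpy())
res = im.anova_oneway(groups)
print(f"HLA one-way ANOVA: F = {res.statistic:.1f}, p = {res.p_value:.2e}")
# Monotone HLA expression across the ordered subgroups mirrors the
# antigen-presentation gradient expected across immune infiltration levels.
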