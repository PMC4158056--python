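"""Detect co-expression modules in a planted synthetic dataset.

Builds a small expression matrix with five planted 40-gene modules
(gene-profile correlation 0.9 with a latent module profile) plus 200
background genes, standardizes it to robust z-scores, and runs the full
detection pipeline (bicor -> signed adjacency -> TOM -> tree cut).
"""

import warnings

from rhodonet import ModulePartition, NetworkParams, detect_modules
from rhodonet.preprocess import robust_z
from rhodonet.synthdata import SynthSpec, gen_two_species

warnings.simplefilter("ignore")

spec = SynthSpec(
    n_genes_A=400, n_conditions_A=30, n_conditions_B=30,
    module_sizes=[40] * 5, preserved_flags=[True] * 5,
    within_module_cor=0.9, background_fraction=0.5,
    ortholog_fraction=1.0, seed=1,
)
exprA, _, _, truth = gen_two_species(spec)
zA, _ = robust_z(exprA)

part, eigengenes, kme = detect_modules(zA, NetworkParams())

print(f"detected {len(part.module_labels)} modules "
      f"(planted: {len(spec.module_sizes)})")
for m, size in part.sizes().items():
    planted = truth.labels_series()
    members = part.members(m)
    best = planted.loc[members].mode().iloc[0]
    purity = (planted.loc[members] == best).mean()
    print(f"  module {m} ({part.color_of(m)}): {size} genes, "
          f"purity vs planted module {best}: {purity:.2f}, "
          f"variance explained by eigengene: "
          f"{eigengenes.prop_var_explained[m]:.2f}")
assigned = int((part.labels != 0).sum())
print(f"{assigned}/{len(part.labels)} genes assigned; the rest is "
      "background left in the unassigned (grey) group")
print("Purity near 1 means each detected module matches one planted "
      "module; variance explained near 0.8 reflects the planted "
      "gene-eigengene correlation of 0.9 (0.9^2 = 0.81).")
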