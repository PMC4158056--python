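"""Quantify which reference modules are preserved in a second species.

Generates a two-species scenario in which three of five planted modules
keep their co-expression structure in species B while two are scrambled,
then computes permutation Zsummary and medianRank statistics.  The
conventional reading: Zsummary > 10 is strong evidence of preservation,
2 < Zsummary < 10 weak to moderate, and Zsummary < 2 no evidence; lower
medianRank means better preserved.
"""

import warnings

from rhodonet import (
    ModulePartition, NetworkParams, module_preservation, restrict_to_common,
)
from rhodonet.preprocess import robust_z
from rhodonet.synthdata import SynthSpec, gen_two_species

warnings.simplefilter("ignore")

spec = SynthSpec(
    n_genes_A=400, n_conditions_A=30, n_conditions_B=30,
    module_sizes=[40] * 5,
    preserved_flags=[True, True, True, False, False],
    within_module_cor=0.9, background_fraction=0.5,
    ortholog_fraction=1.0, seed=1,
)
exprA, exprB, orthologs, truth = gen_two_species(spec)
zA, _ = robust_z(exprA)
zB, _ = robust_z(exprB)
partition = ModulePartition(truth.labels_series())

ref, test, part = restrict_to_common(zA, zB, orthologs, partition)
report = module_preservation(ref, test, part, NetworkParams(),
                             n_perm=200, seed=0)

print("module  size  Zsummary.pres  medianRank.pres  truly_preserved")
for m in part.module_labels:
    row = report.preservation.loc[m]
    print(f"{m:>6}  {int(row['size']):>4}  {row['Zsummary']:>13.2f}  "
          f"{row['medianRank']:>15.1f}  {truth.preserved[m]}")
print("Preserved modules score Zsummary well above the evidence "
      "thresholds while scrambled modules fall below 2, and the "
      "medianRank ordering mirrors this.")
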