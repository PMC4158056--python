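"""Gene-set over-representation and the rank-based packaging test.

Over-representation: hypergeometric tail probability of each module /
gene-set overlap, FDR-corrected across all tests.  Packaging: ranks all
genes by a per-gene signal (here a synthetic DNA-packaging intensity
with module 2 shifted by +3 MAD) and asks, per module, whether its ranks
beat those of 1000 random same-sized gene sets in one-sided rank-sum
tests — the compound criterion keeps false positives rare.
"""

import warnings

import numpy as np

from rhodonet import ModulePartition
from rhodonet.genesets import GeneSetCollection, ora, packaging_test
from rhodonet.synthdata import SynthSpec, gen_packaging_signal, gen_two_species

warnings.simplefilter("ignore")

spec = SynthSpec(
    n_genes_A=400, n_conditions_A=30, n_conditions_B=30,
    module_sizes=[40] * 5, preserved_flags=[True] * 5,
    within_module_cor=0.9, background_fraction=0.5,
    ortholog_fraction=1.0, packaging_shift=3.0, packaged_module=2, seed=1,
)
exprA, _, _, truth = gen_two_species(spec)
partition = ModulePartition(truth.labels_series())

# gene sets: the true members of module 3 plus random decoy sets
rng = np.random.default_rng(0)
genes = np.asarray(exprA.gene_ids, dtype=object)
sets = {"module3_pathway": set(partition.members(3))}
for i in range(20):
    sets[f"random_{i}"] = set(rng.choice(genes, size=40, replace=False))
collection = GeneSetCollection(sets, {name: "pathway" for name in sets})

table, dropped = ora(partition, collection, set(exprA.gene_ids))
hit = table.sort_values("fdr").iloc[0]
print(f"top enrichment: set {hit['set']!r} in module {hit['module']} "
      f"(overlap {hit['overlap']}/{hit['set_size']}, "
      f"FDR = {hit['fdr']:.2g})")
print(f"random decoy rows significant at FDR<0.05: "
      f"{table[table['set'] != 'module3_pathway']['significant'].sum()}")

scores = gen_packaging_signal(truth, spec)
verdicts = packaging_test(scores.to_dict(), partition, n_random=1000,
                          alpha=0.01, frac=0.85, seed=0)
print("\npackaging verdicts per module:")
print(verdicts[["module_size", "count_significantly_lower",
                "count_significantly_greater", "verdict"]].to_string())
print("Only the module carrying the planted +3 MAD shift is called "
      "'packaged'; every other module is neutral.")
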