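"""Build, project and fold a site frequency spectrum from genotypes.

RADseq matrices have missing calls, so each site is down-projected to a
common number of allele copies with hypergeometric weights before the
spectrum is assembled; folding collapses to minor-allele classes when
ancestral states are unknown.
"""

import numpy as np

from rangeedge import (
    SplitModelConfig,
    fold_sfs,
    sfs_from_genotypes,
    simulate_split_genotypes,
    thin_one_snp_per_locus,
)

G = simulate_split_genotypes(SplitModelConfig(seed=5))
thinned = thin_one_snp_per_locus(G, seed=11)
print(f"{G.n_sites} SNPs -> {thinned.n_sites} after one-SNP-per-locus thinning")

# project from up to 156 observed copies down to 70, keeping partial sites
obs = sfs_from_genotypes(thinned, project_to=70)
print(f"unfolded spectrum at n=70 copies holds {obs.total():.1f} expected SNPs")
print("first five classes (singletons first):", np.round(obs.values[:5], 2))

folded = fold_sfs(obs)
print(f"folded spectrum: {len(folded.values)} minor-allele classes, "
      f"total conserved = {np.isclose(folded.total(), obs.total())}")
# an expansion leaves an excess of rare variants: the singleton class
# should dominate the spectrum
print(f"singleton share: {obs.values[0] / obs.total():.1%}")
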