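"""Quantify the simulated population structure: F_ST and ancestry PCA.

Simulates gene panels at two migration rates, concatenates LD-pruned
common variants (MAF >= 5% in deme A, r^2 < 0.2), and reports the
multi-locus Weir-Cockerham F_ST between demes plus how well the leading
principal component separates them.  Lower migration means stronger
differentiation: migration 0.01 corresponds to the neighboring-countries
regime (F_ST near 1e-3).
"""

from dataclasses import replace

import numpy as np

from rarestrat import (
    DemographyConfig,
    haplotypes_to_genotypes,
    ld_prune,
    pca_genotypes,
    simulate_two_pop,
    wc_fst,
)

base = DemographyConfig(n_genes=60)
for m in (0.001, 0.01, 0.1):
    panels = simulate_two_pop(replace(base, migration_rate=m), seed=101)
    rng = np.random.default_rng(202)
    blocks, labels = [], None
    for panel in panels:
        g = haplotypes_to_genotypes(panel, n_a=500, n_b=500, seed=rng)
        kept = ld_prune(g.genotypes, ref_maf=g.maf_a, maf_min=0.05, r2_max=0.2)
        if kept.size:
            blocks.append(g.genotypes[:, kept])
            labels = g.origin
    G = np.concatenate(blocks, axis=1)
    est = wc_fst(G, labels)
    pca = pca_genotypes(G, K=2)
    pc1 = pca.coordinates[:, 0]
    sep = abs(pc1[labels == "A"].mean() - pc1[labels == "B"].mean()) / pc1.std()
    print(f"migration {m:<6}: F_ST = {est.theta:.5f} over {est.n_loci} loci; "
          f"PC1 deme separation = {sep:.2f} sd")
print("\nF_ST decreases as migration mixes the demes; PC1 separation shrinks "
      "in step, which is why PCA corrections weaken at fine scales.")
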