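"""Diversity and structure analysis of a simulated admixed panel.

Simulates 85 accessions from two populations (Fst 0.1) under the
Balding-Nichols model, applies the depth/missingness/MAF filter cascade,
and prints diversity statistics, PCA variance, and the delta-K choice of
the number of ancestral clusters.
"""

import numpy as np

from wgdpop import popgen, synthetic_data as sd

pop = sd.simulate_admixed_genotypes(sd.PopSimSpec(seed=13))
gm, report = popgen.apply_filters(pop.gm, dp_min=20, dp_max=200,
                                  maf_min=0.05, max_missing=0.10)
print(f"filter attrition             : {report.as_dict()}")

stats = popgen.locus_stats(gm)
summary = popgen.stats_summary(stats)
print(f"mean GD / PIC / Ho / MAF     : "
      + " / ".join(f"{summary.loc['mean', c]:.3f}" for c in ("GD", "PIC", "Ho", "MAF")))

pca = popgen.pca_covariance(gm)
print(f"PC1 / PC2 variance explained : "
      f"{100 * pca['proportions'][0]:.1f}% / {100 * pca['proportions'][1]:.1f}%")

fits = popgen.fit_k_range(gm, [1, 2, 3, 4], n_replicates=3, seed=17,
                          max_iter=500, tol=1e-4)
deltak = popgen.evanno_delta_k(fits)
print(f"delta-K selected K           : {deltak.selected_k}")

best = max(fits[2], key=lambda f: f.loglik)
q = popgen.align_cluster_labels(best.Q, pop.Q_true)
print(f"ancestry recovery (mean |Q_hat - Q|) : {np.abs(q - pop.Q_true).mean():.3f}")

# GD (expected heterozygosity) near 0.38 and PIC near 0.30 say the markers
# are moderately informative; delta-K = 2 recovers the two simulated source
# populations, and the small Q error shows individual admixture proportions
# are estimated accurately.
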