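"""Polygenic scores, gene-list overlap, and group statistics.

The polygenic score sums effect-size-weighted alternative-allele dosages per
bee; the overlap test gives hypergeometric enrichment between two gene
lists; group_stats reproduces the ANOVA/Tukey reporting style for comparing
phenotypes between source colonies.
"""

import numpy as np

from hiveflow import (simulate_genotypes, polygenic_score, overlap_test,
                      group_stats, rank_correlation)

rng = np.random.default_rng(0)
effects = rng.normal(0, 0.3, 50)
dosages, truth = simulate_genotypes(n_bees=90, n_snps=50, effect_sizes=effects, seed=1)
eff = {f"snp{i + 1:05d}": effects[i] for i in range(50)}
prs = polygenic_score(dosages, eff)
print(f"polygenic scores: mean {prs.mean():.2f}, sd {prs.std():.2f} "
      f"(matches ground truth: {np.allclose(prs, [truth.prs[b] for b in range(90)])})")

genes = [f"gene{i}" for i in range(1000)]
up = rng.choice(genes, 150, replace=False)
correlated = list(rng.choice(up, 40, replace=False)) + list(rng.choice(genes, 80, replace=False))
res = overlap_test(up, correlated, background_size=1000)
print(f"overlap {res.overlap} genes, fold enrichment {res.fold_enrichment:.1f}, "
      f"p = {res.p_value:.2e}")

colony = np.repeat(["R2", "R8", "R41"], 30)
phenotype = prs + np.where(colony == "R41", 1.5, 0.0)
stats = group_stats(phenotype, colony)
print(f"one-way ANOVA: F = {stats.anova_f:.2f}, p = {stats.anova_p:.2e}")
rho, p = rank_correlation(prs, phenotype)
print(f"Spearman rho(PRS, phenotype) = {rho:.2f} (p = {p:.1e})")
# Fold enrichment > 1 with a tiny p-value means the two gene lists share far
# more members than expected for independent draws from the background.
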