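"""Two-point PPL scan: where does the trait cosegregate with the map?

The PPL integrates the trait-marker likelihood ratio over a grid of
threshold-model parameters and recombination fractions, then updates a 2%
prior probability of linkage.  Per-family Bayes factors multiply
(sequential updating), so the pooled posterior accumulates evidence across
families.  Values near the 0.02 prior mean "no information"; values near 1
mean strong cosegregation.
"""

import numpy as np

from ngla.ppl import PriorConfig, ppl_scan
from ngla.simulate import SimConfig, simulate_study
from ngla.subsample import SubsamplePlan, select_subsample
from ngla.trait import TraitGridConfig, build_trait_grid, standardize_phenotypes

cfg = SimConfig(n_families=8, family_size_range=(20, 30), n_markers=60, seed=11)
bundle, truth = simulate_study(cfg)

std = standardize_phenotypes(bundle.phenotypes["sbp"].to_numpy(float))[0]
grid = build_trait_grid(TraitGridConfig.coarse(), std[np.isfinite(std)])
scan_markers = select_subsample(bundle, SubsamplePlan(seed=1), 0)[::2][:10]
phen = {p.family_id: bundle.pheno_obs(family_id=p.family_id)[0]
        for p in bundle.pedigrees}

track = ppl_scan(
    bundle.pedigrees, phen,
    lambda fam, j: bundle.genotypes.column(j, bundle.pedigree(fam).ids),
    bundle.alt_freq(), bundle.panel.cm, scan_markers, grid,
    PriorConfig(), marker_names=bundle.panel.ids)

print(f"true trait locus at {cfg.trait_locus_cm} cM; prior PPL = 0.020")
print(f"{'pos_cM':>7} {'marker':>8} {'BF':>8} {'PPL':>6}")
for r in track:
    print(f"{r.position_cm:7.1f} {r.marker:>8} {r.bayes_factor:8.2f} {r.posterior:6.3f}")
best = max(track, key=lambda r: r.posterior)
print(f"max pooled PPL {best.posterior:.3f} at {best.position_cm:.1f} cM")
print("A single diallelic SNP carries little cosegregation information in")
print("families of this size, so the posterior moves only modestly off its")
print("prior -- and, crucially, it does NOT inflate at unlinked markers.")
print("Localization is the job of the averaged-LOD subsample scan (example 04)")
print("and of PPLD fine-mapping (example 03), which uses association rather")
print("than transmissions and is far more powerful at the causal site.")
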