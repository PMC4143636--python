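"""PPLD fine-mapping: which variants under the peak are associated?

The PPLD couples the trait allele to a variant allele through founder
haplotype frequencies (standardized LD coefficient d', tight linkage) and
integrates the pedigree likelihood ratio over the trait grid and a d'
grid against the d'=0 null.  The prior probability of LD is 0.04%, so a
posterior of 4% is already a 100-fold update; the causal variant should
rank first.
"""

import numpy as np

from ngla.ppld import ppld_scan
from ngla.simulate import SimConfig, simulate_study
from ngla.trait import TraitGridConfig, build_trait_grid, standardize_phenotypes

cfg = SimConfig(n_families=8, family_size_range=(20, 30), n_markers=60, seed=11)
bundle, truth = simulate_study(cfg)

std = standardize_phenotypes(bundle.phenotypes["sbp"].to_numpy(float))[0]
grid = build_trait_grid(TraitGridConfig.coarse(), std[np.isfinite(std)])

t = bundle.panel.table
region = (int(t["bp"][t["cm"] >= 44].min()), int(t["bp"][t["cm"] <= 64].max()))
full, hits = ppld_scan(bundle, grid, region_bp=region)

print(f"scanned {len(full)} polymorphic variants in a 20 cM window around the peak")
top = full.sort_values("PPLD", ascending=False).head(5)
print(top.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
print(f"causal variant: {truth.trait_marker_id} "
      f"(PPLD far above the 0.0004 prior marks association; "
      f"unassociated variants stay near it)")
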