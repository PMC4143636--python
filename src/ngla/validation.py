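"""Simulation studies validating calibration and recovery.

Two replicate designs drive the package's own validation:

* **Null calibration** -- the trait locus is fully unlinked to the scanned
  map, so both the PPL and the PPLD should stay near their priors.  One
  replicate returns the maximum pooled PPL across an LD-pruned marker
  scan and the maximum PPLD across the rare variants of a fixed region.
* **Linked recovery** -- a protective recessive locus (homozygote
  displacement 2 SD) sits at 54 cM of a 100 cM map and is observed as a
  sequence variant.  One replicate returns the averaged-LOD 1-LOD support
  interval and the rank of the causal variant among the region's PPLD
  records.

Problem sizes are deliberately modest (two 20-member families per null
replicate; eight families of 20-30 for recovery) so that hundreds of
replicates run on a single CPU; the integration grids are coarse but
proper (both orientations, recessive-to-additive dominance, two allele
frequencies and thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ppl import PriorConfig, ppl_scan
from .ppld import DEFAULT_PPLD_PRIOR, ppld
from .simulate import PlantedHaplotype, SimConfig, simulate_study
from .subsample import SubsamplePlan, average_lod_scan, select_subsample
from .trait import TraitGridConfig, TraitModel, build_trait_grid, standardize_phenotypes

__all__ = ["null_replicate", "linked_replicate", "NullResult", "LinkedResult"]

_ACC_THETA = np.array([0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5])
_ACC_DPRIME = np.array([0.0, 0.4, -0.4, 0.8, -0.8])
_REGION_CM = (44.0, 64.0)


def _grid_for(bundle):
    std = standardize_phenotypes(bundle.phenotypes["sbp"].to_numpy(float))[0]
    return build_trait_grid(TraitGridConfig.coarse(), std[np.isfinite(std)])


def _scan_indices(bundle, plan: SubsamplePlan, step: int = 3, cap: int = 8) -> list[int]:
    """Scan markers: every ``step``-th SNP of the first LD-pruned subsample."""
    sub = select_subsample(bundle, plan, 0)
    return sub[::step][:cap]


@dataclass
class NullResult:
    max_ppl: float
    max_ppld: float
    n_individuals: int


def null_replicate(seed: int, n_families: int = 2, family_size: int = 20,
                   n_markers: int = 60) -> NullResult:
    """One null-calibration replicate: trait locus unlinked to the map."""
    cfg = SimConfig(
        n_families=n_families,
        family_size_range=(family_size, family_size),
        n_markers=n_markers,
        trait_locus_cm=None,
        observe_trait_locus=False,
        planted=None,
        seed=seed,
    )
    bundle, _ = simulate_study(cfg)
    grid = _grid_for(bundle)
    priors = PriorConfig(theta_grid=_ACC_THETA)
    plan = SubsamplePlan(n_subsamples=1, seed=seed)
    idxs = _scan_indices(bundle, plan)
    phen = {p.family_id: bundle.pheno_obs(family_id=p.family_id)[0]
            for p in bundle.pedigrees}
    freqs = bundle.alt_freq()
    track = ppl_scan(
        bundle.pedigrees, phen,
        lambda f, j: bundle.genotypes.column(j, bundle.pedigree(f).ids),
        freqs, bundle.panel.cm, idxs, grid, priors)
    max_ppl = max(r.posterior for r in track)

    t = bundle.panel.table
    in_region = [j for j in range(len(t))
                 if _REGION_CM[0] <= t["cm"].iloc[j] <= _REGION_CM[1]]
    rare = [j for j in in_region if str(t["marker"].iloc[j]).startswith("rv")]
    common = [j for j in in_region if j not in rare][:4]
    region = rare + common
    ppld_max = DEFAULT_PPLD_PRIOR
    for j in region:
        rec = ppld(bundle, j, grid, dprime_grid=_ACC_DPRIME)
        if not rec.monomorphic:
            ppld_max = max(ppld_max, rec.posterior)
    return NullResult(max_ppl, ppld_max, len(bundle.genotypes.ids))


@dataclass
class LinkedResult:
    support_interval: tuple[float, float]
    covers_locus: bool
    max_avg_lod: float
    causal_rank: int
    n_records: int
    n_individuals: int


def linked_replicate(seed: int, n_families: int = 8,
                     family_size_range: tuple[int, int] = (20, 30),
                     n_markers: int = 60, n_subsamples: int = 15) -> LinkedResult:
    """One linked-recovery replicate: recessive 2-SD locus at 54 cM.

    The averaged-LOD scan uses the generator's true trait model (in
    standardized units) as its fixed model, mirroring a fixed-model LOD
    analysis at the simulating truth.
    """
    cfg = SimConfig(
        n_families=n_families,
        family_size_range=family_size_range,
        n_markers=n_markers,
        planted=PlantedHaplotype(carrier_families=("2", "4")),
        seed=seed,
    )
    bundle, truth = simulate_study(cfg)
    tm = cfg.trait_model_true
    _, center, scale = bundle.pheno_obs()
    fixed = TraitModel(tm.p_d, tuple((m - center) / scale for m in tm.mu),
                       tm.sigma / scale, (tm.tau - center) / scale)
    plan = SubsamplePlan(n_subsamples=n_subsamples, seed=seed)
    positions = np.arange(0.0, cfg.cm_span + 0.001, 4.0)
    track = average_lod_scan(bundle, plan, fixed, positions)
    lo, hi = track.support_interval()
    covers = lo <= cfg.trait_locus_cm <= hi

    grid = _grid_for(bundle)
    t = bundle.panel.table
    region = [j for j in range(len(t))
              if _REGION_CM[0] <= t["cm"].iloc[j] <= _REGION_CM[1]]
    recs = []
    for j in region:
        rec = ppld(bundle, j, grid, dprime_grid=_ACC_DPRIME)
        if not rec.monomorphic:
            recs.append(rec)
    recs.sort(key=lambda r: (-r.posterior, r.variant))
    names = [r.variant for r in recs]
    rank = names.index(truth.trait_marker_id) + 1 if truth.trait_marker_id in names else len(names) + 1
    return LinkedResult((lo, hi), covers, track.max_lod, rank, len(recs),
                        len(bundle.genotypes.ids))
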