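"""Synthetic family-study generator.

Emulates the statistical structure of a large multi-family sequencing
study of systolic blood pressure: several multi-generation pedigrees,
dense diallelic markers with block LD, a diallelic trait locus whose
genotype shifts a normal SBP distribution, a treatment threshold that
censors high SBP values to affected-status, missing phenotypes, and a
planted rare multi-site haplotype confined to a designated subset of
families.

Founder haplotypes are drawn from a small per-block haplotype pool
(giving high adjacent r-squared that the linkage subsampler must prune
away); nonfounder genotypes arise by Mendelian gene dropping with
recombination per Haldane map distances.  Everything is reproducible
from (config, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .likelihood import haldane_theta
from .pedigree import Individual, Pedigree
from .study_io import GenotypeMatrix, MarkerPanel, StudyBundle
from .trait import TraitModel

__all__ = ["SimConfig", "SimTruth", "simulate_pedigrees", "drop_genotypes",
           "simulate_phenotypes", "simulate_study"]

_BASES = ("A", "C", "G", "T")


def _default_trait_model() -> TraitModel:
    # protective recessive locus: dd homozygotes sit 2 SD below the rest;
    # tau = 140 mmHg is the conventional hypertension treatment threshold.
    return TraitModel(p_d=0.2, mu=(125.0, 125.0, 95.0), sigma=15.0, tau=140.0)


@dataclass
class PlantedHaplotype:
    """A rare multi-site haplotype carried only by designated families."""

    n_sites: int = 4
    carrier_families: tuple[str, ...] = ("4", "15")
    founder_carriers_per_family: int = 1
    # physically clustered sites at negligible genetic distance from the
    # trait locus (below map resolution), so the haplotype never recombines
    offsets_cm: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)


@dataclass
class SimConfig:
    """Study-generator configuration.

    Defaults emulate the family study the pipeline is designed for:
    20 multi-generation pedigrees (tens of members each), a dense panel
    with block LD and ~43% mean heterozygosity, a protective recessive
    trait locus at 54 cM of a 100 cM map, deterministic treatment above
    140 mmHg, 38% missing phenotypes, and a 4-site rare haplotype planted
    in families "4" and "15".
    """

    n_families: int = 20
    family_size_range: tuple[int, int] = (20, 60)
    n_markers: int = 120
    cm_span: float = 100.0
    ld_block_size: int = 4
    block_pool_mutation: float = 0.006  # per-site flip away from the pool haplotype
    rare_fraction: float = 0.1  # fraction of panel sites that are rare variants
    rare_freq_range: tuple[float, float] = (0.002, 0.01)
    trait_locus_cm: float | None = 54.0  # None = unlinked to the scanned map
    trait_model_true: TraitModel = field(default_factory=_default_trait_model)
    treatment_mechanism: str = "deterministic"  # or "stochastic"
    treatment_prob: float = 0.8  # used only by the stochastic mechanism
    missing_phenotype_rate: float = 0.38
    observe_trait_locus: bool = True
    planted: PlantedHaplotype | None = field(default_factory=PlantedHaplotype)
    annotation_conserved_fraction: float = 0.15
    chrom: str = "3"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        lo, hi = self.family_size_range
        if lo < 3 or hi < lo:
            raise ValueError(f"infeasible family size range {self.family_size_range}")
        for r in (self.missing_phenotype_rate, self.rare_fraction,
                  self.block_pool_mutation, self.treatment_prob):
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"rate {r} outside [0,1]")
        if self.trait_locus_cm is not None and not (
                0.0 <= self.trait_locus_cm <= self.cm_span):
            raise ValueError("trait locus must lie inside the map span")


@dataclass
class SimTruth:
    """Generator ground truth, for validation and power studies."""

    trait_genotypes: dict[str, int]
    trait_marker_id: str | None
    planted_marker_ids: list[str]
    planted_carrier_ids: list[str]
    panel_is_rare: np.ndarray
    config: SimConfig


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------


def simulate_pedigrees(config: SimConfig, rng: np.random.Generator | None = None
                       ) -> list[Pedigree]:
    """Generate loop-free multi-generation pedigrees.

    Each family starts from one founder couple; children marry in new
    founders and reproduce until the target size (uniform in
    ``family_size_range``) is reached.  Every nonfounder mates only with a
    married-in founder, which guarantees loop-freeness by construction.
    """
    rng = rng or np.random.default_rng(config.seed)
    out = []
    for k in range(config.n_families):
        fam = str(k + 1)
        target = int(rng.integers(config.family_size_range[0],
                                  config.family_size_range[1] + 1))
        out.append(_simulate_one_family(fam, target, rng))
    return out


def _simulate_one_family(fam: str, target: int, rng: np.random.Generator) -> Pedigree:
    members: list[Individual] = []
    counter = itertools.count(1)

    def new_id() -> str:
        return f"{fam}-{next(counter)}"

    f0, m0 = new_id(), new_id()
    members.append(Individual(f0, None, None, 1, fam))
    members.append(Individual(m0, None, None, 2, fam))
    couples = [(f0, m0)]
    while couples and len(members) < target:
        next_couples = []
        for fa, mo in couples:
            if len(members) >= target:
                break
            n_kids = int(rng.integers(2, 5))
            for ci in range(n_kids):
                if len(members) >= target:
                    break
                sex = int(rng.integers(1, 3))
                kid = new_id()
                members.append(Individual(kid, fa, mo, sex, fam))
                # first child always marries on (keeps the pedigree deep);
                # later children marry in a founder with probability 0.6
                marries = (ci == 0) or (rng.random() < 0.6)
                if marries and len(members) < target - 1:
                    sp = new_id()
                    members.append(Individual(sp, None, None, 3 - sex, fam))
                    if sex == 1:
                        next_couples.append((kid, sp))
                    else:
                        next_couples.append((sp, kid))
        couples = next_couples
    return Pedigree(fam, members)


# ---------------------------------------------------------------------------
# marker panel
# ---------------------------------------------------------------------------


def build_panel(config: SimConfig, rng: np.random.Generator):
    """Construct the marker map: LD blocks + rare sites (+ planted sites,
    + the trait variant when observed).

    Returns (MarkerPanel, block_id array (-1 for non-block sites),
    pool_freq array, is_rare array, site_freq array, planted_idx,
    trait_idx).
    """
    n_rare = int(round(config.n_markers * config.rare_fraction))
    n_common = config.n_markers - n_rare
    n_blocks = max(1, n_common // config.ld_block_size)

    rows = []
    block_id = []
    pool_freq_site = []
    is_rare = []
    freqs = []

    block_starts = np.linspace(1.0, config.cm_span - 1.0, n_blocks)
    j = 0
    for b, start in enumerate(block_starts):
        f = rng.uniform(0.2, 0.8)
        size = config.ld_block_size if b < n_blocks - 1 else n_common - config.ld_block_size * (n_blocks - 1)
        for s in range(size):
            rows.append((f"snp{j+1}", start + 0.02 * s))
            block_id.append(b)
            pool_freq_site.append(f)
            is_rare.append(False)
            freqs.append(f)
            j += 1
    rare_pos = rng.uniform(0.0, config.cm_span, size=n_rare)
    for k, pos in enumerate(sorted(rare_pos)):
        rows.append((f"rv{k+1}", pos))
        block_id.append(-1)
        pool_freq_site.append(np.nan)
        is_rare.append(True)
        freqs.append(rng.uniform(*config.rare_freq_range))

    planted_ids = []
    if config.planted is not None and config.trait_locus_cm is not None:
        base = config.trait_locus_cm
        for s in range(config.planted.n_sites):
            off = config.planted.offsets_cm[s % len(config.planted.offsets_cm)]
            rows.append((f"hap{s+1}", float(np.clip(base + off, 0, config.cm_span))))
            block_id.append(-1)
            pool_freq_site.append(np.nan)
            is_rare.append(True)
            freqs.append(0.0)  # carried only by the planted founders
            planted_ids.append(f"hap{s+1}")

    trait_id = None
    if config.observe_trait_locus and config.trait_locus_cm is not None:
        trait_id = "causal1"
        rows.append((trait_id, float(config.trait_locus_cm)))
        block_id.append(-1)
        pool_freq_site.append(np.nan)
        is_rare.append(False)
        freqs.append(config.trait_model_true.p_d)

    order = np.argsort([r[1] for r in rows], kind="stable")
    rows = [rows[i] for i in order]
    block_id = np.array([block_id[i] for i in order])
    pool_freq_site = np.array([pool_freq_site[i] for i in order])
    is_rare = np.array([is_rare[i] for i in order])
    freqs = np.array([freqs[i] for i in order])

    ref = rng.choice(_BASES, size=len(rows))
    alt = np.array([rng.choice([b for b in _BASES if b != r]) for r in ref])
    tab = pd.DataFrame({
        "marker": [r[0] for r in rows],
        "chrom": config.chrom,
        "cm": [r[1] for r in rows],
        "bp": (np.array([r[1] for r in rows]) * 1e6).astype(np.int64) + 1,
        "ref": ref,
        "alt": alt,
    })
    # bp must be unique & increasing with cm ties
    tab["bp"] = tab["bp"] + np.arange(len(tab))
    panel = MarkerPanel(tab)
    planted_idx = [panel.index_of(x) for x in planted_ids]
    trait_idx = panel.index_of(trait_id) if trait_id else None
    return panel, block_id, pool_freq_site, is_rare, freqs, planted_idx, trait_idx


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------


def _founder_haplotype(n_sites, block_id, pool_freq, freqs, config, rng) -> np.ndarray:
    """One founder haplotype over all panel sites (alt-allele 0/1)."""
    hap = np.zeros(n_sites, dtype=np.int8)
    for b in np.unique(block_id[block_id >= 0]):
        sel = block_id == b
        f = pool_freq[sel][0]
        base = 1 if rng.random() < f else 0
        hap[sel] = base
        flips = rng.random(sel.sum()) < config.block_pool_mutation
        hap[sel] = np.where(flips, 1 - hap[sel], hap[sel])
    loose = block_id < 0
    hap[loose] = rng.random(loose.sum()) < freqs[loose]
    return hap


def drop_genotypes(pedigrees: list[Pedigree], panel: MarkerPanel, config: SimConfig,
                   rng: np.random.Generator | None = None,
                   aux=None) -> tuple[GenotypeMatrix, SimTruth]:
    """Gene-drop the panel through the pedigrees.

    Founder haplotypes come from the block-LD pool model; transmissions
    recombine between adjacent sites with Haldane probabilities.  The
    planted rare haplotype is written onto the configured founder
    chromosomes of the carrier families before dropping.  The trait locus
    is dropped jointly: linked at ``trait_locus_cm`` (or fully unlinked
    when the configured position is None).
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    if aux is None:
        panel, block_id, pool_freq, is_rare, freqs, planted_idx, trait_idx = build_panel(
            config, rng)
    else:
        block_id, pool_freq, is_rare, freqs, planted_idx, trait_idx = aux

    cm = panel.cm
    theta_gap = haldane_theta(np.diff(cm))
    n_sites = len(panel)

    ids: list[str] = []
    dosage_cols = []
    trait_geno: dict[str, int] = {}
    carrier_ids: list[str] = []
    p_d = config.trait_model_true.p_d
    unlinked_trait = trait_idx is None

    for ped in pedigrees:
        haps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        t_haps: dict[str, tuple[int, int]] = {}
        planted_founders: set[str] = set()
        if (config.planted is not None and planted_idx
                and ped.family_id in config.planted.carrier_families):
            cands = [m.iid for m in ped.founders]
            pick = rng.choice(cands, size=min(config.planted.founder_carriers_per_family,
                                              len(cands)), replace=False)
            planted_founders = set(str(x) for x in pick)
        for ind in ped.members:
            if ind.is_founder:
                h1 = _founder_haplotype(n_sites, block_id, pool_freq, freqs, config, rng)
                h2 = _founder_haplotype(n_sites, block_id, pool_freq, freqs, config, rng)
                if ind.iid in planted_founders:
                    h1[planted_idx] = 1
                t1 = int(rng.random() < p_d) if unlinked_trait else None
                t2 = int(rng.random() < p_d) if unlinked_trait else None
            else:
                fh = haps[ind.father]
                mh = haps[ind.mother]
                h1 = _transmit(fh, theta_gap, rng)
                h2 = _transmit(mh, theta_gap, rng)
                if unlinked_trait:
                    t1 = t_haps[ind.father][rng.integers(2)]
                    t2 = t_haps[ind.mother][rng.integers(2)]
            haps[ind.iid] = (h1, h2)
            if unlinked_trait:
                t_haps[ind.iid] = (t1, t2)
                trait_geno[ind.iid] = t1 + t2
            else:
                trait_geno[ind.iid] = int(h1[trait_idx] + h2[trait_idx])
            ids.append(ind.iid)
            dosage_cols.append(h1 + h2)
            if planted_idx and (haps[ind.iid][0][planted_idx].all()
                                or haps[ind.iid][1][planted_idx].all()):
                carrier_ids.append(ind.iid)

    dosage = np.stack(dosage_cols).astype(np.int16)
    truth = SimTruth(
        trait_genotypes=trait_geno,
        trait_marker_id=(panel.ids[trait_idx] if trait_idx is not None else None),
        planted_marker_ids=[panel.ids[j] for j in planted_idx],
        planted_carrier_ids=carrier_ids,
        panel_is_rare=is_rare,
        config=config,
    )
    return GenotypeMatrix(ids, dosage), truth


def _transmit(parent_haps, theta_gap, rng) -> np.ndarray:
    h1, h2 = parent_haps
    n = h1.shape[0]
    origin = np.empty(n, dtype=np.int8)
    origin[0] = rng.integers(2)
    flips = rng.random(n - 1) < theta_gap
    origin[1:] = origin[0] ^ np.cumsum(flips.astype(np.int8)) % 2
    return np.where(origin == 0, h1, h2)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def simulate_phenotypes(pedigrees: list[Pedigree], trait_genotypes: dict[str, int],
                        config: SimConfig, rng: np.random.Generator | None = None
                        ) -> pd.DataFrame:
    """Latent SBP ~ Normal(mu[g], sigma); exceed tau -> treated, value censored.

    The deterministic default flags everyone above the threshold as
    treated (mirroring the analysis model); the stochastic mechanism
    flags them with probability ``treatment_prob`` instead.  Untreated
    individuals then lose their value with ``missing_phenotype_rate``.
    Ages decrease by generation from the founders.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    tm = config.trait_model_true
    rows = []
    for ped in pedigrees:
        depth: dict[str, int] = {}
        for ind in ped.members:
            depth[ind.iid] = 1 if ind.is_founder else 1 + max(
                depth[ind.father], depth[ind.mother])
        for ind in ped.members:
            g = trait_genotypes[ind.iid]
            latent = tm.mu[g] + tm.sigma * rng.standard_normal()
            age = max(18.0, 95.0 - 28.0 * depth[ind.iid] + rng.uniform(-6, 6))
            if latent > tm.tau and (
                    config.treatment_mechanism == "deterministic"
                    or rng.random() < config.treatment_prob):
                rows.append((ind.iid, np.nan, True, age))
            elif rng.random() < config.missing_phenotype_rate:
                rows.append((ind.iid, np.nan, False, age))
            else:
                rows.append((ind.iid, round(latent, 4), False, age))
    df = pd.DataFrame(rows, columns=["id", "sbp", "treated", "age"]).set_index("id")
    return df


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------


def simulate_study(config: SimConfig) -> tuple[StudyBundle, SimTruth]:
    """Generate a complete, validated StudyBundle plus ground truth."""
    rng = np.random.default_rng(config.seed)
    peds = simulate_pedigrees(config, rng)
    panel, *aux = build_panel(config, rng)
    geno, truth = drop_genotypes(peds, panel, config, rng, aux=tuple(aux))
    pheno = simulate_phenotypes(peds, truth.trait_genotypes, config, rng)

    t = panel.table
    scores = np.where(rng.random(len(t)) < config.annotation_conserved_fraction,
                      rng.uniform(220, 400, len(t)),
                      rng.uniform(0, 200, len(t)))
    for j, mid in enumerate(truth.planted_marker_ids):
        # one haplotype site lands in a conserved element, like a real hit
        if j == 1:
            scores[panel.index_of(mid)] = rng.uniform(260, 320)
    ann = pd.DataFrame({
        "chrom": t["chrom"], "pos": t["bp"], "ref": t["ref"], "alt": t["alt"],
        "phastcons44": np.round(scores, 1),
    })
    bundle = StudyBundle(pedigrees=peds, phenotypes=pheno, panel=panel,
                         genotypes=geno, annotations=ann)
    return bundle, truth
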