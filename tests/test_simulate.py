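import numpy as np
import pytest

from ngla.likelihood import haldane_theta
from ngla.simulate import (
    PlantedHaplotype,
    SimConfig,
    build_panel,
    drop_genotypes,
    simulate_pedigrees,
    simulate_phenotypes,
    simulate_study,
)
from ngla.trait import TraitModel


def small_cfg(**kw):
    base = dict(n_families=2, family_size_range=(8, 12), n_markers=24, seed=1)
    base.update(kw)
    return SimConfig(**base)


def test_seed_is_mandatory():
    with pytest.raises(ValueError):
        SimConfig(seed=None)


def test_infeasible_size_range_rejected():
    with pytest.raises(ValueError, match="size range"):
        small_cfg(family_size_range=(5, 3))


def test_trait_locus_must_lie_in_span():
    with pytest.raises(ValueError, match="span"):
        small_cfg(trait_locus_cm=150.0)


def test_trio_size_range_gives_trio():
    peds = simulate_pedigrees(small_cfg(n_families=1, family_size_range=(3, 3)))
    assert len(peds) == 1 and len(peds[0]) == 3
    assert len(peds[0].founders) == 2


def test_large_family_has_at_least_three_generations():
    peds = simulate_pedigrees(small_cfg(n_families=1, family_size_range=(55, 60)))
    ped = peds[0]
    assert 55 <= len(ped) <= 60
    assert ped.n_generations() >= 3
    assert len(ped.founders) >= 2


def test_same_seed_reproduces_everything():
    cfg = small_cfg(seed=77)
    b1, t1 = simulate_study(cfg)
    b2, t2 = simulate_study(small_cfg(seed=77))
    assert b1.genotypes.ids == b2.genotypes.ids
    assert (b1.genotypes.dosage == b2.genotypes.dosage).all()
    assert b1.phenotypes.equals(b2.phenotypes)
    assert t1.trait_genotypes == t2.trait_genotypes
    b3, _ = simulate_study(small_cfg(seed=78))
    assert not (b3.genotypes.dosage.shape == b1.genotypes.dosage.shape
                and (b3.genotypes.dosage == b1.genotypes.dosage).all())


def test_mendelian_consistency_of_dropped_genotypes():
    """Independent validator: every child dosage must be reachable from its
    parents' dosages at every marker."""
    bundle, _ = simulate_study(small_cfg(n_families=3, seed=3))
    D = bundle.genotypes.dosage
    for ped in bundle.pedigrees:
        for ind in ped.nonfounders:
            c = D[bundle.genotypes.row(ind.iid)]
            f = D[bundle.genotypes.row(ind.father)]
            m = D[bundle.genotypes.row(ind.mother)]
            # child alt count bounded by what the parents can transmit
            assert np.all(c >= (f == 2).astype(int) + (m == 2).astype(int)), ind.iid
            assert np.all(c <= (f > 0).astype(int) + (m > 0).astype(int)), ind.iid


def test_zero_distance_markers_never_recombine():
    """Two markers at the same cM position always travel together: the
    transmitted two-site haplotypes stay in perfect association."""
    cfg = small_cfg(n_families=4, family_size_range=(10, 14), seed=9,
                    planted=PlantedHaplotype(n_sites=2, carrier_families=("1", "2")))
    bundle, truth = simulate_study(cfg)
    j1, j2 = (bundle.panel.index_of(m) for m in truth.planted_marker_ids)
    d1 = bundle.genotypes.dosage[:, j1]
    d2 = bundle.genotypes.dosage[:, j2]
    assert (d1 == d2).all()


def test_distant_markers_recombine_at_half():
    """Empirical recombination fraction between markers >= 50 cM apart
    approaches 1/2 (within Monte-Carlo error)."""
    rng = np.random.default_rng(0)
    theta = float(haldane_theta(80.0))
    from ngla.simulate import _transmit
    h1 = np.array([0, 0], dtype=np.int8)
    h2 = np.array([1, 1], dtype=np.int8)
    gap = np.array([theta])
    rec = 0
    n = 4000
    for _ in range(n):
        out = _transmit((h1, h2), gap, rng)
        rec += out[0] != out[1]
    assert rec / n == pytest.approx(theta, abs=0.03)
    assert theta > 0.39


def test_planted_haplotype_confined_to_carrier_families():
    cfg = SimConfig(n_families=6, family_size_range=(10, 16), n_markers=40,
                    seed=21, planted=PlantedHaplotype(carrier_families=("2", "5")))
    bundle, truth = simulate_study(cfg)
    idx = [bundle.panel.index_of(m) for m in truth.planted_marker_ids]
    D = bundle.genotypes.dosage[:, idx]
    full_carriers = [bundle.genotypes.ids[i] for i in range(D.shape[0])
                     if (D[i] >= 1).all()]
    fams = {bundle.family_of(i) for i in full_carriers}
    assert full_carriers and fams <= {"2", "5"}


def test_zero_sd_gives_exact_genotype_means():
    cfg = small_cfg(
        trait_model_true=TraitModel(0.3, (120.0, 110.0, 100.0), 1e-9, 1e9),
        missing_phenotype_rate=0.0)
    bundle, truth = simulate_study(cfg)
    for iid, row in bundle.phenotypes.iterrows():
        g = truth.trait_genotypes[iid]
        assert row["sbp"] == pytest.approx((120.0, 110.0, 100.0)[g], abs=1e-3)


def test_infinite_threshold_means_no_treated():
    cfg = small_cfg(trait_model_true=TraitModel(0.2, (120.0, 120.0, 100.0), 15.0, 1e9))
    bundle, _ = simulate_study(cfg)
    assert bundle.phenotypes["treated"].sum() == 0


def test_equal_means_decouple_sbp_from_genotype():
    """With equal genotype means the regression of SBP on trait dosage has
    slope ~ 0."""
    cfg = SimConfig(n_families=10, family_size_range=(15, 20), n_markers=12,
                    trait_model_true=TraitModel(0.3, (120.0, 120.0, 120.0), 10.0, 1e9),
                    missing_phenotype_rate=0.0, planted=None, seed=4)
    bundle, truth = simulate_study(cfg)
    y = bundle.phenotypes["sbp"]
    g = np.array([truth.trait_genotypes[i] for i in y.index], float)
    slope = np.polyfit(g, y.to_numpy(float), 1)[0]
    assert abs(slope) < 1.5  # SD units: 10 mmHg noise, n ~ 170


def test_founder_frequencies_converge_to_target():
    cfg = SimConfig(n_families=60, family_size_range=(3, 3), n_markers=20,
                    rare_fraction=0.0, planted=None, seed=8)
    bundle, truth = simulate_study(cfg)
    jc = bundle.panel.index_of(truth.trait_marker_id)
    f = bundle.alt_freq(jc)
    assert f == pytest.approx(cfg.trait_model_true.p_d, abs=0.08)


def test_unlinked_trait_locus_has_no_observed_variant():
    cfg = small_cfg(trait_locus_cm=None, observe_trait_locus=False, planted=None)
    bundle, truth = simulate_study(cfg)
    assert truth.trait_marker_id is None
    assert set(truth.trait_genotypes) == set(bundle.genotypes.ids)
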