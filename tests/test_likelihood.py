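import math

import numpy as np
import pytest

from studyfactories import random_observations, random_pedigree, trio_pedigree

from ngla.likelihood import (
    MeiosisCapExceeded,
    haldane_cm,
    haldane_theta,
    multipoint_likelihood,
    single_locus_likelihood,
    trait_only_likelihood,
    two_point_likelihood,
)
from ngla.oracle import (
    enumerate_multipoint,
    enumerate_single_locus,
    enumerate_two_point,
)
from ngla.pedigree import Individual, Pedigree
from ngla.trait import TraitModel

MODEL = TraitModel(p_d=0.25, mu=(-0.2, 0.1, 1.0), sigma=1.0, tau=1.1)


def test_haldane_round_trip():
    cm = np.array([0.0, 1.0, 10.0, 50.0])
    assert np.allclose(haldane_cm(haldane_theta(cm)), cm)
    assert haldane_theta(1e9) == pytest.approx(0.5)


def test_trio_homozygous_alt_is_p4(trio):
    p = 0.3
    val = single_locus_likelihood(trio, {"f": 2, "m": 2, "c": 2}, p)
    assert val == pytest.approx(p ** 4, rel=1e-12)


def test_fully_missing_genotypes_sum_to_one(three_gen):
    assert single_locus_likelihood(three_gen, {}, 0.37) == pytest.approx(1.0, rel=1e-12)


def test_mendelian_inconsistency_gives_zero_not_exception(trio):
    # AA x AA parents cannot produce an aa child
    assert single_locus_likelihood(trio, {"f": 2, "m": 2, "c": 0}, 0.5) == 0.0


def test_two_point_at_half_theta_factorizes(three_gen):
    pheno = {"f": 0.4, "m": "treated", "c": None, "w": -1.0, "g": 0.9}
    geno = {"f": 1, "m": 0, "c": 1, "w": 2, "g": 1}
    joint = two_point_likelihood(three_gen, pheno, geno, 0.5, MODEL, 0.4)
    factored = (single_locus_likelihood(three_gen, geno, 0.4)
                * trait_only_likelihood(three_gen, pheno, MODEL))
    assert joint == pytest.approx(factored, rel=1e-12)


def test_uninformative_trait_model_reduces_to_marker_likelihood(three_gen):
    flat = TraitModel(0.25, (0.0, 0.0, 0.0), 1.0, 1.0)
    pheno = {"f": 0.4, "g": -0.2}
    geno = {"f": 1, "m": 0, "g": 2}
    joint = two_point_likelihood(three_gen, pheno, geno, 0.1, flat, 0.4)
    marker = single_locus_likelihood(three_gen, geno, 0.4)
    trait = trait_only_likelihood(three_gen, pheno, flat)
    # equal genotype means: phenotypes are independent of everything genetic
    assert joint == pytest.approx(marker * trait, rel=1e-12)


def test_likelihood_invariant_under_member_reordering(three_gen):
    pheno = {"f": 0.4, "m": "treated", "g": 0.9}
    geno = {"f": 1, "m": 0, "c": 1, "w": 2, "g": 1}
    reordered = Pedigree("1", list(reversed(three_gen.members)))
    a = two_point_likelihood(three_gen, pheno, geno, 0.2, MODEL, 0.4)
    b = two_point_likelihood(reordered, pheno, geno, 0.2, MODEL, 0.4)
    assert a == pytest.approx(b, rel=1e-12)


@pytest.mark.parametrize("seed", range(12))
def test_peeling_matches_enumeration_on_random_families(seed):
    rng = np.random.default_rng(900 + seed)
    ped = random_pedigree(rng, n_max=6)
    geno, pheno = random_observations(ped, rng)
    p = float(rng.uniform(0.15, 0.85))
    a = single_locus_likelihood(ped, geno, p)
    b = enumerate_single_locus(ped, geno, p)
    assert a == pytest.approx(b, rel=1e-12, abs=1e-300)
    if len(ped) <= 5:
        theta = float(rng.uniform(0, 0.5))
        a2 = two_point_likelihood(ped, pheno, geno, theta, MODEL, p)
        b2 = enumerate_two_point(ped, pheno, geno, theta, MODEL, p)
        assert a2 == pytest.approx(b2, rel=1e-12, abs=1e-300)


def test_multipoint_single_marker_reduces_to_two_point_at_zero(trio):
    pheno = {"f": 0.4, "m": "treated", "c": -0.3}
    D = np.array([[1, 0, 1]])
    lik = multipoint_likelihood(trio, D, np.array([10.0]), np.array([0.4]),
                                10.0, pheno, MODEL)
    tp = two_point_likelihood(trio, pheno, dict(zip(trio.ids, D[0])), 0.0, MODEL, 0.4)
    assert lik == pytest.approx(tp, rel=1e-12)


def test_multipoint_distant_markers_factorize(trio):
    # 10000 cM apart: markers are independent
    D = np.array([[1, 0, 1], [2, 1, 1]])
    cm = np.array([0.0, 10000.0])
    fr = np.array([0.4, 0.6])
    lik = multipoint_likelihood(trio, D, cm, fr, 0.0, None, None)
    split = (single_locus_likelihood(trio, dict(zip(trio.ids, D[0])), 0.4)
             * single_locus_likelihood(trio, dict(zip(trio.ids, D[1])), 0.6))
    assert lik == pytest.approx(split, rel=1e-10)


@pytest.mark.parametrize("seed", range(4))
def test_multipoint_matches_enumeration(seed, trio):
    rng = np.random.default_rng(40 + seed)
    D = rng.integers(-1, 3, size=(2, 3))
    cm = np.sort(rng.uniform(0, 30, size=2))
    fr = rng.uniform(0.2, 0.8, size=2)
    pos = float(rng.uniform(0, 30))
    pheno = {"f": float(rng.normal()), "m": "treated", "c": None}
    a = multipoint_likelihood(trio, D, cm, fr, pos, pheno, MODEL)
    b = enumerate_multipoint(trio, D, cm, fr, pos, pheno, MODEL)
    assert a == pytest.approx(b, rel=1e-12, abs=1e-300)


def test_meiosis_cap_raises_informative_error():
    members = [Individual("f", None, None, 1), Individual("m", None, None, 2)]
    members += [Individual(f"k{i}", "f", "m", 1) for i in range(10)]
    big = Pedigree("1", members)
    with pytest.raises(MeiosisCapExceeded, match="subsampling"):
        multipoint_likelihood(big, np.zeros((1, 12), dtype=int) - 1,
                              np.array([1.0]), np.array([0.5]), 1.0, {}, MODEL,
                              meiosis_cap=16)


def test_large_family_loglik_does_not_underflow():
    """A 3-generation, 42-member family with fully observed data keeps a
    finite log-likelihood (scaling is tracked; no silent zero)."""
    from ngla.likelihood import two_locus_loglik_batch
    from ngla.simulate import SimConfig, simulate_study

    cfg = SimConfig(n_families=1, family_size_range=(42, 42), n_markers=12,
                    missing_phenotype_rate=0.0, seed=5)
    bundle, truth = simulate_study(cfg)
    ped = bundle.pedigrees[0]
    phen = bundle.pheno_obs(family_id="1")[0]
    geno = bundle.genotypes.column(3, ped.ids)
    ll = two_locus_loglik_batch(ped, phen, geno, [MODEL],
                                np.array([0.1, 0.5]), 0.4)
    assert np.all(np.isfinite(ll))
    assert np.all(ll < 0)
    # probabilities this small would underflow without tracked scaling
    assert ll.min() < -40


def test_oracle_total_probability_over_all_genotype_patterns(trio):
    """Summing the single-locus likelihood over every possible fully
    observed genotype configuration gives exactly 1."""
    import itertools

    p = 0.3
    total = sum(
        enumerate_single_locus(trio, dict(zip(trio.ids, combo)), p)
        for combo in itertools.product([0, 1, 2], repeat=3)
    )
    assert total == pytest.approx(1.0, rel=1e-12)


def test_linked_data_prefer_small_theta(three_gen):
    """On data simulated with the trait locus on top of the marker, the
    oracle likelihood at theta=0 exceeds theta=0.5."""
    rng = np.random.default_rng(7)
    model = TraitModel(0.5, (-1.5, 0.0, 1.5), 0.7, 10.0)
    # perfect correlation between marker dosage and trait dosage by design
    geno = {"f": 0, "m": 2, "c": 1, "w": 0, "g": 1}
    pheno = {i: float(model.mu[geno[i]] + 0.1 * rng.normal()) for i in geno}
    l0 = enumerate_two_point(three_gen, pheno, geno, 0.0, model, 0.5)
    l5 = enumerate_two_point(three_gen, pheno, geno, 0.5, model, 0.5)
    assert l0 > l5
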