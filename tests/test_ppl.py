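import numpy as np
import pytest

from studyfactories import three_generation_pedigree

from ngla.ppl import (
    PosteriorResult,
    PriorConfig,
    integrated_bayes_factor,
    posterior_mean_trait_params,
    ppl_from_bf,
    ppl_scan,
    sequential_update,
    support_region,
)
from ngla.trait import TraitGrid, TraitModel

MODEL = TraitModel(p_d=0.25, mu=(-0.3, 0.0, 1.2), sigma=1.0, tau=1.0)
ONE_POINT = TraitGrid([MODEL], np.array([1.0]))


def test_posterior_from_printed_bayes_factor():
    # the published pairing: BF 104.125 with a 2% linkage prior gives 68%
    assert ppl_from_bf(104.125, 0.02) == pytest.approx(0.680, abs=5e-4)


@pytest.mark.parametrize("pi", [0.01, 0.02, 0.3])
def test_uninformative_and_impossible_bayes_factors(pi):
    assert ppl_from_bf(1.0, pi) == pytest.approx(pi)
    assert ppl_from_bf(0.0, pi) == 0.0


def test_posterior_strictly_increasing_in_bf():
    bfs = np.linspace(0.0, 50, 200)
    posts = [ppl_from_bf(b, 0.02) for b in bfs]
    assert np.all(np.diff(posts) > 0)


def test_update_identity_holds_exactly():
    for bf in (0.3, 1.0, 7.7, 104.125):
        post = ppl_from_bf(bf, 0.02)
        assert post == pytest.approx(0.02 * bf / (0.02 * bf + 0.98), rel=1e-12)


def test_no_phenotype_information_gives_unit_bf(three_gen):
    pheno = {i: None for i in three_gen.ids}
    geno = {"f": 1, "m": 0, "c": 1, "w": 2, "g": 1}
    bf, per_model, _ = integrated_bayes_factor(three_gen, pheno, geno, 0.4, ONE_POINT)
    assert bf == pytest.approx(1.0, rel=1e-10)
    assert per_model[0] == pytest.approx(1.0, rel=1e-10)


def test_bf_invariant_under_adding_uninformative_individual():
    from ngla.pedigree import Individual, Pedigree
    base = three_generation_pedigree()
    extended = Pedigree("1", list(base.members)
                        + [Individual("x", "f", "m", 1, "1")])
    pheno = {"f": 0.5, "m": "treated", "g": -0.4}
    geno = {"f": 1, "m": 0, "c": 1, "g": 1}
    bf1, _, _ = integrated_bayes_factor(base, pheno, geno, 0.4, ONE_POINT)
    bf2, _, _ = integrated_bayes_factor(extended, pheno, geno, 0.4, ONE_POINT)
    assert bf1 == pytest.approx(bf2, rel=1e-10)


def test_sequential_update_examples():
    pi = 0.02
    assert sequential_update([1.0, 1.0], pi).posterior == pytest.approx(pi)
    r = sequential_update([10.0, 10.0], pi)
    assert r.bayes_factor == pytest.approx(100.0)
    assert r.posterior == pytest.approx(0.02 * 100 / (0.02 * 100 + 0.98), rel=1e-12)
    single = sequential_update({"15": 7.0}, pi)
    assert single.posterior == pytest.approx(ppl_from_bf(7.0, pi), rel=1e-12)


def test_pooled_posterior_of_k_copies_is_bf_to_the_k():
    pi, bf, k = 0.02, 3.3, 4
    pooled = sequential_update([bf] * k, pi)
    assert pooled.posterior == pytest.approx(ppl_from_bf(bf ** k, pi), rel=1e-10)


def test_theta_grid_refinement_changes_bf_negligibly(three_gen):
    pheno = {"f": 0.5, "m": "treated", "c": -0.1, "w": 0.3, "g": -0.4}
    geno = {"f": 1, "m": 0, "c": 1, "w": 2, "g": 1}
    coarse = PriorConfig(theta_grid=np.linspace(0, 0.5, 11))
    fine = PriorConfig(theta_grid=np.linspace(0, 0.5, 21))
    bf1, _, _ = integrated_bayes_factor(three_gen, pheno, geno, 0.4, ONE_POINT, coarse)
    bf2, _, _ = integrated_bayes_factor(three_gen, pheno, geno, 0.4, ONE_POINT, fine)
    assert bf1 == pytest.approx(bf2, rel=1e-3)


def test_mendelian_impossible_data_raise_diagnostic(trio):
    pheno = {"f": 0.5}
    geno = {"f": 2, "m": 2, "c": 0}
    with pytest.raises(ValueError, match="impossible"):
        integrated_bayes_factor(trio, pheno, geno, 0.4, ONE_POINT)


def test_posterior_mean_on_single_point_grid_returns_that_point():
    per_model = np.array([5.0])
    est = posterior_mean_trait_params(ONE_POINT, per_model)
    assert est.p_d == MODEL.p_d and est.mu == pytest.approx(MODEL.mu)


def test_posterior_mean_symmetric_grid_symmetric_data():
    m_plus = TraitModel(0.2, (-0.5, 0.0, 0.5), 1.0, 1.0)
    m_minus = TraitModel(0.2, (0.5, 0.0, -0.5), 1.0, 1.0)
    grid = TraitGrid([m_plus, m_minus], np.array([0.5, 0.5]))
    est = posterior_mean_trait_params(grid, np.array([2.0, 2.0]))
    assert est.mu[2] - est.mu[0] == pytest.approx(0.0, abs=1e-12)


def test_priorconfig_validation():
    with pytest.raises(ValueError):
        PriorConfig(pi_linkage=0.0)
    with pytest.raises(ValueError):
        PriorConfig(theta_grid=np.array([0.0, 0.7]))


def test_scan_single_position_and_support_region(three_gen):
    pheno = {"f": 0.5, "m": "treated", "g": -0.4}
    geno_col = lambda fam, j: {"f": 1, "m": 0, "c": 1, "w": 2, "g": 1}
    track = ppl_scan([three_gen], {"1": pheno}, geno_col,
                     np.array([0.4]), np.array([12.0]), [0], ONE_POINT)
    assert len(track) == 1
    r = track[0]
    assert r.position_cm == 12.0
    assert r.posterior == pytest.approx(ppl_from_bf(r.bayes_factor, 0.02), rel=1e-12)
    lo, hi = support_region(track)
    assert lo == hi == 12.0


def test_trait_grid_refinement_is_stable():
    """Doubling the density of the trait grid (same ranges) moves the
    integrated Bayes factor only modestly: the grid behaves as a
    quadrature of a smooth prior, not as a knife-edge."""
    from studyfactories import three_generation_pedigree
    from ngla.trait import TraitGridConfig, build_trait_grid

    ped = three_generation_pedigree()
    pheno = {"f": 0.5, "m": "treated", "c": -0.1, "w": 0.3, "g": -0.4}
    geno = {"f": 1, "m": 0, "c": 1, "w": 2, "g": 1}
    base = TraitGridConfig(p_d=(0.1, 0.3), displacements=(1.0, 2.0),
                           dominance=(0.0, 1.0), sigma=(0.5, 1.0),
                           tau_quantiles=(0.8, 0.95))
    fine = TraitGridConfig(p_d=(0.1, 0.2, 0.3), displacements=(1.0, 1.5, 2.0),
                           dominance=(0.0, 0.5, 1.0), sigma=(0.5, 0.75, 1.0),
                           tau_quantiles=(0.8, 0.875, 0.95))
    bf1, _, _ = integrated_bayes_factor(ped, pheno, geno, 0.4, build_trait_grid(base))
    bf2, _, _ = integrated_bayes_factor(ped, pheno, geno, 0.4, build_trait_grid(fine))
    assert bf2 == pytest.approx(bf1, rel=0.25)


def test_posterior_mean_recovers_generating_allele_frequency():
    """Simulating from one grid point with a strong additive signal pulls
    the posterior-mean trait parameters toward that point."""
    from ngla.simulate import SimConfig, simulate_study
    from ngla.trait import TraitGrid, TraitModel

    true = TraitModel(0.4, (130.0, 115.0, 100.0), 8.0, 1e9)
    cfg = SimConfig(n_families=3, family_size_range=(14, 14), n_markers=8,
                    trait_model_true=true, missing_phenotype_rate=0.0,
                    planted=None, seed=2)
    bundle, truth = simulate_study(cfg)
    _, c, s = bundle.pheno_obs()
    mu = tuple((m - c) / s for m in true.mu)
    cand = [TraitModel(p, mu, true.sigma / s, 5.0) for p in (0.05, 0.4)]
    grid = TraitGrid(cand, np.array([0.5, 0.5]))
    jc = bundle.panel.index_of(truth.trait_marker_id)
    log_mass = np.zeros(2)
    for ped in bundle.pedigrees:
        phen = bundle.pheno_obs(family_id=ped.family_id)[0]
        _, per, log_null = integrated_bayes_factor(
            ped, phen, bundle.genotypes.column(jc, ped.ids),
            float(bundle.alt_freq(jc)), grid)
        log_mass += np.log(np.maximum(per, 1e-300)) + log_null
    est = posterior_mean_trait_params(grid, np.exp(log_mass - log_mass.max()))
    assert abs(est.p_d - 0.4) < abs(est.p_d - 0.05)
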