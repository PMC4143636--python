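import itertools
import math

import numpy as np
import pandas as pd
import pytest

from studyfactories import cousin_pedigree, fba_fixture_bundle

from ngla.filters import (
    FbaConfig,
    fba_filter,
    founder_genotype_counts,
    founder_maf,
    hwe_exact_test,
    qc_filter,
    select_distant_carriers,
)
from ngla.simulate import SimConfig, simulate_study


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def brute_force_hwe(n_aa, n_ab, n_bb):
    """Oracle: enumerate all genotype tables with the same allele counts,
    weight by the conditional multinomial probability, sum those no more
    probable than the observed table."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab

    def prob(h):
        a_hom = (na - h) // 2
        b_hom = n - h - a_hom
        if a_hom < 0 or b_hom < 0 or (na - h) % 2:
            return 0.0
        return (math.factorial(n) / (math.factorial(a_hom) * math.factorial(h)
                                     * math.factorial(b_hom))) * 2.0 ** h
    hs = [h for h in range(0, min(na, 2 * n - na) + 1)
          if (na - h) % 2 == 0 and n - h - (na - h) // 2 >= 0]
    ps = np.array([prob(h) for h in hs], dtype=float)
    ps /= ps.sum()
    p_obs = ps[hs.index(n_ab)]
    return float(ps[ps <= p_obs * (1 + 1e-12)].sum())


def test_monomorphic_sample_gives_p_one():
    assert hwe_exact_test(40, 0, 0) == 1.0
    assert hwe_exact_test(0, 0, 40) == 1.0


def test_all_heterozygote_sample_is_extreme():
    assert hwe_exact_test(0, 50, 0) < 1e-10


@pytest.mark.parametrize("counts", [
    (5, 10, 5), (20, 10, 3), (1, 8, 12), (7, 0, 7), (13, 21, 6),
])
def test_exact_test_matches_brute_force_conditioning(counts):
    assert hwe_exact_test(*counts) == pytest.approx(
        brute_force_hwe(*counts), rel=1e-12)


def test_invalid_counts_rejected():
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 0, 3)
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def test_qc_removes_low_maf_and_hwe_violations():
    bundle, _ = simulate_study(SimConfig(
        n_families=8, family_size_range=(6, 8), n_markers=30, seed=13))
    # force one common marker into gross HWE violation among founders
    t = bundle.panel.table
    j_common = next(j for j, m in enumerate(t["marker"]) if m.startswith("snp"))
    founders = set(bundle.founder_ids())
    for iid in founders:
        bundle.genotypes.dosage[bundle.genotypes.row(iid), j_common] = 1
    kept, rep = qc_filter(bundle)
    names = [t["marker"].iloc[j] for j in kept]
    assert t["marker"].iloc[j_common] not in names
    for j in kept:
        assert founder_maf(bundle, j) >= 0.01
    assert rep.steps[0].n_in == len(bundle.panel)
    rep.validate_telescope()


def test_qc_example_cutoffs():
    bundle = fba_fixture_bundle()
    kept, rep = qc_filter(bundle)  # all five variants are rare -> all removed
    assert kept == [] and rep.steps[0].n_out == 0


# ---------------------------------------------------------------------------
# distant-carrier selection
# ---------------------------------------------------------------------------


def _pheno(rows):
    return pd.DataFrame(rows, columns=["id", "sbp", "treated", "age"]).set_index("id")


def test_founder_trio_with_low_sbp_is_optimal():
    ped = cousin_pedigree()
    rows = [("S1", 90.0, False, 40.0), ("S2", 91.0, False, 40.0),
            ("S3", 92.0, False, 40.0)]
    rows += [(i, 140.0, False, 50.0) for i in ("A", "B")]
    rows += [(f"C{k}", np.nan, True, 50.0) for k in (1, 2, 3)]
    rows += [(f"G{k}", np.nan, False, 20.0) for k in (1, 2, 3)]
    sel = select_distant_carriers(ped, _pheno(rows), n=3)
    assert sorted(sel) == ["S1", "S2", "S3"]  # unrelated founders: kinship 0


def test_cousins_preferred_over_siblings():
    ped = cousin_pedigree()
    # both the sib trio C1-C3 and the cousin trio G1-G3 are eligible with
    # identical SBP; cousins have pairwise kinship 1/16 < 1/4
    rows = [(f"C{k}", 95.0, False, 60.0) for k in (1, 2, 3)]
    rows += [(f"G{k}", 95.0, False, 40.0) for k in (1, 2, 3)]
    rows += [(i, np.nan, False, np.nan) for i in ("A", "B", "S1", "S2", "S3")]
    sel = select_distant_carriers(ped, _pheno(rows), n=3)
    assert sorted(sel) == ["G1", "G2", "G3"]


def test_age_cutoff_and_error_listing():
    ped = cousin_pedigree()
    rows = [(f"G{k}", 95.0, False, 25.0) for k in (1, 2, 3)]  # too young
    rows += [(i, np.nan, False, np.nan) for i in
             ("A", "B", "C1", "C2", "C3", "S1", "S2", "S3")]
    with pytest.raises(ValueError, match="eligible"):
        select_distant_carriers(ped, _pheno(rows), n=3)


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------


def test_fba_fixture_telescopes_and_keeps_single_variant(fba_bundle):
    rep = fba_filter(fba_bundle, "F")
    assert [(s.n_in, s.n_out) for s in rep.steps] == [(5, 5), (5, 5), (5, 2), (2, 1)]
    assert rep.kept == ["v1"]
    assert sorted(rep.selected_individuals) == ["G1", "G2", "G3"]
    rep.validate_telescope()


def test_fba_output_invariant_to_variant_order(fba_bundle):
    rep1 = fba_filter(fba_bundle, "F", variant_indices=[0, 1, 2, 3, 4])
    rep2 = fba_filter(fba_bundle, "F", variant_indices=[4, 2, 0, 3, 1])
    assert rep1.kept == rep2.kept
    assert [(s.n_in, s.n_out) for s in rep1.steps] == \
        [(s.n_in, s.n_out) for s in rep2.steps]


def test_fba_empty_input_and_all_common(fba_bundle):
    rep = fba_filter(fba_bundle, "F", variant_indices=[])
    assert rep.kept == [] and rep.steps[0].n_in == 0
    # raise the MAF bar so nothing is "rare": empty after step 1
    rep2 = fba_filter(fba_bundle, "F", FbaConfig(maf_max=1e-6))
    assert rep2.steps[0].n_out == 0 and rep2.kept == []


def test_fba_unscored_variant_retained_with_flag(fba_bundle):
    fba_bundle.annotations = fba_bundle.annotations.iloc[1:].reset_index(drop=True)
    rep = fba_filter(fba_bundle, "F")
    assert "v1" in rep.kept
    assert any("retained" in f for f in rep.flags.values())


def test_founder_maf_shared_between_qc_and_fba(fba_bundle):
    # one carrier chromosome among 60 founders
    n0, n1, n2 = founder_genotype_counts(fba_bundle, 0)
    assert (n1, n2) == (1, 0)
    assert founder_maf(fba_bundle, 0) == pytest.approx(1.0 / (2 * (n0 + n1 + n2)))
    assert founder_maf(fba_bundle, 0) < 0.01
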