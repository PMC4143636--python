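"""Variant QC and the 4-step family-based filtering approach (FBA).

QC removes variants with founder minor-allele frequency below a cutoff or
Hardy-Weinberg exact-test p below a threshold (defaults 0.01 and 1e-4).
The FBA prioritizes rare variants for follow-up:

1. keep only rare variants (founder MAF < 0.01);
2. select n distant relatives above an age cutoff with low phenotype
   values (lowest quartile; the subset minimizing maximum pairwise
   kinship);
3. keep variants carrying the minor allele in ALL selected individuals
   (allele-state sharing, not identity-by-descent);
4. keep variants whose conservation score meets a threshold (>= 220 on
   the phastCons 44-way scale); unscored variants are retained with a
   flag.

All minor-allele frequencies here come from founders only, through one
shared implementation, to avoid double-counting transmitted chromosomes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree, kinship_matrix
from .study_io import StudyBundle

__all__ = ["FilterReport", "qc_filter", "hwe_exact_test", "founder_genotype_counts",
           "select_distant_carriers", "fba_filter", "FbaConfig"]


@dataclass
class FilterStep:
    name: str
    n_in: int
    n_out: int
    removed: list[str]


@dataclass
class FilterReport:
    """Telescoping per-step accounting of a filtering run."""

    steps: list[FilterStep] = field(default_factory=list)
    kept: list[str] = field(default_factory=list)
    flags: dict[str, str] = field(default_factory=dict)
    selected_individuals: list[str] = field(default_factory=list)

    def add(self, name: str, before: list[str], after: list[str]) -> None:
        removed = [v for v in before if v not in set(after)]
        self.steps.append(FilterStep(name, len(before), len(after), removed))
        self.kept = list(after)

    def counts(self) -> list[tuple[int, int]]:
        return [(s.n_in, s.n_out) for s in self.steps]

    def validate_telescope(self) -> None:
        for a, b in zip(self.steps, self.steps[1:]):
            if a.n_out != b.n_in:
                raise AssertionError(
                    f"filter counts do not telescope: {a.name}->{b.name}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"step": s.name, "n_in": s.n_in, "n_out": s.n_out,
              "n_removed": len(s.removed)} for s in self.steps])


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities no larger than that of the
    observed heterozygote count.  Monomorphic samples return 1.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0
    hets = range(rare % 2, rare + 1, 2)
    # log P(n_ab = h | allele counts) up to a constant
    logs = []
    for h in hets:
        haa = (n_a - h) // 2 if n_a <= n_b else (n_b - h) // 2
        # count homozygotes of the rare allele
        hrr = (rare - h) // 2
        hcc = n - h - hrr
        lp = (h * np.log(2.0)
              + _lgamma(n + 1) - _lgamma(hrr + 1) - _lgamma(h + 1) - _lgamma(hcc + 1))
        logs.append(lp)
    logs = np.array(logs)
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs_h = n_ab
    p_obs = probs[list(hets).index(obs_h)] if obs_h in hets else 0.0
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def _lgamma(x: float) -> float:
    import math
    return math.lgamma(x)


def founder_genotype_counts(study: StudyBundle, j: int) -> tuple[int, int, int]:
    """(hom-major, het, hom-minor) counts among genotyped founders."""
    dos = study.minor_dosage(j)
    founders = set(study.founder_ids())
    vals = [d for i, d in dos.items() if i in founders and d >= 0]
    return (sum(d == 0 for d in vals), sum(d == 1 for d in vals),
            sum(d == 2 for d in vals))


def founder_maf(study: StudyBundle, j: int) -> float:
    """Minor-allele frequency from founders only -- the single source of
    truth shared by QC and FBA step 1."""
    n0, n1, n2 = founder_genotype_counts(study, j)
    n = n0 + n1 + n2
    return (n1 + 2 * n2) / (2.0 * n) if n else float("nan")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def qc_filter(study: StudyBundle, maf_min: float = 0.01, hwe_alpha: float = 1e-4,
              variant_indices: list[int] | None = None
              ) -> tuple[list[int], FilterReport]:
    """Standard marker QC: drop founder MAF < ``maf_min`` or HWE p < ``hwe_alpha``."""
    if not study.founder_ids():
        raise ValueError("no genotyped founders: cannot estimate MAF/HWE")
    idxs = variant_indices if variant_indices is not None else list(range(len(study.panel)))
    names = [study.panel.ids[j] for j in idxs]
    rep = FilterReport()
    keep_maf = [j for j in idxs if founder_maf(study, j) >= maf_min]
    rep.add("maf", names, [study.panel.ids[j] for j in keep_maf])
    keep_hwe = []
    for j in keep_maf:
        p = hwe_exact_test(*founder_genotype_counts(study, j))
        if p >= hwe_alpha:
            keep_hwe.append(j)
    rep.add("hwe", [study.panel.ids[j] for j in keep_maf],
            [study.panel.ids[j] for j in keep_hwe])
    rep.validate_telescope()
    return keep_hwe, rep


# ---------------------------------------------------------------------------
# distant-carrier selection (FBA step 2)
# ---------------------------------------------------------------------------


def select_distant_carriers(
    ped: Pedigree,
    phenotypes: pd.DataFrame,
    n: int = 3,
    min_age: float = 31.0,
    criterion: str = "low_sbp",
) -> list[str]:
    """Select n distantly related, untreated individuals with low SBP.

    Eligible: age > ``min_age``, untreated, SBP present.  Among the
    eligible individuals in the lowest SBP quartile, returns the n-subset
    minimizing the maximum pairwise kinship coefficient, ties broken by
    lower summed kinship, then by ID order.
    """
    if criterion != "low_sbp":
        raise ValueError(f"unknown criterion {criterion!r}")
    elig = []
    reasons: dict[str, str] = {}
    for iid in ped.ids:
        if iid not in phenotypes.index:
            reasons[iid] = "no phenotype record"
            continue
        row = phenotypes.loc[iid]
        if bool(row["treated"]):
            reasons[iid] = "treated"
        elif not np.isfinite(row["sbp"]):
            reasons[iid] = "missing SBP"
        elif not (np.isfinite(row["age"]) and row["age"] > min_age):
            reasons[iid] = f"age not above {min_age}"
        else:
            elig.append(iid)
    if len(elig) < n:
        raise ValueError(
            f"only {len(elig)} eligible individuals (need {n}); "
            f"exclusions: {reasons}")
    sbp = phenotypes.loc[elig, "sbp"]
    cut = float(np.quantile(sbp.to_numpy(float), 0.25))
    pool = sorted([i for i in elig if sbp[i] <= cut])
    if len(pool) < n:  # quartile too small for n picks: pad by next-lowest SBP
        extra = sorted((i for i in elig if i not in pool), key=lambda i: (sbp[i], i))
        pool = pool + extra[: n - len(pool)]
    phi = kinship_matrix(ped)
    best = None
    for combo in itertools.combinations(sorted(pool), n):
        ks = [phi[ped.index(a), ped.index(b)]
              for a, b in itertools.combinations(combo, 2)]
        key = (max(ks) if ks else 0.0, sum(ks), combo)
        if best is None or key < best:
            best = key
    return list(best[2])


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------


@dataclass
class FbaConfig:
    maf_max: float = 0.01  # step 1 keeps MAF < this
    n_carriers: int = 3
    min_age: float = 31.0
    conservation_min: float = 220.0


def fba_filter(
    study: StudyBundle,
    family_id: str,
    config: FbaConfig | None = None,
    variant_indices: list[int] | None = None,
) -> FilterReport:
    """The 4-step family-based filter; counts telescope across steps.

    Step 3 uses allele-state sharing (every selected individual carries at
    least one minor allele).  Variants lacking a conservation score are
    retained with a flag at step 4.  Output is invariant to the input
    order of variants.
    """
    cfg = config or FbaConfig()
    ped = study.pedigree(family_id)
    idxs = variant_indices if variant_indices is not None else list(range(len(study.panel)))
    idxs = sorted(idxs)
    names = {j: study.panel.ids[j] for j in idxs}
    rep = FilterReport()

    rare = [j for j in idxs if 0.0 < founder_maf(study, j) < cfg.maf_max]
    rep.add("1:rare", [names[j] for j in idxs], [names[j] for j in rare])

    carriers = select_distant_carriers(ped, study.phenotypes, n=cfg.n_carriers,
                                       min_age=cfg.min_age)
    rep.selected_individuals = carriers
    rep.add("2:select_carriers", [names[j] for j in rare], [names[j] for j in rare])

    shared = []
    for j in rare:
        dos = study.minor_dosage(j)
        if all(dos.get(i, -1) >= 1 for i in carriers):
            shared.append(j)
    rep.add("3:shared", [names[j] for j in rare], [names[j] for j in shared])

    ann = study.annotations
    scores = {}
    if len(ann):
        key = ann.set_index(["chrom", "pos"])["phastcons44"]
        for j in shared:
            row = study.panel.table.iloc[j]
            try:
                scores[j] = float(key.loc[(row["chrom"], int(row["bp"]))])
            except KeyError:
                pass
    conserved = []
    for j in shared:
        if j not in scores:
            rep.flags[names[j]] = "no conservation score; retained"
            conserved.append(j)
        elif scores[j] >= cfg.conservation_min:
            conserved.append(j)
    rep.add("4:conserved", [names[j] for j in shared], [names[j] for j in conserved])
    rep.validate_telescope()
    return rep
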