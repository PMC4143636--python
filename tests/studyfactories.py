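"""Hand-built study fixtures shared by the unit and acceptance tests."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ngla.pedigree import Individual, Pedigree
from ngla.study_io import GenotypeMatrix, MarkerPanel, StudyBundle


def trio_pedigree(fam: str = "1") -> Pedigree:
    return Pedigree(fam, [
        Individual("f", None, None, 1, fam),
        Individual("m", None, None, 2, fam),
        Individual("c", "f", "m", 1, fam),
    ])


def three_generation_pedigree(fam: str = "1") -> Pedigree:
    """5 members: founder couple, son, married-in wife, granddaughter."""
    return Pedigree(fam, [
        Individual("f", None, None, 1, fam),
        Individual("m", None, None, 2, fam),
        Individual("c", "f", "m", 1, fam),
        Individual("w", None, None, 2, fam),
        Individual("g", "c", "w", 2, fam),
    ])


def cousin_pedigree(fam: str = "1") -> Pedigree:
    """Founder couple, three married children, three first-cousin grandkids."""
    members = [
        Individual("A", None, None, 1, fam),
        Individual("B", None, None, 2, fam),
    ]
    for k in (1, 2, 3):
        members += [
            Individual(f"C{k}", "A", "B", 1, fam),
            Individual(f"S{k}", None, None, 2, fam),
            Individual(f"G{k}", f"C{k}", f"S{k}", 2, fam),
        ]
    return Pedigree(fam, members)


def random_pedigree(rng: np.random.Generator, n_max: int = 6, fam: str = "1") -> Pedigree:
    """A random small loop-free pedigree for oracle cross-checks."""
    n = int(rng.integers(3, n_max + 1))
    members = [
        Individual("p1", None, None, 1, fam),
        Individual("p2", None, None, 2, fam),
    ]
    k = 3
    while len(members) < n:
        # add either a child of a random existing couple-compatible pair or a founder
        if len(members) >= 2 and rng.random() < 0.75:
            males = [m for m in members if m.sex == 1]
            females = [m for m in members if m.sex == 2]
            if males and females:
                fa = males[int(rng.integers(len(males)))]
                mo = females[int(rng.integers(len(females)))]
                child = Individual(f"p{k}", fa.iid, mo.iid, int(rng.integers(1, 3)), fam)
                try:
                    Pedigree(fam, members + [child])
                except Exception:
                    k += 1
                    continue
                members.append(child)
                k += 1
                continue
        members.append(Individual(f"p{k}", None, None, int(rng.integers(1, 3)), fam))
        k += 1
    return Pedigree(fam, members)


def random_observations(ped: Pedigree, rng: np.random.Generator):
    """Random genotypes (with missingness) and mixed phenotype observations."""
    geno = {i: int(rng.integers(-1, 3)) for i in ped.ids}
    pheno = {}
    for i in ped.ids:
        u = rng.random()
        if u < 0.25:
            pheno[i] = None
        elif u < 0.5:
            pheno[i] = "treated"
        else:
            pheno[i] = float(rng.normal())
    return geno, pheno


# ---------------------------------------------------------------------------
# the hand-traceable FBA fixture
# ---------------------------------------------------------------------------


def fba_fixture_bundle(n_extra_founders: int = 55) -> StudyBundle:
    """One extended family plus unrelated genotyped founders.

    Five rare variants, each with a single carrier founder chromosome
    (founder MAF 1/(2*(5 + n_extra)) < 0.01 with the default 55 extras):

    * v1: carried by founder A and passed to all three cousins G1-G3;
      phastCons-44 score 294.
    * v2: same carriers as v1; score 100 (fails the conservation cut).
    * v3, v4: carried by only one cousin (not shared by the trio).
    * v5: carried by child C1 only.

    Eligible distant relatives with observed low SBP are exactly the
    first-cousin trio G1-G3, so the 4-step filter telescopes 5->5->2->1
    and keeps v1 alone.
    """
    ped = cousin_pedigree("F")
    members = list(ped.members) + [
        Individual(f"U{j}", None, None, 1 + j % 2, "F")
        for j in range(n_extra_founders)
    ]
    ped = Pedigree("F", members)

    panel = MarkerPanel(pd.DataFrame({
        "marker": ["v1", "v2", "v3", "v4", "v5"],
        "chrom": "3",
        "cm": [50.0, 50.5, 51.0, 51.5, 52.0],
        "bp": [31_000_000, 31_100_000, 31_200_000, 31_300_000, 31_400_000],
        "ref": ["A", "C", "G", "T", "A"],
        "alt": ["G", "T", "A", "C", "C"],
    }))
    ids = ped.ids
    dosage = np.zeros((len(ids), 5), dtype=np.int16)
    rows = {iid: k for k, iid in enumerate(ids)}

    def set1(variant: int, carriers: list[str]) -> None:
        for c in carriers:
            dosage[rows[c], variant] = 1

    lineage = ["A", "C1", "C2", "C3", "G1", "G2", "G3"]
    set1(0, lineage)            # v1: shared by the trio, conserved
    set1(1, lineage)            # v2: shared by the trio, not conserved
    set1(2, ["A", "C1", "G1"])  # v3: only one cousin carries it
    set1(3, ["S1", "G1"])       # v4: only one cousin carries it
    set1(4, ["B", "C1"])        # v5: no cousin carries it

    pheno_rows = []
    for iid in ids:
        if iid in ("G1", "G2", "G3"):
            sbp = {"G1": 95.0, "G2": 97.0, "G3": 99.0}[iid]
            pheno_rows.append((iid, sbp, False, 45.0))
        elif iid.startswith("C") or iid.startswith("S"):
            pheno_rows.append((iid, np.nan, True, 60.0))  # treated: ineligible
        else:
            pheno_rows.append((iid, np.nan, False, np.nan))
    pheno = pd.DataFrame(pheno_rows, columns=["id", "sbp", "treated", "age"]).set_index("id")

    ann = pd.DataFrame({
        "chrom": "3",
        "pos": panel.table["bp"],
        "ref": panel.table["ref"],
        "alt": panel.table["alt"],
        "phastcons44": [294.0, 100.0, 250.0, 400.0, 10.0],
    })
    return StudyBundle(pedigrees=[ped], phenotypes=pheno,
                       genotypes=GenotypeMatrix(ids, dosage),
                       panel=panel, annotations=ann)
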