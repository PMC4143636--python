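"""Rare shared-haplotype detection.

Rare variants whose carrier sets are exactly identical behave as sites on
one rare haplotype segregating through the families that carry it -- the
evidence pattern behind a family-confined multi-site haplotype.  With
unphased genotypes, "haplotype" here means co-carriage: the sites are
carried by exactly the same individuals, not proven to sit on one phased
chromosome (imputed or unphased data deserve experimental confirmation).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .filters import founder_maf
from .study_io import StudyBundle

__all__ = ["HaplotypeCluster", "carrier_sets", "cluster_shared"]


@dataclass
class HaplotypeCluster:
    """Variants with identical carrier sets, ordered along the chromosome."""

    variants: list[str]
    positions_bp: list[int]
    carriers: frozenset[str]
    carrier_families: frozenset[str]
    confined: bool | None = None  # carriers within the configured target families?

    @property
    def n_sites(self) -> int:
        return len(self.variants)


def carrier_sets(
    study: StudyBundle,
    maf_max: float = 0.01,
    variant_indices: list[int] | None = None,
) -> dict[str, frozenset[str]]:
    """Carrier set (>= 1 minor allele) per rare variant (founder MAF <= cap).

    Variants carried by nobody, and variants above the MAF cap, are
    excluded.
    """
    idxs = variant_indices if variant_indices is not None else range(len(study.panel))
    out: dict[str, frozenset[str]] = {}
    for j in idxs:
        maf = founder_maf(study, j)
        if not (maf == maf) or maf > maf_max:
            continue
        dos = study.minor_dosage(j)
        carr = frozenset(i for i, d in dos.items() if d >= 1)
        if carr:
            out[study.panel.ids[j]] = carr
    return out


def cluster_shared(
    study: StudyBundle,
    carrier_map: dict[str, frozenset[str]],
    min_sites: int = 2,
    target_families: tuple[str, ...] | None = None,
) -> tuple[list[HaplotypeCluster], list[str]]:
    """Group variants by exact carrier-set equality.

    Returns (clusters with >= ``min_sites`` sites, singleton variant list).
    Clusters are ordered by (site count descending, leftmost position);
    the partition and ordering are independent of input order.  When
    ``target_families`` is given, each cluster's ``confined`` flag records
    whether its carriers fall entirely inside that family set.
    """
    pos = {m: int(study.panel.table["bp"].iloc[study.panel.index_of(m)])
           for m in carrier_map}
    groups: dict[frozenset[str], list[str]] = {}
    for v, carr in carrier_map.items():
        groups.setdefault(carr, []).append(v)
    clusters: list[HaplotypeCluster] = []
    singles: list[str] = []
    for carr, vs in groups.items():
        vs = sorted(vs, key=lambda m: (pos[m], m))
        if len(vs) < min_sites:
            singles.extend(vs)
            continue
        fams = frozenset(study.family_of(i) for i in carr)
        conf = None if target_families is None else fams <= set(target_families)
        clusters.append(HaplotypeCluster(vs, [pos[v] for v in vs], carr, fams, conf))
    clusters.sort(key=lambda c: (-c.n_sites, c.positions_bp[0], c.variants[0]))
    singles.sort(key=lambda m: (pos[m], m))
    return clusters, singles


def clusters_to_frame(clusters: list[HaplotypeCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "n_sites": c.n_sites,
            "variants": ",".join(c.variants),
            "first_bp": c.positions_bp[0],
            "n_carriers": len(c.carriers),
            "families": ",".join(sorted(c.carrier_families, key=str)),
            "confined": c.confined,
        } for c in clusters]
    )
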