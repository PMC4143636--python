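"""LD-pruned SNP subsampling and averaged-LOD linkage scans.

Dense SNP panels violate the inter-marker independence that multipoint
linkage methods assume.  The remedy implemented here: draw several
random, informative subsamples in which consecutive selected SNPs have
founder r-squared at most a cap (0.20 by default), compute a fixed-model
LOD curve per subsample, and average the curves.  The maximum of the
averaged LOD and its 1-LOD-drop support interval summarize the evidence;
averaging over subsamples (15 by default) makes the result robust to any
single SNP selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .likelihood import (
    DEFAULT_MEIOSIS_CAP,
    haldane_theta,
    multipoint_scan,
    trait_only_likelihood,
    two_locus_loglik_batch,
)
from .study_io import StudyBundle
from .trait import TraitModel

__all__ = ["SubsamplePlan", "AvgLodTrack", "estimate_r2", "select_subsample",
           "average_lod_scan"]


@dataclass
class SubsamplePlan:
    """How to draw the random informative subsamples."""

    n_subsamples: int = 15
    r2_max: float = 0.20
    min_spacing_cm: float = 0.5  # consecutive picks at least this far apart
    window_cm: float = 8.0  # look-ahead window for the next pick
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_max <= 1.0):
            raise ValueError("r2_max must be in (0, 1]")
        if self.n_subsamples < 1:
            raise ValueError("need at least one subsample")


def estimate_r2(dose_i: np.ndarray, dose_j: np.ndarray) -> float:
    """Squared Pearson correlation of founder allele dosages (composite LD).

    Phase-free: computed on 0/1/2 dosages, missing (-1) pairs dropped.
    Returns NaN (flagged undefined) when either marker is monomorphic
    among the genotyped founders.
    """
    x = np.asarray(dose_i, float)
    y = np.asarray(dose_j, float)
    ok = (x >= 0) & (y >= 0)
    x, y = x[ok], y[ok]
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def founder_dosages(study: StudyBundle) -> np.ndarray:
    rows = [study.genotypes.row(i) for i in study.founder_ids()
            if i in study.genotypes._row]
    return study.genotypes.dosage[rows]


def select_subsample(
    study: StudyBundle,
    plan: SubsamplePlan,
    k: int,
    candidate_indices: list[int] | None = None,
) -> list[int]:
    """Draw the k-th random informative subsample (deterministic in (seed, k)).

    Greedy randomized left-to-right selection: among the markers within
    the look-ahead window whose founder r-squared with the previously
    selected SNP is at most ``r2_max``, the next SNP is sampled with
    probability proportional to its founder heterozygosity 2p(1-p).  If a
    window contains no eligible SNP it is recorded as a gap and selection
    jumps ahead rather than failing.
    """
    rng = np.random.default_rng(np.random.SeedSequence((plan.seed, k)))
    cm = study.panel.cm
    fd = founder_dosages(study)
    if candidate_indices is None:
        candidate_indices = list(range(len(cm)))
    cand = sorted(candidate_indices, key=lambda j: cm[j])
    freqs = np.array([_obs_freq(fd[:, j]) for j in cand])
    het = 2.0 * freqs * (1.0 - freqs)
    poly = het > 0
    picked: list[int] = []
    cursor = cm[cand[0]] - 1e-9 if cand else 0.0
    last_ci = -1
    while True:
        lo = cursor if not picked else max(cursor, cm[picked[-1]] + plan.min_spacing_cm)
        elig = [
            (ci, j) for ci, j in enumerate(cand)
            if ci > last_ci and poly[ci] and lo <= cm[j] <= lo + plan.window_cm
            and (not picked or _r2_ok(fd, picked[-1], j, plan.r2_max))
        ]
        if not elig:
            # gap: advance the look-ahead window; stop at the end of the map
            if not any(cm[j] > lo + plan.window_cm for j in cand):
                break
            cursor = lo + plan.window_cm
            continue
        w = np.array([het[ci] for ci, _ in elig])
        pick = int(rng.choice(len(elig), p=w / w.sum()))
        last_ci, j = elig[pick]
        picked.append(j)
        cursor = cm[j]
    return picked


def _obs_freq(col: np.ndarray) -> float:
    ok = col >= 0
    return float(col[ok].sum() / (2.0 * ok.sum())) if ok.any() else 0.0


def _r2_ok(fd: np.ndarray, i: int, j: int, cap: float) -> bool:
    r2 = estimate_r2(fd[:, i], fd[:, j])
    return not (r2 == r2 and r2 > cap)  # NaN (undefined) passes


def subsample_heterozygosity(study: StudyBundle, subset: list[int]) -> float:
    fd = founder_dosages(study)
    f = np.array([_obs_freq(fd[:, j]) for j in subset])
    return float(np.mean(2 * f * (1 - f))) if subset else float("nan")


@dataclass
class AvgLodTrack:
    positions_cm: np.ndarray
    per_subsample: np.ndarray  # (n_subsamples, n_positions)
    subsamples: list[list[int]]
    mean_heterozygosity: float
    fallback_families: list[str]

    @property
    def avg_lod(self) -> np.ndarray:
        return self.per_subsample.mean(axis=0)

    @property
    def max_lod(self) -> float:
        return float(self.avg_lod.max())

    @property
    def peak_cm(self) -> float:
        return float(self.positions_cm[int(self.avg_lod.argmax())])

    def support_interval(self, drop: float = 1.0) -> tuple[float, float]:
        """1-LOD-drop support interval of the averaged curve."""
        a = self.avg_lod
        keep = self.positions_cm[a >= a.max() - drop]
        return float(keep.min()), float(keep.max())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"pos_cM": self.positions_cm, "avgLOD": self.avg_lod})
        for k in range(self.per_subsample.shape[0]):
            df[f"LOD_s{k+1}"] = self.per_subsample[k]
        return df


def average_lod_scan(
    study: StudyBundle,
    plan: SubsamplePlan,
    model: TraitModel,
    positions_cm: np.ndarray,
    family_ids: list[str] | None = None,
    meiosis_cap: int = DEFAULT_MEIOSIS_CAP,
    standardize: bool = True,
) -> AvgLodTrack:
    """Averaged fixed-model LOD curve over random LD-pruned subsamples.

    Per subsample and family, the LOD at each position is
    log10 L(position) - log10 L(unlinked), computed by the exact
    inheritance-vector HMM when the family fits under ``meiosis_cap`` and
    otherwise by a two-point approximation against the nearest selected
    marker (recorded in ``fallback_families``).  Curves are summed over
    families and averaged over subsamples.  The trait model is fixed: no
    integration.
    """
    positions_cm = np.asarray(positions_cm, float)
    fams = family_ids or [p.family_id for p in study.pedigrees]
    peds = [study.pedigree(f) for f in fams]
    phen = {f: study.pheno_obs(family_id=f, standardize=standardize)[0] for f in fams}
    cm = study.panel.cm
    freqs = study.alt_freq()
    curves = np.zeros((plan.n_subsamples, positions_cm.size))
    subsets = []
    fallback: set[str] = set()
    caches: dict[str, dict] = {f: {} for f in fams}
    for k in range(plan.n_subsamples):
        subset = select_subsample(study, plan, k)
        subsets.append(subset)
        for ped in peds:
            if ped.n_meioses <= meiosis_cap:
                curves[k] += _multipoint_lod(
                    study, ped, phen[ped.family_id], model, subset, positions_cm,
                    meiosis_cap, cache=caches[ped.family_id])
            else:
                fallback.add(ped.family_id)
                curves[k] += _two_point_lod(
                    study, ped, phen[ped.family_id], model, subset, positions_cm,
                    cache=caches[ped.family_id])
    het = float(np.mean([subsample_heterozygosity(study, s) for s in subsets]))
    return AvgLodTrack(positions_cm, curves, subsets, het, sorted(fallback))


def _multipoint_lod(study, ped, phen, model, subset, positions, meiosis_cap,
                    cache=None):
    cm = study.panel.cm
    freqs = study.alt_freq()
    D = np.stack([
        np.array([study.genotypes.column(j, ped.ids).get(i, -1) for i in ped.ids])
        for j in subset
    ]) if subset else np.zeros((0, len(ped)), dtype=int)
    liks, null = multipoint_scan(ped, D, cm[subset], freqs[subset], positions,
                                 phen, model, meiosis_cap=meiosis_cap,
                                 marker_ids=[study.panel.ids[j] for j in subset],
                                 emission_cache=cache)
    denom = null * trait_only_likelihood(ped, phen, model)
    out = np.zeros(positions.size)
    ok = (liks > 0) & (denom > 0)
    out[ok] = np.log10(liks[ok] / denom)
    return out


def _two_point_lod(study, ped, phen, model, subset, positions, cache=None):
    """Two-point fallback: LOD against the nearest selected marker.

    Batched per marker over all requested thetas; the cache is shared
    across subsamples of the same family (the same marker and distance
    recur in overlapping subsamples).
    """
    cm = study.panel.cm
    freqs = study.alt_freq()
    if not subset:
        return np.zeros(positions.size)
    if cache is None:
        cache = {}
    mcm = cm[subset]
    nearest = np.array([subset[int(np.abs(mcm - p).argmin())] for p in positions])
    need: dict[int, list[tuple[int, float]]] = {}
    out = np.empty(positions.size)
    for i, (pos, j) in enumerate(zip(positions, nearest)):
        theta = min(float(haldane_theta(abs(cm[j] - pos))), 0.5)
        key = (j, round(theta, 10))
        if key in cache:
            out[i] = cache[key]
        else:
            need.setdefault(j, []).append((i, theta))
    for j, items in need.items():
        thetas = np.array([t for _, t in items] + [0.5])
        geno = study.genotypes.column(j, ped.ids)
        ll = two_locus_loglik_batch(ped, phen, geno, [model], thetas,
                                    float(freqs[j]))[0]
        lods = (ll[:-1] - ll[-1]) / np.log(10.0)
        for (i, t), v in zip(items, lods):
            cache[(j, round(t, 10))] = float(v)
            out[i] = float(v)
    return out
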