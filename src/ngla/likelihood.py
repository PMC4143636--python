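"""Exact pedigree likelihoods.

Three engines, all exact and all underflow-safe:

* Elston-Stewart peeling (implemented as sum-product variable elimination
  over per-individual latent states, with a min-degree elimination order)
  for single-locus and trait-marker two-point likelihoods.  States are
  ordered haplotype pairs, so phase is handled exactly; the engine is
  batched over a leading "model" axis so a whole integration grid and
  theta grid are peeled in one pass.
* A Lander-Green inheritance-vector HMM for multipoint likelihoods, with
  founder-phase symmetry reduction (one meiosis bit fixed per founder
  with children) and a configurable meiosis cap.
* Brute-force enumeration oracles over all founder haplotype assignments
  and meiosis outcomes, guarded to small pedigrees, used to verify the
  other two.

Genotypes are dosages of the second (alt) allele: 0/1/2, -1 missing.
Phenotype observations are ``None`` (missing), ``"treated"`` (censored
above the threshold) or a float (observed value, untreated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .pedigree import Pedigree
from .trait import TraitModel, penetrance_table

__all__ = [
    "haldane_theta",
    "haldane_cm",
    "single_locus_likelihood",
    "two_point_likelihood",
    "multipoint_likelihood",
    "trait_only_likelihood",
    "MeiosisCapExceeded",
    "DEFAULT_MEIOSIS_CAP",
]

DEFAULT_MEIOSIS_CAP = 16


class MeiosisCapExceeded(RuntimeError):
    """Pedigree too large for exact multipoint; use subsampling or raise the cap."""


def haldane_theta(cm: float | np.ndarray):
    """Map distance (cM) -> recombination fraction, Haldane (no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(cm, float) / 100.0))


def haldane_cm(theta: float | np.ndarray):
    """Recombination fraction -> map distance in cM (inverse Haldane)."""
    t = np.asarray(theta, float)
    return -50.0 * np.log(1.0 - 2.0 * np.clip(t, 0.0, 0.4999999))


# ---------------------------------------------------------------------------
# generic batched sum-product elimination over per-individual states
# ---------------------------------------------------------------------------


@dataclass
class _Step:
    var: int
    inputs: list[tuple[int, tuple[int, ...]]]  # (factor id, scope)
    union: tuple[int, ...]
    out_id: int
    subscripts: str = ""  # einsum spec contracting the eliminated variable
    path: object = None  # cached contraction path


class _Schedule:
    """A symbolic min-degree elimination order for one pedigree shape.

    Computed once per pedigree and reused for every batch: the order and
    the factor-merge pattern depend only on the family graph, never on
    genotypes, phenotypes or model grids.
    """

    def __init__(self, scopes: list[tuple[int, ...]], n_vars: int):
        factors = {i: s for i, s in enumerate(scopes)}
        next_id = len(scopes)
        remaining = set(range(n_vars))
        self.steps: list[_Step] = []
        self.max_scope = 1
        while remaining:
            neigh: dict[int, set[int]] = {v: set() for v in remaining}
            for s in factors.values():
                live = [v for v in s if v in remaining]
                for v in live:
                    neigh[v].update(x for x in live if x != v)
            v = min(remaining, key=lambda x: (len(neigh[x]), x))
            ids = [i for i, s in factors.items() if v in s]
            union: tuple[int, ...] = (v,)
            for i in ids:
                union = union + tuple(x for x in factors[i] if x not in union)
            self.max_scope = max(self.max_scope, len(union))
            letters = {u: chr(ord("c") + k) for k, u in enumerate(union)}
            subs = ",".join("b" + "".join(letters[x] for x in factors[i]) for i in ids)
            subs += "->b" + "".join(letters[x] for x in union[1:])
            step = _Step(v, [(i, factors[i]) for i in ids], union, next_id, subs)
            for i in ids:
                del factors[i]
            factors[next_id] = union[1:]
            next_id += 1
            self.steps.append(step)
            remaining.discard(v)
        self.residual = list(factors)


_SCHEDULES: dict[tuple, _Schedule] = {}


def _schedule_for(ped: Pedigree) -> _Schedule:
    """Scopes: per individual a site factor and either a founder prior or a
    transmission factor (child, father, mother)."""
    key = tuple(
        (None if m.is_founder else (ped.index(m.father), ped.index(m.mother)))
        for m in ped.members
    )
    sched = _SCHEDULES.get(key)
    if sched is None:
        scopes: list[tuple[int, ...]] = []
        for i, m in enumerate(ped.members):
            scopes.append((i,))  # site factor
            if m.is_founder:
                scopes.append((i,))  # founder prior
            else:
                scopes.append((i, ped.index(m.father), ped.index(m.mother)))
        sched = _Schedule(scopes, len(ped))
        _SCHEDULES[key] = sched
    return sched


def _peel_scheduled(sched: _Schedule, arrays: list[np.ndarray],
                    S: int, B: int) -> np.ndarray:
    """Execute an elimination schedule; returns log-likelihood per batch row.

    Rescales after every elimination so no intermediate result underflows;
    impossible data yield -inf, never a silent 0.
    """
    store: dict[int, np.ndarray] = {i: a for i, a in enumerate(arrays)}
    scalar_log = np.zeros(B)
    for st in sched.steps:
        union = st.union
        ops = [store[fid] for fid, _ in st.inputs]
        if st.path is None:
            st.path = np.einsum_path(st.subscripts, *ops, optimize="optimal")[0]
        new = np.einsum(st.subscripts, *ops, optimize=st.path)
        for fid, _ in st.inputs:
            del store[fid]
        if new.ndim != len(union):  # (B,) + union[1:] axes expected
            raise AssertionError("schedule/einsum mismatch")
        mx = new.reshape(B, -1).max(axis=1)
        safe = np.where(mx > 0, mx, 1.0)
        new /= safe.reshape((B,) + (1,) * (len(union) - 1))
        scalar_log += np.where(mx > 0, np.log(safe), -np.inf)
        if len(union) > 1:
            store[st.out_id] = new
        else:
            store[st.out_id] = np.ones(B)
    for fid in sched.residual:
        val = store[fid].reshape(B, -1).prod(axis=1)
        scalar_log += np.where(val > 0, np.log(np.where(val > 0, val, 1.0)), -np.inf)
    return scalar_log


def _transmission_1locus() -> np.ndarray:
    """t[a, s_parent]: probability parent in ordered-pair state s transmits allele a."""
    t = np.zeros((2, 4))
    for s in range(4):
        a_pat, a_mat = s >> 1, s & 1
        t[a_pat, s] += 0.5
        t[a_mat, s] += 0.5
    return t


_T1 = _transmission_1locus()


def _hap_transmission(thetas: np.ndarray) -> np.ndarray:
    """t[b, h, s]: P(transmit two-locus haplotype h | parent ordered state s).

    Haplotypes h = 2*t + m over (trait allele t, marker allele m); parent
    states s = 4*h_pat + h_mat.  Recombination theta between the loci.
    """
    B = thetas.shape[0]
    t = np.zeros((B, 4, 16))
    th = thetas
    for s in range(16):
        hp, hm = s >> 2, s & 3
        t1, m1 = hp >> 1, hp & 1
        t2, m2 = hm >> 1, hm & 1
        t[:, 2 * t1 + m1, s] += (1 - th) / 2
        t[:, 2 * t1 + m2, s] += th / 2
        t[:, 2 * t2 + m1, s] += th / 2
        t[:, 2 * t2 + m2, s] += (1 - th) / 2
    return t


def _state_dosage(S: int) -> np.ndarray:
    if S == 4:  # single locus: s = 2*a_pat + a_mat
        return np.array([(s >> 1) + (s & 1) for s in range(4)])
    raise ValueError(S)


# dosage of the marker allele / trait allele per 16-state
_TP_MARKER_DOSE = np.array([((s >> 2) & 1) + (s & 1) for s in range(16)])
_TP_TRAIT_DOSE = np.array([((s >> 3) & 1) + ((s >> 1) & 1) for s in range(16)])


def _geno_site_factor(dosages: np.ndarray, state_dose: np.ndarray) -> np.ndarray:
    """Hard observation factor (n, S): 1 where state dosage matches, 1 if missing."""
    n = dosages.shape[0]
    S = state_dose.shape[0]
    out = np.ones((n, S))
    obs = dosages >= 0
    out[obs] = (state_dose[None, :] == dosages[obs, None]).astype(float)
    return out


def _run_peel(
    ped: Pedigree,
    founder_prior: np.ndarray,  # (B, S)
    trans: np.ndarray,  # (B, S, S, S) indexed [b, child, father, mother]
    site: np.ndarray,  # (B or 1, n, S)
) -> np.ndarray:
    B, S = founder_prior.shape
    arrays: list[np.ndarray] = []
    scopes: list[tuple[int, ...]] = []
    for i, ind in enumerate(ped.members):
        arrays.append(site[:, i, :] if site.shape[0] == B
                      else np.broadcast_to(site[0, i, :], (B, S)))
        scopes.append((i,))
        if ind.is_founder:
            arrays.append(founder_prior)
            scopes.append((i,))
        else:
            f, m = ped.index(ind.father), ped.index(ind.mother)
            arrays.append(trans)
            scopes.append((i, f, m))
    sched = _schedule_for(ped)
    return _peel_scheduled(sched, arrays, S, B)


# ---------------------------------------------------------------------------
# batched cores
# ---------------------------------------------------------------------------


def _marker_logliks(ped: Pedigree, dosages: np.ndarray, p_alt: np.ndarray) -> np.ndarray:
    """(B,) log P(marker genotypes) for alt-allele freq p_alt per batch element."""
    p = np.atleast_1d(np.asarray(p_alt, float))
    B = p.shape[0]
    q = np.stack([1 - p, p], axis=1)  # (B,2)
    prior = (q[:, :, None] * q[:, None, :]).reshape(B, 4)  # s = 2*a_pat + a_mat
    # child state s_c = 2*a_pat + a_mat; build (S,S,S)
    T = np.zeros((4, 4, 4))
    for ap in range(2):
        for am in range(2):
            T[2 * ap + am] = np.outer(_T1[ap], _T1[am])
    trans = np.broadcast_to(T, (B, 4, 4, 4))
    site = _geno_site_factor(dosages, _state_dosage(4))[None, :, :]
    return _run_peel(ped, prior, trans, site)


def _trait_logliks(ped: Pedigree, pen: np.ndarray, p_d: np.ndarray) -> np.ndarray:
    """(B,) log P(phenotypes); pen is (B, n, 3) penetrance by trait dosage."""
    p = np.asarray(p_d, float)
    B = p.shape[0]
    q = np.stack([1 - p, p], axis=1)
    prior = (q[:, :, None] * q[:, None, :]).reshape(B, 4)
    T = np.zeros((4, 4, 4))
    for ap in range(2):
        for am in range(2):
            T[2 * ap + am] = np.outer(_T1[ap], _T1[am])
    trans = np.broadcast_to(T, (B, 4, 4, 4))
    site = pen[:, :, _state_dosage(4)]  # (B, n, 4)
    return _run_peel(ped, prior, trans, site)


def _two_locus_logliks(
    ped: Pedigree,
    hap_freqs: np.ndarray,  # (B, 4) over h = 2*t + m
    thetas: np.ndarray,  # (B,)
    pen: np.ndarray,  # (B, n, 3) penetrance by trait dosage
    dosages: np.ndarray,  # (n,) marker dosages
    chunk: int = 128,
) -> np.ndarray:
    """(B,) log joint P(phenotypes, marker genotypes | theta, model)."""
    B = hap_freqs.shape[0]
    n = len(ped)
    geno_fac = _geno_site_factor(dosages, _TP_MARKER_DOSE)  # (n, 16)
    out = np.empty(B)
    for lo in range(0, B, chunk):
        hi = min(B, lo + chunk)
        q = hap_freqs[lo:hi]
        b = hi - lo
        prior = (q[:, :, None] * q[:, None, :]).reshape(b, 16)
        th = _hap_transmission(thetas[lo:hi])  # (b, 4, 16)
        # child state s_c = 4*h_pat + h_mat
        trans = (th[:, :, None, :, None] * th[:, None, :, None, :]).reshape(b, 16, 16, 16)
        site = pen[lo:hi][:, :, _TP_TRAIT_DOSE] * geno_fac[None, :, :]  # (b, n, 16)
        out[lo:hi] = _run_peel(ped, prior, trans, site)
    return out


# ---------------------------------------------------------------------------
# public single-model wrappers
# ---------------------------------------------------------------------------


def single_locus_likelihood(ped: Pedigree, genotypes: dict[str, int], p_alt: float) -> float:
    """Exact P(observed genotypes at one diallelic marker).

    Founders carry Hardy-Weinberg priors with alt-allele frequency
    ``p_alt``; missing genotypes (dosage -1 or absent) are summed over.
    A Mendelian-inconsistent configuration returns 0.0 (diagnosable via
    ``math.isinf`` of the log), never raises.
    """
    dos = np.array([genotypes.get(i, -1) for i in ped.ids])
    ll = _marker_logliks(ped, dos, np.array([p_alt]))[0]
    return float(np.exp(ll))


def trait_only_likelihood(ped: Pedigree, phenotypes: dict[str, object], model: TraitModel) -> float:
    """Exact P(phenotypes) under the threshold model, marker-free."""
    pen = _pen_matrix(ped, phenotypes, [model])
    ll = _trait_logliks(ped, pen, np.array([model.p_d]))[0]
    return float(np.exp(ll))


def _pen_matrix(ped: Pedigree, phenotypes: dict[str, object], models) -> np.ndarray:
    """(M, n, 3) penetrance table for each model x individual x trait dosage."""
    cols = [penetrance_table(phenotypes.get(i), models) for i in ped.ids]  # each (M,3)
    return np.stack(cols, axis=1)


def _equilibrium_hapfreqs(p_d: np.ndarray, p_m: np.ndarray) -> np.ndarray:
    """(B,4) haplotype frequencies under linkage equilibrium, h = 2*t + m."""
    return np.stack(
        [(1 - p_d) * (1 - p_m), (1 - p_d) * p_m, p_d * (1 - p_m), p_d * p_m], axis=1
    )


def two_point_likelihood(
    ped: Pedigree,
    phenotypes: dict[str, object],
    genotypes: dict[str, int],
    theta: float,
    model: TraitModel,
    p_marker: float,
) -> float:
    """Joint P(phenotypes, marker genotypes) at recombination ``theta``.

    The trait locus and marker are peeled jointly over ordered two-locus
    haplotype pairs; founder haplotypes are in linkage equilibrium.
    """
    if not (0.0 <= theta <= 0.5):
        raise ValueError("theta must be in [0, 0.5]")
    dos = np.array([genotypes.get(i, -1) for i in ped.ids])
    pen = _pen_matrix(ped, phenotypes, [model])
    hf = _equilibrium_hapfreqs(np.array([model.p_d]), np.array([p_marker]))
    ll = _two_locus_logliks(ped, hf, np.array([theta]), pen, dos)[0]
    return float(np.exp(ll))


def two_locus_loglik_batch(
    ped: Pedigree,
    phenotypes: dict[str, object],
    genotypes: dict[str, int],
    models: list[TraitModel],
    thetas: np.ndarray,
    p_marker: float,
) -> np.ndarray:
    """(M, T) log-likelihood over the model x theta product grid."""
    thetas = np.asarray(thetas, float)
    M, T = len(models), thetas.shape[0]
    dos = np.array([genotypes.get(i, -1) for i in ped.ids])
    pen = _pen_matrix(ped, phenotypes, models)  # (M, n, 3)
    p_d = np.array([m.p_d for m in models])
    hf = _equilibrium_hapfreqs(p_d, np.full(M, p_marker))  # (M,4)
    hf_b = np.repeat(hf, T, axis=0)
    th_b = np.tile(thetas, M)
    pen_b = np.repeat(pen, T, axis=0)
    ll = _two_locus_logliks(ped, hf_b, th_b, pen_b, dos)
    return ll.reshape(M, T)


def ld_loglik_batch(
    ped: Pedigree,
    phenotypes: dict[str, object],
    genotypes: dict[str, int],
    models: list[TraitModel],
    hap_freqs: np.ndarray,  # (M*D, 4) or per-pair
) -> np.ndarray:
    """(B,) log-likelihood at theta=0 with explicit founder haplotype freqs."""
    dos = np.array([genotypes.get(i, -1) for i in ped.ids])
    pen = _pen_matrix(ped, phenotypes, models)
    B = hap_freqs.shape[0]
    if B % len(models):
        raise ValueError("hap_freqs rows must be a multiple of len(models)")
    reps = B // len(models)
    pen_b = np.repeat(pen, reps, axis=0)
    return _two_locus_logliks(ped, hap_freqs, np.zeros(B), pen_b, dos)


# ---------------------------------------------------------------------------
# multipoint: Lander-Green inheritance-vector HMM
# ---------------------------------------------------------------------------


def _meiosis_layout(ped: Pedigree):
    """Assign a bit index to every meiosis; fix one bit per founder (phase symmetry).

    Returns (free_bits, fixed, meiosis list) where meiosis k is
    (child_index, parent_index, is_paternal); ``fixed`` maps meiosis index
    -> forced bit value (0) for one transmission per founder-with-children.
    """
    meioses: list[tuple[int, int, bool]] = []
    for ind in ped.nonfounders:
        c = ped.index(ind.iid)
        meioses.append((c, ped.index(ind.father), True))
        meioses.append((c, ped.index(ind.mother), False))
    fixed: dict[int, int] = {}
    seen_founders: set[int] = set()
    for k, (c, p, _) in enumerate(meioses):
        if ped.members[p].is_founder and p not in seen_founders:
            fixed[k] = 0
            seen_founders.add(p)
    free = [k for k in range(len(meioses)) if k not in fixed]
    return free, fixed, meioses


def _descent_slots(ped: Pedigree, meioses, bits_for: dict[int, int]) -> np.ndarray:
    """Founder-haplotype slot carried by each individual's (pat, mat) allele.

    Slots: founder i contributes slots 2*idx and 2*idx+1 (paternal,
    maternal chromosome).  Returns (n, 2) slot indices.
    """
    n = len(ped)
    slots = -np.ones((n, 2), dtype=int)
    for i, ind in enumerate(ped.members):
        if ind.is_founder:
            slots[i] = (2 * i, 2 * i + 1)
    for k, (c, p, is_pat) in enumerate(meioses):
        b = bits_for[k]
        slots[c, 0 if is_pat else 1] = slots[p, b]
    return slots


def _emission_tables(ped: Pedigree, free, fixed, meioses, site_prob) -> np.ndarray:
    """Emission vector over all reduced inheritance vectors.

    ``site_prob(slots)`` maps the (n,2) descent-slot table to a probability.
    """
    V = 1 << len(free)
    out = np.empty(V)
    bits_for = dict(fixed)
    for v in range(V):
        for j, k in enumerate(free):
            bits_for[k] = (v >> j) & 1
        slots = _descent_slots(ped, meioses, bits_for)
        out[v] = site_prob(slots)
    return out


def _component_site_prob(constraints: list[tuple[int, int, np.ndarray]],
                         p_allele: float) -> float:
    """P(all per-individual factors | descent) for one locus.

    ``constraints`` are (paternal slot, maternal slot, weight-by-dosage)
    triples; founder-slot alleles are iid Bernoulli(p_allele).  Slots are
    grouped into connected components (slots tied by a shared factor) and
    each component is summed exactly over its 2^k allele assignments --
    untouched slots integrate to one.
    """
    if not constraints:
        return 1.0
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, _ in constraints:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comp: dict[int, list[tuple[int, int, np.ndarray]]] = {}
    for a, b, w in constraints:
        comp.setdefault(find(a), []).append((a, b, w))
    total = 1.0
    for group in comp.values():
        slots = sorted({s for a, b, _ in group for s in (a, b)})
        k = len(slots)
        if k > 22:
            raise MeiosisCapExceeded(
                f"emission component over {k} founder slots; pedigree too "
                "entangled for exact multipoint")
        pos = {s: i for i, s in enumerate(slots)}
        bits = (np.arange(1 << k)[:, None] >> np.arange(k)[None, :]) & 1
        prob = np.where(bits == 1, p_allele, 1 - p_allele).prod(axis=1)
        w_all = np.ones(1 << k)
        for a, b, w in group:
            dose = bits[:, pos[a]] + bits[:, pos[b]]
            w_all *= w[dose]
        total *= float(prob @ w_all)
    return total


_HARD = [np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]),
         np.array([0.0, 0.0, 1.0])]


def _marker_site_prob_factory(ped: Pedigree, dosages: np.ndarray, p_alt: float):
    obs = [(i, _HARD[int(d)]) for i, d in enumerate(dosages) if d >= 0]

    def site_prob(slots: np.ndarray) -> float:
        cons = [(int(slots[i, 0]), int(slots[i, 1]), w) for i, w in obs]
        return _component_site_prob(cons, p_alt)

    return site_prob


def _trait_site_prob_factory(ped: Pedigree, phenotypes: dict[str, object], model: TraitModel):
    pen = _pen_matrix(ped, phenotypes, [model])[0]  # (n, 3)
    informative = [i for i in range(len(ped)) if phenotypes.get(ped.ids[i]) is not None]

    def site_prob(slots: np.ndarray) -> float:
        cons = [(int(slots[i, 0]), int(slots[i, 1]), pen[i]) for i in informative]
        return _component_site_prob(cons, model.p_d)

    return site_prob


def _transition_inplace(alpha: np.ndarray, theta: float, n_bits: int) -> np.ndarray:
    """One HMM step: independent flip probability theta per free meiosis bit."""
    if theta <= 0:
        return alpha
    for j in range(n_bits):
        a = alpha.reshape(-1, 2, 1 << j)
        lo = a[:, 0, :].copy()
        hi = a[:, 1, :].copy()
        a[:, 0, :] = (1 - theta) * lo + theta * hi
        a[:, 1, :] = theta * lo + (1 - theta) * hi
    return alpha


def _forward_pass(loci_cm: list[float], emits: list[np.ndarray], n_bits: int) -> float:
    V = 1 << n_bits
    alpha = np.full(V, 1.0 / V)
    log_scale = 0.0
    prev = None
    for cm, emit in zip(loci_cm, emits):
        if prev is not None:
            theta = float(haldane_theta(cm - prev))
            alpha = _transition_inplace(alpha.copy(), theta, n_bits)
        alpha = alpha * emit
        mx = alpha.max()
        if mx <= 0:
            return 0.0
        alpha /= mx
        log_scale += math.log(mx)
        prev = cm
    return float(alpha.sum() * math.exp(log_scale))


def multipoint_scan(
    ped: Pedigree,
    marker_dosages: np.ndarray,  # (n_markers, n_individuals)
    marker_cm: np.ndarray,
    marker_freqs: np.ndarray,  # alt-allele frequency per marker
    positions_cm: np.ndarray,
    phenotypes: dict[str, object] | None,
    model: TraitModel | None,
    meiosis_cap: int = DEFAULT_MEIOSIS_CAP,
    marker_ids: list | None = None,
    emission_cache: dict | None = None,
) -> tuple[np.ndarray, float]:
    """Exact multipoint joint likelihood at each candidate trait position.

    Lander-Green HMM over inheritance vectors with founder-phase symmetry
    reduction and Haldane map distances.  Marker and trait emissions are
    position-independent, so they are computed once and only the forward
    pass is rerun per position.  Returns (per-position joint likelihoods,
    markers-only likelihood); with ``model=None`` only the latter is
    meaningful.  Raises :class:`MeiosisCapExceeded` for pedigrees with
    more than ``meiosis_cap`` meioses: use marker subsampling or raise
    the cap.
    """
    if ped.n_meioses > meiosis_cap:
        raise MeiosisCapExceeded(
            f"family {ped.family_id}: {ped.n_meioses} meioses exceed the cap of "
            f"{meiosis_cap}; use subsampling or raise the cap"
        )
    marker_cm = np.asarray(marker_cm, float)
    order = np.argsort(marker_cm, kind="stable")
    marker_cm = marker_cm[order]
    marker_dosages = np.asarray(marker_dosages)[order]
    marker_freqs = np.asarray(marker_freqs, float)[order]
    if marker_ids is not None:
        marker_ids = [marker_ids[k] for k in order]
    positions_cm = np.atleast_1d(np.asarray(positions_cm, float))

    free, fixed, meioses = _meiosis_layout(ped)
    n_bits = len(free)
    cache = emission_cache if emission_cache is not None else {}

    def marker_emit(k: int) -> np.ndarray:
        key = ("marker", marker_ids[k]) if marker_ids is not None else None
        if key is not None and key in cache:
            return cache[key]
        e = _emission_tables(ped, free, fixed, meioses,
                             _marker_site_prob_factory(ped, marker_dosages[k],
                                                       marker_freqs[k]))
        if key is not None:
            cache[key] = e
        return e

    m_emits = [marker_emit(k) for k in range(marker_cm.shape[0])]
    null = _forward_pass(list(marker_cm), m_emits, n_bits)
    if model is None:
        return np.full(positions_cm.shape, null), null
    if "trait" in cache:
        t_emit = cache["trait"]
    else:
        t_emit = _emission_tables(ped, free, fixed, meioses,
                                  _trait_site_prob_factory(ped, phenotypes or {}, model))
        cache["trait"] = t_emit
    out = np.empty(positions_cm.shape)
    for i, pos in enumerate(positions_cm):
        k = int(np.searchsorted(marker_cm, pos))
        cms = list(marker_cm[:k]) + [float(pos)] + list(marker_cm[k:])
        emits = m_emits[:k] + [t_emit] + m_emits[k:]
        out[i] = _forward_pass(cms, emits, n_bits)
    return out, null


def multipoint_likelihood(
    ped: Pedigree,
    marker_dosages: np.ndarray,
    marker_cm: np.ndarray,
    marker_freqs: np.ndarray,
    position_cm: float,
    phenotypes: dict[str, object] | None,
    model: TraitModel | None,
    meiosis_cap: int = DEFAULT_MEIOSIS_CAP,
) -> float:
    """Exact multipoint P(phenotypes, window genotypes) with the trait locus
    inserted at ``position_cm``; pass ``model=None`` for markers only."""
    liks, null = multipoint_scan(ped, marker_dosages, marker_cm, marker_freqs,
                                 np.array([position_cm]), phenotypes, model,
                                 meiosis_cap=meiosis_cap)
    return float(liks[0]) if model is not None else null
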