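"""Brute-force enumeration oracles for pedigree likelihoods.

These compute the same quantities as :mod:`ngla.likelihood` by direct,
exhaustive summation over every joint assignment of per-individual
multi-locus ordered haplotype pairs -- no peeling, no HMM, no symmetry
reduction -- and are used in the test suite to verify the fast engines to
machine precision.  Guarded to small pedigrees and few loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree import Pedigree
from .likelihood import haldane_theta
from .trait import TraitModel, penetrance_table

__all__ = [
    "enumerate_joint",
    "enumerate_single_locus",
    "enumerate_two_point",
    "enumerate_multipoint",
    "enumerate_oracle",
]

_MAX_CONFIGS = 40_000_000
_CHUNK = 1 << 20


@dataclass
class _Locus:
    """One locus in the enumeration: either a genotyped marker or the trait."""

    freq: float  # allele-1 frequency (marker alt or trait allele d)
    dosages: np.ndarray | None = None  # (n,) -1 missing; None for trait locus
    pen: np.ndarray | None = None  # (n, 3) penetrance; None for marker


def _hap_probs(loci: list[_Locus], founder_hap_freqs: np.ndarray | None) -> np.ndarray:
    L = len(loci)
    H = 1 << L
    if founder_hap_freqs is not None:
        hp = np.asarray(founder_hap_freqs, float)
        if hp.shape != (H,):
            raise ValueError("founder_hap_freqs must have length 2^L")
        return hp
    hp = np.ones(H)
    for k, loc in enumerate(loci):
        bit = (np.arange(H) >> k) & 1
        hp *= np.where(bit == 1, loc.freq, 1 - loc.freq)
    return hp


def _hap_transmission_table(L: int, thetas: list[float]) -> np.ndarray:
    """T[h, s]: P(parent in ordered state s = h1*H + h2 transmits haplotype h)."""
    H = 1 << L
    T = np.zeros((H, H * H))
    for h1 in range(H):
        for h2 in range(H):
            s = h1 * H + h2
            for o in range(1 << L):
                p = 0.5
                for k in range(1, L):
                    same = ((o >> k) & 1) == ((o >> (k - 1)) & 1)
                    p *= (1 - thetas[k - 1]) if same else thetas[k - 1]
                h = 0
                for k in range(L):
                    src = h2 if (o >> k) & 1 else h1
                    h |= ((src >> k) & 1) << k
                T[h, s] += p
    return T


def enumerate_joint(
    ped: Pedigree,
    loci: list[_Locus],
    thetas: list[float],
    founder_hap_freqs: np.ndarray | None = None,
) -> float:
    """Probability of all observations by full joint-state enumeration.

    Every individual is assigned an ordered pair of L-locus haplotypes;
    the sum runs over all (2^L * 2^L)^n joint assignments in vectorized
    chunks.  ``thetas`` are the L-1 recombination fractions between
    consecutive loci.  ``founder_hap_freqs`` (length 2^L) overrides the
    default linkage-equilibrium founder haplotype distribution.
    """
    n = len(ped)
    L = len(loci)
    H = 1 << L
    S = H * H
    n_conf = S ** n
    if n_conf > _MAX_CONFIGS:
        raise ValueError(f"oracle guard: {n_conf} joint configurations")
    hp = _hap_probs(loci, founder_hap_freqs)
    T = _hap_transmission_table(L, list(thetas))
    prior = np.repeat(hp, H) * np.tile(hp, H)  # (S,) over s = h1*H + h2

    obs = np.ones((n, S))
    h_pat = np.arange(S) // H
    h_mat = np.arange(S) % H
    for k, loc in enumerate(loci):
        a1 = (h_pat >> k) & 1
        a2 = (h_mat >> k) & 1
        dose = a1 + a2
        for i in range(n):
            if loc.dosages is not None:
                d = loc.dosages[i]
                if d >= 0:
                    obs[i] *= (dose == d).astype(float)
            else:
                obs[i] *= loc.pen[i, dose]

    fam = ped.members
    parents = [
        (None if m.is_founder else (ped.index(m.father), ped.index(m.mother)))
        for m in fam
    ]
    total = 0.0
    for lo in range(0, n_conf, _CHUNK):
        hi = min(n_conf, lo + _CHUNK)
        idx = np.arange(lo, hi, dtype=np.int64)
        states = np.empty((n, hi - lo), dtype=np.int64)
        rem = idx
        for i in range(n):
            states[i] = rem % S
            rem = rem // S
        p = np.ones(hi - lo)
        for i in range(n):
            s_i = states[i]
            p *= obs[i, s_i]
            if parents[i] is None:
                p *= prior[s_i]
            else:
                f, m = parents[i]
                p *= T[s_i // H, states[f]] * T[s_i % H, states[m]]
        total += p.sum()
    return float(total)


# -- convenience wrappers ----------------------------------------------------


def enumerate_single_locus(ped: Pedigree, genotypes: dict[str, int], p_alt: float) -> float:
    dos = np.array([genotypes.get(i, -1) for i in ped.ids])
    return enumerate_joint(ped, [_Locus(freq=p_alt, dosages=dos)], [])


def enumerate_two_point(
    ped: Pedigree,
    phenotypes: dict[str, object],
    genotypes: dict[str, int],
    theta: float,
    model: TraitModel,
    p_marker: float,
    founder_hap_freqs: np.ndarray | None = None,
) -> float:
    """Joint trait-marker probability; trait locus first, marker second.

    ``founder_hap_freqs`` is indexed h = 2*t + m, matching the LD-model
    haplotype order in the fast engine.
    """
    dos = np.array([genotypes.get(i, -1) for i in ped.ids])
    pen = np.stack([penetrance_table(phenotypes.get(i), [model])[0] for i in ped.ids])
    # enumeration bit order: locus 0 = bit 0; put marker at bit 0, trait at bit 1
    # so h_enum = 2*t + m matches the engine's haplotype index directly.
    loci = [_Locus(freq=p_marker, dosages=dos), _Locus(freq=model.p_d, pen=pen)]
    # loci list is in bit order (marker bit 0, trait bit 1); theta between them
    return enumerate_joint(ped, loci, [theta], founder_hap_freqs=founder_hap_freqs)


def enumerate_multipoint(
    ped: Pedigree,
    marker_dosages: np.ndarray,
    marker_cm: np.ndarray,
    marker_freqs: np.ndarray,
    position_cm: float | None = None,
    phenotypes: dict[str, object] | None = None,
    model: TraitModel | None = None,
) -> float:
    """Multipoint probability with optional trait locus at ``position_cm``."""
    marker_cm = np.asarray(marker_cm, float)
    order = np.argsort(marker_cm, kind="stable")
    cms = list(marker_cm[order])
    D = np.asarray(marker_dosages)[order]
    fr = np.asarray(marker_freqs, float)[order]
    loci = [_Locus(freq=fr[k], dosages=D[k]) for k in range(len(cms))]
    if model is not None:
        pen = np.stack(
            [penetrance_table((phenotypes or {}).get(i), [model])[0] for i in ped.ids]
        )
        t_idx = int(np.searchsorted(cms, float(position_cm)))
        loci.insert(t_idx, _Locus(freq=model.p_d, pen=pen))
        cms.insert(t_idx, float(position_cm))
    thetas = [float(haldane_theta(cms[k + 1] - cms[k])) for k in range(len(cms) - 1)]
    return enumerate_joint(ped, loci, thetas)


def enumerate_oracle(ped: Pedigree, *, kind: str, **kw) -> float:
    """Dispatch: kind in {"single_locus", "two_point", "multipoint"}."""
    fn = {
        "single_locus": enumerate_single_locus,
        "two_point": enumerate_two_point,
        "multipoint": enumerate_multipoint,
    }[kind]
    return fn(ped, **kw)
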