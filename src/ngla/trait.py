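"""Quantitative-trait threshold model and its integration grid.

The trait model: a diallelic locus with trait-allele frequency ``p_d``
shifts the mean of a normally distributed phenotype (here systolic blood
pressure).  Individuals whose latent phenotype exceeds a treatment
threshold ``tau`` are observed only as "affected" (on medication); their
numeric value is censored.  Untreated individuals contribute the normal
*density* of their observed value; treated individuals contribute the
exceedance probability P(X > tau | genotype); a missing phenotype
contributes 1.

Linkage and LD statistics integrate the likelihood ratio over a proper
prior on the trait-model parameters; :func:`build_trait_grid` constructs
that prior as a finite tensor-product grid in standardized phenotype
units, so the default grid is scale-free.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "TraitModel",
    "TraitGrid",
    "TraitGridConfig",
    "phenotype_likelihood",
    "build_trait_grid",
    "standardize_phenotypes",
]

_SQRT2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class TraitModel:
    """One point in trait-model parameter space.

    mu is indexed by the count of the trait allele d: (mu_DD, mu_Dd, mu_dd)
    stored as ``mu[g]`` for g = number of d alleles in {0, 1, 2}.
    Units are whatever the phenotypes are expressed in (mmHg raw, or SD
    units after standardization).
    """

    p_d: float
    mu: tuple[float, float, float]
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_d < 1.0):
            raise ValueError(f"p_d must be in (0,1), got {self.p_d}")
        if not (self.sigma > 0.0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not all(math.isfinite(m) for m in self.mu):
            raise ValueError("genotype means must be finite")

    def genotype_priors(self) -> np.ndarray:
        """Hardy-Weinberg priors over g = 0, 1, 2 copies of d."""
        p = self.p_d
        return np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])

    def swapped(self) -> "TraitModel":
        """Relabel d <-> D: allele frequency 1-p_d, means reversed."""
        return TraitModel(1.0 - self.p_d, self.mu[::-1], self.sigma, self.tau)


def phenotype_likelihood(obs, g: int, m: TraitModel) -> float:
    """Likelihood contribution of one phenotype record given trait genotype.

    Parameters
    ----------
    obs
        ``None`` (missing), the string ``"treated"``, or a numeric SBP value
        for an untreated individual.
    g
        Trait-locus genotype: number of copies of the trait allele (0/1/2).
    m
        Trait-model parameter point.
    """
    if m.sigma <= 0:
        raise ValueError("sigma must be positive")
    if obs is None:
        return 1.0
    mu_g = m.mu[g]
    if isinstance(obs, str):
        if obs != "treated":
            raise ValueError(f"unknown phenotype observation {obs!r}")
        return float(norm.sf((m.tau - mu_g) / m.sigma))
    x = float(obs)
    z = (x - mu_g) / m.sigma
    return math.exp(-0.5 * z * z) / (_SQRT2PI * m.sigma)


def penetrance_table(obs, models: "TraitGrid | list[TraitModel]") -> np.ndarray:
    """Vector of phenotype likelihoods over (model, genotype): shape (M, 3)."""
    mods = models.models if isinstance(models, TraitGrid) else list(models)
    mu = np.array([m.mu for m in mods])  # (M, 3)
    sigma = np.array([m.sigma for m in mods])[:, None]
    if obs is None:
        return np.ones_like(mu)
    if isinstance(obs, str):
        tau = np.array([m.tau for m in mods])[:, None]
        return norm.sf((tau - mu) / sigma)
    z = (float(obs) - mu) / sigma
    return np.exp(-0.5 * z * z) / (_SQRT2PI * sigma)


@dataclass
class TraitGrid:
    """A finite proper prior over trait models: points with positive weights."""

    models: list[TraitModel]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.models) != len(self.weights):
            raise ValueError("models/weights length mismatch")
        if np.any(self.weights <= 0):
            raise ValueError("grid weights must be positive")
        s = self.weights.sum()
        if abs(s - 1.0) > 1e-12:
            raise ValueError(f"grid weights must sum to 1 (got {s!r})")

    def __len__(self) -> int:
        return len(self.models)

    def p_d(self) -> np.ndarray:
        return np.array([m.p_d for m in self.models])


@dataclass
class TraitGridConfig:
    """Ranges for the tensor-product trait grid (standardized units).

    ``displacements`` are |mu_DD - mu_dd| in SD units; both orientations
    (which homozygote is high) are included.  ``dominance`` places the
    heterozygote: 0 recessive (at mu of the common homozygote), 0.5
    additive, 1 dominant.  ``tau_quantiles`` are sample quantiles of the
    standardized untreated phenotypes at which the treatment threshold is
    placed.
    """

    p_d: tuple[float, ...] = (0.001, 0.01, 0.05, 0.1, 0.2, 0.3, 0.5)
    displacements: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 3.0)
    dominance: tuple[float, ...] = (0.0, 0.5, 1.0)
    sigma: tuple[float, ...] = (0.5, 1.0)
    tau_quantiles: tuple[float, ...] = (0.7, 0.8, 0.9, 0.95)
    both_orientations: bool = True

    @classmethod
    def coarse(cls) -> "TraitGridConfig":
        """A small grid for quick scans and large replicate studies."""
        return cls(
            p_d=(0.05, 0.2),
            displacements=(1.0, 2.0),
            dominance=(0.0, 0.5),
            # sigma below 1 is essential: with a real locus the residual SD
            # within genotype is well below the sample SD, and a grid pinned
            # at sigma = 1 cannot fit any displacement signal
            sigma=(0.5, 1.0),
            tau_quantiles=(0.8, 0.95),
        )


def standardize_phenotypes(sbp: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Standardize observed (untreated) phenotype values to mean 0, SD 1.

    Returns (standardized values, center, scale).  NaNs pass through.
    """
    sbp = np.asarray(sbp, dtype=float)
    obs = sbp[np.isfinite(sbp)]
    if obs.size < 2 or obs.std(ddof=1) == 0:
        center, scale = (obs.mean() if obs.size else 0.0), 1.0
    else:
        center, scale = obs.mean(), obs.std(ddof=1)
    return (sbp - center) / scale, float(center), float(scale)


def build_trait_grid(
    config: TraitGridConfig | None = None,
    phenotypes: np.ndarray | None = None,
) -> TraitGrid:
    """Build the tensor-product integration grid with uniform weights.

    The threshold grid is placed at the configured sample quantiles of the
    standardized untreated phenotypes when ``phenotypes`` (already
    standardized) are given, else at the corresponding standard-normal
    quantiles.  Genotype means are centered so the population mean under
    Hardy-Weinberg is zero, keeping the grid aligned with standardized data.
    """
    cfg = config or TraitGridConfig()
    for name in ("p_d", "displacements", "dominance", "sigma", "tau_quantiles"):
        if len(getattr(cfg, name)) == 0:
            raise ValueError(f"empty grid range: {name}")
    if phenotypes is not None:
        obs = np.asarray(phenotypes, float)
        obs = obs[np.isfinite(obs)]
    else:
        obs = None
    taus = tuple(
        float(np.quantile(obs, q)) if obs is not None and obs.size
        else float(norm.ppf(q))
        for q in cfg.tau_quantiles
    )
    orientations = (1.0, -1.0) if cfg.both_orientations else (1.0,)
    models: list[TraitModel] = []
    seen: set[tuple] = set()
    for p, d, h, s, tau, sign in itertools.product(
        cfg.p_d, cfg.displacements, cfg.dominance, cfg.sigma, taus, orientations
    ):
        mu0 = 0.0
        mu2 = sign * d
        mu1 = mu0 + h * (mu2 - mu0)
        # center to zero population mean under HWE
        q = 1.0 - p
        shift = q * q * mu0 + 2 * p * q * mu1 + p * p * mu2
        mu = (mu0 - shift, mu1 - shift, mu2 - shift)
        key = (round(p, 12), tuple(round(x, 12) for x in mu), round(s, 12), round(tau, 12))
        if key in seen:  # e.g. zero displacement duplicates
            continue
        seen.add(key)
        models.append(TraitModel(p_d=p, mu=mu, sigma=s, tau=tau))
    w = np.full(len(models), 1.0 / len(models))
    return TraitGrid(models, w)
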