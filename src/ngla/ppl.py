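"""The posterior probability of linkage (PPL).

The PPL integrates the trait-marker likelihood ratio over the trait-model
parameter grid and a prior on the recombination fraction theta, yielding
a Bayes factor

    BF = sum_grid sum_theta w_model * w_theta * L(data | theta, model)
                                             / L(data | theta = 1/2, model),

which updates a small prior probability of linkage pi:

    PPL = pi * BF / (pi * BF + 1 - pi).

The default pi = 0.02 is consistent with a printed posterior/Bayes-factor
pair of 68% and 104.125.  Evidence accumulates across families by
multiplying per-family Bayes factors before the posterior update
(sequential updating).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .likelihood import two_locus_loglik_batch
from .pedigree import Pedigree
from .trait import TraitGrid, TraitModel

__all__ = [
    "PriorConfig",
    "PosteriorResult",
    "ppl_from_bf",
    "integrated_bayes_factor",
    "ppl_scan",
    "sequential_update",
    "posterior_mean_trait_params",
]

DEFAULT_PI_LINKAGE = 0.02
DEFAULT_THETA_GRID = np.array(
    [0.0, 0.01, 0.02, 0.03, 0.04, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5]
)


def _uniform_theta_weights(thetas: np.ndarray) -> np.ndarray:
    """Trapezoid weights for a uniform prior density on theta in [0, 0.5]."""
    t = np.asarray(thetas, float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("theta grid must be a nonempty 1-D array")
    if t.size == 1:
        return np.array([1.0])
    w = np.empty_like(t)
    w[0] = (t[1] - t[0]) / 2
    w[-1] = (t[-1] - t[-2]) / 2
    w[1:-1] = (t[2:] - t[:-2]) / 2
    return w / w.sum()


@dataclass
class PriorConfig:
    """Prior probability of linkage and the theta integration grid."""

    pi_linkage: float = DEFAULT_PI_LINKAGE
    theta_grid: np.ndarray = field(default_factory=lambda: DEFAULT_THETA_GRID.copy())
    theta_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.pi_linkage < 1.0):
            raise ValueError("pi_linkage must be in (0,1)")
        self.theta_grid = np.asarray(self.theta_grid, float)
        if np.any((self.theta_grid < 0) | (self.theta_grid > 0.5)):
            raise ValueError("theta grid must lie in [0, 0.5]")
        if self.theta_weights is None:
            self.theta_weights = _uniform_theta_weights(self.theta_grid)
        self.theta_weights = np.asarray(self.theta_weights, float)
        if abs(self.theta_weights.sum() - 1.0) > 1e-9:
            raise ValueError("theta weights must sum to 1")


@dataclass
class PosteriorResult:
    """A Bayes factor with its prior-to-posterior update at one position."""

    position_cm: float
    bayes_factor: float
    prior: float
    posterior: float
    family_bfs: dict[str, float] = field(default_factory=dict)
    marker: str | None = None


def ppl_from_bf(bf: float, pi: float = DEFAULT_PI_LINKAGE) -> float:
    """Posterior probability from a Bayes factor: pi*BF / (pi*BF + 1 - pi)."""
    if bf < 0:
        raise ValueError("Bayes factor must be nonnegative")
    if not (0.0 < pi < 1.0):
        raise ValueError("prior must be in (0,1)")
    return pi * bf / (pi * bf + 1.0 - pi)


def _bf_from_logliks(ll: np.ndarray, grid: TraitGrid, theta_w: np.ndarray) -> float:
    """BF from an (M, T) log-likelihood array whose last theta column is 0.5."""
    null = ll[:, -1][:, None]  # log L(theta=0.5 | model)
    with np.errstate(over="ignore"):
        lr = np.exp(ll - null)
    bf = float(np.sum(grid.weights[:, None] * theta_w[None, :] * lr))
    return bf


def integrated_bayes_factor(
    ped: Pedigree,
    phenotypes: dict[str, object],
    genotypes: dict[str, int],
    p_marker: float,
    grid: TraitGrid,
    priors: PriorConfig | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Integrated trait-marker Bayes factor for one family at one marker.

    Returns (BF, per-grid-point theta-integrated likelihood ratios,
    per-grid-point log null likelihoods).  The ratios define the BF; the
    product ratio x null is each grid point's integrated likelihood,
    which is the posterior mass fed to
    :func:`posterior_mean_trait_params`.  All phenotype information
    absent gives BF = 1 exactly.
    """
    priors = priors or PriorConfig()
    thetas = priors.theta_grid
    if thetas[-1] != 0.5:
        thetas = np.append(thetas, 0.5)
        tw = np.append(priors.theta_weights, 0.0)
    else:
        tw = priors.theta_weights
    ll = two_locus_loglik_batch(ped, phenotypes, genotypes, grid.models, thetas, p_marker)
    if not np.any(np.isfinite(ll)):
        raise ValueError(
            "all-zero likelihoods: the genotype data are impossible under every "
            "model (Mendelian inconsistency?)"
        )
    null = ll[:, -1][:, None]
    lr = np.exp(ll - null)
    per_model = lr[:, : tw.size] @ tw  # theta-integrated LR per grid point
    bf = float(grid.weights @ per_model)
    return bf, per_model, ll[:, -1]


def sequential_update(family_bfs: dict[str, float] | list[float],
                      pi: float = DEFAULT_PI_LINKAGE) -> PosteriorResult:
    """Pool evidence across families: BF_pooled = product of family BFs."""
    if isinstance(family_bfs, dict):
        vals = list(family_bfs.values())
        named = dict(family_bfs)
    else:
        vals = list(family_bfs)
        named = {str(i + 1): b for i, b in enumerate(vals)}
    bf = float(np.prod(vals)) if vals else 1.0
    return PosteriorResult(np.nan, bf, pi, ppl_from_bf(bf, pi), family_bfs=named)


def ppl_scan(
    families: list[Pedigree],
    phenotypes_by_family: dict[str, dict[str, object]],
    genotype_column,  # callable (family_id, marker_index) -> dict iid -> dosage
    marker_freqs: np.ndarray,
    marker_cm: np.ndarray,
    marker_indices: list[int],
    grid: TraitGrid,
    priors: PriorConfig | None = None,
    marker_names: list[str] | None = None,
) -> list[PosteriorResult]:
    """Two-point PPL track over a set of scan markers.

    At each marker the integrated Bayes factor is computed per family and
    pooled by sequential updating.  Markers chosen for scanning should be
    LD-pruned (see :mod:`ngla.subsample`) so their founder genotypes are
    roughly independent, matching the two-point model.
    """
    priors = priors or PriorConfig()
    out: list[PosteriorResult] = []
    for j in marker_indices:
        fam_bfs: dict[str, float] = {}
        for ped in families:
            bf, _, _ = integrated_bayes_factor(
                ped, phenotypes_by_family[ped.family_id],
                genotype_column(ped.family_id, j), float(marker_freqs[j]),
                grid, priors)
            fam_bfs[ped.family_id] = bf
        pooled = sequential_update(fam_bfs, priors.pi_linkage)
        pooled.position_cm = float(marker_cm[j])
        if marker_names is not None:
            pooled.marker = marker_names[j]
        out.append(pooled)
    return out


def scan_summary(track: list[PosteriorResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "pos_cM": r.position_cm,
            "marker": r.marker,
            "BF": r.bayes_factor,
            "PPL": r.posterior,
            **{f"BF_fam{f}": b for f, b in r.family_bfs.items()},
        } for r in track]
    )


def support_region(track: list[PosteriorResult], drop_log10: float = 1.0
                   ) -> tuple[float, float]:
    """Positions whose pooled BF is within ``drop_log10`` of the maximum
    (the posterior-scale analogue of a 1-LOD support interval)."""
    if not track:
        raise ValueError("empty track")
    lbf = np.log10(np.maximum([r.bayes_factor for r in track], 1e-300))
    keep = lbf >= lbf.max() - drop_log10
    pos = np.array([r.position_cm for r in track])[keep]
    return float(pos.min()), float(pos.max())


def posterior_mean_trait_params(grid: TraitGrid, per_model_lr: np.ndarray,
                                log_null: np.ndarray | None = None
                                ) -> TraitModel:
    """Posterior-mean trait parameters, a by-product of the BF integration.

    Each grid point's posterior mass is its prior weight times its
    integrated likelihood -- the theta-integrated likelihood ratio times
    the model's own null likelihood (``log_null``); without ``log_null``
    the ratios alone are used, which is exact only when the null
    likelihood is model-free (e.g. a single-point grid).
    """
    w = grid.weights * per_model_lr
    if log_null is not None:
        ln = np.asarray(log_null, float)
        w = w * np.exp(ln - ln.max())
    tot = w.sum()
    if tot <= 0:
        raise ValueError("degenerate posterior: no grid point has positive mass")
    w = w / tot
    import warnings
    if w.max() > 1 - 1e-9:
        warnings.warn("posterior mass concentrated on a single boundary grid point")
    p_d = float(w @ np.array([m.p_d for m in grid.models]))
    mu = tuple(float(x) for x in w @ np.array([m.mu for m in grid.models]))
    sigma = float(w @ np.array([m.sigma for m in grid.models]))
    tau = float(w @ np.array([m.tau for m in grid.models]))
    return TraitModel(p_d=p_d, mu=mu, sigma=sigma, tau=tau)
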