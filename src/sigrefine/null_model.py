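"""Permutation null for connectivity scores and its 3-Gaussian mixture model.

Significance of an observed connectivity score is measured against the
distribution of scores the same signature produces on uniformly random
ranked lists.  Those null scores are well described by a mixture of three
Gaussians; the fitted mixture gives closed-form one-sided tail p-values and
a mixture-moment z-score (the normalised connectivity score, NCS):

    NCS = (cs - mu_mix) / sigma_mix,
    mu_mix = sum_i w_i mu_i,  sigma_mix^2 = sum_i w_i (sigma_i^2 + mu_i^2) - mu_mix^2.

The null depends only on the signature's set sizes and the universe size
(random lists are exchangeable), so one null serves every ranked list
queried with the same signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from .ranked_lists import GeneSignature, GeneUniverse, ValidationError
from .gsea_engine import es_from_hit_ranks

MIN_PERMUTATIONS = 100
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class GaussianMixtureModel:
    """A 1-D Gaussian mixture: weights, means, standard deviations."""

    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if abs(w.sum() - 1.0) > 1e-6:
            raise ValidationError(f"mixture weights sum to {w.sum()}, not 1")
        if np.any(np.asarray(self.sds) <= 0):
            raise ValidationError("mixture component sds must be positive")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def mean(self) -> float:
        return float(np.dot(self.weights, self.means))

    @property
    def sd(self) -> float:
        w = np.asarray(self.weights)
        m = np.asarray(self.means)
        s = np.asarray(self.sds)
        var = float(np.dot(w, s**2 + m**2) - self.mean**2)
        return float(np.sqrt(max(var, 0.0)))

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x, dtype=float)
        for w, m, s in zip(self.weights, self.means, self.sds):
            out += w * stats.norm.pdf(x, m, s)
        return out

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x, dtype=float)
        for w, m, s in zip(self.weights, self.means, self.sds):
            out += w * stats.norm.cdf(x, m, s)
        return out

    def sf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x, dtype=float)
        for w, m, s in zip(self.weights, self.means, self.sds):
            out += w * stats.norm.sf(x, m, s)
        return out


@dataclass(frozen=True)
class NullDistribution:
    """Permutation null scores of one signature plus their fitted mixture."""

    scores: np.ndarray
    mixture: GaussianMixtureModel
    seed: int


def sample_null_scores(
    sig: GeneSignature,
    universe: GeneUniverse,
    n_perm: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Connectivity scores of a signature against i.i.d. uniform permutations.

    Only the ranks the signature genes land on matter, so each permutation is
    realised by sampling |U| + |D| distinct positions uniformly from 1..N.
    """
    if n_perm < MIN_PERMUTATIONS:
        raise ValidationError(
            f"n_perm must be >= {MIN_PERMUTATIONS} for a stable mixture fit, got {n_perm}"
        )
    sig.validate_for_query(universe)
    n = universe.n
    u, d = len(sig.up), len(sig.down)
    rng = np.random.default_rng(seed)
    out = np.empty(n_perm, dtype=float)
    for i in range(n_perm):
        pos = rng.choice(n, size=u + d, replace=False) + 1
        es_u = es_from_hit_ranks(np.sort(pos[:u]), n).value
        es_d = es_from_hit_ranks(np.sort(pos[u:]), n).value
        out[i] = (es_u - es_d) / 2.0
    return out


def fit_gmm3(scores: np.ndarray, n_components: int = 3, seed: int = 0) -> GaussianMixtureModel:
    """EM fit of a Gaussian mixture to null scores.

    Components that collapse (weight < 1e-3 or sd < 1e-4) trigger a refit
    with fewer components, down to a single Gaussian, so near-unimodal nulls
    are handled gracefully.
    """
    scores = np.asarray(scores, dtype=float)
    scores = scores[np.isfinite(scores)]
    if scores.size < MIN_PERMUTATIONS:
        raise ValidationError(f"need >= {MIN_PERMUTATIONS} finite scores, got {scores.size}")
    if np.ptp(scores) == 0:
        raise ValidationError("all null scores identical; mixture variance would be zero")
    x = scores.reshape(-1, 1)
    for k in range(n_components, 0, -1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=10,
            init_params="k-means++",
            tol=1e-6,
            max_iter=500,
            random_state=seed,
        ).fit(x)
        weights = gm.weights_.ravel()
        means = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.reshape(k))
        if k == 1 or (weights.min() >= 1e-3 and sds.min() >= 1e-4):
            order = np.argsort(means)
            return GaussianMixtureModel(
                tuple(weights[order] / weights.sum()),
                tuple(means[order]),
                tuple(sds[order]),
            )
    raise AssertionError("unreachable")


def build_null(
    sig: GeneSignature,
    universe: GeneUniverse,
    n_perm: int = 10_000,
    seed: int = 0,
    n_components: int = 3,
) -> NullDistribution:
    scores = sample_null_scores(sig, universe, n_perm=n_perm, seed=seed)
    mixture = fit_gmm3(scores, n_components=n_components, seed=seed)
    return NullDistribution(scores, mixture, seed)


def empirical_pvalue(cs: float, mixture: GaussianMixtureModel, direction: str) -> float:
    """One-sided tail mass of the fitted null at the observed score.

    ``positive`` connections use the upper tail P(X >= cs), ``negative`` the
    lower tail P(X <= cs).
    """
    if direction == "positive":
        p = float(mixture.sf(cs))
    elif direction == "negative":
        p = float(mixture.cdf(cs))
    else:
        raise ValidationError(f"direction must be 'positive' or 'negative', got {direction!r}")
    return float(np.clip(p, _P_FLOOR, 1.0))


def normalize_cs(cs, mixture: GaussianMixtureModel):
    """Mixture-moment z-score of a connectivity score (the NCS)."""
    sd = mixture.sd
    if sd == 0:
        raise ValidationError("mixture sd is zero; NCS undefined")
    z = (np.asarray(cs, dtype=float) - mixture.mean) / sd
    return float(z) if z.ndim == 0 else z


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
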