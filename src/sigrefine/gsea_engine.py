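"""Running-sum enrichment scores, connectivity scores, and drug-drug distances.

The enrichment score (ES) is the classic unweighted Kolmogorov-Smirnov
statistic: walking down a ranked list, a running sum increases by 1/|set| on
genes in the set and decreases by 1/(N-|set|) otherwise; the ES is the signed
maximum deviation from zero.  ES is +1 when the set occupies the top of the
list contiguously, -1 when it occupies the bottom.

The connectivity score of a two-sided signature S = {U, D} against a ranked
list A is

    CS(S, A) = (ES_A(U) - ES_A(D)) / 2        in [-1, 1],

positive when A mimics the signature (U at the top, D at the bottom) and
negative when A reverses it.

The distance between two drugs A and B compares each drug's optimal
signature (top/bottom k of its PRL) against the other's full PRL:

    d(A, B) = 1 - (CS(S_A, B) + CS(S_B, A)) / 2     in [0, 2],

0 for identical PRLs, 2 for exactly reversed ones, ~1 for unrelated ones.
The combiner is pluggable.
"""

from __future__ import annotations

from collections.abc import Callable, Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ranked_lists import (
    GeneSignature,
    RankedList,
    ValidationError,
    make_optimal_signature,
)


@dataclass(frozen=True)
class EnrichmentScore:
    """Signed maximum running-sum deviation and the 1-based rank where it occurs."""

    value: float
    arg_rank: int


@dataclass(frozen=True)
class ConnectivityScore:
    cs: float
    es_up: EnrichmentScore
    es_down: EnrichmentScore


@dataclass(frozen=True)
class DrugDistance:
    value: float
    cs_ab: float  # CS of A's optimal signature along B's PRL
    cs_ba: float


def es_from_hit_ranks(hit_ranks: np.ndarray, n: int) -> EnrichmentScore:
    """ES from the sorted 1-based ranks of the gene set within a list of size n.

    At an exact tie between the maximum positive and maximum negative
    deviation, the one occurring earliest in the list wins.
    """
    ranks = np.asarray(hit_ranks, dtype=np.int64)
    h = ranks.size
    if h == 0 or h >= n:
        raise ValidationError("gene set must be a nonempty proper subset of the universe")
    hits = np.arange(1, h + 1)
    miss_step = 1.0 / (n - h)
    # running sum immediately after the i-th hit (at position ranks[i]) ...
    peaks = hits / h - (ranks - hits) * miss_step
    # ... and immediately before it (at position ranks[i] - 1)
    troughs = (hits - 1) / h - (ranks - hits) * miss_step
    # tolerance absorbs float noise so ties resolve by position, not rounding
    tol = 1e-9
    i_max = int(np.argmax(peaks >= peaks.max() - tol))  # earliest among tied maxima
    i_min = int(np.argmax(troughs <= troughs.min() + tol))
    pos_val, pos_at = float(peaks[i_max]), int(ranks[i_max])
    neg_val, neg_at = float(troughs[i_min]), int(ranks[i_min]) - 1
    pos_mag = max(pos_val, 0.0)
    neg_mag = max(-neg_val, 0.0)
    if pos_mag > neg_mag + tol or (abs(pos_mag - neg_mag) <= tol and pos_at <= neg_at):
        return EnrichmentScore(pos_val, pos_at)
    return EnrichmentScore(neg_val, neg_at)


def enrichment_score(prl: RankedList, genes: Iterable[str]) -> EnrichmentScore:
    """Running-sum enrichment of a gene set along a ranked list."""
    gene_set = set(genes)
    if not gene_set:
        raise ValidationError("enrichment of the empty set is undefined")
    if len(gene_set) >= prl.n:
        raise ValidationError("enrichment of the full universe is undefined")
    ranks = np.sort(prl.ranks_of(gene_set))
    return es_from_hit_ranks(ranks, prl.n)


def connectivity_score(sig: GeneSignature, prl: RankedList) -> ConnectivityScore:
    """Two-tailed GSEA connectivity of a signature against a ranked list."""
    sig.validate_for_query(prl.universe)
    es_up = enrichment_score(prl, sig.up)
    es_down = enrichment_score(prl, sig.down)
    return ConnectivityScore((es_up.value - es_down.value) / 2.0, es_up, es_down)


def default_distance_combiner(cs_ab: float, cs_ba: float) -> float:
    return 1.0 - (cs_ab + cs_ba) / 2.0


def drug_distance(
    prl_a: RankedList,
    prl_b: RankedList,
    k: int = 250,
    combiner: Callable[[float, float], float] = default_distance_combiner,
) -> DrugDistance:
    """Symmetric two-way GSEA distance between two drugs' PRLs."""
    if prl_a.universe != prl_b.universe:
        raise ValidationError("drug distance requires a common universe")
    sig_a = make_optimal_signature(prl_a, k)
    sig_b = make_optimal_signature(prl_b, k)
    cs_ab = connectivity_score(sig_a, prl_b).cs
    cs_ba = connectivity_score(sig_b, prl_a).cs
    return DrugDistance(combiner(cs_ab, cs_ba), cs_ab, cs_ba)


def distance_matrix(
    prls: Mapping[str, RankedList],
    k: int = 250,
    combiner: Callable[[float, float], float] = default_distance_combiner,
) -> pd.DataFrame:
    """Square symmetric matrix of pairwise drug distances (zero diagonal)."""
    ids = list(prls)
    n = len(ids)
    mat = np.zeros((n, n), dtype=float)
    sigs = {d: make_optimal_signature(prls[d], k) for d in ids}
    for i, a in enumerate(ids):
        for j in range(i + 1, n):
            b = ids[j]
            cs_ab = connectivity_score(sigs[a], prls[b]).cs
            cs_ba = connectivity_score(sigs[b], prls[a]).cs
            mat[i, j] = mat[j, i] = combiner(cs_ab, cs_ba)
    return pd.DataFrame(mat, index=ids, columns=ids)
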