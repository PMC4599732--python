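"""Aggregate per-treatment ranked lists into a Prototype Ranked List (PRL).

One drug in a connectivity-map compendium is typically profiled several
times (different cell lines, doses, batches).  The PRL is a consensus
permutation that keeps what is reproducible across treatments and dilutes
batch- and cell-line-specific effects.

Two merge modes are provided:

``hierarchical``
    Repeatedly merge the two most similar lists (smallest Spearman footrule
    distance) by Borda average rank, re-ranking after each merge, until one
    list remains.  Similar lists are combined first so that an outlier
    treatment cannot dominate early.
``borda``
    Single-pass Borda: average the rank of each gene over all lists.

Both modes re-rank averaged ranks to a strict permutation, breaking ties
lexicographically by gene id, so the result is order-of-input invariant and
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ranked_lists import GeneUniverse, RankedList, ValidationError


@dataclass(frozen=True)
class TreatmentSet:
    """All per-treatment ranked lists available for one drug."""

    drug_id: str
    lists: tuple[RankedList, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.lists:
            raise ValidationError(f"treatment set for {self.drug_id!r} is empty")
        universe = self.lists[0].universe
        for rl in self.lists[1:]:
            if rl.universe is not universe and rl.universe != universe:
                raise ValidationError(
                    f"treatment set for {self.drug_id!r} mixes universes"
                )
        labels = self.labels or tuple(rl.id for rl in self.lists)
        if len(labels) != len(self.lists):
            raise ValidationError("one label per treatment list required")
        if len(set(labels)) != len(labels):
            raise ValidationError(f"treatment labels for {self.drug_id!r} are not unique")
        object.__setattr__(self, "labels", labels)

    @property
    def universe(self) -> GeneUniverse:
        return self.lists[0].universe


def spearman_footrule(a: RankedList, b: RankedList) -> int:
    """Sum of absolute rank differences; 0 iff the two orders are identical."""
    if a.universe != b.universe:
        raise ValidationError("footrule distance requires a common universe")
    return int(np.abs(a.rank_vector - b.rank_vector).sum())


def _rerank(avg_ranks: np.ndarray, universe: GeneUniverse) -> np.ndarray:
    """Convert averaged ranks to a strict 1..N rank vector (lexicographic ties)."""
    genes = np.asarray(universe.genes, dtype=object)
    order = np.lexsort((genes, avg_ranks))  # ascending avg rank, then gene id
    ranks = np.empty(universe.n, dtype=np.int64)
    ranks[order] = np.arange(1, universe.n + 1)
    return ranks


def _ranks_to_list(drug_id: str, ranks: np.ndarray, universe: GeneUniverse) -> RankedList:
    genes = np.asarray(universe.genes, dtype=object)
    order = np.empty(universe.n, dtype=object)
    order[ranks - 1] = genes
    return RankedList(drug_id, universe, tuple(order))


def merge_ranked_lists(ts: TreatmentSet, mode: str = "hierarchical") -> RankedList:
    """Merge a drug's treatment lists into its PRL."""
    if mode not in ("hierarchical", "borda"):
        raise ValidationError(f"unknown merge mode {mode!r}")
    universe = ts.universe
    if len(ts.lists) == 1:
        return RankedList(ts.drug_id, universe, ts.lists[0].order)

    if mode == "borda":
        avg = np.mean([rl.rank_vector for rl in ts.lists], axis=0)
        return _ranks_to_list(ts.drug_id, _rerank(avg, universe), universe)

    # hierarchical: label -> current rank vector; labels keep pair selection
    # deterministic regardless of input order
    items: dict[tuple[str, ...], np.ndarray] = {
        (label,): rl.rank_vector.astype(np.int64)
        for label, rl in zip(ts.labels, ts.lists)
    }
    while len(items) > 1:
        keys = sorted(items)
        best: tuple[tuple[str, ...], tuple[str, ...]] | None = None
        best_d = None
        for i, ka in enumerate(keys):
            for kb in keys[i + 1:]:
                d = int(np.abs(items[ka] - items[kb]).sum())
                if best_d is None or d < best_d:
                    best_d, best = d, (ka, kb)
        assert best is not None
        ka, kb = best
        avg = (items[ka] + items[kb]) / 2.0
        merged = _rerank(avg, universe)
        del items[ka], items[kb]
        items[tuple(sorted(ka + kb))] = merged
    (ranks,) = items.values()
    return _ranks_to_list(ts.drug_id, ranks, universe)
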