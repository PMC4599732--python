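"""Core containers for connectivity mapping: gene universes, ranked lists, signatures.

A :class:`RankedList` is a strict permutation of a fixed :class:`GeneUniverse`,
with rank 1 the most up-regulated gene.  It represents either a drug's
Prototype Ranked List (PRL) — the consensus transcriptional response to that
drug across treatments — or a cell line's basal-expression ranked list (CLR).
A :class:`GeneSignature` is a pair of disjoint gene sets (up- and
down-regulated) used as a two-sided query against ranked lists.

Identifiers are case-sensitive and matched exactly (probe-set ids are
case-sensitive artifacts).  Ties, wherever scores are converted to ranks, are
broken lexicographically by gene id so that every list is a strict permutation.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True)
class GeneUniverse:
    """An ordered set of unique gene (or probe-set) identifiers."""

    genes: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        if len(self.genes) < 4:
            raise ValidationError(f"universe needs >= 4 genes, got {len(self.genes)}")
        index: dict[str, int] = {}
        for i, g in enumerate(self.genes):
            if not isinstance(g, str) or not g:
                raise ValidationError(f"gene identifier at position {i} is empty or not a string")
            if g in index:
                raise ValidationError(f"duplicate gene in universe: {g!r}")
            index[g] = i
        object.__setattr__(self, "_index", index)

    @classmethod
    def from_iterable(cls, genes: Iterable[str]) -> "GeneUniverse":
        return cls(tuple(genes))

    @property
    def n(self) -> int:
        return len(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __contains__(self, gene: object) -> bool:
        return gene in self._index

    def index_of(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise ValidationError(f"gene not in universe: {gene!r}") from None


@dataclass(frozen=True)
class RankedList:
    """A strict permutation of the universe; ``rank(g)`` is 1-based.

    Rank 1 holds the most up-regulated gene, rank N the most down-regulated.
    """

    id: str
    universe: GeneUniverse
    order: tuple[str, ...]
    # rank (1-based) of each gene, aligned with universe.genes
    _ranks: np.ndarray = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        n = self.universe.n
        ranks = np.zeros(n, dtype=np.int64)
        seen = 0
        for pos, g in enumerate(self.order, start=1):
            i = self.universe.index_of(g)
            if ranks[i]:
                raise ValidationError(f"duplicate gene in ranked list {self.id!r}: {g!r}")
            ranks[i] = pos
            seen += 1
        if seen != n:
            raise ValidationError(
                f"ranked list {self.id!r} is missing {n - seen} universe gene(s)"
            )
        ranks.setflags(write=False)
        object.__setattr__(self, "_ranks", ranks)

    @property
    def n(self) -> int:
        return self.universe.n

    def rank(self, gene: str) -> int:
        return int(self._ranks[self.universe.index_of(gene)])

    def percentile(self, gene: str) -> float:
        """rank/N — in (0, 1]; small means toward the up-regulated top."""
        return self.rank(gene) / self.n

    def ranks_of(self, genes: Iterable[str]) -> np.ndarray:
        """1-based ranks of the given genes, in input order."""
        idx = [self.universe.index_of(g) for g in genes]
        return self._ranks[idx].copy()

    @property
    def rank_vector(self) -> np.ndarray:
        """Read-only array of 1-based ranks aligned with ``universe.genes``."""
        return self._ranks

    def reversed(self, new_id: str | None = None) -> "RankedList":
        return RankedList(new_id or f"{self.id}_reversed", self.universe, self.order[::-1])

    @classmethod
    def from_scores(
        cls, id: str, universe: GeneUniverse, scores: Mapping[str, float]
    ) -> "RankedList":
        """Rank genes by descending score; ties broken lexicographically."""
        missing = [g for g in universe if g not in scores]
        if missing:
            raise ValidationError(
                f"scores for {id!r} missing {len(missing)} universe gene(s)"
            )
        order = sorted(universe, key=lambda g: (-float(scores[g]), g))
        return cls(id, universe, tuple(order))

    @classmethod
    def from_score_vector(
        cls, id: str, universe: GeneUniverse, scores: np.ndarray
    ) -> "RankedList":
        """Scores aligned with ``universe.genes``; descending, lexicographic ties."""
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (universe.n,):
            raise ValidationError("score vector length does not match universe size")
        genes = np.asarray(universe.genes, dtype=object)
        idx = np.lexsort((genes, -scores))
        return cls(id, universe, tuple(genes[idx]))


@dataclass(frozen=True)
class GeneSignature:
    """Two disjoint gene sets: U (up-regulated) and D (down-regulated)."""

    name: str
    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "up", frozenset(self.up))
        object.__setattr__(self, "down", frozenset(self.down))
        overlap = self.up & self.down
        if overlap:
            raise ValidationError(
                f"signature {self.name!r}: genes in both U and D: {sorted(overlap)[:5]}"
            )

    def validate_for_query(self, universe: GeneUniverse) -> None:
        if not self.up or not self.down:
            raise ValidationError(
                f"signature {self.name!r} needs nonempty U and D to query "
                f"(|U|={len(self.up)}, |D|={len(self.down)})"
            )
        for side, genes in (("U", self.up), ("D", self.down)):
            out = [g for g in genes if g not in universe]
            if out:
                raise ValidationError(
                    f"signature {self.name!r} {side}-side has {len(out)} gene(s) "
                    f"outside the universe, e.g. {sorted(out)[:3]}"
                )


@dataclass(frozen=True)
class DrugAnnotation:
    """Community membership and mode-of-action labels of one drug."""

    drug_id: str
    community_id: int
    moa_labels: frozenset[str] = frozenset()


def percentile_of(prl: RankedList, gene: str) -> float:
    """Percentile of a gene along a ranked list: rank/N, 1-based.

    Values near 0 mean the gene sits at the up-regulated top; "above the
    70th percentile" (rank/N > 0.70) means toward the down-regulated tail.
    """
    return prl.percentile(gene)


def make_optimal_signature(prl: RankedList, k: int = 250) -> GeneSignature:
    """Top-k and bottom-k genes of a PRL as a two-sided query signature."""
    n = prl.n
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if 2 * k > n:
        raise ValidationError(
            f"2k = {2 * k} exceeds universe size {n}; maximum admissible k is {n // 2}"
        )
    return GeneSignature(
        name=f"{prl.id}_optimal_k{k}",
        up=frozenset(prl.order[:k]),
        down=frozenset(prl.order[n - k:]),
    )


# ---------------------------------------------------------------------------
# I/O: ranked lists (TSV), signatures (GMT), annotations (TSV)
# ---------------------------------------------------------------------------

def load_ranked_list(path: str | Path, universe: GeneUniverse, id: str | None = None) -> RankedList:
    """Read a ranked list from a one-gene-per-line or ``rank<TAB>gene`` TSV."""
    path = Path(path)
    entries: list[tuple[int, str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                entries.append((lineno, parts[0]))
            elif len(parts) == 2:
                try:
                    rank = int(parts[0])
                except ValueError:
                    raise ValidationError(
                        f"{path}:{lineno}: first column is not an integer rank: {parts[0]!r}"
                    ) from None
                entries.append((rank, parts[1]))
            else:
                raise ValidationError(f"{path}:{lineno}: expected 1 or 2 columns, got {len(parts)}")
    entries.sort(key=lambda e: e[0])
    order = tuple(g for _, g in entries)
    seen: set[str] = set()
    for g in order:
        if g in seen:
            raise ValidationError(f"{path}: duplicate gene {g!r}")
        seen.add(g)
    return RankedList(id or path.stem, universe, order)


def write_ranked_list(prl: RankedList, path: str | Path, two_column: bool = False) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rank, g in enumerate(prl.order, start=1):
            fh.write(f"{rank}\t{g}\n" if two_column else f"{g}\n")


def load_gmt(path: str | Path, universe: GeneUniverse | None = None) -> dict[str, GeneSignature]:
    """Read signatures from GMT: rows ``<name>_UP`` / ``<name>_DOWN`` are paired.

    A row without the ``_UP``/``_DOWN`` suffix becomes a one-sided signature
    with an empty down set (usable for plain enrichment, not for querying).
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    for raw in path.read_text().splitlines():
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) < 3:
            raise ValidationError(f"{path}: GMT rows need name, description, >=1 gene")
        sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    out: dict[str, GeneSignature] = {}
    consumed: set[str] = set()
    for row_name in sets:
        if row_name in consumed:
            continue
        if row_name.endswith("_UP"):
            base = row_name[: -len("_UP")]
            down = sets.get(f"{base}_DOWN", frozenset())
            consumed.update({row_name, f"{base}_DOWN"})
            out[base] = GeneSignature(base, sets[row_name], down)
        elif row_name.endswith("_DOWN"):
            base = row_name[: -len("_DOWN")]
            if f"{base}_UP" in sets:
                continue  # handled from the _UP row
            consumed.add(row_name)
            out[base] = GeneSignature(base, frozenset(), sets[row_name])
        else:
            consumed.add(row_name)
            out[row_name] = GeneSignature(row_name, sets[row_name], frozenset())
    if universe is not None:
        for sig in out.values():
            for g in sig.up | sig.down:
                universe.index_of(g)
    return out


def write_gmt(signatures: Iterable[GeneSignature], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for sig in signatures:
            if sig.up:
                fh.write("\t".join([f"{sig.name}_UP", "up-regulated", *sorted(sig.up)]) + "\n")
            if sig.down:
                fh.write("\t".join([f"{sig.name}_DOWN", "down-regulated", *sorted(sig.down)]) + "\n")


def load_annotations(path: str | Path) -> dict[str, DrugAnnotation]:
    """Read ``drug_id<TAB>community_id<TAB>moa1;moa2`` (moa column optional)."""
    path = Path(path)
    out: dict[str, DrugAnnotation] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.split("\t")
        if len(parts) < 2:
            raise ValidationError(f"{path}:{lineno}: need at least drug_id and community_id")
        drug = parts[0]
        if drug in out:
            raise ValidationError(f"{path}:{lineno}: duplicate drug {drug!r}")
        try:
            community = int(parts[1])
        except ValueError:
            raise ValidationError(
                f"{path}:{lineno}: community_id is not an integer: {parts[1]!r}"
            ) from None
        moas = frozenset(m for m in parts[2].split(";") if m) if len(parts) > 2 else frozenset()
        out[drug] = DrugAnnotation(drug, community, moas)
    return out


def write_annotations(annotations: Mapping[str, DrugAnnotation], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for drug in sorted(annotations):
            a = annotations[drug]
            fh.write(f"{a.drug_id}\t{a.community_id}\t{';'.join(sorted(a.moa_labels))}\n")
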