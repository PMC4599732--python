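"""Supervised refinement of a seed signature against confounder drug classes.

A seed drug's optimal signature usually mixes its primary mode of action
with secondary effects shared with other drug classes (e.g. a microtubule
stabiliser's signature is entangled with a generic mitotic-arrest response
it shares with proteasome inhibitors).  Refinement splits the seed
signature by agreement with the confounder class PRLs:

* a seed up-gene that falls *above* a high percentile (default 70th) in the
  PRLs of at least ``min_support`` confounders behaves inconsistently — the
  confounders push it down — so it is assigned to the *inconsistent*
  signature, which isolates the seed-specific (primary) component;
* everything else stays in the *consistent* signature (the shared component).
  Down-genes are treated mirror-wise with the low percentile (default 30th).

A later iteration can build a *contrast* signature: genes extreme in the
seed PRL and oppositely extreme in an opposing class's PRLs (default
quantile 25%/75%), e.g. a microtubule-stabilisation signature contrasting
the seed with destabilising benzimidazoles.

Querying the compendium with several refined signatures keeps the drugs
positively connected at fdr below threshold to *every* signature and ranks
them by the average of the per-signature normalised connectivity scores.
The sign of the contrast-signature NCS then classifies each kept drug as
acting like the seed (positive) or opposing it (negative).
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gsea_engine import connectivity_score
from .null_model import NullDistribution, bh_fdr, build_null, empirical_pvalue, normalize_cs
from .ranked_lists import (
    GeneSignature,
    RankedList,
    ValidationError,
    make_optimal_signature,
    percentile_of,
)


@dataclass(frozen=True)
class RefinementConfig:
    hi_percentile: float = 0.70
    lo_percentile: float = 0.30
    min_support: int = 2
    contrast_quantile: float = 0.25
    contrast_support: int | None = None  # None = all opposing drugs
    fdr_threshold: float = 0.05
    signature_k: int = 250
    n_perm: int = 10_000
    refilter_on_contrast: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.lo_percentile < self.hi_percentile < 1:
            raise ValidationError("need 0 < lo_percentile < hi_percentile < 1")
        if self.min_support < 1:
            raise ValidationError("min_support must be >= 1")
        if not 0 < self.contrast_quantile < 0.5:
            raise ValidationError("contrast_quantile must be in (0, 0.5)")
        if not 0 < self.fdr_threshold < 1:
            raise ValidationError("fdr_threshold must be in (0, 1)")


def average_ncs(values: Sequence[float]) -> float:
    """The score combiner: arithmetic mean of per-signature NCS values."""
    return float(np.mean(np.asarray(values, dtype=float)))


def split_signature(
    seed_sig: GeneSignature,
    confounder_prls: Sequence[RankedList],
    cfg: RefinementConfig = RefinementConfig(),
) -> tuple[GeneSignature, GeneSignature]:
    """Partition a seed signature into (consistent, inconsistent) parts.

    ``inconsistent.up`` collects seed up-genes above ``hi_percentile`` in at
    least ``min_support`` confounder PRLs (strictly above: the confounders
    rank them toward the bottom); ``inconsistent.down`` mirrors with
    ``lo_percentile`` (within, i.e. <=).  The two parts are disjoint and
    their union is the seed signature, side-wise.
    """
    if not confounder_prls:
        raise ValidationError("need at least one confounder PRL")
    if cfg.min_support > len(confounder_prls):
        raise ValidationError(
            f"min_support={cfg.min_support} exceeds the {len(confounder_prls)} confounder(s)"
        )
    inc_up = frozenset(
        g
        for g in seed_sig.up
        if sum(percentile_of(prl, g) > cfg.hi_percentile for prl in confounder_prls)
        >= cfg.min_support
    )
    inc_down = frozenset(
        g
        for g in seed_sig.down
        if sum(percentile_of(prl, g) <= cfg.lo_percentile for prl in confounder_prls)
        >= cfg.min_support
    )
    inconsistent = GeneSignature(f"{seed_sig.name}_inconsistent", inc_up, inc_down)
    consistent = GeneSignature(
        f"{seed_sig.name}_consistent", seed_sig.up - inc_up, seed_sig.down - inc_down
    )
    return consistent, inconsistent


def contrast_signature(
    seed_prl: RankedList,
    opposing_prls: Sequence[RankedList],
    cfg: RefinementConfig = RefinementConfig(),
    name: str | None = None,
) -> GeneSignature:
    """Genes extreme in the seed PRL and oppositely extreme in opposing PRLs.

    U: within the ``contrast_quantile`` of the seed PRL and over the
    complementary quantile in at least ``contrast_support`` opposing PRLs
    (default: all of them); D mirrored.
    """
    if not opposing_prls:
        raise ValidationError("need at least one opposing PRL")
    support = cfg.contrast_support if cfg.contrast_support is not None else len(opposing_prls)
    if support > len(opposing_prls):
        raise ValidationError(
            f"contrast_support={support} exceeds the {len(opposing_prls)} opposing drug(s)"
        )
    q = cfg.contrast_quantile
    up, down = [], []
    for g in seed_prl.universe:
        p_seed = percentile_of(seed_prl, g)
        if p_seed <= q:
            if sum(percentile_of(prl, g) > 1 - q for prl in opposing_prls) >= support:
                up.append(g)
        elif p_seed > 1 - q:
            if sum(percentile_of(prl, g) <= q for prl in opposing_prls) >= support:
                down.append(g)
    return GeneSignature(
        name or f"{seed_prl.id}_contrast_q{q:g}", frozenset(up), frozenset(down)
    )


@dataclass(frozen=True)
class RefinedQueryResult:
    """Scores of a multi-signature query over a drug compendium.

    ``table`` has one row per queried drug with, per signature s, columns
    ``cs_<s>``, ``ncs_<s>``, ``p_<s>``, ``fdr_<s>``, plus ``avg_ncs`` and
    ``kept``; rows are sorted descending by ``avg_ncs``.
    """

    table: pd.DataFrame
    signatures: tuple[GeneSignature, ...]
    kept: tuple[str, ...]


def combined_query(
    sigs: Sequence[GeneSignature],
    prls: Mapping[str, RankedList],
    cfg: RefinementConfig = RefinementConfig(),
    seed: int = 0,
    exclude: Sequence[str] = (),
    nulls: Mapping[str, NullDistribution] | None = None,
) -> RefinedQueryResult:
    """Query a compendium with several signatures simultaneously.

    Drugs are kept iff they show a positive connection (cs > 0) with BH fdr
    below ``cfg.fdr_threshold`` for *every* signature; the BH family is the
    full set of queried drugs, per signature.  Pre-built nulls may be passed
    (keyed by signature name); missing ones are built with ``cfg.n_perm``
    permutations and deterministic per-signature seeds.
    """
    if not sigs:
        raise ValidationError("need at least one query signature")
    drug_ids = [d for d in prls if d not in set(exclude)]
    if not drug_ids:
        raise ValidationError("no drugs left to query after exclusions")
    universe = prls[drug_ids[0]].universe
    table = pd.DataFrame(index=pd.Index(drug_ids, name="drug"))
    kept_mask = np.ones(len(drug_ids), dtype=bool)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(sigs))]
    for sig, sig_seed in zip(sigs, child_seeds):
        sig.validate_for_query(universe)
        null = (nulls or {}).get(sig.name)
        if null is None:
            null = build_null(sig, universe, n_perm=cfg.n_perm, seed=sig_seed)
        cs = np.array([connectivity_score(sig, prls[d]).cs for d in drug_ids])
        ncs = normalize_cs(cs, null.mixture)
        pvals = np.array(
            [empirical_pvalue(c, null.mixture, "positive") for c in cs]
        )
        fdr = bh_fdr(pvals)
        table[f"cs_{sig.name}"] = cs
        table[f"ncs_{sig.name}"] = ncs
        table[f"p_{sig.name}"] = pvals
        table[f"fdr_{sig.name}"] = fdr
        kept_mask &= (cs > 0) & (fdr < cfg.fdr_threshold)
    ncs_cols = [c for c in table.columns if c.startswith("ncs_")]
    table["avg_ncs"] = table[ncs_cols].mean(axis=1)
    table["kept"] = kept_mask
    table = table.sort_values(["avg_ncs", "drug"], ascending=[False, True], kind="stable")
    kept = tuple(table.index[table["kept"]])
    return RefinedQueryResult(table=table, signatures=tuple(sigs), kept=kept)


def classify_by_sign(ncs_contrast: float) -> str:
    """Sign-based call against the contrast signature.

    Positive: same directional effect as the seed (e.g. stabiliser-like);
    negative: opposing effect (destabiliser-like); exactly 0: neutral.
    """
    if ncs_contrast > 0:
        return "stabiliser"
    if ncs_contrast < 0:
        return "destabiliser"
    return "neutral"


@dataclass(frozen=True)
class IterationSpec:
    """One supervised refinement step: which drugs play confounder/opposer.

    ``kind='split'`` partitions the current seed signature against the named
    confounders (the first iteration); ``kind='contrast'`` builds a contrast
    signature against the named opposing class (later iterations).
    """

    kind: str
    drugs: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("split", "contrast"):
            raise ValidationError(f"iteration kind must be 'split' or 'contrast', got {self.kind!r}")
        if not self.drugs:
            raise ValidationError("iteration needs at least one named drug")
        object.__setattr__(self, "drugs", tuple(self.drugs))


@dataclass(frozen=True)
class IterationRecord:
    spec: IterationSpec | None
    signatures: tuple[GeneSignature, ...]
    result: RefinedQueryResult


@dataclass(frozen=True)
class RefinementRun:
    seed_id: str
    config: RefinementConfig
    iterations: tuple[IterationRecord, ...] = field(default=())

    @property
    def final(self) -> RefinedQueryResult:
        return self.iterations[-1].result

    def audit_json(self) -> str:
        """A machine-readable trail of every iteration's signatures and scores."""
        payload = []
        for i, rec in enumerate(self.iterations):
            payload.append(
                {
                    "iteration": i,
                    "kind": rec.spec.kind if rec.spec else "seed-query",
                    "named_drugs": list(rec.spec.drugs) if rec.spec else [],
                    "signatures": [
                        {"name": s.name, "up": sorted(s.up), "down": sorted(s.down)}
                        for s in rec.signatures
                    ],
                    "kept": list(rec.result.kept),
                    "table": json.loads(
                        rec.result.table.reset_index().to_json(orient="records", double_precision=15)
                    ),
                }
            )
        return json.dumps({"seed": self.seed_id, "iterations": payload}, indent=2)


def _lookup_prls(compendium: Mapping[str, RankedList], drugs: Sequence[str]) -> list[RankedList]:
    missing = [d for d in drugs if d not in compendium]
    if missing:
        raise ValidationError(f"named drug(s) absent from the compendium: {missing}")
    return [compendium[d] for d in drugs]


def run_iterations(
    seed_id: str,
    compendium: Mapping[str, RankedList],
    iterations: Sequence[IterationSpec],
    cfg: RefinementConfig = RefinementConfig(),
    seed: int = 0,
) -> RefinementRun:
    """Execute the iterative network-guided refinement pipeline.

    Iteration structure: a ``split`` iteration replaces the current query
    signatures with the (consistent, inconsistent) partition and re-queries
    the compendium with both, filtering at the fdr threshold; a ``contrast``
    iteration appends a contrast signature and re-scores the kept drugs
    (without re-filtering unless ``cfg.refilter_on_contrast``), adding a
    sign-based classification column.  With no iterations the run reduces to
    the plain optimal-seed-signature query.

    The seed drug and every drug named in an iteration are excluded from the
    ranked output: they are inputs to the supervised step, not discoveries.
    """
    if seed_id not in compendium:
        raise ValidationError(f"seed drug {seed_id!r} absent from the compendium")
    seed_prl = compendium[seed_id]
    seed_sig = make_optimal_signature(seed_prl, cfg.signature_k)
    named: set[str] = {seed_id}
    for spec in iterations:
        named.update(spec.drugs)

    records: list[IterationRecord] = []
    if not iterations:
        result = combined_query([seed_sig], compendium, cfg, seed=seed, exclude=[seed_id])
        return RefinementRun(seed_id, cfg, (IterationRecord(None, (seed_sig,), result),))

    query_sigs: list[GeneSignature] = [seed_sig]
    current: RefinedQueryResult | None = None
    for it_index, spec in enumerate(iterations):
        prls = _lookup_prls(compendium, spec.drugs)
        if spec.kind == "split":
            base = query_sigs[0] if current is None else seed_sig
            consistent, inconsistent = split_signature(base, prls, cfg)
            for side_name, side_sig in (("consistent", consistent), ("inconsistent", inconsistent)):
                if not side_sig.up or not side_sig.down:
                    raise ValidationError(
                        f"{side_name} signature has an empty side after splitting; "
                        "relax the percentile thresholds or min_support"
                    )
            query_sigs = [consistent, inconsistent]
            current = combined_query(
                query_sigs, compendium, cfg, seed=seed, exclude=sorted(named)
            )
            records.append(IterationRecord(spec, tuple(query_sigs), current))
        else:  # contrast
            if current is None:
                raise ValidationError("a 'contrast' iteration requires a preceding 'split'")
            c_sig = contrast_signature(
                seed_prl, prls, cfg, name=f"{seed_id}_contrast_it{it_index + 1}"
            )
            if not c_sig.up or not c_sig.down:
                raise ValidationError(
                    "contrast signature has an empty side; relax contrast_quantile"
                )
            query_sigs = list(query_sigs) + [c_sig]
            scope = dict(compendium) if cfg.refilter_on_contrast else {
                d: compendium[d] for d in current.kept
            }
            if not scope:
                raise ValidationError("no drugs were kept by the previous iteration")
            rescored = combined_query(
                query_sigs, scope, cfg, seed=seed, exclude=sorted(named & set(scope))
            )
            table = rescored.table.copy()
            if not cfg.refilter_on_contrast:
                # kept status is inherited from the filtering iteration
                table["kept"] = True
            table["classification"] = [
                classify_by_sign(v) for v in table[f"ncs_{c_sig.name}"]
            ]
            current = RefinedQueryResult(
                table=table,
                signatures=tuple(query_sigs),
                kept=tuple(table.index[table["kept"]]),
            )
            records.append(IterationRecord(spec, (c_sig,), current))
    return RefinementRun(seed_id, cfg, tuple(records))
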