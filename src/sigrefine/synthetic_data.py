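"""Desk-scale simulators with known ground truth for the whole pipeline.

Two generators emulate the statistical structure of a connectivity-map
style study:

* :func:`simulate_compendium` builds per-treatment ranked lists for a drug
  compendium with planted mode-of-action (MoA) classes and, optionally,
  secondary effects shared between classes.  Each treatment draws a latent
  differential-expression score per gene (Gaussian noise, default sd 1)
  and adds the drug's class effects (+effect on the class's up-genes,
  -effect on its down-genes); ranking the latent scores yields the list.
  Signal injection through a latent score mimics how real ranked lists
  arise from differential-expression statistics and makes effect strength
  directly interpretable in noise-sd units.

* :func:`simulate_cellline_panel` builds a basal-expression panel in which
  a chosen subset of "reverted" cell lines under-express a target
  signature's up-genes and over-express its down-genes, and are more
  sensitive (lower log IC50 / AUC) to a hypothetical drug.

Default desk-scale sizes are 60 drugs x 2,000 genes x 3 treatments and 100
cell lines, so the full pipeline runs in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prl_builder import TreatmentSet
from .ranked_lists import DrugAnnotation, GeneSignature, GeneUniverse, RankedList, ValidationError

DEFAULT_N_DRUGS = 60
DEFAULT_N_GENES = 2_000
DEFAULT_N_TREATMENTS = 3
DEFAULT_NOISE_SD = 1.0
DEFAULT_EFFECT = 5.0
DEFAULT_N_LINES = 100


def gene_ids(n_genes: int) -> tuple[str, ...]:
    return tuple(f"g{i:04d}" for i in range(n_genes))


@dataclass(frozen=True)
class MoaClass:
    """A planted drug class: its members share up/down gene effects."""

    label: str
    n_drugs: int
    up_genes: tuple[str, ...]
    down_genes: tuple[str, ...]
    effect: float = DEFAULT_EFFECT


@dataclass(frozen=True)
class SecondaryEffect:
    """A gene-level effect shared by every drug of the listed classes."""

    labels: frozenset[str]
    up_genes: tuple[str, ...]
    down_genes: tuple[str, ...]
    effect: float = DEFAULT_EFFECT


@dataclass(frozen=True)
class CompendiumSpec:
    n_drugs: int = DEFAULT_N_DRUGS
    n_genes: int = DEFAULT_N_GENES
    n_treatments: int = DEFAULT_N_TREATMENTS
    noise_sd: float = DEFAULT_NOISE_SD
    classes: tuple[MoaClass, ...] = ()
    secondary: tuple[SecondaryEffect, ...] = ()

    def __post_init__(self) -> None:
        if sum(c.n_drugs for c in self.classes) > self.n_drugs:
            raise ValidationError("class sizes exceed n_drugs")
        labels = [c.label for c in self.classes]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate class labels")
        universe = set(gene_ids(self.n_genes))
        for c in self.classes:
            if set(c.up_genes) & set(c.down_genes):
                raise ValidationError(f"class {c.label!r}: up/down gene sets overlap")
            if not set(c.up_genes) <= universe or not set(c.down_genes) <= universe:
                raise ValidationError(f"class {c.label!r}: genes outside the universe")
        known = set(labels)
        for s in self.secondary:
            if not s.labels <= known:
                raise ValidationError(f"secondary effect names unknown class(es): {s.labels - known}")
            if not set(s.up_genes) | set(s.down_genes) <= universe:
                raise ValidationError("secondary-effect genes outside the universe")


@dataclass(frozen=True)
class SimulationTruth:
    """Everything needed to score pipeline output against the planted signal."""

    primary_moa: dict[str, str | None]
    secondary_moa: dict[str, tuple[str, ...]]
    annotations: dict[str, DrugAnnotation]
    gene_driver: dict[str, str] = field(default_factory=dict)
    reverted_lines: tuple[str, ...] = ()
    reversion_strength: float = 0.0
    ic50_shift: float = 0.0

    def drugs_with_moa(self, label: str) -> list[str]:
        return sorted(d for d, m in self.primary_moa.items() if m == label)


def simulate_compendium(
    spec: CompendiumSpec = CompendiumSpec(),
    seed: int = 0,
) -> tuple[dict[str, TreatmentSet], SimulationTruth]:
    """Generate per-drug treatment sets with planted MoA structure."""
    rng = np.random.default_rng(seed)
    universe = GeneUniverse(gene_ids(spec.n_genes))
    gidx = {g: i for i, g in enumerate(universe.genes)}

    drug_class: dict[str, MoaClass | None] = {}
    for c in spec.classes:
        for j in range(c.n_drugs):
            drug_class[f"{c.label}_{j:02d}"] = c
    n_unlabelled = spec.n_drugs - len(drug_class)
    for j in range(n_unlabelled):
        drug_class[f"cmpd_{j:03d}"] = None

    # per-class additive effect vectors (primary + applicable secondary)
    class_effect: dict[str, np.ndarray] = {}
    for c in spec.classes:
        eff = np.zeros(spec.n_genes)
        eff[[gidx[g] for g in c.up_genes]] += c.effect
        eff[[gidx[g] for g in c.down_genes]] -= c.effect
        for s in spec.secondary:
            if c.label in s.labels:
                eff[[gidx[g] for g in s.up_genes]] += s.effect
                eff[[gidx[g] for g in s.down_genes]] -= s.effect
        class_effect[c.label] = eff

    gene_driver: dict[str, str] = {}
    for c in spec.classes:
        for g in c.up_genes + c.down_genes:
            gene_driver[g] = c.label
    for s in spec.secondary:
        tag = "+".join(sorted(s.labels))
        for g in s.up_genes + s.down_genes:
            gene_driver[g] = f"secondary:{tag}"

    compendium: dict[str, TreatmentSet] = {}
    community_of = {c.label: i + 1 for i, c in enumerate(spec.classes)}
    annotations: dict[str, DrugAnnotation] = {}
    primary: dict[str, str | None] = {}
    secondary_of: dict[str, tuple[str, ...]] = {}
    for drug in sorted(drug_class):
        c = drug_class[drug]
        eff = class_effect[c.label] if c is not None else 0.0
        lists = []
        for t in range(spec.n_treatments):
            latent = rng.normal(0.0, spec.noise_sd, spec.n_genes) + eff
            lists.append(
                RankedList.from_score_vector(f"{drug}__t{t}", universe, latent)
            )
        compendium[drug] = TreatmentSet(drug, tuple(lists))
        primary[drug] = c.label if c is not None else None
        secondary_of[drug] = tuple(
            sorted(
                "+".join(sorted(s.labels))
                for s in spec.secondary
                if c is not None and c.label in s.labels
            )
        )
        annotations[drug] = DrugAnnotation(
            drug,
            community_of[c.label] if c is not None else 0,
            frozenset([c.label]) if c is not None else frozenset(),
        )
    truth = SimulationTruth(
        primary_moa=primary,
        secondary_moa=secondary_of,
        annotations=annotations,
        gene_driver=gene_driver,
    )
    return compendium, truth


def confounded_compendium_spec(
    n_drugs: int = DEFAULT_N_DRUGS,
    n_genes: int = DEFAULT_N_GENES,
    n_per_class: int = 10,
    block: int = 125,
    effect: float = DEFAULT_EFFECT,
    noise_sd: float = DEFAULT_NOISE_SD,
    n_treatments: int = DEFAULT_N_TREATMENTS,
) -> CompendiumSpec:
    """The planted-confounder study design.

    Two classes of ``n_per_class`` drugs each: a primary class (the seed's,
    e.g. microtubule stabilisers) with its own up/down gene blocks, and a
    confounder class (e.g. proteasome inhibitors) with different primary
    blocks; both share a secondary up/down effect (e.g. mitotic arrest) of
    the same strength.  With ``block`` = 125 and a top/bottom-250 optimal
    signature, the shared secondary effect contributes half of the seed
    signature, which refinement against the confounders must strip out.
    The remaining drugs are unlabelled noise compounds.
    """
    genes = gene_ids(n_genes)
    if 6 * block > n_genes:
        raise ValidationError("six gene blocks do not fit in the universe")
    a_up, a_dn = genes[0:block], genes[block:2 * block]
    sh_up, sh_dn = genes[2 * block:3 * block], genes[3 * block:4 * block]
    c_up, c_dn = genes[4 * block:5 * block], genes[5 * block:6 * block]
    primary = MoaClass("stabiliser", n_per_class, a_up, a_dn, effect)
    confounder = MoaClass("proteasome_inh", n_per_class, c_up, c_dn, effect)
    shared = SecondaryEffect(
        frozenset({"stabiliser", "proteasome_inh"}), sh_up, sh_dn, effect
    )
    return CompendiumSpec(
        n_drugs=n_drugs,
        n_genes=n_genes,
        n_treatments=n_treatments,
        noise_sd=noise_sd,
        classes=(primary, confounder),
        secondary=(shared,),
    )


def default_panel_signature(n_genes: int = 1_000, size: int = 100) -> GeneSignature:
    """A target signature over the simulated panel universe: first ``size``
    genes up, last ``size`` down."""
    genes = gene_ids(n_genes)
    if 2 * size > n_genes:
        raise ValidationError("signature does not fit in the universe")
    return GeneSignature("planted_target", frozenset(genes[:size]), frozenset(genes[-size:]))


def simulate_cellline_panel(
    target_signature: GeneSignature,
    n_lines: int = DEFAULT_N_LINES,
    n_genes: int = 1_000,
    n_reverted: int = 10,
    reversion_strength: float = 2.0,
    ic50_shift: float = 2.0,
    noise_sd: float = 1.0,
    drug_id: str = "seed_drug",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Basal expression + drug response for a panel with planted reverted lines.

    Expression: x_{g,l} = mu_g + N(0, noise_sd) with gene baselines
    mu_g ~ N(0, 1); in reverted lines the signature's up-genes are shifted
    down by ``reversion_strength`` and its down-genes up by the same amount
    (in noise-sd units when noise_sd = 1).  Response: log IC50 ~ N(0,
    noise_sd), reduced by ``ic50_shift`` in reverted lines; AUC ~ N(0.85,
    0.05) reduced by 0.05 * ic50_shift (clipped to (0, 1)).
    """
    if n_reverted >= n_lines:
        raise ValidationError("n_reverted must be < n_lines")
    genes = gene_ids(n_genes)
    universe = set(genes)
    sig_genes = target_signature.up | target_signature.down
    if not sig_genes <= universe:
        raise ValidationError("target signature genes outside the panel universe")
    rng = np.random.default_rng(seed)
    lines = tuple(f"line_{i:03d}" for i in range(n_lines))
    reverted = lines[:n_reverted]
    gidx = {g: i for i, g in enumerate(genes)}
    mu = rng.normal(0.0, 1.0, n_genes)
    x = mu[:, None] + rng.normal(0.0, noise_sd, (n_genes, n_lines))
    up_idx = [gidx[g] for g in sorted(target_signature.up)]
    dn_idx = [gidx[g] for g in sorted(target_signature.down)]
    x[np.ix_(up_idx, range(n_reverted))] -= reversion_strength
    x[np.ix_(dn_idx, range(n_reverted))] += reversion_strength
    expr = pd.DataFrame(x, index=pd.Index(genes, name="gene"), columns=lines)

    log_ic50 = rng.normal(0.0, noise_sd, n_lines)
    log_ic50[:n_reverted] -= ic50_shift
    auc = rng.normal(0.85, 0.05, n_lines)
    auc[:n_reverted] -= 0.05 * ic50_shift
    auc = np.clip(auc, 1e-3, 1.0 - 1e-3)
    resp = pd.DataFrame(
        {
            "cell_line": lines,
            "drug": drug_id,
            "log_ic50": log_ic50,
            "auc": auc,
        }
    )
    truth = SimulationTruth(
        primary_moa={},
        secondary_moa={},
        annotations={},
        reverted_lines=reverted,
        reversion_strength=reversion_strength,
        ic50_shift=ic50_shift,
    )
    return expr, resp, truth
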