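"""Signature reversion against cell-line basal expression and drug response.

Basal expression of a cell-line panel is turned into one ranked list per
cell line (a CLR): per gene, the cross-panel distribution is smoothed with a
Gaussian kernel density estimate and each expression value is mapped to the
logit of its smoothed CDF,

    z_{g,l} = log( CDF_g(x_{g,l}) / (1 - CDF_g(x_{g,l})) ),

then genes are sorted by z within each cell line, descending.  Cell lines
whose CLR is significantly *negatively* connected to every refined
signature are predicted sensitive (signature reversion), and an unpaired
two-sample t-test compares their drug response (log IC50 or AUC) with the
rest of the panel.
"""

from __future__ import annotations

from collections.abc import Collection, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .gsea_engine import connectivity_score
from .null_model import NullDistribution, bh_fdr, build_null, empirical_pvalue, normalize_cs
from .ranked_lists import GeneSignature, GeneUniverse, RankedList, ValidationError

_CDF_EPS = 1e-6


def collapse_probesets(
    matrix: pd.DataFrame, probe_map: Mapping[str, Collection[str]]
) -> pd.DataFrame:
    """Collapse a probe-level matrix (probes x cell lines) to gene level.

    Probes mapping to multiple genes are discarded; multiple probes mapping
    to the same gene are averaged per cell line.
    """
    unmapped = [p for p in matrix.index if p not in probe_map]
    if unmapped:
        raise ValidationError(f"unmapped probe(s): {unmapped[:10]}")
    gene_of: dict[str, str] = {}
    for probe in matrix.index:
        genes = list(probe_map[probe])
        if len(genes) == 1:
            gene_of[probe] = genes[0]
    kept = matrix.loc[list(gene_of)]
    collapsed = kept.groupby([gene_of[p] for p in kept.index]).mean()
    collapsed.index.name = "gene"
    return collapsed


def _kde_cdf(values: np.ndarray, bandwidth: float) -> np.ndarray:
    """Smoothed CDF of each value under a Gaussian kernel mixture on the row."""
    return stats.norm.cdf((values[:, None] - values[None, :]) / bandwidth).mean(axis=1)


def expression_logit_scores(
    matrix: pd.DataFrame,
    eps: float = _CDF_EPS,
    on_constant: str = "error",
) -> pd.DataFrame:
    """Per-gene KDE-CDF logit scores of a gene x cell-line expression matrix.

    The kernel bandwidth follows Silverman's rule per gene row.  The CDF is
    clipped to [eps, 1 - eps] so z stays finite; within a gene z is strictly
    increasing in x.  Constant gene rows either raise (``on_constant='error'``)
    or are dropped (``'drop'``).
    """
    if on_constant not in ("error", "drop"):
        raise ValidationError("on_constant must be 'error' or 'drop'")
    if matrix.shape[1] < 2:
        raise ValidationError("need >= 2 cell lines for the KDE")
    if matrix.isna().any().any():
        raise ValidationError("expression matrix contains missing values")
    rows = {}
    for gene, row in matrix.iterrows():
        x = row.to_numpy(dtype=float)
        if np.ptp(x) == 0:
            if on_constant == "error":
                raise ValidationError(f"gene {gene!r} has constant expression across lines")
            continue
        kde = stats.gaussian_kde(x, bw_method="silverman")
        bw = float(np.sqrt(kde.covariance[0, 0]))
        cdf = np.clip(_kde_cdf(x, bw), eps, 1 - eps)
        rows[gene] = np.log(cdf / (1 - cdf))
    out = pd.DataFrame.from_dict(rows, orient="index", columns=matrix.columns)
    out.index.name = matrix.index.name
    return out


def build_clr(
    z: pd.DataFrame, universe: GeneUniverse | None = None
) -> dict[str, RankedList]:
    """One ranked list per cell line: genes by z descending, ties lexicographic."""
    if z.isna().any().any():
        raise ValidationError("z-score matrix contains missing values")
    genes = np.asarray(z.index, dtype=object)
    if universe is None:
        universe = GeneUniverse(tuple(sorted(z.index)))
    out: dict[str, RankedList] = {}
    for line in z.columns:
        col = z[line].to_numpy(dtype=float)
        order = np.lexsort((genes, -col))
        out[str(line)] = RankedList(str(line), universe, tuple(genes[order]))
    return out


def predict_sensitive(
    clrs: Mapping[str, RankedList],
    sigs: Sequence[GeneSignature],
    fdr_threshold: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
    nulls: Mapping[str, NullDistribution] | None = None,
) -> tuple[frozenset[str], pd.DataFrame]:
    """Cell lines significantly negatively connected to every signature.

    Per signature: connectivity of each CLR, lower-tail mixture p-value, BH
    across the panel; a line is selected iff cs < 0 and fdr < threshold for
    all signatures.  Returns the selected set and the per-line score table.
    """
    if not sigs:
        raise ValidationError("need at least one signature")
    lines = list(clrs)
    if not lines:
        raise ValidationError("empty cell-line panel")
    universe = clrs[lines[0]].universe
    for sig in sigs:
        missing = [g for g in sig.up | sig.down if g not in universe]
        if missing:
            frac = len(missing) / (len(sig.up) + len(sig.down))
            raise ValidationError(
                f"signature {sig.name!r}: {frac:.1%} of genes absent from the "
                f"expression universe, e.g. {sorted(missing)[:3]}"
            )
    table = pd.DataFrame(index=pd.Index(lines, name="cell_line"))
    selected_mask = np.ones(len(lines), dtype=bool)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(sigs))]
    for sig, sig_seed in zip(sigs, child_seeds):
        null = (nulls or {}).get(sig.name)
        if null is None:
            null = build_null(sig, universe, n_perm=n_perm, seed=sig_seed)
        cs = np.array([connectivity_score(sig, clrs[ln]).cs for ln in lines])
        pvals = np.array([empirical_pvalue(c, null.mixture, "negative") for c in cs])
        fdr = bh_fdr(pvals)
        table[f"cs_{sig.name}"] = cs
        table[f"ncs_{sig.name}"] = normalize_cs(cs, null.mixture)
        table[f"fdr_{sig.name}"] = fdr
        selected_mask &= (cs < 0) & (fdr < fdr_threshold)
    table["selected"] = selected_mask
    return frozenset(table.index[selected_mask]), table


@dataclass(frozen=True)
class AssociationResult:
    drug: str
    measure: str
    n_selected: int
    n_rest: int
    t: float
    pvalue: float
    delta_m: float  # mean(selected) - mean(rest)


def sensitivity_association(
    selected: Collection[str],
    resp: pd.DataFrame,
    drug: str,
    measure: str = "log_ic50",
    welch: bool = False,
) -> AssociationResult:
    """Two-sample unpaired t-test of drug response between predicted-sensitive
    cell lines and the rest of the panel.

    ``resp`` needs columns ``cell_line``, ``drug`` and the chosen measure
    (``log_ic50`` or ``auc``); missing responses are skipped.  Pooled-variance
    Student t by default, Welch with ``welch=True``; two-sided p.
    """
    if measure not in resp.columns:
        raise ValidationError(f"response table lacks a {measure!r} column")
    sub = resp[(resp["drug"] == drug) & resp[measure].notna()]
    if sub.empty:
        raise ValidationError(f"no response values for drug {drug!r}")
    sel = set(selected)
    a = sub.loc[sub["cell_line"].isin(sel), measure].to_numpy(dtype=float)
    b = sub.loc[~sub["cell_line"].isin(sel), measure].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError(
            f"group too small for a t-test on {drug!r}: "
            f"{len(a)} predicted-sensitive vs {len(b)} rest (need >= 2 each)"
        )
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return AssociationResult(
        drug=drug,
        measure=measure,
        n_selected=len(a),
        n_rest=len(b),
        t=float(t),
        pvalue=float(p),
        delta_m=float(a.mean() - b.mean()),
    )


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def load_expression_matrix(path: str | Path) -> pd.DataFrame:
    """TSV with gene/probe rows and cell-line columns (first column = id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def load_probe_map(path: str | Path) -> dict[str, frozenset[str]]:
    """TSV ``probe<TAB>gene1;gene2``."""
    out: dict[str, frozenset[str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path}:{lineno}: expected probe<TAB>genes")
        out[parts[0]] = frozenset(g for g in parts[1].split(";") if g)
    return out


def load_response_table(path: str | Path) -> pd.DataFrame:
    """CSV with columns cell_line, drug, log_ic50, auc."""
    resp = pd.read_csv(path)
    required = {"cell_line", "drug"}
    missing = required - set(resp.columns)
    if missing:
        raise ValidationError(f"response table lacks column(s): {sorted(missing)}")
    return resp
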