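# Methods

This note documents the models, numerical choices, and limitations behind
`sigrefine`, in the spirit of a statistical-software methods appendix.

## Ranked lists and signatures

The gene universe is a fixed ordered set of unique identifiers (probe-sets
or genes; matching is exact and case-sensitive). A ranked list is a strict
permutation of the universe with rank 1 the most up-regulated element; the
percentile of a gene is `rank/N` with 1-based ranks, so "above the 70th
percentile" means toward the down-regulated tail. Whenever ranks are
derived from scores, ties are broken lexicographically by identifier — all
downstream computation is therefore deterministic and permutations are
always strict. Signatures are pairs of disjoint gene sets {U, D}; the
"optimal signature" of a PRL is its top-k and bottom-k genes (default
k = 250, a size that works well for genome-wide ranked lists where no
fold-change or significance filter is available).

## PRL merging

A drug's per-treatment ranked lists are merged hierarchically: the two
lists with the smallest Spearman footrule distance (sum of absolute rank
differences) are replaced by their Borda merge (mean rank, re-ranked with
lexicographic ties) until one list remains. Merging the most similar lists
first lets reproducible structure accumulate before outlier treatments are
folded in; a single-pass Borda mode is available (`mode="borda"`). Pair
selection ties are broken by lexicographic label pair. The procedure is
idempotent on identical inputs, invariant to input order, and preserves
unanimous extremes (a gene ranked first everywhere stays first).

## Enrichment and connectivity

The enrichment score is the unweighted KS running sum: +1/|set| on hits,
−1/(N−|set|) on misses, signed maximum |deviation|. Positive maxima occur
immediately after hits and negative minima immediately before them, so the
implementation evaluates only those 2·|set| candidate positions (O(h log h)
per evaluation rather than O(N)); it is verified exhaustively against a
literal walk for every gene set on universes N ≤ 8. At an exact tie between
the maximum positive and maximum negative deviation the earlier position in
the list wins; a 1e-9 tolerance absorbs float noise so ties resolve by
position rather than rounding. CS(S, A) = (ES_A(U) − ES_A(D))/2. The drug
distance is d(A,B) = 1 − (CS(S_A,B) + CS(S_B,A))/2, giving self-distance 0,
reversal distance 2, and ~1 for unrelated lists; the combiner is a
pluggable function.

## The permutation null and its mixture model

The null distribution of CS for a given signature is generated by scoring
the signature against i.i.d. uniform random permutations. Because only the
ranks of the |U|+|D| signature genes matter, each permutation is realised
by sampling that many distinct positions, which makes 10,000 permutations
cheap at any N. One null serves all ranked lists queried with the same
signature (random lists are exchangeable), and the sampler is seeded, so
nulls are reproducible.

Null CS values are strongly trimodal: each ES is a signed maximum
deviation, hence bimodal around ±(typical KS magnitude), and the
difference of two such values has a central and two side lobes. The null
density is modelled as a 3-component Gaussian mixture fitted by EM
(scikit-learn, 10 k-means++ restarts, tol 1e-6, ≤ 500 iterations);
components that collapse (weight < 1e-3 or sd < 1e-4) trigger a refit with
fewer components down to a single Gaussian, which handles near-unimodal
nulls. P-values are one-sided closed-form mixture tails in the direction
of the claimed connection (upper for positive connections, lower for
negative ones), clipped to [1e-300, 1]. The NCS is the mixture-moment
z-score, `(cs − μ_mix)/σ_mix` with `μ_mix = Σ wᵢμᵢ` and
`σ²_mix = Σ wᵢ(σᵢ² + μᵢ²) − μ²_mix`. BH correction is applied across the
set of simultaneously queried drugs (or cell lines).

**Known limitation.** The side lobes of the null are skewed
(max-statistics are Gumbel-like), so three Gaussians approximate but do
not exactly represent the density. At desk scale (100up/100down over
N = 1,000) the best achievable 3-Gaussian fit sits at a Kolmogorov
distance of about 0.010 from the true null even when fitted on 30,000
samples; p-value uniformity on fresh null draws is therefore good but not
perfect (KS typically 0.015–0.025 at 5,000 draws), while NCS mean/sd
calibration (0 ± 0.05, 1 ± 0.05) is comfortably met. At genome scale
(250-gene tails over >20k probes) the lobes are relatively narrower and
the approximation correspondingly better. Consumers needing exact tail
calibration at small N should raise `n_perm` and treat mixture p-values
as approximate beyond ~3 null standard deviations.

## Drug network and neighbourhood statistics

All n(n−1)/2 pairwise PRL distances are computed; the edge threshold is
the linear-interpolation ("type 7") empirical quantile of that multiset at
the configured level (default 5%), and edges are pairs with distance ≤
threshold. A neighbourhood query returns the seed's adjacent drugs
ascending by distance (or the top-m closest, `mode="top-m"`), each with
the fraction of all pairwise distances at or below it. Community
enrichment is an exact hypergeometric upper tail per prefix length: the
probability of at least the observed number of community members among the
first n neighbours, drawing from the networked drugs with the seed
excluded from both population and draws (the seed is the query, not an
observation), BH-adjusted within each prefix. Communities are consumed as
an input annotation table; a greedy-modularity detector is included as a
convenience only.

## Refinement

Splitting uses strict `>` for "above the high percentile" and `≤` for
"within the low percentile", making the two conditions complementary at
the boundary; `min_support` (default 2) counts how many confounder PRLs
must displace a gene. The partition is exact by construction: consistent
and inconsistent tile the seed signature side-wise. The contrast signature
uses quantile q (default 0.25) on the seed side and 1−q on the opposing
side, with all opposing drugs required by default (`contrast_support=None`).
In the query step a drug is kept iff cs > 0 and BH fdr < 5% for every
query signature; kept drugs are ranked by the arithmetic mean of their
per-signature NCS values. Contrast iterations re-score the kept drugs and
classify them by the sign of the contrast NCS (positive: same directional
effect as the seed; negative: opposing; exactly 0: neutral) without
re-filtering, since a contrast signature measures direction rather than
membership; `refilter_on_contrast=True` restores filtering. The seed drug
and all drugs named in iterations are excluded from the ranked output —
they are inputs to the supervised step, not discoveries.

## Cell-line scoring

Probe-level expression is collapsed by discarding multi-gene probes and
averaging same-gene probes. Per gene, the cross-panel distribution is
smoothed with a Gaussian KDE (Silverman bandwidth); the CDF of the kernel
mixture is evaluated in closed form (a mean of normal CDFs), clipped to
[1e-6, 1−1e-6] so the logit score z = log(CDF/(1−CDF)) stays finite, and z
is strictly increasing in expression within each gene, so any monotone
per-gene transform of the input leaves the cell-line ranked lists (CLRs)
unchanged in order. Constant gene rows either raise or are dropped
(`on_constant`). Lines are called predicted-sensitive when cs < 0 with
lower-tail fdr < 5% against every supplied signature. The response test is
a pooled-variance unpaired two-sample t-test (Welch optional) on log IC50
or AUC between the predicted-sensitive lines and the rest, reporting t,
two-sided p, and the group-mean difference ΔM; groups with fewer than two
responses raise, since such a test would be meaningless.

## Synthetic data

The compendium simulator draws, per treatment, a latent per-gene score
(Gaussian noise, sd 1) plus the drug's class effects (+effect on the
class's up-genes, −effect on its down-genes, plus any secondary effects
shared between classes) and ranks the latent vector, mimicking how real
ranked lists arise from differential-expression statistics; effect
strengths are interpretable in noise-sd units. The bundled
planted-confounder design (`confounded_compendium_spec`) uses 60 drugs x
2,000 genes x 3 treatments: two 10-drug classes with 125-gene up/down
blocks each and a shared 125/125 secondary block at effect 5, so the
shared effect contributes half of the seed's top/bottom-250 signature —
the structure the refinement stage must dissect. The panel simulator
shifts a target signature's up-genes down (and down-genes up) by a
reversion strength (default 2 noise sd) in a chosen subset of lines and
lowers their log IC50 by a configurable shift (default 2), with AUC
reduced proportionally (0.05 per log-IC50 unit, clipped to (0,1)).

What the simulators do **not** emulate: batch structure, probe-level
intensity distributions, correlated gene modules, dose dependence, or
tissue covariates. Passing the planted-truth tests therefore demonstrates
that the pipeline recovers the signal structure it is designed for, not
that it is robust to every artefact of real microarray compendia.

## Problem sizes and determinism

Default analysis sizes were chosen so the full pipeline (simulation, PRL
merging, nulls, refinement, panel scoring) completes in seconds to
minutes on one CPU: 2,000-permutation nulls in the synthetic refinement
and reversion studies, 5,000 for the calibration study, 10,000 as the
production default. All randomness flows through `numpy` Generators
seeded explicitly (child seeds via `SeedSequence.spawn`), and all sorting
is stable with lexicographic tie-breaks, so every result in this package
is bit-reproducible given its seed.
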