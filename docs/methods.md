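# Methods

## Mutual-information scoring

Each feature vector (one microbe or gene over n samples) is discretized by
the equal-frequency method: bin edges at the j/nbins empirical quantiles,
taken as nearest-rank order statistics (`numpy` `inverted_cdf`), with
assignment by value into right-closed intervals. Two consequences are
deliberate:

- **Ties never split across bins.** Zero-inflated microbial vectors have a
  large atom at 0; rank-splitting ties would manufacture spurious entropy
  there. Duplicate quantile edges are collapsed, so the occupied bin count
  can fall below the requested `nbins`.
- **Monotone invariance.** Nearest-rank edges are equivariant under any
  strictly increasing transform, so MI is invariant to the normalization
  scale (log, CPM, FPKM) of the inputs. Interpolating quantile rules do
  not have this property, which is why they are not used.

MI is the plug-in estimate MI = H(X) + H(Y) − H(X,Y) over the observed
joint contingency table, in nats by default (bits = nats / ln 2, exact
division). Negative values from floating-point cancellation are clamped to
zero, and the joint-entropy summation uses a canonical argument order so
MI(x, y) == MI(y, x) holds exactly in floating point. `pairwise_mi`
discretizes each feature once, reuses the codes across all its pairs, and
accumulates contingency tables in gene chunks, bounding memory by
`chunk × nbins²` rather than by the number of pairs.

**Bin count.** The default is the cube-root rule, nbins = ⌈n^(1/3)⌉
(4 bins at n = 60). A rule assigning one bin per observation is exposed as
`bin_rule="n-obs"` for audit only: with all-distinct values it makes every
marginal uniform over n singleton bins and scores every such pair at
exactly ln n, which destroys the MI ranking the edge threshold depends on.

**No MI significance testing.** Edges are chosen by ranking plus a
quantile threshold; permutation nulls or p-values on MI are out of scope.

## Networks and thresholding

The edge threshold is the nearest-rank empirical quantile (default 0.995)
of all |U| × |V| MI values of the network being built; retained edges are
*strictly above* it, so ties at the threshold are excluded and a constant
MI matrix yields an edgeless network. The realized edge count is recorded
in the run manifest. The built network keeps every measured microbe and
gene as a node regardless of edge participation; bipartiteness is enforced
at construction and same-side or unknown-id edges are structural errors.

Network comparison reports percentualized Jaccard similarity of the two
giant-connected-component node sets and of the edge sets (unordered
(microbe, gene) identity, weights ignored), plus per-side Spearman
correlations of the degree vectors over the full shared node universe with
average-rank ties; degree-0 nodes are included there because both networks
share the same measured universe by construction. When one degree vector
is constant the rank correlation is undefined and reported as null, except
for elementwise-identical vectors, which report 1.

## Topology

Clustering uses the pairwise-Jaccard ("dot") variant of the Latapy
bipartite coefficient — the mean over same-side nodes at distance exactly
2 of |N(u)∩N(v)|/|N(u)∪N(v)| — with min- and max-normalized variants as
options; nodes without distance-2 neighbors score 0. Redundancy of v is
the fraction of unordered neighbor pairs of v co-covered by some other
node, undefined (NaN in tables, None in the API) below degree 2. Both are
computed via `networkx.algorithms.bipartite` and are verified against
exhaustive enumeration oracles in the test suite. The giant component is
taken over nodes with degree > 0; an edgeless network has GCC size 0.

Microbe-vs-gene coefficient distributions are compared with the two-sample
KS test (asymptotic two-sided p by default; the exact method is available
for small samples). Degree-0 nodes are excluded from these distribution
comparisons — they carry no topological signal and would otherwise
dominate the statistic — and undefined redundancies are likewise dropped.
Degree rankings break ties lexicographically by node id, making top-k
lists deterministic.

## Enrichment

For each of the top 10 microbes by degree (configurable), each harmonized
gene set is tested with the exact hypergeometric upper tail
(`scipy.stats.hypergeom.sf`), with the universe N = all measured genes in
the expression matrix (the "full genome" reference; restriction to
annotated genes is an option). Benjamini–Hochberg correction is applied
within each microbe's family of tests by default, with a pooled option;
rows are flagged at FDR ≤ 0.05. Gene sets are intersected with the
network's gene universe and kept only at sizes 5–500 (common ORA
guardrails, configurable); genes absent from every annotation stay in the
universe, which is the conservative choice. Microbes with empty
neighborhoods appear in the summary as untestable rather than vanishing.

Token summaries lowercase the significant terms' names and descriptions,
split on non-alphanumeric runs, and drop tokens shorter than 3 characters
or on the fixed stopword list shipped in `tokens.py` (versioned with the
package so counts are reproducible). Only significant rows are tokenized.
No stemming by default; a minimal suffix-stripping flag exists. Top-k
token sets (default k = 20) are compared by exact Venn partition.

## Synthetic data

The generator emulates the qualitative properties of the upstream
normalization pipelines without reimplementing them:

- genes: log-normal, per-gene μ ~ U(0, 3) and σ ~ U(0.5, 1.5) — heavy
  right tail, nonnegative;
- microbes: per-feature Gaussian log-CPM (mean U(1, 8), sd U(0.5, 2))
  with an independent Bernoulli zero mask (`zero_inflation`, default 0.3);
- identical sample columns and ordering across the two matrices, with
  stage labels `early`/`late` per sample.

A planted coupling replaces the target gene's latent Gaussian z, within
the samples of one condition, by √s·T(x) + √(1−s)·ε, where x is the
microbe's observed (post zero-mask) values, T is the standardized
monotone, centered-quadratic or median-threshold transform, and
s = `coupling_strength` is the squared correlation between T(x) and the
latent value. The latent is then pushed through the gene's own log-normal
link, so coupled and null genes share the same marginal family and s = 0
reduces exactly to the null draw. Couplings are assigned to microbes with
rank-inverse (Zipf-like) weights over a randomly permuted microbe order,
so hub microbes with many coupled genes arise naturally (the enrichment
study needs a hub with a sizeable neighborhood); each gene is the target
of at most one coupling per condition so plantings never overwrite each
other — hence the constraint `n_couplings ≤ n_genes`. `rewire_fraction`
of the early couplings are replaced by fresh pairs in the late condition
(targets drawn from untouched genes whenever enough remain), so 0 gives
identical and 1 disjoint truth sets. One root seed drives a
`SeedSequence` stream-splitting scheme (microbe draw, gene baseline,
assignment, coupling noise), making every sub-stream independently
reproducible and two same-seed calls bit-identical.

What the generator does **not** model: taxonomic structure among microbes,
batch effects, library-size artifacts, read-level noise, or the joint
distribution of a real cohort. Passing recovery tests therefore shows the
inference chain is correct and well-calibrated under these idealized
conditions, not that real tumor data would yield comparable precision.

Gene-set generation draws `n_sets` random sets within `size_range`;
`n_enriched` of them take at least half their members from the hub
microbe's coupled genes, giving ORA a known positive.

## Default study sizes

Analyses and tests run at reduced scale, chosen to keep every study
comfortably within an interactive session while leaving clear signal
margins: the recovery study uses 300 genes × 80 microbes over 60 + 60
samples with 150 couplings at strength 0.8 and full rewiring (the 99.5 %
quantile of 24,000 pairs admits 120 edges per condition); the enrichment
study uses 200 genes × 15 microbes, 50 + 50 samples, 60 persistent
couplings, 40 gene sets and a 98 % quantile so the hub's neighborhood
survives thresholding; the full cohort scale (~16,600 genes × ~4,450
microbes) is supported by the chunked MI engine but not exercised in the
default suite.

## Known limitations

- The plug-in MI estimator is biased upward at small n; since edges come
  from a within-network quantile ranking the shared bias largely cancels,
  but absolute MI values should not be compared across different sample
  sizes or bin counts.
- The quantile threshold is computed per network, so two networks always
  receive (nearly) equal edge budgets; this guarantees fair comparison but
  makes edge counts a property of the threshold, not the data.
- Redundancy is reported as undefined below degree 2 and excluded from
  distribution tests; alternative conventions exist.
- Stage labels outside I–IV/early/late are excluded (and counted in the
  manifest), not imputed.
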