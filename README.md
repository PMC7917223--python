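# migenet

Bipartite mutual-information co-expression networks between microbial
abundance and host gene expression.

Tumor tissue carries resident microorganisms, and their abundance co-varies
with host transcription. `migenet` is for researchers who have two matched
feature × sample matrices — microbial abundance (log-CPM-like, e.g. from
k-mer taxonomic quantification of non-human reads) and gene expression
(FPKM-like) over the *same* samples — and want to ask which microbe–gene
pairs are statistically coupled, how that coupling is wired per clinical
condition (e.g. early vs late tumor stage), and which host functions the
most-connected microbes associate with.

## Method

For every microorganism *u* and gene *v*, both vectors are discretized by
the equal-frequency (empirical quantile) method and scored with the plug-in
mutual information

&nbsp;&nbsp;&nbsp;&nbsp;MI(X, Y) = H(X) + H(Y) − H(X, Y),&nbsp;&nbsp;
H(Z) = −Σ_b p̂_b ln p̂_b&nbsp;&nbsp;(nats),

which, unlike correlation, captures non-linear and non-monotone coupling.
Pairs with MI strictly above the 99.5 % empirical quantile of all
|U| × |V| values become edges of a bipartite graph B(microbes, genes) that
retains **every** measured feature as a node, connected or not. Per
network, the package computes degrees and degree rankings, the giant
connected component (GCC), and the Latapy bipartite clustering and
redundancy coefficients, comparing microbe vs gene coefficient
distributions with two-sample Kolmogorov–Smirnov tests. Two condition
networks are compared by percentualized Jaccard similarity
(100·|A∩B|/|A∪B|) of GCC node sets and of edge sets, and by Spearman
correlation of per-side degree vectors. Finally, the gene neighborhood
N(u) of each top-degree microbe is tested for over-representation in
user-supplied gene sets (GMT) with the hypergeometric upper tail
P(X ≥ k), X ~ Hypergeom(N, K, n), Benjamini–Hochberg corrected at
FDR ≤ 0.05, and the significant terms' names/descriptions are summarized
by token frequency with a top-20 Venn partition across conditions.

A first-class synthetic-data module generates matched matrices with
planted (monotone/quadratic/threshold) microbe–gene couplings,
condition-specific rewiring and known enriched gene sets, so the entire
chain is testable without any external download.

## Worked example

```python
from migenet import SynthConfig, generate_matched_dataset, pairwise_mi
from migenet.network import network_from_mi, compare_networks

ds = generate_matched_dataset(SynthConfig(seed=1))  # 300 genes x 80 microbes
nets = {}
for stage in ("early", "late"):
    cols = ds.samples_of(stage)
    mi = pairwise_mi(ds.microbe_matrix.subset_samples(cols),
                     ds.gene_matrix.subset_samples(cols))
    nets[stage] = network_from_mi(mi, quantile=0.995)
    recovered = nets[stage].edge_set() & ds.truth_pairs(stage)
    print(f"{stage}: {nets[stage].n_edges} edges above MI "
          f"{nets[stage].threshold_value:.3f} nats; "
          f"{len(recovered)} planted couplings recovered")

comp = compare_networks(nets["early"], nets["late"])
print(f"edge Jaccard {comp.edge_jaccard:.2f}%, "
      f"GCC node Jaccard {comp.node_jaccard_gcc:.2f}%")
```

prints

```
early: 120 edges above MI 0.536 nats; 120 planted couplings recovered
late: 120 edges above MI 0.545 nats; 120 planted couplings recovered
edge Jaccard 0.00%, GCC node Jaccard 2.22%
```

The 99.5 % quantile of 24,000 pairs admits 120 edges per condition; every
one of them is a planted coupling (precision 1.0), and since the truth was
fully rewired between conditions the two networks share node universes but
no edges — the "similar composition, dissimilar wiring" signature this
kind of analysis looks for in real cohorts.

The same pipeline runs from the shell on TSV/GMT files:

```bash
migenet generate --seed 1 -o data/
migenet run --genes data/gene_matrix.tsv --microbes data/microbe_matrix.tsv \
    --stages data/stage_labels.tsv --gmt data/gene_sets.gmt -o out/
```

`out/` then holds, per condition, the MI matrix, edge list, GraphML
network, per-node topology table, KS distribution tests, enrichment table
and token counts, plus the network comparison and a manifest sufficient to
re-run the pipeline bit-identically.

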