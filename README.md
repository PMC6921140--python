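# pgxnet

Network analysis of gene-drug co-metabolism for combinatorial
pharmacogenomics.

Most drugs are absorbed, distributed, metabolized and eliminated (ADME) by
several enzymes and transporters at once, so functional variants in *pairs*
of pharmacogenes can amplify or mask each other's effect on drug exposure.
Searching for such gene-gene-drug interactions head-on is combinatorially
hopeless; `pgxnet` implements a network strategy that shrinks the search
space. From a binary gene × drug ADME association table it computes:

1. **Posterior-probability overlap (ΔP).** For every ordered gene pair
   (i, j),

   ΔP_ij = P(X_i | X_j) − P(X_i),

   where P(X_i | X_j) = |drugs(i) ∩ drugs(j)| / |drugs(j)| and
   P(X_i) = |drugs(i)| / N.  ΔP_ij > 0 means that a drug handled by gene j
   is more likely than chance to also be handled by gene i.

2. **An association-strength item network.** Genes and drugs form one node
   set with similarity s_ij = c_ij / (w_i · w_j), where w_i counts an
   item's occurrences in the table and c_ij the co-occurrences of items i
   and j (optionally weighted by the number of pharmacogenomic labels
   backing each link).  Degree assortativity of this network is reported.

3. **A constrained 2D map.** Coordinates x_i ∈ R² minimize
   V = Σ_{i<j} s_ij ‖x_i − x_j‖² subject to
   (2/(n(n−1))) Σ_{i<j} ‖x_i − x_j‖ = 1, fitted by an iterative
   majorization (SMACOF-family) algorithm with guaranteed monotone descent.
   Distance on the map is a proxy for shared metabolic fate; k-means and
   Ward clustering of the embedding recover substrate families.

4. **A variability overlay.** Per-gene aggregated minor allele frequencies
   of functional variants are mapped onto the layout and genes are ranked
   by MAF or MAF × degree, flagging *hotspots*: variable genes embedded in
   dense metabolic overlap — priority candidates for epistasis screens.

A synthetic generator produces association tables with the statistical
structure real ADME surveys show (heavy-tailed gene degrees, planted
substrate-overlap blocks, label weights, per-gene MAF scores), so the whole
pipeline is testable without any external download.

## Worked example

```python
from pgxnet import GeneDrugNetworkModel, paper_scale_preset

model = GeneDrugNetworkModel.from_synthetic(paper_scale_preset(seed=1))
results = model.fit(seed=1, n_clusters=6)
print(results.summary())
```

```
==================================================================
                    Gene-Drug Network Analysis
==================================================================
Genes:                              94  Drugs:               212
Gene-drug links:                   648  Mode:           weighted
Degree assortativity:           0.3951
------------------------------------------------------------------
Layout objective V:            32.0371  Iterations:          405
Constraint (mean dist):       1.000000  Converged:          True
Clusters:                            6  Method:           kmeans
------------------------------------------------------------------
Strongest metabolic-overlap pairs (ΔP, responding | conditioning):
  ΔP(G29 | G91) = +0.995
  ΔP(G91 | G29) = +0.995
  ΔP(G43 | G29) = +0.991
  ΔP(G43 | G91) = +0.991
  ΔP(G48 | G86) = +0.991
------------------------------------------------------------------
Top pharmacogenetic hotspot genes (score = MAF × degree):
   1. G01        score=16.26 (MAF=0.1848, degree=88)
   2. G02        score=10.1 (MAF=0.1086, degree=93)
   3. G09        score=1.511 (MAF=0.1259, degree=12)
   4. G36        score=1.413 (MAF=0.471, degree=3)
   5. G10        score=1.203 (MAF=0.1336, degree=9)
==================================================================
```

Reading the output: the synthetic table at realistic scale (94 genes, 212
drugs) is assortative (index 0.40) — pleiotropic genes co-occur with other
heavily-used items.  The layout converged with the mean pairwise distance
pinned at 1 by the constraint.  Pairs with ΔP ≈ 1 share essentially their
whole substrate set; the hotspot list combines high aggregated MAF with
many drug interactions, exactly the genes a combinatorial pharmacogenetic
screen would start from.  `results.plot_heatmap()`, `.plot_network()` and
`.plot_overlay()` render the corresponding figures, and
`results.hotspots(top_k=10)` adds each hotspot's nearest map neighbors as
candidate epistasis partners.

On real counts the arithmetic is exact: with 212 drugs, a hub gene linked
to 141 of them, a transporter linked to 94, and 81 drugs shared,
ΔP(hub | transporter) = 81/94 − 141/212 = 0.197 — transporter substrates
are 19.7% more likely than chance to be hub substrates.

## Command line

```bash
pgxnet simulate --preset paper-scale --seed 1 --outdir data/
pgxnet run --associations data/associations.tsv --variability data/variability.tsv \
           --seed 1 --outdir out/
```

`run` writes the ΔP matrix, network edge list, layout, cluster assignment,
hotspot report and a manifest with SHA-256 checksums; identical config and
seed reproduce identical artifacts.  Stages are also available as
individual subcommands (`deltap`, `network`, `layout`, `cluster`,
`overlay`).

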