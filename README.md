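# netbim

Pan-specific HLA class I epitope prediction that treats the corpus of
measured HLA–peptide pairs as a **weighted bipartite network** and feeds
network centrality features, alongside BLOSUM50-encoded peptide sequences,
into a dual-input convolutional + attention neural network.  Two models are
trained — a binding-affinity regressor and an immunogenicity classifier —
and combined so that the immunogenicity model filters predicted binders that
are unlikely to trigger a T-cell response.  It is aimed at immunoinformatics
users prioritising T-cell epitope / neoantigen candidates.

## The method

**Data.**  Binding data are (allele, 9-mer peptide, IC50 nM) triples;
immunogenicity data are (allele, peptide, 0/1) labels.  Affinities are
mapped onto [0, 1] with

```
BA = 1 − log(IC50) / log(50000)
```

so the conventional 500 nM binder cutoff sits at BA = 0.426.  Only 9-mers
are kept, duplicates are collapsed, and alleles with fewer than six entries
are dropped.

**Network features.**  Every allele and peptide is a node; every measured
pair an edge weighted by BA (binding network) or by the binary label
(immunogenic network, with ε = 1e-10 standing in for zero).  Per node, four
centrality metrics are computed — degree, closeness (1/Σ shortest-path
distances), betweenness, eigenvector — and z-scored within node class.  A
pair is described by the 8-vector (4 HLA + 4 peptide metrics).  Peptides or
alleles never seen in training are imputed by the nearest training peptide
in BLOSUM50-encoding space (Euclidean) or by the per-metric HLA median.

**Model.**  The 9×21 encoded peptide and the 1×8 metric vector each pass
through a 1-D convolution (256 filters, stride 1, ReLU, 70% dropout),
flatten + 4 extra tiled copies, and FC(64)→FC(4); an attention module scores
the 9 peptide positions with a shared one-hidden-layer network and returns
their softmax-weighted average.  Everything is concatenated into a final
sigmoid unit.  Binding uses MSE + Adam, immunogenicity BCE + RMSprop
(minibatch 256).  Implemented in pure NumPy with hand-derived backprop,
verified against finite differences.

**Combination.**

```
combined = BA   if IC = 1
         = 0    if IC = 0
```

**Controls.**  Shuffle networks (a fraction of edge weights permuted,
topology intact) and random networks (weights ~ U(0,1)) quantify the
information carried by correctly assigned weights; stepwise AIC regressions,
KS and chi-squared tests probe each centrality metric's association with
binding/immunogenicity.

## Worked example

```bash
python examples/03_train_and_predict.py
```

```
trained on 500 pairs, tested on 125
test MAE: 0.238
(predicting the training-set mean would give 0.272)
MAE is on the transformed-affinity scale [0, 1]; lower is better.
```

The script simulates an IEDB-shaped binding dataset, trains the dual-input
model on 80% of pairs and reports held-out MAE on the transformed-affinity
scale; beating the mean-predictor baseline shows the model learned both the
sequence motif and the network signal.  `examples/05_ablation_experiment.py`
repeats the internal control of the method:

```
mean test MAE per condition (lower = better):
original       0.2079
random         0.2355
shuffle:1.0    0.2400
pep_only       0.2570
```

`original` (true network weights) outperforms the sequence-only model and
both null networks — the centrality features carry real signal.  The other
examples cover the affinity transform, network construction, the combined
model and the regression diagnostics.

A thin CLI mirrors the workflow: `netbim simulate`, `netbim build-network`,
`netbim features`, `netbim train`, `netbim predict`, `netbim combine`,
`netbim cv`, `netbim eval`.

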