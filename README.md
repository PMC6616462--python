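# netcentroid

Predictive subnetwork discovery from multi-omics data.

Supervised multi-omics studies often ask not *which molecules* separate
phenotypic groups, but *which molecular interactions* do: a transcription
factor's protein abundance moving together with its target genes' mRNA, or two
physically binding proteins rising and falling in concert. `netcentroid`
integrates transcriptomic and proteomic (optionally DNA copy-number) matrices
over a user-supplied composite network of TF-regulatory and protein-protein
interactions, and selects sparse, densely connected subnetworks that predict
group membership. It is aimed at systems-biology analysts with matched omics
layers, gene-symbol-keyed networks and a sample-to-group table.

## Method

Each omics layer (log2 scale) is standardised per feature to Z-scores. Every
measurable network edge *i* then gets one **interaction score** per sample
*j*:

- TF edge (protein A → mRNA B): `e_ij = z_prot(A) + z_mRNA(B)`,
  or `z_prot(A) + (z_mRNA(B) − z_dna(B))` when a copy-number layer normalises
  transcription per DNA copy;
- PPI edge (proteins A, B): `e_ij = z_prot(A) + z_prot(B)`.

These edge scores are the feature space for a network-adjusted **nearest
shrunken centroid** classifier. For edge *i* and group *k*,

```
d_ik = (x̄_ik − x̄_i) / (m_k (s_i + s_0)),       m_k = √(1/n_k + 1/n)
```

with the overall centroid `x̄_i` taken as the *unweighted* mean of group
centroids (immune to group-size imbalance), `s_i` the pooled within-class SD
and `s_0` the median of the `s_i`. The statistic is then augmented by its
network neighbourhood (edges sharing a node):

```
d*_ik = d_ik + ψ(p_ik) · mean_{j ∈ N(i)} d_jk
```

where `p_ik` is the proportion of neighbours agreeing in sign with `d_ik` and
`ψ(p) = 2·e^{5(p−½)} / (1 + e^{5(p−½)})` maps agreement to a factor in (0, 2).
Densely connected, consistently signed subnetworks are thereby promoted over
scattered signals. Soft-thresholding `d′_ik = sign(d*_ik)(|d*_ik| − Δ_k)_+`
with a group-rescaled threshold `Δ_k = (Δ/Δ_max)·max_i |d*_ik|` shrinks class
centroids toward the overall centroid along a 30-point grid; the operating Δ
is chosen by stratified cross-validation. Samples are classified by the
smallest discriminant score
`δ_k(x) = Σ_i (x_i − x̄′_ik)²/(s_i + s_0)² − 2 log π_k`, and the selected
subnetworks are tested for signed pathway over-representation (hypergeometric
upper tail, Benjamini–Hochberg per group × direction).

A simulator generates dual-omics benchmarks with planted TF-activation
signals, heavy-tailed target in-degrees, proteomic assay-sensitivity dropout
and optional network corruption, and scores planted-edge recovery by ROC/AUC
against two baselines (shrunken centroids on interaction scores without the
neighbourhood adjustment, and textbook NSC on concatenated node-level data).

## Worked example

`examples/02_discover_subnetworks.py` simulates a 30-sample dual-omics cohort
with planted signal, runs the full discovery pipeline and prints:

```
measurable edges: 544, samples: 30
chosen delta = 1.856 (of delta_max 2.833), CV error 0.033
group G1: 51 edges selected, 33 of them planted signal
group G2: 51 edges selected, 33 of them planted signal
```

Of 544 measurable interactions, cross-validation keeps a shrinkage that
selects 51 per group while misclassifying ~3% of held-out samples; 33 of the
selected edges are the simulator's planted TF→target interactions, i.e. the
selection recovers the generating signal rather than noise. The other
examples show interaction scoring on a 4-sample toy, the recovery benchmark
(`mean_auc` per method) and signed pathway enrichment.

The same pipeline runs from the shell:

```sh
netcentroid simulate --n-tf 40 --n-targets 150 --group-size 15 --out study/
netcentroid discover --mrna study/mrna.tsv --protein study/protein.tsv \
    --network study/network.tsv --groups study/groups.tsv --out results/
```

writing `scores.tsv`, `cv_errors.tsv`, `subnetworks.tsv`, Cytoscape node/edge
attribute tables and (with `--gmt`) `enrichment.tsv`.

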