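# Methods

## Model and pipeline

`netcentroid` treats molecular interactions, not molecules, as the unit of
analysis. The composite network is the union of TF-regulatory edges (protein
side = TF, mRNA side = target) and PPI edges, handled as an undirected graph:
with cross-sectional expression data the evidence for an interaction is
co-expression of its members, not a directional regulatory model. Gene symbols
are uppercased on input so layers and networks meet on the HGNC convention.

The pipeline is: align → standardise → score edges → fit the network-adjusted
shrunken-centroid model → choose the shrinkage by cross-validation → select
per-group subnetworks → signed pathway enrichment.

**Alignment.** Samples are restricted to the intersection of all layers and
the group table; an edge is measurable when each required molecule has a
feature row that is not entirely missing (TF edge: protein of the TF and mRNA
of the target, plus its CNV row when copy-number normalisation is on; PPI
edge: both proteins). Molecules off every measurable edge are dropped, making
alignment idempotent.

**Standardisation and scores.** Z-scores are computed per feature across
*all* samples (group structure enters only downstream), with the unbiased
(n−1) SD; features with <2 observations or zero variance become missing.
Values are assumed to be on log2 scale already — the package never re-logs.
Interaction scores add the member Z-scores; with a CNV layer the target-side
term is `z_mRNA − z_dna`, i.e. the CNV normalisation acts in Z-space, which is
algebraically identical to scoring a CNV-adjusted mRNA matrix (tested). A
missing Z propagates to the edge score; the default policy drops incomplete
edges, with within-group mean imputation (`group_mean`) as the alternative.
No policy is imposed silently: the choice is a user-visible parameter.

## The classifier

Per edge *i* and group *k* the standardised statistic is
`d_ik = (x̄_ik − x̄_i) / (m_k (s_i + s_0))` with `m_k = √(1/n_k + 1/n)`,
pooled within-class SD `s_i` (divisor n − K, the standard pooled-variance
convention) and offset `s_0 = median(s_i)`. The overall centroid `x̄_i` is
the unweighted mean of the group centroids, so groups contribute equally
regardless of size.

**Neighbourhood adjustment.** Neighbours of an edge are all edges sharing at
least one node. The adjusted statistic is `d* = d + ψ(p)·A`, where `p` is the
sign-agreement proportion among neighbours (`sign(0)` counts as agreeing only
with other zeros) and `ψ(p) = 2 expit(5(p−½))`. Two points were genuinely
open and are resolved as follows, each switchable:

- *Form of A.* The adjustment as a type-weighted expression
  `(|N₁|·Σ_{N₁} d + |N₂|·Σ_{N₂} d)/|N|` multiplies each type's neighbour sum
  by its count, which leaves d* on a different scale from d and grows with
  degree. The default is the neighbourhood mean `A = (Σ_{N₁} d + Σ_{N₂} d)/|N|`,
  which keeps d* on the scale of d and expresses "consistency of neighbour
  scores" directly; `eq_form="literal"` restores the type-weighted form.
- *Threshold scale.* The grid scale uses `max_i |d*_ik|` per group (default):
  soft-thresholding acts on |d*|, so a signed raw-d maximum would under-shrink
  groups dominated by negative signals. `delta_form="literal"` uses the signed
  `max_i d_ik` instead.

Edges without neighbours get `A = 0` (no information, no adjustment); their
agreement proportion is undefined and never reaches ψ.

**Shrinkage and classification.** `Δ_max = mean_k max_i |d*_ik|`; the grid is
30 equally spaced values from 0 to Δ_max, and `Δ_k = (Δ/Δ_max)·max_i |d*_ik|`
rescales the global shrinkage per group so that Δ = Δ_max empties every group
simultaneously. Shrunken centroids are reconstructed as
`x̄′_ik = x̄_i + m_k (s_i + s_0) d′_ik` — the step the statistic's definition
inverts — so an unselected edge contributes the same term to every group's
discriminant score. Discriminant scores use equal priors by default
(`priors="empirical"` available); ties go to the lexicographically first group
label, deterministically; posteriors are `softmax(−δ/2)` computed with
max-subtraction so extreme scores cannot overflow.

With the adjustment disabled, equal group sizes and equal priors the engine
coincides with a textbook shrunken-centroid classifier; the test suite checks
this against an independently loop-coded reference to 1e-8.

## Cross-validation

Stratified K-fold (default 5; reduced with a warning when the smallest group
is smaller). Within each fold the full pipeline downstream of the edge scores
— centroids, pooled SDs, neighbourhood adjustment and the grid scale — is
refit on the training samples only. Because Δ_max differs per fold, grid
positions are aligned across folds by their *fraction* of each fold's own
Δ_max (30 fractions of the full-data grid); errors reported per position
therefore compare like with like. The operating Δ is, by default, the largest
grid value attaining the minimal overall CV error that still selects at least
one edge ("min_error_sparsest"); a one-standard-error rule is available.

Edge scores themselves are standardised once, globally, before CV — matching
an architecture where scoring is a preprocessing step. This leaks a small
amount of marginal (not group-related) information into the folds; all
group-dependent quantities are fold-internal, which the suite verifies by
showing a fold's model is bit-identical when test-sample values are mangled.

## Enrichment

Selected edges are split by the sign of `d′` per group; the query is the set
of genes incident to those edges (a gene can legitimately appear in both
directions through different edges). Pathway annotations describe genes, so
the default sampling unit is the node, with the background being all genes
incident to any measurable edge; an edge-level mode (an edge belongs to a
pathway iff both endpoints are annotated, background = measurable edges) is
available. P-values are upper-tail hypergeometric; BH adjustment is applied
per (group × direction) family, matching how the results are read — one panel
per group and direction. Pathways with fewer than 3 background genes are
skipped. The signed significance score is `−log10(adj p)` for up and its
negative for down, with adjusted p floored at 1e-300 before the logarithm.

## Simulator

The generator emulates a supervised dual-omics study over a TF-regulatory
network:

- **Network**: bipartite TF → target; each edge draws its TF uniformly and
  its target with probability proportional to (in-degree + 1), giving
  heavy-tailed target in-degrees; mean in-degree defaults to 9.7
  (edges ≈ 9.7 × targets). Defaults: 1000 TFs × 5000 targets.
- **Signal**: 10% of TFs (uniformly chosen) carry activation; a target
  regulated by c signal TFs activates with probability c / max(c), so the
  most co-regulated target always activates. Truth edges are the
  signal-TF → activated-target pairs. The effect +μ is added to signal-TF
  protein rows and activated-target mRNA rows in the first group only;
  baseline expression is N(0, σ²) i.i.d.
- **Assay sensitivity** P_AS removes whole protein rows with probability
  1 − P_AS: the platform either quantifies a protein or never sees it.
- **Network corruption** removes true edges at `fn_rate` and adds uniform
  spurious TF → target non-edges so they form ≈ `fp_rate` of the result.

Signal-to-noise settings step μ/σ down: A (0.30, 1.0), B (0.25, 1.0),
C (0.27, 1.25). These are calibration knobs of the generator, chosen once so
that, at the benchmark operating point (200 TFs × 1000 targets, 2 × 50
samples, P_AS = 0.7), the full method's mean recovery AUC in setting A sits
mid-band at ≈ 0.85 with the A → B → C ordering of signal strength preserved.

**Recovery evaluation.** Edges are ranked by `max_k |d*_ik|` — the order in
which they survive the shrinkage path, up to per-group rescaling — and the
ROC/AUC is computed against the truth labels restricted to measurable edges.
Baselines: the same fit's `max_k |d|` (adjustment off), and a textbook NSC
(grand-mean centroid, `m_k = √(1/n_k − 1/n)`) on the stacked protein + mRNA
node matrix, an edge scored by the mean of its members' node statistics. All
methods see the same measurable edge set.

What the generator does *not* emulate: real marginal distributions (iTRAQ
ratio artefacts, count overdispersion), correlated baseline expression,
PPI edges among the simulated proteins, batch effects, or missingness other
than whole-protein dropout. Passing benchmarks therefore demonstrate correct
mechanics and the relative merit of interaction-level modelling under the
stated generative model — not performance guarantees on real cohorts.

A consequence of restricting truth to measurable edges: corrupting the
network removes exactly the planted edges that would have been easy positives
and adds spurious edges that rank low, so measured AUC barely moves at
moderate corruption; the meaningful check, implemented in the suite, is that
corruption never *helps* and that the margin over the concatenation baseline
survives it.

## Numerical and degenerate-case choices

- Z-scores: (n−1) SD; constant or near-empty features become missing.
- s_0 = 0 (more than half the edges constant) is not guarded beyond the
  statistics becoming infinite where s_i = 0; such inputs are pathological.
- All d* = 0 collapses the grid to {0} with a warning.
- Duplicate feature rows collapse by mean on read; PPI self-loops are dropped;
  TF self-loops (autoregulation: protein and mRNA of the same gene) are kept.
- Benchmark replicates derive child seeds from a `SeedSequence` spawn of the
  spec seed (kept below 2³¹), making every table bit-reproducible.
- Problem sizes in the test suite and the reproduction script are scaled to
  desk size (e.g. 200 × 1000 × 100 benchmark, small CV instances), chosen so
  the statistical assertions retain comfortable margins at those sizes.

## Known limitations

- No prediction module for external cohorts; the classifier's error is
  reported by internal cross-validation only.
- Global standardisation before CV (see above) — adequate for model selection,
  not a substitute for nested CV if an unbiased error estimate is needed.
- Molecules absent from the network are discarded; predictive singletons are
  invisible to the method by construction.
- Node-level enrichment treats a gene selected through one edge the same as a
  gene selected through many; the edge-level mode is stricter but depends on
  both endpoints being annotated.
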