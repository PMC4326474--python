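# xgram — transcriptogram profiling of genome-wide expression data

`xgram` implements transcriptogram profiling: a way to analyse
genome-wide expression data that first orders the gene list so that
genes whose protein products are associated sit close together, then
replaces each gene's expression by the average over a window of its
list neighbours.  Because functionally related genes tend to be
co-regulated while measurement noise is not, the window average damps
noise, preserves coherent signal, sharpens contrast between
conditions, and improves agreement between laboratories.  The package
is aimed at people analysing bulk microarray or RNA-seq profiles who
want differential expression of *functionally related gene sets*
without committing to predefined pathway annotations.

## The method

**Seriation.** Starting from an undirected protein–protein association
network (e.g. a STRING `protein.links` file thresholded at combined
score 800), write its adjacency matrix `A` in the coordinates of a
candidate gene ordering and score the ordering with

    F = Σ_{i<j} A_ij |i − j|^α + β Σ_{i,j} ( |A_{i,j} − A_{i+1,j}| + |A_{i,j} − A_{i,j+1}| )

The first term pulls associated genes together along the list (α
controls its range; α = 1 is the standard choice, α ≈ 10 empties the
far field of the matrix entirely).  The second rewards placing genes
with similar association partners next to each other.  `F` is
minimised over permutations by Metropolis simulated annealing with
O(degree) incremental cost updates: the temperature starts at 0.01 %
of the initial cost and is halved every 100 Monte Carlo steps until
the acceptance rate stabilises near zero.  Ordering quality is
diagnosed by the occupation fraction γ(d) — the average fraction of a
gene's partners at list distance d — and the window modularity
M_i(r) — the fraction of edges touching the window at position i that
lie entirely inside it.

**Profiling.** For a sample with (log2, pre-normalised) expression
values E_j placed on the ordering, the transcriptogram at position i is

    T_i = Σ_{j∈window(i)} θ_j E_j / Σ_{j∈window(i)} θ_j

with window radius r (length w = 2r + 1), θ_j the platform coverage
mask, and windows truncated at the list ends.  r = 0 recovers the
transcriptome.  The measured value is modelled as signal + biological
variation + technical noise; with uncorrelated noise the per-position
replicate SD falls as w^(−1/2) while a coherent signal survives, which
is the source of the method's power and reproducibility gains.

**Statistics.** Conditions are compared position by position with
Welch's two-tailed t-test, Bonferroni control over the family of
ordering positions (family level 0.01) and FDR q-values
(Benjamini–Hochberg and a Storey-style estimate with smoothed π₀).
Class-level diagnostics include the contrast-to-noise ratio ω(r), the
average noise Ω(r), and Lin's concordance correlation coefficient
ρ_c = 2σ₁₂ / (σ₁² + σ₂² + (μ₁ − μ₂)²) between laboratories'
fold-change vectors.

## Worked example

```python
import xgram

# 1. simulate a modular association network (8 clusters x 25 genes)
net_spec = xgram.PlantedNetworkSpec(n_clusters=8, cluster_size=25,
                                    p_in=0.5, p_out=0.01, seed=42)
network, clusters = xgram.make_planted_network(net_spec)

# 2. seriate the gene list by simulated annealing (alpha = 1)
result = xgram.OrderingModel(network, alpha=1.0).fit(seed=42)
print(result.summary())

# 3. expression data: condition B shifts two clusters by 0.3 log2 units
signals = xgram.make_signal(clusters, conditions=("A", "B"),
                            shifted_clusters=[2, 5], delta=0.3, seed=42)
spec = xgram.SyntheticExpressionSpec(sigma_b=0.3, sigma_xi=0.5,
                                     n_b=5, n_a=4, seed=42)
expression, design, truth = xgram.make_expression(clusters, spec, signals)

# 4. windowed differential expression at radius r = 10
model = xgram.DifferentialTranscriptogram(expression, design,
                                          result.ordering, radius=10)
res = model.fit("A", "B")
print(res.summary())
```

which prints

```
Seriation results
=================
nodes            : 200
edges            : 1365
alpha            : 1.0
beta             : 1.0
seed             : 42
MCS run          : 837
best cost F      : 26284
gamma mass d<=10 : 0.6588

Transcriptogram comparison: A vs B
==========================================================
replicate profiles    : 20 vs 20
window radius r       : 10
positions tested      : 200 of 200
family alpha          : 0.01  (Bonferroni P < 5e-05)
Bonferroni significant: 36
P < 0.01 positions    : 59
Storey pi0            : 0.654
min P                 : 4.21e-11
```

The annealing has pulled 66 % of each gene's association partners to
within 10 list positions (`gamma mass`), and the two shifted clusters —
a per-gene shift of only ~0.5 standard deviations — come out as 36
window positions significant even under Bonferroni correction.  Real
data enter through `read_interactions`, `read_expression`,
`read_design`, `read_gene_sets` and `read_ordering`; the same steps
are exposed on the command line as `xgram order / diagnose / profile /
project / compare / simulate`.

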