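# Methods

## Model and assumptions

The package treats a gene list as a one-dimensional arrangement of an
association network.  Three assumptions carry the whole method:

1. **Association implies co-function.** Edges of the input network
   (protein–protein associations above a confidence threshold) mark
   pairs of genes likely to participate in the same biological
   process, so a good ordering makes functional modules contiguous.
2. **Co-function implies correlated expression.** Averaging expression
   over a window of the ordered list then averages over genes whose
   expression moves together.
3. **Technical noise is uncorrelated across genes.** The measured log2
   expression of the gene at position *i* under condition *k* is
   modelled as `E = s_ik + b + ξ`: a condition signal, a biological
   deviation shared by all measurements of one biological replicate,
   and independent technical noise per measurement.  Under assumption
   3 the noise variance of a window mean falls as 1/w with window
   length w = 2r + 1, while the biological term falls as 1/w only to
   the extent that biological variation is uncorrelated across the
   window — the window-mean pairwise covariance κ̄ estimated by
   `decompose_variance` interpolates between the two regimes.

Only genes with at least one association are retained: an isolated
gene carries no ordering information and has no defined neighbourhood.

## Seriation cost and annealing

The ordering is scored by
`F = Σ_{i<j} A_ij |i−j|^α + β·D`, with `D` the summed L1 difference
between adjacent rows and columns of the adjacency matrix in ordering
coordinates.  The distance term concentrates edges near the diagonal;
the adjacency-difference term rewards placing genes with similar
partner sets side by side (it decreases when two genes associated with
a common third gene become neighbours).  The printed form of the
second term is a design choice of this package: β (default 1) weights
it, and β = 0 recovers a pure distance seriation.

Minimisation is Metropolis Monte Carlo: one attempted swap draws an
unordered pair of list positions uniformly; ΔF is computed
incrementally touching only the swapped nodes' neighbour sets and the
adjacent rows (O(k_p + k_q) work; by matrix symmetry D = 2R with R the
summed Hamming distance between consecutive rows, and a swap of
positions p, q can only change the Hamming terms of rows p−1, p, q−1,
q).  The identity ΔF ≡ cost(after) − cost(before) is enforced by test
against full recomputation to machine precision — it is the central
correctness property of the engine.

Schedule and stopping, with defaults:

| parameter | default | meaning |
|---|---|---|
| `alpha` | 1.0 | distance-term exponent; 1 optimises clustering at pathway scale (~100 genes), ~10 suppresses all long-range edges |
| `beta` | 1.0 | weight of the adjacency-difference term |
| `t0_fraction` | 1e-4 | initial temperature as a fraction of the initial cost (0.01 %) |
| `halve_every` | 100 MCS | temperature halving period |
| `mcs_size` | N | attempted swaps per Monte Carlo step |
| `stop_window`, `stop_accept_floor` | 50 MCS, 1e-4 | stop when fewer than 0.01 % of proposals over 50 consecutive MCS are accepted |
| `max_mcs` | 20000 | hard cap |

The stopping rule quantifies "the number of changes has stabilised";
the best-seen ordering (not the final state) is returned, so the
result can never be worse than the initial permutation.  A single
seeded generator drives proposals, acceptance and the initial
permutation; identical seed and inputs give identical output.

## Diagnostics

* **Occupation fraction γ(d)**: each gene contributes the fraction of
  its k_i partners at list distance d; averaging over genes makes
  Σ_d γ(d) = 1 exact (each edge is counted from both endpoints).
* **Window modularity M_i(r)** = edges inside the window / edges
  touching it.  Windows truncate at the list ends — the list has a
  biological start and end, and the θ-weighted window average
  renormalises short windows naturally, so no wrap-around is used.
  A window touching no edge is reported as missing (NaN), because 0
  has the distinct meaning "every edge exits the window".

## Profiles

Transcriptograms smooth each sample separately
(average-after-smoothing): smoothing and class-averaging commute under
full coverage, but when the platform misses genes (θ gaps) per-sample
smoothing is the faithful reading of the windowed mean.  Windows with
no covered position propagate as missing values; downstream statistics
skip them and report the effective family size.  Genes measured but
absent from the ordering are returned in an `unmapped` list, never
silently dropped.  Relative class profiles divide position-wise by the
reference-class mean profile — a ratio of log2-scale values, kept as a
ratio deliberately for contrast with a reference near a common
baseline; the reference class relative to itself averages to 1, and
non-positive reference values flag the position missing rather than
raising.

Gene-set projection assigns 1/0 membership per position and applies
the same truncated box-car with θ ≡ 1; peaks of the smoothed indicator
mark enrichment intervals.

## Statistics

* **Welch test** per position, Satterthwaite degrees of freedom,
  two-tailed P from the t distribution, no continuity adjustments.
  Degenerate positions follow the conventions: both groups constant
  and equal → t = 0, P = 1; both constant but different → P = 0.
  The replicate unit is the sample transcriptogram (technical and
  biological replicates pooled as provided); `collapse_technical=True`
  averages technical replicates into biological-replicate profiles
  first.  Pooling correlated technical replicates anti-conservatively
  shrinks the error estimate — the flag exists precisely for that
  trade-off.
* **Bonferroni** family size defaults to the number of non-missing
  tested positions; the full-ordering convention (e.g. 9684 positions)
  is available via `family_size=` and coincides when coverage is full.
* **FDR**: Benjamini–Hochberg always; a Storey-style q-value
  multiplies the BH quantity by π₀ estimated from tail counts
  #{p>λ}/(m(1−λ)) on the λ grid 0.05..0.95 (step 0.05), smoothed by a
  cubic polynomial and evaluated at λ = 0.95, clipped to (0, 1].
* **Contrast-to-noise**: Ω(r) is the position-average of the
  per-position replicate SD; ω = (position-averaged contrast)/Ω and
  SNR = (position-averaged class mean)/Ω.  Ratios of position averages
  are the default aggregation; a per-position-ratio variant sits
  behind `per_position=True`.  All-zero noise yields inf/NaN flags,
  not exceptions.
* **Concordance** ρ_c uses population (1/n) moments (Lin's original
  convention); Pearson r is reported alongside, and |ρ_c| ≤ |r| with
  equality exactly at matched means and variances.

## Synthetic data

The planted-partition generator emulates the modular structure of
curated association networks: m clusters of c nodes, within-cluster
edge probability p_in, between-cluster p_out, isolated nodes rewired
to one within-cluster partner.  The expression generator draws the
three additive components exactly; within-cluster biological
correlation is realised as b = σ_b(√ρ·z_cluster + √(1−ρ)·z_gene),
preserving the marginal SD for every ρ.  Default study conditions —
σ_b = 0.3, σ_ξ = 0.5 log2 units, 5 biological × 4 technical
replicates, baseline 8.0, one-fifth of clusters shifted in the second
condition — mirror a small two-condition microarray experiment with
moderate technical noise exceeding biological spread.

What the generator does *not* emulate: probe-level effects,
saturation, batch structure, count noise of RNA-seq, and the
heavy-tailed degree distribution and overlapping pathway membership of
real association networks.  Passing tests therefore demonstrate the
method's internal consistency and its behaviour under its own model
assumptions, not performance on any particular real platform.

Problem sizes used by the test suite and acceptance script — planted
networks of 300 nodes, expression panels of 2,000 genes, radii up to
80 — were chosen as the smallest scales at which the asymptotic
properties under test (1/√w noise scaling, window-power gain,
concordance saturation) are cleanly expressed.

## Known limitations

* The γ-mass-versus-random-baseline ratio on the default planted
  network is bounded near 4.9 by construction: ~8–9 % of edges are
  between-cluster at p_out = 0.005 and a random ordering already puts
  ~19 % of partner mass within distance 30 of a 300-gene list, so
  ratios of 5 or more are out of reach at these parameters regardless
  of how good the ordering is.
* Annealing is stochastic seriation, not exact optimisation; distinct
  seeds give distinct (near-)optimal orderings, and the published
  ordering of a large genome cannot be reproduced bit-for-bit without
  the original network snapshot and RNG history.
* Storey's π₀ estimator is reliable for thousands of P-values; for
  short families the BH column is the safer default.
* Relative (ratio) profiles assume a strictly positive reference; on
  data that can cross zero after normalisation, use differences of
  transcriptograms instead.
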