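# Methods

## Problem and overall procedure

Given a genes × samples matrix of real expression intensities (typically
log-scale microarray values), the package scores the degree of interaction
of every unordered gene pair, keeps pairs whose two scores agree within an
acceptance threshold θ, orients each kept pair, and returns a directed
weighted gene regulatory network per condition. Two conditions fitted on
the same gene set can be compared edge-by-edge.

Stages: read → (optional rank/select) → per-gene max–min normalization →
all-pairs bridged-RBM training → θ filter → Gaussian naive-Bayes
orientation → network assembly/export.

## Normalization

Each gene row g is rescaled to (g − min g)/(max g − min g), so every
non-constant row spans [0, 1] exactly and within-row order statistics are
preserved. The map is idempotent. A constant row has no defined rescaling;
it is mapped to all zeros (the conservative "no signal" encoding, avoiding
a 0/0) and a warning is logged. Normalization happens after any gene
selection, so each run's gene subset defines its own row ranges.

## The bridged RBM pair

Architecture. One single-layer RBM per gene, each with n visible and n
hidden units where n is the sample count, so both weight matrices are
n × n. Both matrices are initialized from a *single* uniform[−1/n, 1/n]
draw (W₂ is a copy of W₁); one bias vector, initialized to zero and never
updated, serves every propagation (the hidden bias exists only in the
diagnostic energy function E(v,h) = −v·W·h − b·v − c·h). The shared
initialization makes the two machines exactly exchangeable, which forces
the identical-input symmetry property below.

Per epoch:

1. One threshold vector t ~ U(0,1)ⁿ is drawn and shared by both machines
   (a per-unit vector, one fresh draw per epoch).
2. Forward: h = σ(b + g·W); the hidden state is h > t elementwise.
3. Backward: the visible reconstruction is σ(b + h_src·Wᵀ), where h_src is
   the machine's own forward activation at epoch 1 and the partner's
   previous-epoch activation from epoch 2 on — the "bridge" that makes
   each machine reconstruct its gene from the other gene's features. The
   reconstruction is re-propagated to σ(b + v̂·W). The transpose is the
   standard RBM weight-sharing contract; a `backward_uses_transpose=False`
   flag restores the literal same-orientation product (the two coincide
   for symmetric W).
4. Errors: sum of squared differences between each gene and its
   reconstruction.
5. Update: W += η·(g ⊗ h − v̂ ⊗ ĥ)/n for each machine — the difference of
   the data association (outer product of the raw gene with its forward
   hidden activation) and the reconstruction association, one
   contrastive-divergence-style step.

Strengths. At the final epoch, hidden units active in *both* machines are
"matched"; each gene's interaction strength is the mean of its activation
probabilities over matched units. If no unit is matched the strengths are
undefined (NaN) and the pair is unusable downstream.

Termination. Whichever fires first: (a) both errors ≤ `error_tol`
(converged); (b) |strength₁ − strength₂| > `weight_diff_break` (the pair
has diverged — training stops and the θ filter will reject it); (c)
`max_epochs`. Non-converged pairs are marked and excluded by the filter.

Hyperparameters and defaults:

| parameter | default | units / role |
|---|---|---|
| `learning_rate` | 0.1 | step size of the association update |
| `max_epochs` | 1000 | epoch cap |
| `error_tol` | 0.01 | SSE floor defining convergence |
| `weight_diff_break` | 0.01 | strength-divergence break |
| θ | 0.006 (range 0.004–0.016) | acceptance threshold on the strength gap |

The error floor, the divergence break and the θ range are part of the
method's definition. The learning rate, epoch cap and zero bias are not
pinned down by it; the defaults here are ordinary choices for
sigmoid-scale inputs and are configurable. Empirically, identical inputs
converge in ≈320 epochs at n = 6 under these defaults, so 1000 epochs
leaves headroom, while unrelated pairs hit the divergence break within a
few epochs.

Seeding. Every pair draws from its own `numpy` Generator seeded by
(global seed, SHA-256 of the sorted pair ids), so whole-matrix runs are
reproducible, independent of iteration order, and symmetric under swapping
the two genes.

Properties the tests pin down: identical gene vectors give *exactly* equal
strengths for every seed (shared initialization + shared thresholds);
swapping inputs swaps the result fields; with learning rate 0 the weights
never move; the loop replayed through the individual step operations
(forward, backward, associations, error, update) reproduces the result to
1e-12; epochs never exceed the cap and `converged` implies both errors at
or below the floor.

## Direction of regulation

For an accepted pair, each gene's **raw** values (not the normalized ones)
fit a univariate Gaussian: µ the arithmetic mean and σ the population
(divisor-n) standard deviation — divisor n is what reproduces the worked
example's printed σ. The score for "B regulates A" is the normal density
of A's mean value under B's fitted Gaussian; the higher-scoring direction
wins and the edge carries the regulator-side strength value. The point at
which the density is evaluated (the target's mean) is a design choice: the
simplest single-number summary of the target's vector, and it preserves
the worked example's ordering. The decision is equivalent to comparing
log σ and squared standardized mean distances in closed form, is invariant
to argument order, and resolves exact ties deterministically
(lexicographically smaller id reported as regulator, flagged `tie=True`).
A gene with zero variance has no valid Gaussian and raises.

## Filtering and network assembly

The θ comparison is inclusive (gap ≤ θ): the worked 4 × 4 example retains
its boundary pairs only under ≤. Retention is monotone and idempotent in
θ, so edge counts along an ascending θ grid are non-decreasing — the
qualitative edges-vs-threshold behaviour reported for the full-scale
experiments. Networks forbid self-loops and multiple edges over one
unordered pair. Two networks are compared by partitioning the union of
their unordered edge pairs into only-in-x / only-in-y /
shared-same-direction / shared-reversed-direction; the four classes are
disjoint and exhaustive.

## Gene ranking

Genes are ranked between two phenotype groups with a two-sided Wilcoxon
rank-sum test: mid-ranks for ties, tie-corrected variance, normal
approximation, no continuity correction, no multiple-testing correction —
the p-values only order the genes. At the smallest group sizes the normal
approximation is coarse: exhaustively over every no-tie group split with
at most 8 total samples, the worst absolute gap between the approximate
and the exact permutation p-value is 0.237 (at a 2 vs 3 split); the tests
assert agreement within 0.24. Ranking order within a fixed design is
unaffected, since the approximation is monotone in the rank-sum deviation.

## Synthetic data

The generator draws each gene's baseline as Normal(7, 1.2²) per sample
plus a per-gene offset — magnitudes chosen to mimic the ≈4–9 range of
log-scale microarray intensities in the embedded worked-example tables,
documented as an emulation, not a claim about the assay. A planted pair
rebuilds the target as effect × (regulator − its mean) + its own baseline
+ Normal(0, noise_sd) noise. Because max–min normalization removes affine
offsets, a low-noise planted pair yields near-identical normalized rows,
which is exactly the regime the paired RBM accepts. What passing tests on
this generator do **not** show: robustness to probe effects, saturation,
batch effects, heavy-tailed noise or missingness in real microarray data —
none of which are modelled.

## Embedded fixtures

Five small tables ship with the package: the 5 × 6 raw worked-example
matrix and its 4-dp normalized form (the printed normalized values are
truncations, so cross-checks use an absolute tolerance of 1e-4; the
observed maximum deviation is 8.3e-5), the 4 × 4 strength matrices before
and after threshold filtering (one cell, Gene3/Gene4, differs between the
two printings — 0.7 vs 0.6843; the filtering walk-through is only
consistent with 0.6843, which the filter tests use), and the 2 × 9 raw
rows of the direction worked example. The direction example's printed
densities are not reproducible from its own printed rows under any natural
evaluation point; only their ordering (and hence the regulator call) is
treated as ground truth.

## Problem sizes

Tests and the acceptance script run at deliberately small scale: matrices
of 5–12 genes and 6–50 samples, 20-seed property sweeps, 10-replicate
recovery runs. At these sizes the full suite completes in seconds while
still exercising every stage end to end.

## Known limitations

- The strength of a pair is only interpretable relative to the θ filter;
  the method yields no calibrated probability of interaction.
- Training is stochastic by design; different seeds change a minority of
  accepted edges at full scale. All entry points are seeded.
- The direction rule uses only two marginal Gaussians; it cannot express
  "no direction" beyond exact ties and ignores joint structure.
- The SOFT reader handles the minimal GDS dialect only (no GSE/GPL,
  no download); probe-to-gene collapsing, background correction and
  quantile/RMA normalization are out of scope.
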