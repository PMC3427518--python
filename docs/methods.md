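# Methods

This note records the modelling assumptions, numerical conventions and
design choices behind `pinabc`, at the level of detail a maintainer or a
careful user needs.

## Graphs and the spectral distance

Networks are simple undirected graphs on nodes `0..n-1`; isolated nodes
are first-class (the sampling model produces them, and they contribute
zero eigenvalues). The ABC distance between two equal-size graphs is the
Euclidean distance between their descending-sorted adjacency eigenvalues.
By Umeyama's theorem for Hermitian matrices this is a lower bound on the
edit distance minimized over node correspondences, where the edit distance
is counted over all *ordered* node pairs — each undirected edge mismatch
contributes 2. The brute-force permutation minimizer (`n ≤ 8`, factorial
enumeration) exists purely as a test oracle for the bound; the bound
itself is the production distance.

Conventions:

- Eigenvalues come from the standard symmetric eigensolver
  (`numpy.linalg.eigvalsh`); ties are left in solver order, which cannot
  affect the distance after sorting.
- "Distance zero" assertions use tolerance `1e-9 × node_count`.
- Unequal node counts raise by default; an opt-in `pad=True` inserts zero
  eigenvalues into the shorter spectrum. The intended workflow always
  compares equal sizes (simulations are grown/sampled to the data's size),
  so a mismatch normally means user error.
- The distance is used raw, not normalized by graph size; the adaptive
  tolerance schedule absorbs the scale.

## Growth models

All six simulators start from a seed graph — by default two nodes joined
by one edge, the smallest graph on which every move is defined; a small
ring is available, and the choice is immaterial to the tested behaviours
at the scales used. One `numpy.random.Generator` is threaded through every
stochastic choice in a fixed documented order (parent choice, per-edge
divergence draws over sorted neighbours, heterodimer draw, move-type draw,
Poisson draw, attachment draws), making runs bit-reproducible.

Simple-graph semantics are preserved by discarding, without retry, any
proposed edge that already exists or is a self-loop; this distorts the
nominal attachment probabilities by at most a few percent at the sizes
used (visible in the uniform-edge-addition mean edge count, which sits
~3–4% under the Poisson-mean sum at n = 500). Poisson draws for a step are
capped at the number of existing nodes. Preferential attachment on a
momentarily edgeless graph falls back to uniform node choice for that
step. Duplicated nodes that lose every edge remain as degree-zero nodes.

Specific conventions:

- DAC divergence: per original/copy edge pair, with probability 1 − δ both
  survive; otherwise a fair coin decides which single edge survives. Total
  edge count therefore never decreases.
- DACR's random-addition move places each of Poisson(m) edges between two
  uniformly chosen nodes of the whole current network (the new node
  included), so these edges need not touch the new node; DACL attaches all
  of them from the new node preferentially.
- Mixture models skip the Bernoulli move-choice draw when p is exactly 0
  or 1, so those degenerate cases consume the RNG stream identically to
  the pure models (tested as exact edge-set equality).
- GSF selects edges by rejection sampling against the running maximum
  weight — exact, O(1) amortized, and deterministic under a fixed stream.
  Newly created edges enter at weight 1 and are immediately selectable;
  the weight increment is ω per attachment. An attachment may select the
  same edge repeatedly within one step.

## ABC-SMC

- **Likelihood approximation.** R simulations per proposal; s counts those
  within tolerance. Default R = 1: for these models the extra variance is
  cheaper to counter with more particles than with repeats; R > 1 is fully
  supported.
- **Tolerance schedule.** Default is adaptive: ε_1 = ∞ (the first
  generation is an iid prior sample) and ε_{t+1} is the median (midpoint
  quantile convention) of generation t's accepted distances, clamped
  strictly below ε_t. An explicit strictly decreasing schedule can be
  supplied instead.
- **Kernel.** Independent zero-mean Gaussians per active parameter;
  bandwidth per parameter and generation is √(2 × weighted sample
  variance) of the previous population — the standard adaptive choice —
  floored at 1e-3 of the prior range so the kernel never degenerates when
  a marginal collapses. Out-of-prior proposals are redrawn (cap 100, then
  a new source particle is resampled), making the effective kernel a
  truncated Gaussian; densities in the weight denominator use the
  untruncated form, as is customary.
- **Weights.** w ∝ prior × s / Σ_j w_j K(θ″|θ_j), with w ← s in the first
  generation. The joint (model + parameter) weight divides by the model
  proposal mass Σ_m' P_{t-1}(m') K_M(m″|m') times the within-model kernel
  mixture; when the proposed model had no particles, its parameters are
  drawn fresh from the prior and the prior density replaces the mixture.
- **Model kernel.** Stay with probability 1 − p_switch (default 0.2), else
  move to a uniformly chosen other model. A model whose marginal hits zero
  can only be revisited through this kernel. On a model switch the
  parameter vector is re-proposed from the target model's own particles —
  parameters are not commensurable across models.
- **Single-model runs** are executed by the same joint engine with no RNG
  draws spent on model choice, so the single-model and joint samplers
  produce bit-identical traces for one model — this is a tested invariant,
  not an accident.
- **Failure mode.** A generation that exceeds `max_attempts_factor × N`
  proposals aborts with the tolerance and attempt count in the message.

Defaults (N = 1000 particles, T = 8 generations) suit production-size
runs; the bundled experiments use N = 80–100, T = 4–5, which pilot runs
showed sufficient for the self-consistency checks at n = 150–600 nodes.

## Sampling model and degree-zero correction

Proteins are assumed sampled uniformly without replacement from the full
proteome; the observed network is the induced subgraph. Simulations
therefore grow to the genome size N_T and are subsampled to the data's
N_S. A fixed edge survives with probability N_S(N_S−1)/(N_T(N_T−1)), and
two-stage subsampling is distributionally equal to direct subsampling —
both are tested. Induced subsamples contain degree-zero nodes that real
interactome data never show; this known mismatch is left in the distance
computation (no tractable alternative exists under uniform sampling) and
corrected only in predictive degree distributions, which are truncated to
k ≥ 1 and renormalized — the minimal correction consistent with the data
containing no isolated proteins. Any bias the distance inherits from the
retained degree-zero nodes is a documented caveat, not compensated.

## Model averaging

A statistic is pooled as Σ_m P(m|D) t_m. The posterior-predictive degree
distribution resamples final-generation particles by weight (default: one
draw per particle), simulates each through the growth-plus-sampling
pipeline, averages within models, pools with the marginal model posterior
(renormalized over the models that received draws), then applies the
degree-zero correction. Per-model vectors of different lengths are
zero-padded on the right, which preserves normalization. Raw parameters
are deliberately not averaged across models — their roles differ between
mechanisms.

## Synthetic data and what the tests show

There is no bundled real interactome; every experiment simulates its own
data from known models (the reference test case is a DACR network with
δ = 0.4, α = 0.25, p = 0.7, m = 3). The end-to-end experiments are
self-consistency checks at desk scale: data of 150–600 nodes, particle
populations of 80–100, and predictive reconstruction from 50% and 25%
node samples of a 600-node truth. The reconstruction experiment measures a
total-variation ordering of a few 1e-3, so it uses 400 posterior-predictive
simulations per fit — enough to push the predictive Monte Carlo error well
below the effect being ordered. Passing them shows the estimator
recovers generating parameters, discriminates dissimilar mechanisms, and
degrades as sampling thins — on clean model-generated data. It does not
show that any of the six mechanisms describes real interactomes, nor
does the uniform sampling model capture bait/prey experimental designs or
interaction-level false positives/negatives; those are out of scope.
Closely related mechanisms (DACR vs DACL) are often not distinguishable
from a single network realization — overlapping model posteriors there
are expected behaviour.

The preferential-attachment scaling check fits the degree tail (k ≥ 10)
with the discrete maximum-likelihood estimator a = 1 + n/Σ ln(k/(k_min −
0.5)). At n = 20,000 the fitted mean sits near 2.85 — the estimator sees
finite-size curvature below the asymptotic scaling coefficient 3, which
is why the acceptance band is ±0.3.

## Known limitations

- The spectral distance is a lower bound; two non-isomorphic graphs can
  in principle be cospectral, though this is immaterial against stochastic
  simulations.
- Eigendecomposition is O(n³); desk-scale networks (≤ ~2000 nodes) are
  comfortable, proteome-scale runs are compute-bound there.
- Uniform node sampling is the most parsimonious incompleteness model, not
  the most realistic.
- The brute-force edit-distance oracle is unusable beyond 8 nodes by
  design.
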