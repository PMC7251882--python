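# Methods

This note documents the models, algorithms, defaults and design choices
behind `wgdsig`, and what the synthetic test beds do and do not establish
about real data.

## The decision framework

Three duplication histories are distinguished for a single genome:

* **WGD-consistent** — a distinct interior peak in the node-weighted
  whole-paranome Ks distribution, anchor-pair Ks mass concentrated in that
  peak, and co-linear blocks residing predominantly on different scaffolds.
* **Segmental burst** — co-linear blocks exist, but their anchor Ks values
  are not clustered in a paranome peak, or the blocks sit mostly within
  single scaffolds (palindromes, tandem arrays).
* **SSD-like** — no blocks and no interior peak; the L-shaped distribution
  of continuous small-scale duplication and loss.

The qualitative criteria are made explicit as configurable thresholds: a
verdict is `WGD_consistent` iff (a) an interior peak exists, (b) ≥ 50% of
anchor-pair Ks weight falls inside the peak's supporting interval, and
(c) ≥ 50% of blocks are inter-scaffold. These two fractions are declared
defaults, not estimated quantities; the verdict record always carries the
underlying evidence so a user can re-threshold. When blocks exist but (b)
or (c) fails the verdict is `segmental_burst`; with no blocks it is
`SSD_like` without a peak and `inconclusive` with one.

## Paranome Ks estimation

**Clustering.** Markov Clustering on the similarity graph (edge weight =
bit score, E-value cutoff 1e-10 by default, 1e-5 in the relaxed regime),
inflation 2.0, pruning threshold 1e-5, at most 100 iterations. Self-loops
are set to each node's maximum incident weight to regularize the flow.
Clusters are read off attractor rows of the limit matrix; singletons are
discarded since they carry no duplication signal.

**Pairwise Ks.** The two-sequence likelihood under GY94 with F3x4 codon
frequencies is maximized over (t, κ, ω) by L-BFGS-B on log parameters with
three starts (guarding against local optima). t is in expected
substitutions per codon (the generator is normalized to unit flux); Ks and
Ka are decomposed with the standard convention that site proportions are
computed at ω = 1 and substitution proportions at the MLE, so Ka/Ks = ω̂
exactly. Estimates with Ks > 5 (or t at its bound) are flagged saturated.
Identical sequences short-circuit to Ks = 0. Alignments shorter than 30
codons (after gap-stripping) are rejected.

**Codon alignments.** An external guide protein alignment is back-threaded
onto the CDS; any column containing a gap is removed. CDS must translate
exactly to the protein under the standard code (a trailing stop codon is
tolerated, an internal one is an error).

**Node weighting.** Each internal node of the family tree is one
duplication event. Pairs are grouped by the most recent common ancestor of
their two genes; each pair at a node carries weight 1/(pairs at that node)
and the event's consensus Ks is their mean, so per-node weights sum to 1
and the distribution counts events, not pairs. Saturated pairs are excluded
*before* averaging by default (`exclude_saturated_before=False` defers
removal to the event-level (0, 5] filter); no within-node outlier trimming
is applied beyond this. Family trees may be supplied externally; the
fallback is neighbor joining on protein p-distances, which suffices because
only the topology's LCA structure matters.

**Peak detection.** Weighted Gaussian KDE with boundary reflection at
Ks = 0 (without reflection the truncated L-shaped density acquires a
spurious interior mode at roughly one bandwidth). The bandwidth follows
Silverman's rule with the total event weight as the sample size — invariant
under splitting an event's weight across pairs — floored at 0.05 Ks. Local
maxima at Ks ≥ 0.1 with prominence ≥ 10% of the maximum interior density
are reported; the exclusion window keeps the SSD boundary mode from being
called a WGD peak. Peak mass share is the event weight inside the interval
between the flanking density minima. At least 200 total event weight is
required.

## Co-linearity

Genes get 0-based ranks per scaffold by start coordinate (ties broken by
id). Deduplicated homolog hits are placed on the rank×rank grid per
scaffold pair (self-hits dropped, intra-scaffold hits canonicalized to the
upper triangle, which masks the main diagonal). For each orientation
(parallel, and inverted via negated second coordinate) the best chain is
found by dynamic programming: +50 per anchor, −1 per unit of Manhattan rank
distance beyond the perfect diagonal step, extension allowed only while
consecutive anchors are within `max_gap` (25 stringent / 40 relaxed).
Chains are extracted greedily (best first, across both orientations); a
best chain below the seed size (5 stringent / 3 relaxed) retires its hits
without being reported, which resolves overlaps by score then length.
Tie-breaks are fully deterministic (smallest hit index), and the
implementation is property-tested against exhaustive chain enumeration on
small grids.

The cited gap parameter is interpreted as a Manhattan distance in
*gene-rank* units — the natural metric of rank-grid chaining; a
tool-specific gap count is the plausible alternative reading.

Block topology: `inter_scaffold` iff the two copies lie on different
scaffolds; intra-scaffold blocks are `palindrome` when inverted (the formal
criterion adopted for "palindrome") and `tandem_array` when parallel.
Classification precedence is anchor > tandem > dispersed, with tandem
defined as same-scaffold rank distance ≤ 1 (adjacent) by default.

A note on orientation symmetries: reversing the coordinate system of *one*
scaffold flips the orientation of inter-scaffold blocks touching it while
preserving membership; reversing *both* scaffolds (or reversing the single
scaffold of an intra-scaffold block) preserves orientation, because
palindromes and tandem arrays are mirror-symmetric. The test suite checks
the one-scaffold version.

## Coverage diagnostics

For each candidate block region the mean per-base depth is compared with
the means of `n_random` (default 1000) same-length regions sampled
uniformly over start positions genome-wide (scaffolds weighted by eligible
starts; regions never cross a scaffold end). The flag criterion uses the
normal-assumption *distributional* CI of region means (mean ± 1.96 sd): a
block below the lower bound is a haplotig suspect, giving a nominal
one-sided error of 2.5% under the null, which the suite verifies by Monte
Carlo. The CI of the mean (±1.96 sd/√n) and the empirical 2.5/97.5
percentiles are reported alongside, since the literature describes this
test loosely enough to admit either reading; the sd/√n interval would flag
half of all null blocks and is therefore not used for flagging.

## The DL+WGD count model

Families evolve along a dated species tree under a linear birth-death
process with per-branch duplication rate λ_b and loss rate μ_b
(events/gene lineage/My) and a geometric(η) prior (support {1, 2, ...},
mean 1/η — families must be non-empty at the root) on the root lineage
count. A WGD on a branch transforms the count by n → n + Binomial(n, q).
The family likelihood is a pruning recursion over count states 0..B with
exact per-lineage transition laws (extinction probability α, geometric tail
β; the critical case λ = μ and the pure-birth/death limits handled
analytically; n-lineage transitions by convolution, which is exact for all
entries up to the bound). The likelihood is conditioned on the family being
observable — at least one survivor in each clade stemming from the root —
matching the family filter, via inclusion-exclusion over clade extinction
probabilities.

This is a *gene-count* likelihood under the same generative model used by
gene-tree reconciliation methods. It deliberately ignores gene-tree
topologies: hypotheses about WGD placement are tested against count
patterns only, which is weaker per family but self-contained, exactly
reproducible, and verifiable against brute-force enumeration. Gene-tree
amalgamation is explicitly out of scope.

**Truncation.** The default state bound is 6 × (largest observed family
count) + 10. The smaller bound 4 × max + 10 leaks ≈ 2e-6 of probability
mass on multi-hundred-My branches at duplication rates near 0.002/My,
violating the 1e-6 leak criterion we enforce; leak is monitored on all
states up to twice the largest observed count and raises a `TruncationError`
rather than silently biasing the likelihood. Increasing the bound further
changes log-likelihoods by < 1e-6.

**Priors.** Constant structure: λ, μ ~ Exponential(mean 0.005
events/gene/My), η ~ Beta(10, 2). Independent rates: branch log-rates iid
Normal(log m, σ²) with m ~ Exponential(mean 0.5) and σ² ~
InverseGamma(5, 1). GBM: child log-rate ~ Normal(parent log-rate − ν²t/2,
ν²t) with ν = 0.1 — the drift correction makes the rate a martingale in
expectation. Retention rates are Uniform(0, 1) throughout.

**MCMC.** Blockwise adaptive random-walk Metropolis on unconstrained
parameters (log rates, logit η and q), with per-block proposal scales
adapted toward 30% acceptance during burn-in and frozen afterwards.
Defaults are 11,000 generations with 1000 burn-in; optional pilot chains on
random 1000-family subsets feed the split-chain convergence statistic, and
the two root-adjacent branches can be constrained to share rates (useful
when a long outgroup branch destabilizes branch-wise models). WGD support
requires the 95% credible q-interval's lower bound to exceed 0.01; a crude
bimodality check (posterior mass both below 0.01 and above 0.1) logs a
warning, since retention-rate posteriors are known to go multimodal. WGDs
default to the midpoint of their branch when no age is given.

## Synthetic data: what it emulates, and what it does not

The generator realizes exactly the statistical structure the analyses
assume: Gillespie-exact birth-death count evolution with a replayable event
log; Ks samples as a truncated-exponential SSD background (the
exponential-survival decay is a modeling convention — no generative law for
SSD Ks decay is established — and is fit/recovered as such in tests) plus
Gaussian pulses truncated to (0, 5]; genome layouts whose planted blocks
are contiguous rank runs, spaced ≥ 45 ranks apart so chaining can recover
the registry exactly; negative-binomial coverage (variance m + αm²,
deterministic at α = 0, optionally drawn per fixed-size window so bedgraph
exports stay compact).

Real genomes violate these idealizations in known ways: Ks estimates carry
alignment and saturation error rather than being drawn from the mixture
directly; co-linear blocks are eroded by gene loss and rearrangement rather
than contiguous; tandem arrays recombine; coverage has mappability
structure. Passing the recovery suite therefore demonstrates correctness of
the algorithms under their stated models, not robustness to every artefact
of real assemblies — the thresholds of the decision framework remain
analysis choices the user should sensitivity-check on real data.

**Default study conditions.** The phylo scenario uses a nine-taxon
ultrametric tree of 350 My depth, λ = μ = 0.002 events/gene/My (the order
of magnitude typical of insect paranomes), η = 0.8 and 1000 families;
recovery runs in the test suite use shortened chains (1200 generations, 300
burn-in), which the sharp likelihood at 1000 families makes sufficient for
the 15% recovery tolerance. Genome scenarios use 10 scaffolds × 250 genes,
3000 Ks events, and coverage at 100× with 5% overdispersion.

## Numerical and degenerate-input choices

* Zero-length branches, λ = 0, μ = 0 and t = 0 all reduce to their exact
  limits (identity or pure-death kernels); with all branch lengths 0 the
  likelihood collapses to the conditioned root prior.
* The GY94 optimizer bounds t ∈ [1e-4, 30], κ ∈ [0.1, 30], ω ∈ [1e-3, 20];
  F3x4 frequencies are floored at 1e-6 and renormalized so observed codons
  never get zero probability.
* MCL convergence is declared at max-entry change < 1e-8; non-convergence
  after 100 iterations is an error, not a silent result.
* Histogram bins are right-closed, (0, w], ..., matching the (0, 5] event
  filter, so mass conservation is exact under any bin width.
* All randomness flows from a single seed through `numpy.random.SeedSequence`
  spawning; reruns are byte-identical.

## Known limitations

* No cross-species synteny, mixture-model Ks dating, or Ks rate
  correction; very ancient WGDs outside the usable Ks window are not
  detectable, by construction.
* The count-level likelihood cannot locate a WGD more precisely than the
  branch carrying the hypothesis, and retention estimates for hypotheses on
  long isolated branches inherit the large posterior variance familiar
  from reconciliation analyses.
* The independent-rates and GBM samplers use joint random-walk updates on
  all branch rates; for trees much larger than ~10 taxa a more structured
  sampler would be needed for efficient mixing.
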