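# Methods

## Model and assumptions

The package models a drug's anticancer efficacy as a monotone function of
the set of targets it inhibits. Two set-theoretic assumptions drive all
predictions: a drug inhibiting a superset of a successful drug's targets is
at least as successful, and a drug inhibiting a subset of an unsuccessful
drug's targets is at most as successful. These hold when targeted
inhibitors act by switching off survival signaling pathways whose topology
is not rewired on the time scale of the sensitivity assay; they do not hold
for broadly cytotoxic agents, for strongly dose-limited effects, or when
off-target activities outside the profiled target space dominate the
response.

Predictions proceed in strict precedence: identical training profiles
(mean of their efficacies), then a lower bound from subset profiles
(maximization rule) and an upper bound from superset profiles
(minimization rule), averaged when both exist. When only one bound can be
learned the prediction equals that bound — the natural reading of the
bound semantics; the alternative (declaring single-bound states
non-identifiable) would discard usable evidence. States with neither bound
are non-identifiable and carried as NaN throughout.

Two choices in the averaging rules were genuinely open and are fixed as
follows. The qualifying drugs of each bound ({k_max} plus subset-profile
drugs that are supersets of T(k_max) with lower efficacy, and the
symmetric superset side) are pooled into a *single arithmetic mean*; a
pairwise-iterative running mean would make the estimate depend on drug
order, which contradicts the order-free set semantics and would break the
determinism property we test. Ties in the choice of k_max/k_min are broken
by the lowest drug index; with continuous efficacy scores ties have
measure zero, and the tie-break only matters for hand-constructed data.

## The probabilistic baseline

The comparison baseline (PKIM, after Pal & Berlow) is re-implemented from
its verbal description — the efficacy accumulated from subset profiles
relative to the efficacy loss in superset profiles — as
`clip(mean(y | subsets) − mean(1−y | supersets), 0, 1)`, non-determinable
when either family is empty. Subset/superset are taken non-strictly and
weighted equally. The original algebra is not reproduced bit-for-bit; the
implementation is validated by two independent codings (a vectorized
relation-matrix path and a literal set-scanning path) that must agree
exactly. One consequence of this reconstruction: on degenerate matrices
where all profiles coincide, the baseline's estimate
`clip(2·mean(y)−1, 0, 1)` differs from the identical-set mean, so the two
rules do not coincide there; benchmark grids therefore report whatever the
rules actually produce rather than assuming equality at the degenerate
thresholds.

## Selection objective and search

The objective is the mean absolute leave-one-out (LOO) prediction error of
the model restricted to a candidate target set. Non-identifiable LOO
predictions contribute `|y_i − 0.5|` by default — the error of a maximally
uninformative guess — with `skip` and `worst` (error 1) as configurable
alternatives; the same policy is applied to both rules so comparisons are
like-for-like.

The floating search follows the classic SFFS scheme: initialization at the
exhaustively best single target; inclusion of the error-minimizing target
until no addition strictly decreases the error; conditional exclusion of
the least-harmful target, kept only when it strictly beats the best error
previously achieved at the smaller cardinality, continued while it keeps
beating historical bests. "Strictly" means an improvement larger than an
absolute tolerance of 1e-12, which prevents floating-point livelock;
termination is additionally guarded by a move limit (1e5) that raises
loudly rather than cycling. Equal-error candidates are resolved to the
lowest column index. The result reported is the best (set, error) pair
seen anywhere in the run, so the reported error never exceeds the
initialization error even though floating exclusions may transiently
accept a worse current state. During inclusion sweeps the pairwise
subset-relation matrix for S ∪ {t} is derived incrementally from the
cached matrix for S (one elementwise conjunction); tests assert this
equals recomputation from scratch on every accepted step.

Relation computation is a single integer matrix product
(`X · (1−X)ᵀ == 0`), so no bitmask width limit applies to the engine
itself; the selection default `max_k = min(m, 64)` simply bounds the
search depth. Exhaustive enumeration is guarded to candidate pools of at
most 20 targets.

The random-restart facility draws uniformly random *single-target* starts
(the natural reading of random starting points for a forward search);
random subset starts can be passed explicitly via `start=`.

## Synergy, synthetic lethality, networks

The synergy null is Bliss independence on the [0,1] efficacy scale,
`y_A + y_B − y_A·y_B` (multiplicative on survival fractions), with the
pure product `y_A·y_B` available via `null="product"`. The two nulls agree
whenever either single efficacy is 0 — including the published top
drug-pair rows used as checks — so observed data cannot disambiguate them;
the chosen null is recorded in every synergy output. Drug-pair synergy
averages the cross target-pair scores, skipping same-node pairs (a node
cannot be combined with itself) and NaN pairs.

The synthetic-lethality score groups drugs by their inhibition state over
a target pair and compares three pooled structures — parallel
({11} vs rest), series ({01,10,11} vs {00}) and singleton (the better of
the two single-target splits) — by within-group total sum of squares. The
ratio `min(TSS_series, TSS_singleton)/TSS_parallel` is oriented so that
larger means stronger synthetic lethality, with an infinity sentinel when
the parallel model fits perfectly. The "singleton" reading as the best
single-target split (rather than "no structure at all") is a deliberate
choice: it makes the score penalize pairs explainable by one essential
target, which is the intended contrast with parallel redundancy. The
anchor-partner ranking uses the anchor's self-pair as baseline and returns
only strictly-above-baseline partners; targets inhibited by the same drug
set receive tied ranks.

Network construction binarizes the predicted efficacy function at a
threshold θ (non-identifiable states count as ineffective), repairs any
non-monotonicity by monotone closure (reporting the repaired states via a
warning), extracts prime implicants (minimal effective sets) and computes
their minimal hitting sets by Berge's incremental transversal algorithm.
The resulting parallel pathways reproduce the closed binarized function
exactly; this round-trip is verified at build time for every enumerated
state. A function that is effective at the empty state (θ below the
no-inhibition baseline) yields an empty pathway family, under which every
state is trivially effective. DOT output is written by a small plain-text
serializer; GraphML via networkx.

## Synthetic data: what it emulates and what it does not

`simulate_dataset` reproduces the benchmark study conditions: 100 drugs ×
10 targets, binding affinities and efficacies both uniform on [0,1] — the
maximally uncertain regime in which drug-target structure carries no
signal and all performance differences come from how the rules exploit
subset/superset overlap. Binarization thresholds 0–0.79 in 0.01 steps (the
window over which the benchmark's summary improvement is defined; at
higher thresholds profiles empty out and both rules degenerate).
Efficacies are used directly as draws on [0,1] without re-scaling. Each
(seed, replicate) pair seeds an independent generator stream, so reports
are bit-identical across runs.

`planted_network_dataset` draws random Bernoulli(0.5) profiles and sets
efficacy to 1 exactly when the profile hits every pathway of a hidden
family, plus optional clipped Gaussian noise — the ground truth that
selection and network construction should recover. A `design="complete"`
option enumerates the full factorial of profiles instead; this guarantees
every state restricted to a proper subset of targets recurs, which is the
premise under which the noise-free planted function is exactly recoverable
in LOO (a unique minimal-effective state, by contrast, is predicted at the
bound average 0.5). Neither generator emulates real screening data:
measured efficacies are noisy and correlated across similar compounds,
binding profiles are far from uniform, and target spaces are much larger
and sparser. Passing the simulated benchmarks shows the rules and searches
behave as designed under their own assumptions, not that real cell-line
accuracy will match.

The benchmark's figures of merit are defined explicitly (and printed in
every report): accuracy = 1 − mean LOO error; relative improvement =
100·(acc_rules − acc_baseline)/acc_baseline, averaged per replicate over
the threshold grid and then over replicates, with empirical percentile 95%
CIs. The search-optimality experiment runs all three strategies under the
same (rule-engine) objective so that distances to the exhaustive optimum
measure search quality, not rule differences; relative distance is
(err_alg − err_opt)/err_opt, reported only where the optimum is nonzero.
Benchmark problem sizes in the shipped tests (50 replicates for the sweep;
pools of ≤4 targets for search-vs-exhaustive) were chosen to keep the
default suite fast while leaving the statistics stable.

## Data handling conventions

Efficacy panels are min–max scaled so the least/most efficacious drug maps
to 0/1; constant panels are rejected as degenerate. Kd values (nM) are
inverse-log-scaled by `s = 1 − log10(Kd)/log10(10000)`, clipped to [0,1]
(1 at 1 nM, 0 at the 10 µM assay ceiling); the formula is exposed as a
configurable transform since published analyses differ in the ceiling.
Binarization ties count as inhibited (≥ for scaled affinities, ≤ for the
drug-specific 50-fold-of-minimal-Kd rule). Missing affinities mean "not
binding". Targets inhibited by fewer than 2 drugs are filtered (no
interaction information), and targets inhibited by exactly the same drugs
are collapsed into "/"-joined meta-targets, which the prediction rules
cannot distinguish by construction. Matrices are always drugs × targets.

siRNA screens: replicates disagreeing by more than 15 percentage points
(absolute, on the 0–100 scale) drop the edge-well replicate; when zero or
two edge flags make the rule inapplicable both replicates are kept with a
warning — the conservative choice that never silently discards data.
Single knockdowns are normalized by averaging with the weaker doubles that
contain the gene. Percentage/fraction conversions happen in exactly one
place so measured (0–100) and predicted (0–1) synergies are never mixed;
grouping thresholds (e.g. the High/Low predicted-efficacy split) are
computed from the data at hand rather than hard-coded.

## Known limitations

- Binary inhibition profiles only: dose dependence and partial inhibition
  are out of scope by design.
- The baseline is a reconstruction from a verbal description; absolute
  baseline numbers should be read with that caveat (comparisons use the
  same LOO policy on both sides).
- Full efficacy-matrix enumeration is exponential in |S*| (guarded at 20);
  pairwise mode covers the synergy workflow for larger sets.
- Non-identifiable states are imputed (0.5 by default) in scalar
  prediction output; downstream consumers can detect them via
  `PredictionDetail` or NaNs in the efficacy matrix.
- Selection tie-breaking by column order makes results reproducible but
  means permuting target columns can change which of several equal-error
  sets is reported.
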