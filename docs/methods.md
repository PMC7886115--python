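# Methods

## The design calculus

A design is a weighted inventory of item sequences (length 2 or 3) with
presentation frequencies summing to 1. All probabilities are ratios of
frequency sums:

* **Positional first-order TP** `p(b|a)` at positions *i→i+1*: total frequency
  of sequences with `a` at position *i* and `b` at *i+1*, divided by the total
  frequency of sequences with `a` at position *i*. Positions 1→2 and 2→3 are
  computed separately because the design tabulates them separately; a
  position-agnostic mode is provided for mixed-length worked examples.
* **Position-agnostic first-order TP**: every occurrence of the conditioning
  item counts in the denominator, *including sequence-final occurrences with
  no successor*. This is the convention under which a mixture of two- and
  three-course menus (1/5 Salad–Dish, 1/5 Salad–Dish–Dessert, 3/5
  Dish–Dessert) gives p(Dessert|Dish) = .80 — a dessert follows a dish four
  times out of five — and p(Dish|Salad) = 1.
* **Second-order TP** `p(c|a,b)`: sequences beginning with the pair (a, b)
  that stop after two items count in the denominator, so
  p(Dessert|Salad, Dish) = .5 in the same mixture.
* **Non-adjacent TP** `p(c|a)` conditions on the first item and predicts the
  third.

A conditioning context that never occurs raises `UndefinedContextError`
rather than returning 0 or NaN: downstream prediction code must distinguish
"never seen" from "seen but never followed". Internal arithmetic is plain
float ratios; two-decimal rounding happens only in presentation helpers.

**XOR validation.** A triplet design is XOR iff every triplet's second-order
TP is 1 and, for every triplet, neither `p(third|second)` (positional 2→3)
nor `p(third|first)` (non-adjacent) equals 1. Violations are reported as
human-readable strings, not exceptions.

**Switch construction** searches all permutations of third items over the
triplet prefixes, keeping candidates that (i) preserve the multiset of 2→3
ordered pairs (1→2 pairs are untouched by construction), (ii) share no
triplet with the original, (iii) are themselves valid XOR designs; switched
triplets inherit the frequency of the original triplet with the same prefix.
Among multiple candidates the lexicographically first by label is returned;
for the canonical design the solution {ABF, AEC, DBC, DEF} is unique. A
deliberate consequence of frequency inheritance is that the *values* of the
2→3 first-order TPs change between phases even though the pair *inventory*
does not (e.g. p(F|B) moves from .38 to .62); `switch_tp_report()` tabulates
both phases side by side and flags the changed pairs instead of resolving
which sense of "unchanged first-order TPs" is intended. Analysis covariates
attach the learning-phase pair TPs to switch trials — the TP as experienced
during learning.

## Scheduling

* **Training phase** (default 224 trials of three pairwise-distinct positions
  on the 3×3 grid): a greedy max-deficit chaining guarantees each of the 72
  ordered position pairs at least ⌊448/72⌋ = 6 occurrences (72·6 = 432 of the
  448 available transitions), the remainder falling at random; ties are
  broken by the seeded generator, and a bounded retry loop raises
  `ScheduleInfeasibleError` if the requested minimum coverage exceeds
  capacity. A fully random mode is available since balanced coverage is a
  choice, not a given.
* **Yoking** operationalises "transition times as close as possible" as
  minimising the *range* (max − min) of the eight design-transition times
  over all 9·8·…·4 = 60 480 injective item→position assignments, searched
  exhaustively (vectorised; a variance objective is available). Ties break
  to the lexicographically first assignment. The optimum need not be unique
  in mapping terms: the canonical design has an item-relabelling symmetry
  (A↔D, C↔F) that maps the transition set onto itself.
* **Learning/switch blocks**: per-block counts are the largest-remainder
  apportionment of frequency × block size — exactly (16, 10, 10, 4) for the
  canonical design at block size 40, so empirical sequence proportions and
  first-order TPs on a generated schedule equal the design values exactly.
  Within-block order is a uniform shuffle with no adjacency constraints.
  The switch phase is one block of 40 trials built from the switched design
  with the same allocation rule; its length is a package choice (the
  protocol's learning curves plot it as a single final block).

## The synthetic cohort

The generator is a *stand-in* for human data collection, not a claimed
mechanism. Its job is to emit trial tables with the statistical structure
the analysis pipeline is designed to detect: RTs decreasing over blocks,
late-learning TT1 ordered by first-order TP (not frequency), TT2 faster
than TT1 late in learning, a TT2 switch cost, and no switch cost for the
lowest-TP sequence.

Each participant tracks running transitional probabilities with pseudocount
estimators, `p̂ = (count + s) / (context_count + s·K)` with alphabet size
K = 6, and responds

```
TT1 = b_i + m·d(pos1, pos2) − g1·p̂(2nd|1st) + ε
TT2 = b_i + m·d(pos2, pos3) − g1·p̂(3rd|2nd) − g2·p̂(3rd|1st,2nd)·1[p̂(3rd|2nd) ≥ w2] + ε
```

with per-participant baseline `b_i ~ N(baseline, baseline_sd)`, Euclidean
grid distance `d`, Gaussian noise `ε`, an optional multiplicative lognormal
term, and a 50 ms floor. Unseen contexts contribute predictability 0, so
trial 1 is well defined. An optional frequency drive (`freq_gain` times the
running sequence-frequency estimate) generates frequency-driven rather than
TP-driven data for model-recovery checks.

Defaults (chosen a priori by power analysis so the qualitative structure is
reliably detectable at cohort size 20, and then frozen): baseline 500 ms,
baseline SD 40 ms, motor cost 30 ms per grid unit, g1 = 300 ms, g2 = 120 ms,
noise SD 35 ms, w2 = .3, pseudocount s = 2. Two of these deserve comment:

* **Pseudocount 2.** A heavy pseudocount shrinks low-exposure contexts
  toward the uniform prior, which makes late-block RT order follow context
  *frequency* rather than true TP — the opposite of the structure to be
  emulated. At s = 2 the block-10 running estimates sit within ~.05 of the
  true TPs for every context, so the late TT1 ordering is
  .71 < .62 < .38 < .29 by construction, while early blocks still show the
  crossing block-by-TP interaction for the TP-versus-frequency pair
  (DBF starts slightly slower than ABC, then overtakes it).
* **The w2 gate at .3** reproduces the observation that a sufficiently low
  first-order TP precludes deployment of second-order knowledge: the
  lowest-TP sequence's 2→3 running estimate converges to ≈ .28 < .3, so its
  (perfect) second-order predictor never engages and it alone shows no
  switch cost. Setting w2 = 0 disables the gate.

With these defaults ≥ 98% of simulated RTs fall inside the [150, 850] ms
analysis window, so the outlier filter removes well under the few percent a
human data set loses; the generator makes no attempt to emulate human
outlier *rates*, only the structure of the retained data.

What the generator does **not** emulate: right-skewed RT distributions
(unless the lognormal term is enabled), fatigue and drift, within-participant
autocorrelation beyond the learned estimates, error trials, and any
frequency-conditioned attention effects. Passing tests therefore certify the
*pipeline* — that the analyses detect structure when it is present and stay
calibrated when it is absent — not any claim about human learners.

## Preprocessing

The primary filter is the fixed [150, 850] ms window with **inclusive**
bounds; a ±k·SD window (default k = 2) is offered as an alternative,
computed per transition type when that column is present and globally
otherwise (the per-participant variant is deliberately not guessed at).
Filtering is idempotent, kept ∪ removed partitions the input, and the
removal report carries overall and per-transition-type fractions. The
wide-to-long reshape emits one TT1 and one TT2 row per trial, attaching the
sequence frequency and the transition-specific first-order TP (1→2 for TT1
rows, 2→3 for TT2 rows) from the learning design; it is lossless — pivoting
back reproduces the wide table.

## Statistics

All models are trial-level linear mixed models with a **random intercept per
participant**, fitted by REML via `statsmodels` `MixedLM`. The random-effects
structure is the minimal one consistent with repeated measures; random block
slopes were considered and left out because every reported contrast is
within-participant and trial counts per participant are large. Each
fixed-effect term gets a Wald F computed from the fixed-effects covariance
(`F = b'V⁻¹b / q`), with the **residual denominator-df approximation**
`nobs − k_fixed`; with thousands of trial-level rows this df choice is
immaterial to the reported p-values. An approximate sum of squares
`F·q·σ̂²` is reported so tables read like conventional mixed-ANOVA output.
Exactly matching any particular software's denominator df is a non-goal.
AIC is always taken from a maximum-likelihood refit. Singular or
non-converged fits are flagged, not raised.

First-order TP enters the factorial contrasts as a **categorical** factor
(the four sequences), mirroring a four-level design factor. The AIC
comparison instead uses **numeric** frequency and TP covariates: with
categorical coding the frequency × TP model is rank deficient (TP level
determines frequency level), while numeric coding keeps all three candidate
models full rank and preserves the recovery logic — the equal-frequency pair
(AEF/DBF) forces a frequency-only model to predict equal RTs where TP-driven
data differ, and vice versa.

The contrast battery mirrors the experiment's analysis surface: global
TT1-vs-TT2; first-block transition-type × TP; block effects on TT1 and TT2;
the equal-frequency TT1 pair (block × TP interaction); the TP-versus-
frequency TT1 pair (highest-TP vs most-frequent sequence); the TT2 switch
cost (last learning block vs switch block); block × TP on TT2; the
three-highest-TP equivalence; and the lowest-TP follow-ups. Subsets are
derived from the covariates in the table itself, so the battery applies to
any four-sequence design with one equal-frequency pair. α = .05 throughout,
with no multiplicity correction, matching the analysis surface being
reproduced.

## Validation strategy and problem sizes

The experiment's published F statistics derive from the human data deposit
and are not reproducible from a synthetic cohort; the pipeline is validated
distributionally instead, with every threshold fixed in advance:

* **Type-I calibration**: 300 null cohorts (all gains and the motor cost set
  to 0, so no sequence, block, transition or phase effect exists), each with
  6 participants × 3 learning blocks + switch; every contrast's primary-term
  rejection rate at α = .05 must lie within 3 Monte-Carlo standard errors of
  .05 (≈ [.012, .088]). The motor cost is removed from the null because
  residual movement-time differences between sequences after yoking are a
  real effect, not a false positive.
* **Power**: 20 default-parameter cohorts of 20 participants; the
  equal-frequency interaction, the TP-versus-frequency interaction and the
  switch cost must each be detected in ≥ 80% of replicates.
* **AIC recovery**: 20 cohorts of 8 participants per condition; TP-only
  generated data must rank block × TP at or above block × frequency in
  ≥ 90% of replicates, and symmetrically for frequency-only data.
* **Estimator exactness**: after one full 400-trial schedule the running
  unsmoothed estimates equal brute-force count ratios exactly (integer
  per-block allocations make them equal the design TPs exactly).
* **Yoking optimality**: on 10 random transition-time matrices the
  vectorised exhaustive search must agree with an independent pure-Python
  re-enumeration of all 60 480 assignments.

Replicate counts and cohort sizes are the package's own choices, made to
keep the full suite fast while leaving the Monte-Carlo bands meaningful;
they are stated here so the uncertainty attached to each check is explicit.

## Known limitations

* The calculus covers sequences of length ≤ 3; it is not an n-gram toolkit.
* The switch search enumerates permutations of third items (4! for four
  triplets); designs needing other switch topologies are out of scope.
* Wald F with residual df is mildly liberal in small-group, few-trial
  settings; the calibration check covers the regimes used here, not all
  regimes.
* The generator's independence across trials (given the running estimates)
  understates the autocorrelation of real RT series, so real-data power will
  be lower than simulated power at equal n.
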