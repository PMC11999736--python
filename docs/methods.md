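# Methods

## Reaction, recovery and enrichment

All kinetics are first order.  A species with amplitude *A* ∈ (0, 1]
and relative rate *k* > 0 (scaled so the best catalyst has *k* = 1)
reacts by scaled time τ with probability *A*(1 − e^(−τk)); the amplitude
absorbs misfolding — the fraction 1 − *A* is kinetically trapped and
never reacts within the experiment.  Reacted molecules survive the
separation and processing steps with probability *Q*, identical for all
species.  Background sequences use *A* = 1 (uncatalysed chemistry does
not depend on folding) and a small relative rate *k*_back.  An artefact
is recovered with a τ-independent probability *R*_art because it is
captured by the separation step itself rather than by reacting.

Working defaults throughout the package: *Q* = 0.2, *k*_back = 10⁻³,
initial frequency 10⁻¹⁴ per functional species.  These are the
conditions of the package's worked examples and tests; all are plain
constructor arguments.

Probabilities are evaluated with `expm1` so that the high-stringency
regime (τ ≪ 1, where *R* ≈ *QAk*τ and the enrichment ceiling
*A·k*cat/*k*back is approached) keeps full relative precision;
the τ → 0 ceiling test at τ = 10⁻⁸ requires this.  τ = ∞ is accepted as
a saturation sentinel.

## First-round statistics

Copy numbers of a given library sequence entering round 1 are treated
as Poisson with mean *c* = *N*_RNA/*N*_DNA, giving survival
1 − e^(−QA·c).  `min_copies_for_confidence` searches integers around
the real root −ln(1 − confidence)/QA rather than taking a ceiling, so
exact boundaries (confidence 0.95 at QA = 1, where the root is 2.9957)
cannot go off by one.  Recovered counts are binomial(N, R); the mode is
taken as the argmax of the exact pmf with adjacent ties broken toward
the smaller count — the conservative choice when the mode is used to
flag probable loss.  Sampling uses a per-setup `numpy` Generator so
interleaved draws elsewhere cannot shift the stream.

## Multi-round dynamics

The frequency recursion p·R/Σp·R is evolved in plain float64 with
renormalization every round.  Frequencies in all regimes the model
covers stay far above the ~10⁻³⁰⁸ underflow floor for the round counts
of interest (a species driven below it is physically extinct and clamps
to 0), so a single linear code path is used rather than a log-space
representation.  Rows of every trajectory sum to 1 within 10⁻¹²;
a round whose mean recovery is exactly 0 raises `DegenerateRoundError`
instead of returning NaNs.

Stringency schedules are expanded once to an explicit per-round τ list.
The stepped form (τ₀, factor, first decay round) reproduces the
standard protocol "τ = 5 for rounds 1–5, then ÷5 per round".

Counter-selection applies the two steps in a fixed order — counter
first, then positive — with per-round pass probability
(1 − R_without(τ_c))·R_with(τ_p); the order does not change the product.
Species declare one of three cofactor behaviours: `constitutive` (same
parameters either way), `dependent` (behaves as background without the
cofactor), `leaky` (rate multiplied by a leak factor, default 1/2,
without it).  The two steps may use different τ schedules.

`detect_crossings` reports strict sign changes of pairwise catalyst
frequency differences between consecutive rounds; exact ties (e.g. the
all-equal initial state) are not crossings.  Under constant τ pairwise
ratios are exactly geometric, so no crossings can occur — this is
asserted as a property test.

## Structure-match combinatorics

A structure constraint is (Lstr, conserved sites, base pairs, break
points, 5′ anchoring) with 1-based coordinates in files and messages.
The alphabet is RNA; T is normalized to U on input.  Canonical pairs
are GC, CG, AU, UA and the wobbles GU, UG — 6 of 16 ordered pairs,
hence the 3/8 per-pair probability.  A conserved base inside a stem
must be entered as two conserved sites (the sequence constraints
already enforce the pairing); the parser therefore rejects pairs with a
conserved side rather than guessing a hybrid scoring rule.  Pseudoknot
pairs need no special handling and may cross module boundaries.

Frames: the Lran − Lstr spare bases are distributed over the M + 1 gaps
around and between modules (all ≥ 0), giving W = C(Lran − Lstr + M, M);
anchoring pins the leading gap at 0, giving C(Lran − Lstr + M − 1, M − 1).
Module offsets are the cumulative gaps, a nondecreasing M-tuple, and the
scanner enumerates exactly these placements (tested by counting against
the closed form).

The single-frame mutational-distance distribution is the convolution of
binomial(s, 3/4) conserved-site misses with binomial(b, 5/8) pair
misses; its m = 0 mass is pinned to q = (1/4)^s(3/8)^b exactly and the
rounding residue is spread over m ≥ 1.  The W-frame distribution uses
the tail identity P_W(m) = g(m)^W − g(m+1)^W, which treats frames as
independent.

**The frame-independence approximation is biased, and the package
measures that bias.**  Placements that differ only in one module's
offset share the other modules' constraints outright, and overlapping
windows share most of their bases, so the effective number of
independent frames is well below W and the measured minimum distance is
stochastically larger than the formula predicts.  Brute force
quantifies this: on the 2-module toy (Lran = 8) exhaustive enumeration
gives P_W(0) = 0.0487 against the formula's 0.0516, and on the
hammerhead-like fixture at Lran = 80 a 10⁶-sample Monte Carlo puts the
bulk of the distribution roughly one unit of m to the right of the
formula (e.g. ~0.05 measured vs 0.13 predicted at m = 5).  Provable
brackets hold on both sides: q ≤ P_true(0) ≤ Wq (union bound), and the
formula lies in the same bracket.  The formula is therefore a good
order-of-magnitude guide at small m — the regime that matters for
estimating the frequency of functional founders — but not a
percent-level prediction at the bulk, and tests that compare it with
simulated data at Monte-Carlo precision will reject it there.

Scanner implementation: when all pairs are intra-module (true of the
shipped fixtures), per-module mismatch costs depend only on that
module's offset, and minimizing over the nondecreasing offset chain is
a prefix-minimum dynamic programme over offsets — O(n·G·constraints)
for n sequences and G = Lran − Lstr + 1 offsets, which makes 10⁶ × 80 nt
scans take seconds.  Cross-module pairs fall back to explicit placement
enumeration (vectorized across sequences).  All paths agree exactly
with the scalar reference scanner; the exhaustive oracle (guarded at
Lran ≤ 12) reproduces the single-frame closed form to rounding when
Lran = Lstr.

Structure fixtures: the three ribozyme fixtures encode the constraint
*counts* (Lstr, s, b, M, anchoring) of the hammerhead, twister and
self-triphosphorylation motifs at convenient coordinates, with pairs
placed inside modules; every closed-form quantity depends only on the
counts.  Monte-Carlo and exhaustive results do depend on positions, so
those are reported as properties of the fixture, not of the natural
motifs.

Monte Carlo default: 10⁶ samples, chunked; distances rarer than a few
times 1/n are unresolvable, so the exact-match tail (q ~ 10⁻¹²) is out
of reach at desk scale and only the bulk is measurable.

## Cluster evolution

Each of n clusters holds three sequence classes at mutational distance
m = 0, 1, 2 with rates k₀ ≥ k₁ ≥ k₂ and amplitudes A₀ ≥ A₁ ≥ A₂.
Default parameter draws: k₀ ~ U(0.5, 1), A₀ ~ U(0.8, 1), each step
divides the rate by U(2, 4) and subtracts U(0, 0.2) from the amplitude.
One seed governs the draws; the dynamics are deterministic given the
parameters.

A round is selection (the standard recursion per class) followed by
mutation flow: a fraction p_ben (default 10⁻⁴) of the post-selection
class-2 mass moves to class 1, and of class 1 to class 0, but only
where the source class's post-selection frequency exceeds
p_min = 1/(N_tot·C·p_ben) (default 10⁻¹⁰) — below that threshold the
expected number of beneficially mutated copies among the N_tot·C PCR
products is < 1, so flow is switched off entirely rather than scaled.
The gate tests the post-selection (primed) frequencies.  The update is
a within-cluster stochastic-matrix reshuffle, so total frequency is
conserved to 10⁻¹²; with p_ben = 0 the model reduces exactly to the
species simulator on 3n species (regression-tested).  Deleterious
mutations are omitted: selection keeps them rare, so they perturb
cluster frequencies negligibly, whereas a beneficial variant sweeps its
cluster and changes its fitness.

Fitness is A·k (selection at small τ is proportional to it); cluster
mean fitness is the frequency-weighted mean over the three classes.
The correlation report emits both Pearson and Spearman coefficients of
mean fitness against log₁₀ frequency (frequencies span many decades, so
linear correlation on raw frequencies would be meaningless) and against
the current- and next-round enrichment factors; the rank coefficient is
included to be scale-free since no particular correlation measure is
canonical here.  Zero-variance inputs are flagged as degenerate (NaN)
rather than silently reported as 0.

Standard run sizes: 50 clusters, 13 rounds (report at round 12), the
stepped τ schedule; 20 parameter seeds for the correlation-gap
property.  These complete in well under a second each.

## PCR arithmetic

C = λ^ncyc copies per recovered molecule (λ = 2 for perfect doubling,
λ ≈ 1.6 realistic).  Note 1.6¹⁴ = 721 and 1.6¹⁵ = 1153: a λ = 1.6
protocol needs about 15 cycles to reach the C ≈ 1000 regime.  The
per-copy beneficial-mutation probability for m₁ correctable sites out
of s at error rate u is m₁(u/3)(1 − u/3)^(m₁−1)(1 − u)^(s−m₁) ≈ m₁u/3.

## Scope and limitations

- No thermodynamic folding: the amplitude A is the only concession to
  misfolding, and q ignores the stability of the target structure and
  competing structures formed by the same sequence.
- Only the first round is stochastic; later rounds are deterministic
  frequency recursions, justified because copy numbers grow >10-fold
  per round.
- Mutation classes are abstract distance levels, not explicit
  sequences; no PCR chimeras or per-cycle stochasticity.
- The cofactor comparison is limited to the two-step counter-selection
  protocol; parallel-line sequencing comparisons are out of scope.
- The synthetic scenarios emulate idealized selections (uniform Q,
  first-order kinetics, fixed per-species parameters); passing tests
  demonstrate the internal consistency of the model and its closed
  forms, not the behaviour of any particular laboratory system.
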