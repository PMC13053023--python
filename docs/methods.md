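# Methods

This note documents the models implemented by `modals_effcomm`, the
parameters that matter, the numerical and design choices made where the
procedure was genuinely open, and what the synthetic-data generators do and
do not emulate.

## Meaning space

Force and flavor are treated as properties of contexts of use; a meaning
point is one (force, flavor) pair and a modal's meaning is a non-empty set
of points. The default grid is forces {weak, strong} × flavors {epistemic,
deontic, circumstantial} (6 points, 63 possible meanings), but the space is
fully configurable — the complexity worked examples, for instance, are
stated over a 2×4 grid that adds a teleological flavor, and both grids are
exercised by the tests. Points are ordered force-major in declared label
order so every enumeration, serialization, and seeded run is reproducible.

Communicative need ℙ(p) is a prior over points. Two builtins: `uniform`,
and `estimated` — a packaged table of relative frequencies of force-flavor
pairs of English modal auxiliaries in an expert-annotated news corpus
(weak: .139/.042/.143, strong: .104/.254/.318 over
epistemic/deontic/circumstantial). Estimating need per language is out of
scope; the prior is a config knob (`informativeness.prior`) accepting a
CSV path. Loading preserves a table verbatim when it sums to 1 within 1e-9
and renormalizes otherwise.

## Boolean-LoT complexity

The representation language has one atom per force and per flavor;
connectives are ∧, ∨, and ¬ **applied to atoms only** (negation of
features, not of arbitrary subformulas). Complexity counts atom
occurrences (literals); connectives are free and a negated atom costs 1 —
the only convention under which a meaning like "everything but
circumstantial" costs a single atom (¬c). This is the Feldman-style
Boolean-complexity convention from concept learning.

The search enumerates denotations by increasing atom count: level 1 holds
all (possibly negated) atoms; level c combines pairs of already-minimal
denotations whose costs sum to c with ∧ and ∨. Any formula splits into two
subformulas whose denotations are achievable at no more than their own
cost, so the first level at which a denotation appears certifies its
minimum. Ties are broken deterministically by canonical enumeration order
(positive atoms before negated, forces before flavors, first-found wins);
nested same-connective arguments are flattened for readable output. The
default cap is 8 atoms; `complexity_table` verifies all 2^n − 1 meanings
are covered and raises the cap (to at most 16) otherwise. Measured maxima:
4 atoms on the 2×3 grid, 6 on the 2×4 grid, so the cap is comfortable.

One consequence worth knowing: on the 2×3 grid the two-flavor meaning
{(w,e),(w,d)} costs **2** atoms (w ∧ ¬c), not 3, because with only three
flavors ¬c and e ∨ d denote the same set. On the 2×4 grid, where the worked
examples live, the same meaning costs 3 (w ∧ (e ∨ d)). The test suite's
independent oracle (an exhaustive two-level DNF/CNF set-cover search)
agrees with the level-wise search on every meaning of the 2×3 grid.

Two alternative complexity measures are provided for robustness analyses:
vocabulary size |L| and vocabulary entropy H(M) = −Σ ℙ(m) log₂ ℙ(m) with
ℙ(m) = Σ_p ℙ(p)ℙ(m|p) under the literal speaker (bits; 0·log 0 = 0; points
no modal covers contribute no mass).

## Informativeness

Expected-utility informativeness follows the signaling-game formulation in
the README. Choices that needed fixing:

- **Speaker over tokens.** ℙ(m|p) is uniform over modal *tokens* that can
  express p. Synonyms therefore split and shift speaker mass: duplicating a
  single modal changes I(L) slightly whenever a point has non-synonymous
  alternatives (doubling the entire multiset does not). Tests assert the
  invariant in its correct (whole-multiset) form.
- **Inexpressible points** (no modal covers them) get an all-zero speaker
  row, flagged on the channel tables, and contribute 0 to I — incomplete
  coverage is penalized rather than renormalized away.
- **Pragmatic agents.** The speaker is softmax-rational in the log
  probability that the *literal* listener recovers p: weights
  ℙ_lit(p|m)^α, with α = 1 by default (a speaker neither perfectly
  rational nor incompetent); α = 0 flattens to uniform over all modals.
  The pragmatic listener is the Bayesian posterior from the literal speaker
  **including the prior** — the posterior is what makes the listener
  Bayesian-optimal, and without the prior it is not a proper distribution.
  Pragmatic informativeness pairs the pragmatic speaker with the pragmatic
  listener. Only first-level recursion (S₁/L₁) is implemented.
- **Information Bottleneck.** The speaker's probabilistic meaning is
  ℙ(p′|p) ∝ exp(s·u(p,p′)) with the graded utility and a scale knob s
  (default 1.0, exposed because similarity kernels of this family are
  scale-parameterized). The listener's inferred meaning is the posterior
  over intended points convolved with the same kernel,
  ℙ(p′|m) = Σ_p ℙ(p|m) ℙ(p′|p); the bare posterior over p′ would be zero
  outside 〚m〛 and would drive the KL cost to +∞ for every modal short of
  full coverage, which no finite reported IB quantity could survive.
  Cost_IB is the expected KL divergence in bits; accuracy is
  I(P;P′) − Cost_IB. Infinite KL terms (possible under exotic kernels) are
  surfaced, never clipped.

All information quantities use log base 2.

## Frontier estimation and optimality

The evolutionary search is mutation-only with dominance elitism. Each
generation keeps the non-dominated set and refills the population with
offspring, allocated round-robin across dominant parents; each offspring
receives 1..5 mutations drawn uniformly from five operators: add a modal,
remove a modal, interchange a modal, add a point to a modal, remove a point
from a modal. Operators that would violate invariants (empty language,
empty meaning, nothing to add) are re-sampled. Selection happens
`generations` times with breeding in between, so a one-generation run
returns exactly the seed pool's Pareto front. Defaults are population 2000
and 200 generations; the packaged experiments and tests run a scaled-down
setting (population 200, 50 generations, ≥ 5000 stratified samples), which
already yields perfectly IFF-natural frontiers on the 2×3 grid across
seeds. Exploration of the whole plane additionally runs the search toward
each of the four min/max corners and pools the explored languages.

Optimality is 1 − min-distance to a frontier *point* (no interpolation),
computed on the unit square: complexity is min-max normalized by the pooled
sample's observed range; utility-based cost is already in [0,1] (IB cost,
in bits, is range-normalized instead); the distance is divided by the
metric's maximum on the square (√2 Euclidean, 2 Manhattan). Frontier
members score exactly 1. Note the normalization makes Manhattan optimality
the *more generous* score (d_L1 ≤ √2·d_L2 implies d_L1/2 ≤ d_L2/√2). The
frontier used for scoring is the minimize-both run's final dominant set.

## Sampling and the naturalistic generator

The stratified sampler draws languages with an exact composition: sizes
1–10 (ten being the largest attested inventory) crossed with IFF counts
0..size, uniform with replacement within the IFF (21 of 63) and non-IFF
(42) meaning subsets — uniformity is the minimal assumption where no
weighting is given. The pool is deduplicated as multisets of meanings
(labels carry no content) and a root seed fans out per-cell child seeds, so
pools are byte-reproducible regardless of cell order. Exhaustive
enumeration is never attempted (there are > 5.3 × 10^11 ten-modal
multisets).

The naturalistic generator stands in for attested inventories where the
typological database is not available: sizes 2–10, meanings drawn as IFF
rectangles F × G with small axis subsets favored (axis size k with weight
2^−k), an `iff_bias` of 0.95 (occasional non-IFF meanings, since real
inventories are IFF-heavy but not perfect), and synonyms injected by
replacing Binomial(size−1, 0.15) slots with duplicates — mirroring the
documented synonymy of inventories like Mandarin (three modals for strong
epistemic) and Tlingit. What it does **not** emulate: per-language need
distributions, morphosyntactic realization, tense/aspect interactions, or
any correlation between meaning and form frequency. Passing tests
therefore show that the *pipeline* recovers the efficiency signature from
inventories with the assumed statistical structure, not that any particular
natural language has it; running on real judgment tables requires only the
`typology_io` CSV dialect (language_name, expression, force, flavor,
can_express).

## Statistics

Naturalness correlations are Pearson r over the unique languages of the
measured pool, p from the t transform with N − 2 df; constant columns are
reported as undefined rather than erroring. Group comparisons report mean
simplicity (1 − normalized complexity), informativeness (1 − normalized
cost), and optimality for the natural-style subset vs. the whole pool, with
a one-sided one-sample t-test of the subset against the population mean.
p-values below 1e-10 display as "~0". The robustness grid runs 14
conditions from one config matrix: 8 expected-utility conditions (2 priors
× 2 agent kinds × 2 utilities) plus {expected-utility, IB} informativeness
× {MDL, entropy, size} complexity, one summary row each. At the scaled-down
settings every expected-utility condition and both MDL conditions produce
perfectly natural frontiers; the vocabulary-entropy/size conditions break
that pattern, and the tests assert that direction of contrast rather than
exact magnitudes.

## Known limitations

- Minimality certificates hold relative to the atom-negation grammar; the
  oracle cross-check covers the 2×3 grid exhaustively and the 2×4 grid by
  spot checks.
- Optimality depends on the pooled normalization range, so scores are
  comparable within a run, not across runs with different pools.
- The IB measures are evaluated for given lexicons only; no IB encoder
  optimization (deterministic annealing) is performed.
- Evolution is heuristic: the frontier is an estimate from below, and
  desk-scale runs use smaller populations than the defaults.
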