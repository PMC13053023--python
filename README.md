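# modals-effcomm

An efficient-communication analysis of modal semantic typology.

Modals (*can*, *must*, *might*, …) vary across languages in which
combinations of **force** (weak possibility vs. strong necessity) and
**flavor** (epistemic, deontic, circumstantial, …) a single word can
express. Yet the variation is constrained: attested modals overwhelmingly
satisfy the **Independence of Force and Flavor (IFF)** universal — a
modal's meaning 〚m〛 equals the Cartesian product fo(m) × fl(m) of the
forces and flavors it can express. This package tests whether that
constraint, and modal typology more broadly, can be explained by a pressure
to trade off **cognitive simplicity** against **informative communication**.
It is written for computational-cognitive-science and semantic-typology
researchers who want to run, extend, or stress such analyses.

## The model

A *language* is a multiset of modals; each modal's meaning is a non-empty
set of force-flavor pairs from a configurable grid (default 2 forces × 3
flavors, 6 meaning points).

**Complexity** is minimum description length in a Boolean language of
thought with one atom per force and flavor, connectives ∧, ∨, and ¬ applied
to atoms. A meaning's complexity is the atom count of its shortest denoting
formula (found by exhaustive enumeration by increasing length, certified
minimal); a language's complexity is the sum over its modals:

    Comp(L) = Σ_{m∈L} min { len(φ) : φ ∈ LoT, 〚φ〛 = 〚m〛 }

**Informativeness** is the expected utility of a one-shot signaling game
under a communicative-need prior ℙ(p) over meaning points:

    I(L) = Σ_p ℙ(p) Σ_m ℙ(m|p) Σ_{p′} ℙ(p′|m) · u(p, p′),   Cost(L) = 1 − I(L)

with literal agents (speaker uniform over modals that can express p,
listener uniform over 〚m〛) and a graded utility giving half credit for
each correctly recovered axis. Robustness variants include a binary
utility, a uniform prior, Rational-Speech-Act pragmatic agents
(softmax-rational speaker at temperature α, Bayesian listener), an
Information-Bottleneck cost (expected KL divergence between similarity-based
speaker meanings and the listener's inferred meaning, in bits), and
vocabulary-size / vocabulary-entropy complexity.

The **Pareto frontier** of the joint (complexity, cost) minimization is
estimated with a mutation-only evolutionary algorithm with dominance
elitism; a language's **optimality** is 1 minus its normalized minimum
distance to the frontier, and its **naturalness** is the fraction of its
modals satisfying IFF.

## Worked example

```python
import modals_effcomm as me

# shortest-formula search on the 2-force x 4-flavor grid
space = me.build_space(["weak", "strong"],
                       ["epistemic", "deontic", "circumstantial", "teleological"])
P = me.MeaningPoint
may = me.ModalMeaning([P("weak", "epistemic"), P("weak", "deontic")])
res = me.minimal_formula(may, space)
print(res.formula.to_string(abbrev=space.atom_names()), res.complexity)
# -> w ∧ (e ∨ d)  3        (the factored form beats the 4-atom normal form)

# a small experiment on the default 2x3 space
result = me.run_experiment({"sampling": {"n_per_cell": 100},
                            "evolution": {"population": 200, "generations": 50},
                            "naturalistic": {"n": 27}}, seed=0)
print(len(result.pool), len(result.frontier))
print(result.correlations[["property", "r"]])
```

The run above measures 8960 languages (stratified samples over sizes 1–10
crossed with IFF counts, 27 synthetic attested-style inventories, and
everything discovered by the evolutionary search), estimates a frontier of
128 languages — every one of them perfectly IFF-natural — and prints the
naturalness correlations:

```
       property        r
     simplicity 0.326
informativeness 0.523
     optimality 0.444
```

i.e. the more of a language's modals satisfy IFF, the simpler, more
informative, and closer to optimal it is. The accompanying group comparison
shows the attested-style inventories scoring higher mean optimality than
the population (0.836 vs 0.775, one-sided p ≈ 1.5e-4).

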