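"""Informativeness and communicative cost of modal lexicons.

Communication is modeled as a one-shot signaling game: nature draws a
force-flavor pair p from the need distribution, a speaker picks a modal m,
and a listener guesses a pair p'.  Informativeness is the expected utility

    I(L) = sum_p P(p) sum_m P(m|p) sum_p' P(p'|m) u(p, p'),

with cost(L) = 1 - I(L).  The *graded* utility gives half credit for each
correctly recovered axis (force, flavor); the *binary* utility pays only for
exact recovery.  Literal agents are uniform: the speaker over the modals
that can express p, the listener over the points the modal can express.
Pragmatic agents follow the Rational Speech Act pattern: the speaker is
softmax-rational (temperature alpha) in the log probability that the
literal listener recovers p, and the pragmatic listener is the Bayesian
posterior from the literal speaker and the prior.

The Information Bottleneck variant treats the speaker's intention as a
probabilistic meaning P(p'|p) proportional to exp(u(p,p')) and scores the
expected KL divergence (in bits) to the Bayesian listener's inferred
meaning; accuracy is I(P;P') minus that cost.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .meaning_space import MeaningPoint, MeaningSpace, NeedDistribution
from .typology_io import Language

__all__ = [
    "AgentConfig",
    "ChannelTables",
    "graded_utility",
    "binary_utility",
    "utility_matrix",
    "literal_channels",
    "informativeness",
    "communicative_cost",
    "pragmatic_speaker",
    "pragmatic_listener",
    "ib_cost",
    "ib_accuracy",
    "ib_quantities",
]


@dataclass(frozen=True)
class AgentConfig:
    """Speaker/listener model: literal or pragmatic, graded or binary payoff."""

    agent_kind: str = "literal"  # "literal" | "pragmatic"
    utility_kind: str = "graded"  # "graded" | "binary"
    alpha: float = 1.0  # pragmatic-speaker rationality temperature

    def __post_init__(self) -> None:
        if self.agent_kind not in ("literal", "pragmatic"):
            raise ValueError(f"unknown agent kind {self.agent_kind!r}")
        if self.utility_kind not in ("graded", "binary"):
            raise ValueError(f"unknown utility kind {self.utility_kind!r}")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass(frozen=True)
class ChannelTables:
    """Speaker P(m|p) (points x modals) and listener P(p'|m) (modals x points).

    Points no modal can express get an all-zero speaker row; their indices
    are listed in ``inexpressible``.
    """

    speaker: np.ndarray
    listener: np.ndarray
    inexpressible: tuple[int, ...]


def graded_utility(p: MeaningPoint, q: MeaningPoint) -> float:
    """Half credit for each of force and flavor guessed correctly."""
    return 0.5 * (p.force == q.force) + 0.5 * (p.flavor == q.flavor)


def binary_utility(p: MeaningPoint, q: MeaningPoint) -> float:
    """1 iff the guess is exactly the intended pair."""
    return float(p == q)


@lru_cache(maxsize=None)
def utility_matrix(space: MeaningSpace, kind: str = "graded") -> np.ndarray:
    pts = space.points
    if kind == "binary":
        return np.eye(len(pts))
    if kind != "graded":
        raise ValueError(f"unknown utility kind {kind!r}")
    U = np.empty((len(pts), len(pts)))
    for i, p in enumerate(pts):
        for j, q in enumerate(pts):
            U[i, j] = graded_utility(p, q)
    return U


def _membership(L: Language, space: MeaningSpace) -> np.ndarray:
    """0/1 matrix (modals x points) of which points each modal can express."""
    B = np.zeros((L.size, space.size))
    for k, meaning in enumerate(L.meanings()):
        for p in meaning:
            B[k, space.index(p)] = 1.0
    return B


def _literal_from_membership(B: np.ndarray) -> ChannelTables:
    listener = B / B.sum(axis=1, keepdims=True)
    cols = B.sum(axis=0)
    speaker = np.divide(B, cols, out=np.zeros_like(B), where=cols > 0).T
    dead = tuple(int(i) for i in np.flatnonzero(cols == 0))
    return ChannelTables(speaker, listener, dead)


def literal_channels(L: Language, need: NeedDistribution) -> ChannelTables:
    """Uniform literal speaker and listener channels for ``L``.

    The need distribution fixes the active space; the literal channels
    themselves do not depend on it.
    """
    return _literal_from_membership(_membership(L, need.space))


def pragmatic_speaker(L: Language, need: NeedDistribution, alpha: float = 1.0) -> np.ndarray:
    """Softmax-rational speaker P(m|p) built on the literal listener.

    Weight of modal m for point p is P_lit(p|m)^alpha (exp of alpha times
    the log-probability utility); alpha = 0 flattens to uniform over all
    modals, and modals the literal listener never maps to p get zero weight
    for alpha > 0.
    """
    B = _membership(L, need.space)
    lit = _literal_from_membership(B)
    with np.errstate(divide="ignore", invalid="ignore"):
        W = lit.listener.T ** alpha  # (points x modals); 0**0 == 1
    totals = W.sum(axis=1, keepdims=True)
    return np.divide(W, totals, out=np.zeros_like(W), where=totals > 0)


def pragmatic_listener(L: Language, need: NeedDistribution) -> np.ndarray:
    """Bayesian posterior P(p|m) from the literal speaker and the prior."""
    B = _membership(L, need.space)
    lit = _literal_from_membership(B)
    prior = need.as_array()
    W = lit.speaker.T * prior  # (modals x points)
    totals = W.sum(axis=1, keepdims=True)
    return np.divide(W, totals, out=np.zeros_like(W), where=totals > 0)


def _channels(L: Language, need: NeedDistribution, agents: AgentConfig) -> tuple[np.ndarray, np.ndarray]:
    if agents.agent_kind == "literal":
        lit = literal_channels(L, need)
        return lit.speaker, lit.listener
    return pragmatic_speaker(L, need, agents.alpha), pragmatic_listener(L, need)


def informativeness(L: Language, need: NeedDistribution, agents: AgentConfig = AgentConfig()) -> float:
    """Expected communicative utility I(L) in [0, 1]."""
    speaker, listener = _channels(L, need, agents)
    U = utility_matrix(need.space, agents.utility_kind)
    prior = need.as_array()
    per_point = np.einsum("pm,mq,pq->p", speaker, listener, U)
    return float(prior @ per_point)


def communicative_cost(L: Language, need: NeedDistribution, agents: AgentConfig = AgentConfig()) -> float:
    """Cost(L) = 1 - I(L)."""
    return 1.0 - informativeness(L, need, agents)


def _ib_terms(L: Language, need: NeedDistribution, similarity_scale: float) -> tuple[float, float]:
    space = need.space
    prior = need.as_array()
    U = utility_matrix(space, "graded")
    Q = np.exp(similarity_scale * U)
    Q /= Q.sum(axis=1, keepdims=True)  # speaker meaning P(p'|p)

    B = _membership(L, space)
    lit = _literal_from_membership(B)
    W = lit.speaker.T * prior
    totals = W.sum(axis=1, keepdims=True)
    post_p = np.divide(W, totals, out=np.zeros_like(W), where=totals > 0)  # P(p|m)
    post = post_p @ Q  # listener's inferred meaning P(p'|m) = sum_p P(p|m) q(p'|p)

    cost = 0.0
    for p in range(space.size):
        if prior[p] == 0:
            continue
        for m in range(L.size):
            s = lit.speaker[p, m]
            if s == 0:
                continue
            q, r = Q[p], post[m]
            with np.errstate(divide="ignore"):
                terms = np.where(q > 0, q * (np.log2(q) - np.log2(r)), 0.0)
            cost += prior[p] * s * float(terms.sum())

    joint = prior[:, None] * Q
    marg = joint.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mi = np.where(joint > 0, joint * (np.log2(Q) - np.log2(marg)), 0.0)
    return cost, float(mi.sum())


def ib_cost(L: Language, need: NeedDistribution, similarity_scale: float = 1.0) -> float:
    """Information Bottleneck cost in bits.

    Expected KL divergence between the speaker's similarity-based meaning
    P(p'|p) ∝ exp(scale · u(p, p')) and the Bayesian listener's inferred
    meaning, the posterior over intended points convolved with the same
    meaning kernel: P(p'|m) = sum_p P(p|m) q(p'|p).  KL terms where the
    listener assigns zero to a supported point are +inf, surfaced rather
    than clipped.
    """
    cost, _ = _ib_terms(L, need, similarity_scale)
    return cost


def ib_accuracy(L: Language, need: NeedDistribution, similarity_scale: float = 1.0) -> float:
    """IB informativeness (lexicon accuracy) I(M;P') = I(P;P') - Cost_IB, bits."""
    cost, mi = _ib_terms(L, need, similarity_scale)
    return mi - cost


def ib_quantities(L: Language, need: NeedDistribution, similarity_scale: float = 1.0) -> dict[str, float]:
    """Cost_IB, accuracy, and the channel bound I(P;P'), all in bits."""
    cost, mi = _ib_terms(L, need, similarity_scale)
    return {"ib_cost": cost, "ib_accuracy": mi - cost, "mi_bound": mi}
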