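"""Signaling-game informativeness: literal, pragmatic, and IB measures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modals_effcomm import (
    AgentConfig,
    Language,
    MeaningPoint,
    ModalMeaning,
    binary_utility,
    enumerate_meanings,
    graded_utility,
    ib_accuracy,
    ib_cost,
    informativeness,
    literal_channels,
    pragmatic_listener,
    pragmatic_speaker,
    uniform_need,
)

from conftest import language, meaning


def P(fo, fl):
    return MeaningPoint(fo, fl)


def test_graded_utility_scoring():
    assert graded_utility(P("weak", "e"), P("weak", "e")) == 1.0
    assert graded_utility(P("weak", "e"), P("strong", "e")) == 0.5
    assert graded_utility(P("weak", "e"), P("weak", "d")) == 0.5
    assert graded_utility(P("weak", "e"), P("strong", "d")) == 0.0


def test_binary_utility_scoring():
    assert binary_utility(P("weak", "e"), P("weak", "e")) == 1.0
    assert binary_utility(P("weak", "e"), P("weak", "d")) == 0.0


def test_literal_channels(space, need):
    may = meaning(("weak", "epistemic"), ("weak", "deontic"))
    L = language("L", may)
    ch = literal_channels(L, need)
    # listener uniform over the two expressible points
    np.testing.assert_allclose(ch.listener.sum(axis=1), 1.0)
    assert ch.listener[0, space.index(P("weak", "epistemic"))] == 0.5
    # four points are expressible by nothing: zero speaker rows, flagged
    assert len(ch.inexpressible) == 4
    assert np.all(ch.speaker[list(ch.inexpressible)] == 0)
    # two synonyms split the speaker's probability evenly
    twins = language("T", may, may)
    ch2 = literal_channels(twins, need)
    i = space.index(P("weak", "deontic"))
    np.testing.assert_allclose(ch2.speaker[i], [0.5, 0.5])


def test_perfect_language_has_unit_informativeness(space, need, need_est):
    six = language("six", *[meaning((p.force, p.flavor)) for p in space.points])
    for prior in (need, need_est):
        assert informativeness(six, prior) == pytest.approx(1.0)
        assert informativeness(six, prior, AgentConfig(utility_kind="binary")) == pytest.approx(1.0)


def test_single_full_coverage_modal_closed_forms(space, need):
    """One modal covering all six points, uniform prior: the listener's mean
    graded utility is (1 + 2*0.5 + 1*0.5)/6 = 5/12; binary drops to 1/6."""
    full = meaning(*[(p.force, p.flavor) for p in space.points])
    L = language("full", full)
    assert informativeness(L, need) == pytest.approx(5 / 12)
    assert informativeness(L, need, AgentConfig(utility_kind="binary")) == pytest.approx(1 / 6)


def _random_language(space, rng, max_size=6):
    pool = enumerate_meanings(space)
    k = int(rng.integers(1, max_size + 1))
    return language("rand", *(pool[i] for i in rng.integers(len(pool), size=k)))


def test_informativeness_matches_direct_summation(space, need_est):
    """Vectorized I(L) equals the naive triple-loop expectation."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        L = _random_language(space, rng)
        ch = literal_channels(L, need_est)
        expected = 0.0
        for p in space.points:
            for k, m in enumerate(L.meanings()):
                for q in space.points:
                    expected += (
                        need_est[p]
                        * ch.speaker[space.index(p), k]
                        * ch.listener[k, space.index(q)]
                        * graded_utility(p, q)
                    )
        assert informativeness(L, need_est) == pytest.approx(expected)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_informativeness_bounds_and_utility_ordering(space_seed):
    """0 <= I_binary <= I_graded <= 1 for random languages, all agent kinds."""
    from modals_effcomm import default_space

    space = default_space()
    need = uniform_need(space)
    rng = np.random.default_rng(space_seed)
    L = _random_language(space, rng)
    for agents in ("literal", "pragmatic"):
        ib = informativeness(L, need, AgentConfig(agents, "binary"))
        ig = informativeness(L, need, AgentConfig(agents, "graded"))
        assert 0.0 <= ib <= ig <= 1.0 + 1e-12


def test_doubling_the_whole_lexicon_preserves_informativeness(space, need_est):
    """Duplicating every modal leaves the token-uniform speaker's shares,
    hence I(L), unchanged.  (Duplicating a single modal does shift speaker
    mass toward it whenever a point has non-synonymous alternatives, so only
    the whole-multiset version is invariant.)"""
    rng = np.random.default_rng(11)
    for _ in range(10):
        L = _random_language(space, rng)
        doubled = language("dbl", *(L.meanings() + L.meanings()))
        assert informativeness(doubled, need_est) == pytest.approx(informativeness(L, need_est))
    # single-meaning languages are also immune: nothing competes for mass
    solo = language("solo", meaning(("weak", "epistemic")))
    twin = language("twin", meaning(("weak", "epistemic")), meaning(("weak", "epistemic")))
    assert informativeness(twin, need_est) == pytest.approx(informativeness(solo, need_est))


def test_pragmatic_speaker_flat_at_zero_alpha(space, need):
    L = language(
        "L",
        meaning(("weak", "epistemic")),
        meaning(("strong", "deontic"), ("strong", "circumstantial")),
    )
    S0 = pragmatic_speaker(L, need, alpha=0.0)
    np.testing.assert_allclose(S0, 0.5)


def test_pragmatic_speaker_unique_expressor(space, need):
    """If exactly one modal can express p, the speaker always uses it."""
    L = language(
        "L",
        meaning(("weak", "epistemic")),
        meaning(("strong", "deontic")),
    )
    S = pragmatic_speaker(L, need, alpha=1.0)
    assert S[space.index(P("weak", "epistemic"))].tolist() == [1.0, 0.0]
    assert S[space.index(P("strong", "deontic"))].tolist() == [0.0, 1.0]


def test_pragmatic_speaker_odds_follow_listener_probability(space, need):
    """At alpha = 1, P_lit(p|m) = 1/2 vs 1/4 gives 2:1 speaker odds."""
    p = ("weak", "epistemic")
    m_half = meaning(p, ("weak", "deontic"))
    m_quarter = meaning(p, ("weak", "deontic"), ("strong", "deontic"), ("strong", "epistemic"))
    L = language("L", m_half, m_quarter)
    S = pragmatic_speaker(L, need, alpha=1.0)
    row = S[space.index(P(*p))]
    assert row[0] / row[1] == pytest.approx(2.0)
    np.testing.assert_allclose(row.sum(), 1.0)


def test_pragmatic_listener_is_bayes_posterior(space, need_est):
    L = language("L", meaning(("weak", "epistemic"), ("strong", "deontic")))
    post = pragmatic_listener(L, need_est)
    pe = need_est[P("weak", "epistemic")]
    sd = need_est[P("strong", "deontic")]
    assert post[0, space.index(P("weak", "epistemic"))] == pytest.approx(pe / (pe + sd))
    np.testing.assert_allclose(post.sum(axis=1), 1.0)


def test_channel_rows_normalize_where_defined(space, need_est):
    rng = np.random.default_rng(3)
    for _ in range(10):
        L = _random_language(space, rng)
        ch = literal_channels(L, need_est)
        np.testing.assert_allclose(ch.listener.sum(axis=1), 1.0, atol=1e-9)
        sums = ch.speaker.sum(axis=1)
        for i, s in enumerate(sums):
            assert s == pytest.approx(1.0) or i in ch.inexpressible


def test_ib_cost_zero_when_meanings_match(space, need):
    """With a flat similarity kernel (scale 0) the speaker meaning is uniform;
    a single full-coverage modal induces a uniform listener, so KL = 0."""
    full = meaning(*[(p.force, p.flavor) for p in space.points])
    L = language("full", full)
    assert ib_cost(L, need, similarity_scale=0.0) == pytest.approx(0.0)


def test_ib_cost_full_coverage_oracle(space, need):
    """One full-coverage modal, uniform prior: the listener posterior is
    uniform over the six points and every p contributes the same
    KL(q || uniform) with q ∝ (e^1, e^0.5 x3, e^0 x2)."""
    full = meaning(*[(p.force, p.flavor) for p in space.points])
    L = language("full", full)
    w = np.array([math.e] + [math.exp(0.5)] * 3 + [1.0] * 2)
    q = w / w.sum()
    expected = float(np.sum(q * np.log2(q / (1 / 6))))
    assert ib_cost(L, need) == pytest.approx(expected)
    # here I(P;P') = log2(6) - H(q) = KL(q || uniform), so accuracy vanishes:
    # the single signal conveys none of the relevant information
    assert ib_accuracy(L, need) == pytest.approx(0.0, abs=1e-12)


def test_ib_cost_nonnegative(space, need_est):
    rng = np.random.default_rng(5)
    for _ in range(15):
        L = _random_language(space, rng)
        assert ib_cost(L, need_est) >= -1e-12
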